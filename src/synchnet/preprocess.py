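"""Filtering, re-referencing, artifact rejection, windowing and ERP removal."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .config import ArtifactCriteria, FilterSpec, MovingWindowCriterion
from .epochs import EpochSet


@dataclass
class ERPWaveform:
    """Per-condition trial-average trace (channels x samples, microvolts)."""

    values: np.ndarray
    condition: str
    channels: list[str]
    times: np.ndarray
    n_epochs: int


def _design_bandpass(spec: FilterSpec, sfreq: float) -> np.ndarray:
    nyq = sfreq / 2.0
    if spec.high_hz >= nyq:
        raise ValueError(
            f"passband edge {spec.high_hz} Hz at or above Nyquist {nyq} Hz"
        )
    return signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
        fs=sfreq, output="sos",
    )


def bandpass_filter(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Zero-phase Butterworth band-pass along the sample axis.

    Forward-backward application doubles the effective roll-off (an order-2
    design per pass gives 12 dB/oct per band edge) and cancels phase shift.
    """
    sos = _design_bandpass(spec, epochs.sfreq)
    out = epochs.copy()
    if spec.zero_phase:
        out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    else:
        out.data = signal.sosfilt(sos, out.data, axis=-1)
    if spec.notch_hz is not None:
        q = spec.notch_hz / spec.notch_bandwidth_hz
        b, a = signal.iirnotch(spec.notch_hz, q, fs=epochs.sfreq)
        if spec.zero_phase:
            out.data = signal.filtfilt(b, a, out.data, axis=-1)
        else:
            out.data = signal.lfilter(b, a, out.data, axis=-1)
    return out


def rereference(epochs: EpochSet, references: list[str] | tuple[str, ...]) -> EpochSet:
    """Subtract the mean of the reference channels; drop them from the set."""
    refs = list(references)
    missing = [r for r in refs if r not in epochs.channels]
    if missing:
        raise KeyError(f"reference channels not present: {missing}")
    if not refs:
        return epochs.copy()
    ref_idx = [epochs.channels.index(r) for r in refs]
    keep_idx = [i for i, ch in enumerate(epochs.channels) if ch not in refs]
    ref_mean = epochs.data[:, ref_idx].mean(axis=1, keepdims=True)
    data = epochs.data[:, keep_idx] - ref_mean
    return replace(
        epochs,
        data=data,
        channels=[epochs.channels[i] for i in keep_idx],
        conditions=epochs.conditions.copy(),
    )


def _moving_p2p(
    x: np.ndarray, times: np.ndarray, crit: MovingWindowCriterion
) -> np.ndarray:
    """Max peak-to-peak over a moving window; includes a final partial window.

    ``x`` is (..., samples); returns the per-row maximum across windows.
    """
    n = x.shape[-1]
    dt = times[1] - times[0]
    width = max(2, int(round(crit.width_ms / dt)))
    step = max(1, int(round(crit.step_ms / dt)))
    starts = list(range(0, max(1, n - width + 1), step))
    last = n - width
    if last > 0 and starts[-1] != last:
        starts.append(last)  # final partial-step window, conservative
    best = np.zeros(x.shape[:-1])
    for s in starts:
        seg = x[..., s : s + width]
        best = np.maximum(best, seg.max(axis=-1) - seg.min(axis=-1))
    return best


def reject_artifacts(
    epochs: EpochSet,
    criteria: ArtifactCriteria,
    heog: str | None = None,
    veog: str | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs violating any enabled criterion on any applicable channel.

    Criteria (all peak/peak-to-peak amplitudes in microvolts):

    1. EEG moving-window peak-to-peak above ``eeg_p2p.threshold_uv``;
    2. EEG absolute voltage above ``eeg_abs_uv`` at any sample;
    3. HEOG moving-window peak-to-peak above ``heog_p2p.threshold_uv``;
    4. VEOG peak-to-peak inside ``veog_window_ms`` above ``veog_p2p_uv``.

    EOG criteria apply only when the corresponding channel name is given; a
    criterion that is enabled in ``criteria`` but has no channel raises.
    Returns surviving epochs plus a tidy report (epoch, criterion, channel,
    value) of every violation.
    """
    if criteria.heog_p2p is not None and heog is not None and heog not in epochs.channels:
        raise KeyError(f"HEOG channel {heog!r} not present")
    if criteria.veog_p2p_uv is not None and veog is not None and veog not in epochs.channels:
        raise KeyError(f"VEOG channel {veog!r} not present")

    eog = {ch for ch in (heog, veog) if ch is not None}
    eeg_idx = [i for i, ch in enumerate(epochs.channels) if ch not in eog]
    eeg = epochs.data[:, eeg_idx]
    rows: list[dict] = []
    bad = np.zeros(epochs.n_epochs, dtype=bool)

    def flag(mask2d: np.ndarray, values: np.ndarray, criterion: str, chans: list[str]):
        ep_idx, ch_idx = np.nonzero(mask2d)
        for e, c in zip(ep_idx, ch_idx):
            rows.append(
                {
                    "epoch": int(e),
                    "criterion": criterion,
                    "channel": chans[c],
                    "value_uv": float(values[e, c]),
                }
            )
        bad[np.unique(ep_idx)] = True

    eeg_chans = [epochs.channels[i] for i in eeg_idx]
    if criteria.eeg_p2p is not None:
        p2p = _moving_p2p(eeg, epochs.times, criteria.eeg_p2p)
        flag(p2p > criteria.eeg_p2p.threshold_uv, p2p, "eeg_p2p", eeg_chans)
    if criteria.eeg_abs_uv is not None:
        amax = np.abs(eeg).max(axis=-1)
        flag(amax > criteria.eeg_abs_uv, amax, "eeg_abs", eeg_chans)
    if criteria.heog_p2p is not None and heog is not None:
        h = epochs.data[:, [epochs.channel_index(heog)]]
        p2p = _moving_p2p(h, epochs.times, criteria.heog_p2p)
        flag(p2p > criteria.heog_p2p.threshold_uv, p2p, "heog_p2p", [heog])
    if criteria.veog_p2p_uv is not None and veog is not None:
        lo, hi = criteria.veog_window_ms
        sel = (epochs.times >= lo) & (epochs.times < hi)
        v = epochs.data[:, [epochs.channel_index(veog)], :][..., sel]
        p2p = v.max(axis=-1) - v.min(axis=-1)
        flag(p2p > criteria.veog_p2p_uv, p2p, "veog_p2p", [veog])

    report = pd.DataFrame(rows, columns=["epoch", "criterion", "channel", "value_uv"])
    survivors = epochs.select_epochs(np.nonzero(~bad)[0])
    return survivors, report


def compute_erp(epochs: EpochSet, condition: str) -> ERPWaveform:
    """Arithmetic mean over all epochs of one condition."""
    sub = epochs.select_condition(condition)
    return ERPWaveform(
        values=sub.data.mean(axis=0),
        condition=condition,
        channels=list(sub.channels),
        times=sub.times.copy(),
        n_epochs=sub.n_epochs,
    )


def subtract_erp(epochs: EpochSet, erp: ERPWaveform) -> EpochSet:
    """Remove the condition's trial average from each epoch of that condition.

    By construction the per-condition mean of the result is zero at every
    channel and sample; what remains is the induced (non-phase-locked) part.
    """
    if erp.channels != epochs.channels:
        raise ValueError("ERP channels do not match epochs")
    if erp.values.shape[-1] != epochs.n_samples:
        raise ValueError("ERP sample count does not match epochs")
    out = epochs.copy()
    mask = out.conditions == erp.condition
    if not mask.any():
        raise ValueError(f"no epochs of condition {erp.condition!r}")
    out.data[mask] -= erp.values[None, :, :]
    return out


def subtract_all_erps(
    epochs: EpochSet, conditions: tuple[str, ...] | None = None
) -> tuple[EpochSet, dict[str, ERPWaveform]]:
    """Per-condition ERP subtraction for the given (default: all) conditions."""
    conds = conditions if conditions is not None else tuple(epochs.condition_labels())
    erps: dict[str, ERPWaveform] = {}
    out = epochs
    for cond in conds:
        if cond not in epochs.condition_labels():
            continue
        erp = compute_erp(out, cond)
        out = subtract_erp(out, erp)
        erps[cond] = erp
    return out, erps


def extract_window(epochs: EpochSet, window_ms: tuple[float, float]) -> EpochSet:
    """Keep samples with start <= t < end (half-open, ms)."""
    lo, hi = window_ms
    t = epochs.times
    if lo < t[0] - 1e-9 or hi > t[-1] + (t[1] - t[0]) + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}) outside epoch [{t[0]}, {t[-1] + (t[1] - t[0])})"
        )
    sel = (t >= lo - 1e-9) & (t < hi - 1e-9)
    if not sel.any():
        raise ValueError("window selects no samples")
    return replace(
        epochs,
        data=epochs.data[:, :, sel].copy(),
        times=epochs.times[sel].copy(),
        conditions=epochs.conditions.copy(),
    )
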