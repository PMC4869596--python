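"""Hamming-tapered FFT band power and task-related percent change."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .preprocess import extract_window


def periodogram_hamming(x: np.ndarray, sfreq: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided-energy one-sided periodogram of Hamming-tapered rows.

    ``x`` is (..., n) real; returns (freqs, power) where power sums (over
    bins, counting interior bins twice via the one-sided fold) to the energy
    of the tapered signal: sum_k P_k == sum_t (w_t x_t)^2.
    """
    n = x.shape[-1]
    taper = np.hamming(n)
    xw = x * taper
    spec = np.fft.rfft(xw, axis=-1)
    power = np.abs(spec) ** 2 / n
    # fold the negative frequencies into the interior one-sided bins
    if n % 2 == 0:
        power[..., 1:-1] *= 2.0
    else:
        power[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    return freqs, power


def band_power(
    epochs: EpochSet,
    window_ms: tuple[float, float] | None,
    bands: tuple[tuple[str, float, float], ...],
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per condition/channel/band mean spectral power (microvolts squared).

    A Hamming-tapered periodogram is computed per epoch (no zero padding, so
    bin spacing is 1/window s), averaged across all epochs of a condition,
    then averaged over in-band bins with half-open edges [low, high).
    """
    cropped = extract_window(epochs, window_ms) if window_ms is not None else epochs
    duration_s = cropped.n_samples / cropped.sfreq
    lowest = min(lo for _, lo, _ in bands)
    if lowest * duration_s < 2.0:
        raise ValueError(
            f"window of {duration_s:g} s holds fewer than 2 cycles at {lowest:g} Hz"
        )
    freqs, power = periodogram_hamming(cropped.data, cropped.sfreq)
    conds = conditions if conditions is not None else tuple(cropped.condition_labels())
    rows = []
    for cond in conds:
        mask = cropped.conditions == cond
        if not mask.any():
            raise ValueError(f"no epochs with condition {cond!r}")
        mean_power = power[mask].mean(axis=0)  # channels x freqs
        for band_name, lo, hi in bands:
            sel = (freqs >= lo) & (freqs < hi)
            if not sel.any():
                raise ValueError(
                    f"band {band_name!r} [{lo}, {hi}) Hz has no bins at "
                    f"resolution {freqs[1] - freqs[0]:g} Hz"
                )
            bp = mean_power[:, sel].mean(axis=1)
            for ch, value in zip(cropped.channels, bp):
                rows.append(
                    {
                        "subject": cropped.subject,
                        "condition": cond,
                        "channel": ch,
                        "band": band_name,
                        "power_uv2": float(value),
                    }
                )
    return pd.DataFrame(rows)


def percent_change(task: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """100 * (task - reference) / reference per (subject, channel, band)."""
    keys = ["subject", "channel", "band"]
    merged = task.merge(reference, on=keys, suffixes=("_task", "_ref"))
    if len(merged) != len(task):
        raise ValueError("task and reference tables do not align")
    if (merged["power_uv2_ref"] == 0).any():
        raise ZeroDivisionError("zero reference power")
    merged["pct_change"] = (
        100.0
        * (merged["power_uv2_task"] - merged["power_uv2_ref"])
        / merged["power_uv2_ref"]
    )
    return merged[keys + ["condition_task", "condition_ref", "pct_change"]]
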