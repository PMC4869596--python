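"""Instantaneous phase via the analytic signal and mean-phase-coherence PSI.

The synchrony index between two narrowband phase series phi1, phi2 is the
resultant length of the phase-difference distribution,

    rho = sqrt(<cos(phi1 - phi2)>^2 + <sin(phi1 - phi2)>^2),

which is 0 for uniformly scattered phase differences and 1 for perfect 1:1
locking.  Only 1:1 synchrony is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = ["PhaseSeries", "PSIMatrix", "instantaneous_phase", "psi", "psi_matrix"]


@dataclass
class PhaseSeries:
    """Instantaneous phase in (-pi, pi], epochs x channels x samples."""

    phases: np.ndarray
    band: str
    times: np.ndarray
    channels: list[str]
    conditions: np.ndarray
    #: per (epoch, channel) flag for degenerate (all-zero) signals whose
    #: phase is undefined
    degenerate: np.ndarray | None = None


@dataclass
class PSIMatrix:
    """Symmetric channel x channel synchrony matrix in [0, 1], zero diagonal."""

    values: np.ndarray
    channels: list[str]
    band: str
    condition: str | None = None
    subject: str | None = None
    n_epochs: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PSI matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("PSI matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("PSI values must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _band_sos(band: tuple[float, float], sfreq: float, order: int = 4) -> np.ndarray:
    lo, hi = band
    nyq = sfreq / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band ({lo}, {hi}) Hz invalid for fs={sfreq} Hz")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")


def instantaneous_phase(
    epochs: EpochSet,
    band: tuple[float, float] | None,
    band_name: str = "",
    filter_order: int = 4,
) -> PhaseSeries:
    """Angle of the analytic signal of the (optionally band-filtered) epochs.

    The filter and Hilbert transform run over the full epoch so their edge
    transients can be cropped away later; pass ``band=None`` for signals that
    are already narrowband.
    """
    data = epochs.data
    if band is not None:
        sos = _band_sos(band, epochs.sfreq, filter_order)
        data = signal.sosfiltfilt(sos, data, axis=-1)
    degenerate = np.ptp(data, axis=-1) < 1e-12
    analytic = signal.hilbert(data, axis=-1)
    return PhaseSeries(
        phases=np.angle(analytic),
        band=band_name or (f"{band[0]:g}-{band[1]:g}Hz" if band else "broadband"),
        times=epochs.times.copy(),
        channels=list(epochs.channels),
        conditions=epochs.conditions.copy(),
        degenerate=degenerate,
    )


def psi(phase1: np.ndarray, phase2: np.ndarray) -> float:
    """Mean phase coherence of two equal-length phase series."""
    phase1 = np.asarray(phase1, dtype=float)
    phase2 = np.asarray(phase2, dtype=float)
    if phase1.shape != phase2.shape:
        raise ValueError("phase series must have equal length")
    if phase1.size < 2:
        raise ValueError("need at least 2 samples")
    delta = phase1 - phase2
    return float(np.hypot(np.cos(delta).mean(), np.sin(delta).mean()))


def _epoch_psi_matrices(phases: np.ndarray) -> np.ndarray:
    """All-pairs PSI per epoch; phases is (epochs, channels, samples)."""
    z = np.exp(1j * phases)
    n_t = phases.shape[-1]
    # resultant of exp(i(phi_a - phi_b)) over time for every ordered pair
    coher = np.abs(np.einsum("ect,edt->ecd", z, z.conj())) / n_t
    for m in coher:
        np.fill_diagonal(m, 0.0)
    return np.minimum(coher, 1.0)


def psi_matrix(
    epochs: EpochSet,
    band: tuple[float, float] | None,
    band_name: str = "",
    condition: str | None = None,
    window_ms: tuple[float, float] | None = None,
    filter_order: int = 4,
) -> PSIMatrix:
    """Condition-averaged all-pairs PSI matrix for one band.

    Per-epoch phases come from the analytic signal over the full epoch; the
    matrix is computed on the cropped analysis window and averaged across the
    condition's epochs.  Epochs with any degenerate (all-zero) channel are
    rejected rather than silently scored as perfectly synchronous.
    """
    sub = epochs.select_condition(condition) if condition is not None else epochs
    series = instantaneous_phase(sub, band, band_name, filter_order)
    phases = series.phases
    if window_ms is not None:
        lo, hi = window_ms
        sel = (series.times >= lo - 1e-9) & (series.times < hi - 1e-9)
        if not sel.any():
            raise ValueError("analysis window selects no samples")
        phases = phases[:, :, sel]
    if series.degenerate is not None and series.degenerate.any():
        bad = np.nonzero(series.degenerate.any(axis=1))[0]
        raise ValueError(
            f"phase undefined for all-zero signal in epochs {bad.tolist()}"
        )
    per_epoch = _epoch_psi_matrices(phases)
    return PSIMatrix(
        values=per_epoch.mean(axis=0),
        channels=list(sub.channels),
        band=series.band,
        condition=condition,
        subject=sub.subject,
        n_epochs=sub.n_epochs,
    )
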