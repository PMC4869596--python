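"""Coupled-oscillator surrogate EEG with known ground truth.

Each channel is a sum of band-limited oscillations A_b*cos(phi_bc(t)) whose
phase is a jittered linear ramp (Wiener phase noise around a frequency drawn
inside the band).  Channels named by a :class:`~synchnet.config.CouplingSpec`
share a common oscillator: their phase is the linear mix
``(1 - kappa) * phi_independent + kappa * phi_common``, which makes the mean
phase coherence between members tunable from chance level (kappa = 0) to
perfect locking (kappa = 1).  A phase-locked evoked transient (identical in
every epoch of a condition) and white noise are added on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CouplingSpec, SimulationConfig
from .epochs import EpochSet

TWO_PI = 2.0 * np.pi


@dataclass
class GroundTruth:
    """What the simulator actually injected, for parameter-recovery tests."""

    #: the coupling design, one entry per injected common oscillator
    coupling: list[CouplingSpec] = field(default_factory=list)
    #: condition -> evoked waveform (n_samples,), identical across epochs
    evoked: dict[str, np.ndarray] = field(default_factory=dict)
    #: per-epoch artifact flag (filled in by :func:`inject_artifacts`)
    artifact_flags: np.ndarray | None = None


def _evoked_waveform(config: SimulationConfig, times_ms: np.ndarray) -> np.ndarray:
    """Gaussian-windowed cosine transient (fixed latency, phase-locked)."""
    t = times_ms - config.evoked_peak_ms
    envelope = np.exp(-0.5 * (t / config.evoked_width_ms) ** 2)
    return config.evoked_amplitude * envelope * np.cos(
        TWO_PI * config.evoked_freq_hz * t / 1000.0
    )


def _phase_ramp(
    rng: np.random.Generator,
    freqs_hz: np.ndarray,
    t_sec: np.ndarray,
    jitter_sd: float,
) -> np.ndarray:
    """Phase ramps phi0 + 2*pi*f*t plus a Wiener jitter, one row per oscillator."""
    n = freqs_hz.shape[0]
    phi0 = rng.uniform(-np.pi, np.pi, size=n)
    ramp = phi0[:, None] + TWO_PI * freqs_hz[:, None] * t_sec[None, :]
    if jitter_sd > 0:
        ramp = ramp + np.cumsum(
            rng.normal(0.0, jitter_sd, size=(n, t_sec.shape[0])), axis=1
        )
    return ramp


def generate_epochs(config: SimulationConfig) -> tuple[EpochSet, GroundTruth]:
    """Simulate one subject's epochs for all configured conditions.

    Returns the epochs (condition blocks concatenated in config order) and
    the ground truth describing injected couplings and evoked transients.
    Bit-identical for identical config (including seed).
    """
    labels = list(config.labels())
    dt_ms = 1000.0 / config.sampling_rate
    start, stop = config.epoch_window
    n_samples = int(round((stop - start) / dt_ms))
    times = start + dt_ms * np.arange(n_samples)
    t_sec = times / 1000.0

    specs_by: dict[tuple[str, str], list[CouplingSpec]] = {}
    for s in config.coupling_specs:
        specs_by.setdefault((s.condition, s.band), []).append(s)
    truth = GroundTruth(coupling=list(config.coupling_specs))

    root = np.random.SeedSequence(config.seed)
    cond_seeds = root.spawn(len(config.conditions))

    blocks: list[np.ndarray] = []
    cond_labels: list[str] = []
    for cond, seed_seq in zip(config.conditions, cond_seeds):
        rng = np.random.default_rng(seed_seq)
        evoked = None
        if config.evoked_amplitude != 0 and cond != "Baseline":
            evoked = _evoked_waveform(config, times)
            truth.evoked[cond] = evoked
        block = np.zeros((config.n_epochs_per_condition, len(labels), n_samples))
        for ep in range(config.n_epochs_per_condition):
            x = np.zeros((len(labels), n_samples))
            for band_name, lo, hi in config.bands:
                amp = config.band_amplitudes.get(band_name, 1.0)
                freqs = rng.uniform(lo, hi, size=len(labels))
                phases = _phase_ramp(rng, freqs, t_sec, config.phase_jitter_sd)
                for spec in specs_by.get((cond, band_name), []):
                    if spec.kappa == 0:
                        continue
                    f_common = rng.uniform(lo, hi, size=1)
                    common = _phase_ramp(
                        rng, f_common, t_sec, config.phase_jitter_sd
                    )[0]
                    idx = [labels.index(ch) for ch in spec.channel_set]
                    phases[idx] = (
                        (1.0 - spec.kappa) * phases[idx]
                        + spec.kappa * common[None, :]
                    )
                if amp != 0:
                    x += amp * np.cos(phases)
            if evoked is not None:
                x += evoked[None, :]
            if config.noise_sd > 0:
                x += rng.normal(0.0, config.noise_sd, size=x.shape)
            block[ep] = x
        blocks.append(block)
        cond_labels.extend([cond] * config.n_epochs_per_condition)

    epochs = EpochSet(
        data=np.concatenate(blocks, axis=0),
        times=times,
        sfreq=config.sampling_rate,
        channels=labels,
        conditions=np.array(cond_labels, dtype=object),
    )

    if config.artifact_fraction > 0:
        epochs, flags = inject_artifacts(
            epochs,
            fraction=config.artifact_fraction,
            amplitude=config.artifact_amplitude,
            seed=root.spawn(1)[0],
        )
        truth.artifact_flags = flags
    else:
        truth.artifact_flags = np.zeros(epochs.n_epochs, dtype=bool)
    return epochs, truth


def inject_artifacts(
    epochs: EpochSet,
    fraction: float,
    amplitude: float,
    seed: int | np.random.SeedSequence = 0,
    width_ms: float = 10.0,
) -> tuple[EpochSet, np.ndarray]:
    """Add a high-amplitude square transient to ``round(fraction * n)`` epochs.

    The transient is placed on one random channel at a random latency; its
    amplitude should exceed the downstream rejection thresholds being
    exercised.  Returns the modified copy and per-epoch flags.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = epochs.copy()
    n_flag = int(round(fraction * epochs.n_epochs))
    flags = np.zeros(epochs.n_epochs, dtype=bool)
    if n_flag == 0:
        return out, flags
    rng = np.random.default_rng(seed)
    chosen = rng.choice(epochs.n_epochs, size=n_flag, replace=False)
    width = max(1, int(round(width_ms * epochs.sfreq / 1000.0)))
    for ep in chosen:
        ch = int(rng.integers(epochs.n_channels))
        t0 = int(rng.integers(0, max(1, epochs.n_samples - width)))
        out.data[ep, ch, t0 : t0 + width] += amplitude
        flags[ep] = True
    return out, flags
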