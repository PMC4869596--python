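"""Configuration dataclasses and structured-text (YAML) round-tripping.

Every analysis constant (filter bands, artifact thresholds, analysis windows,
edge-number sweep, ...) lives here as a default; nothing downstream hard-codes
them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .montage import DEFAULT_ROIS, FRONTAL_CENTRAL_ROI

#: (name, low Hz, high Hz) analysis bands.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
)

#: Edge-number sweep 60..180 step 20 (7 density levels).
DEFAULT_K_SWEEP: tuple[int, ...] = tuple(range(60, 181, 20))

#: Per-band oscillation amplitudes for the simulator (microvolts).
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {"theta": 10.0, "alpha": 8.0, "beta": 5.0}

CONDITIONS: tuple[str, ...] = ("Baseline", "Go", "NoGo")


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling injected among a channel set in one condition and band.

    ``kappa`` is the fraction of a shared oscillator phase mixed into each
    member channel's phase: 0 = independent, 1 = identical phases.
    """

    condition: str
    band: str
    channel_set: tuple[str, ...]
    kappa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.kappa > 0 and len(self.channel_set) == 0:
            raise ValueError("coupling spec with kappa > 0 needs a channel set")


@dataclass
class SimulationConfig:
    """Ground-truth simulator settings (28-channel, 1 kHz epochs by default)."""

    n_channels: int = 28
    channel_labels: tuple[str, ...] | None = None
    sampling_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-200.0, 800.0)
    n_epochs_per_condition: int = 30
    conditions: tuple[str, ...] = CONDITIONS
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    coupling_specs: tuple[CouplingSpec, ...] = ()
    evoked_amplitude: float = 0.0
    evoked_freq_hz: float = 5.0
    evoked_peak_ms: float = 350.0
    evoked_width_ms: float = 80.0
    noise_sd: float = 5.0
    phase_jitter_sd: float = 0.05
    artifact_fraction: float = 0.0
    artifact_amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch window start must precede end")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must be in [0, 1]")
        if self.channel_labels is not None:
            self.channel_labels = tuple(self.channel_labels)
            if len(self.channel_labels) != self.n_channels:
                raise ValueError("channel_labels length must equal n_channels")
            if len(set(self.channel_labels)) != self.n_channels:
                raise ValueError("channel labels must be unique")
        band_names = {b[0] for b in self.bands}
        montage = set(self.labels())
        for spec in self.coupling_specs:
            if spec.band not in band_names:
                raise ValueError(f"coupling spec references unknown band {spec.band!r}")
            extra = set(spec.channel_set) - montage
            if extra:
                raise ValueError(
                    f"coupling spec channels not in montage: {sorted(extra)}"
                )

    def labels(self) -> tuple[str, ...]:
        if self.channel_labels is not None:
            return self.channel_labels
        from .montage import default_montage

        analysis = default_montage().analysis_channels()
        if self.n_channels <= len(analysis):
            return tuple(analysis[: self.n_channels])
        return tuple(f"CH{i + 1}" for i in range(self.n_channels))


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass (order per pass; applied forward-backward)."""

    low_hz: float = 0.1
    high_hz: float = 40.0
    order: int = 2
    zero_phase: bool = True
    notch_hz: float | None = None
    notch_bandwidth_hz: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low < high")


@dataclass(frozen=True)
class MovingWindowCriterion:
    threshold_uv: float
    width_ms: float
    step_ms: float

    def __post_init__(self) -> None:
        if self.threshold_uv <= 0 or self.width_ms <= 0 or self.step_ms <= 0:
            raise ValueError("moving-window criterion values must be positive")


@dataclass(frozen=True)
class ArtifactCriteria:
    """Epoch rejection thresholds (microvolts)."""

    eeg_p2p: MovingWindowCriterion = MovingWindowCriterion(150.0, 200.0, 50.0)
    eeg_abs_uv: float = 100.0
    heog_p2p: MovingWindowCriterion | None = MovingWindowCriterion(40.0, 400.0, 10.0)
    veog_window_ms: tuple[float, float] = (-200.0, 200.0)
    veog_p2p_uv: float | None = 50.0


@dataclass
class PipelineConfig:
    """End-to-end analysis settings."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    artifact: ArtifactCriteria = field(default_factory=ArtifactCriteria)
    band_filter_order: int = 4
    analysis_window_ms: tuple[float, float] = (200.0, 700.0)
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0)
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    k_sweep: tuple[int, ...] = DEFAULT_K_SWEEP
    n_random_networks: int = 20
    degree_threshold_k: int = 120
    rois: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ROIS)
    )
    erp_subtract_conditions: tuple[str, ...] = ("Go", "NoGo")
    clustering_mode: str = "onnela"
    path_length_mode: str = "harmonic"
    relative_change_mode: str = "symmetric"
    alpha: float = 0.05
    min_significant_levels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random_networks < 1:
            raise ValueError("n_random_networks must be >= 1")
        if any(k <= 0 for k in self.k_sweep):
            raise ValueError("edge numbers must be positive")

    def max_edges(self, n_nodes: int) -> int:
        return n_nodes * (n_nodes - 1) // 2

    def validate_sweep(self, n_nodes: int) -> None:
        m = self.max_edges(n_nodes)
        bad = [k for k in self.k_sweep if k > m]
        if bad:
            raise ValueError(f"edge numbers exceed n(n-1)/2={m}: {bad}")


# -- YAML round-trip ---------------------------------------------------------


def _coupling_from_dict(d: dict) -> CouplingSpec:
    return CouplingSpec(
        condition=d["condition"],
        band=d["band"],
        channel_set=tuple(d["channel_set"]),
        kappa=float(d["kappa"]),
    )


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "coupling_specs" in d:
        d["coupling_specs"] = tuple(
            _coupling_from_dict(c) for c in d["coupling_specs"]
        )
    for key in ("epoch_window", "conditions", "channel_labels"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if "bands" in d:
        d["bands"] = tuple((b[0], float(b[1]), float(b[2])) for b in d["bands"])
    return SimulationConfig(**d)


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "filter" in d:
        d["filter"] = FilterSpec(**d["filter"])
    if "artifact" in d:
        a = dict(d["artifact"])
        for key in ("eeg_p2p", "heog_p2p"):
            if a.get(key) is not None:
                a[key] = MovingWindowCriterion(**a[key])
        if a.get("veog_window_ms") is not None:
            a["veog_window_ms"] = tuple(a["veog_window_ms"])
        d["artifact"] = ArtifactCriteria(**a)
    for key in (
        "analysis_window_ms",
        "baseline_window_ms",
        "erp_subtract_conditions",
        "k_sweep",
    ):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if "bands" in d:
        d["bands"] = tuple((b[0], float(b[1]), float(b[2])) for b in d["bands"])
    if "rois" in d:
        d["rois"] = {name: tuple(labels) for name, labels in d["rois"].items()}
    return PipelineConfig(**d)


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into ``simulation`` / ``pipeline`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "simulation" in raw:
        out["simulation"] = simulation_config_from_dict(raw["simulation"])
    if "pipeline" in raw:
        out["pipeline"] = pipeline_config_from_dict(raw["pipeline"])
    return out


def save_config(
    path: str | Path,
    simulation: SimulationConfig | None = None,
    pipeline: PipelineConfig | None = None,
) -> None:
    doc: dict = {}
    if simulation is not None:
        doc["simulation"] = asdict(simulation)
    if pipeline is not None:
        doc["pipeline"] = asdict(pipeline)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def nogo_like_config(kappa: float = 0.6, **kwargs) -> SimulationConfig:
    """Theta coupling among the frontal-central ROI channels (inhibition-like)."""
    specs = (
        CouplingSpec("NoGo", "theta", FRONTAL_CENTRAL_ROI, kappa),
    )
    return SimulationConfig(coupling_specs=specs, **kwargs)


def clustered_config(
    kappa: float = 0.6,
    band: str = "theta",
    condition: str = "Task",
    cluster_size: int = 8,
    stride: int = 4,
    **kwargs,
) -> SimulationConfig:
    """Ring of overlapping coupled channel clusters (lattice-like synchrony).

    Neighbouring clusters share ``cluster_size - stride`` channels, giving the
    banded, locally-clustered synchrony structure for which small-world
    organization (sigma > 1 against degree-preserving rewired nulls) is
    expected.  A single global clique cannot show this: its hub-dominated
    degree sequence forces rewired nulls to rebuild the clique.
    """
    from .montage import default_montage

    labels = default_montage().analysis_channels()
    n = len(labels)
    specs = []
    for start in range(0, n, stride):
        members = tuple(labels[(start + j) % n] for j in range(cluster_size))
        specs.append(CouplingSpec(condition, band, members, kappa))
    return SimulationConfig(
        conditions=(condition,), coupling_specs=tuple(specs), **kwargs
    )


def go_like_config(kappa: float = 0.6, **kwargs) -> SimulationConfig:
    """Beta coupling among the central-parietal ROI channels (execution-like)."""
    from .montage import CENTRAL_PARIETAL_ROI

    specs = (
        CouplingSpec("Go", "beta", CENTRAL_PARIETAL_ROI, kappa),
    )
    return SimulationConfig(coupling_specs=specs, **kwargs)
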