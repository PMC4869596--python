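"""Channel montage, reference definitions and scalp regions of interest."""

from __future__ import annotations

from dataclasses import dataclass, field


#: 30 recording channels of the default 32-electrode cap (FCz = online
#: reference, AFz = ground; both absent from the recorded set).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "FC1", "FC2", "FC5", "FC6",
    "C3", "C4", "Cz", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6",
    "P3", "P4", "P7", "P8", "Pz",
    "O1", "O2", "Oz",
    "TP9", "TP10",
)

#: Bilateral mastoid electrodes used for offline re-referencing.
DEFAULT_REFERENCES: tuple[str, ...] = ("TP9", "TP10")

FRONTAL_CENTRAL_ROI: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "F7", "F8",
    "Fz", "Cz", "FC1", "FC2", "FC5", "FC6",
)

CENTRAL_PARIETAL_ROI: tuple[str, ...] = (
    "C3", "C4", "P3", "P4", "Cz", "Pz", "CP1", "CP2", "CP5", "CP6",
)

DEFAULT_ROIS: dict[str, tuple[str, ...]] = {
    "frontal_central": FRONTAL_CENTRAL_ROI,
    "central_parietal": CENTRAL_PARIETAL_ROI,
}


@dataclass(frozen=True)
class Montage:
    """Ordered recording channels, reference labels and named ROIs.

    Parameters
    ----------
    channels
        Ordered recording-channel labels.
    references
        Subset of ``channels`` used as the offline reference; these are
        dropped from the analysis set after re-referencing.
    rois
        Mapping of ROI name to a set of channel labels.  ROI labels must be
        analysis channels (i.e. not reference channels).
    """

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    references: tuple[str, ...] = DEFAULT_REFERENCES
    rois: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ROIS)
    )

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("montage channel labels must be unique")
        missing = set(self.references) - set(self.channels)
        if missing:
            raise ValueError(f"reference labels not in montage: {sorted(missing)}")
        analysis = set(self.analysis_channels())
        for name, labels in self.rois.items():
            bad = set(labels) - analysis
            if bad:
                raise ValueError(
                    f"ROI {name!r} contains non-analysis labels: {sorted(bad)}"
                )

    def analysis_channels(self) -> list[str]:
        """Recording channels minus the reference labels, order preserved."""
        refs = set(self.references)
        return [ch for ch in self.channels if ch not in refs]

    @property
    def n_analysis(self) -> int:
        return len(self.analysis_channels())

    def roi_channels(self, name: str) -> list[str]:
        try:
            labels = self.rois[name]
        except KeyError:
            raise KeyError(f"unknown ROI {name!r}; have {sorted(self.rois)}") from None
        order = {ch: i for i, ch in enumerate(self.channels)}
        return sorted(labels, key=order.__getitem__)


def default_montage() -> Montage:
    """The 30-channel recording montage with mastoid references and both ROIs."""
    return Montage()
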