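"""Epoched multichannel EEG container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class EpochSet:
    """Labeled epochs x channels x samples array with time axis and metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_epochs, n_channels, n_samples)`` in microvolts.
    times
        Sample times in milliseconds relative to the event, strictly
        increasing and uniformly spaced.
    sfreq
        Sampling rate in Hz.
    channels
        Channel labels, one per data channel.
    conditions
        Per-epoch condition label (e.g. ``Baseline``/``Go``/``NoGo``).
    subject
        Subject identifier.
    group
        Group label (e.g. ``younger``/``older``), optional.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: list[str]
    conditions: np.ndarray
    subject: str = "S01"
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.channels = list(self.channels)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        n_epochs, n_channels, n_samples = self.data.shape
        if len(self.channels) != n_channels:
            raise ValueError(
                f"{len(self.channels)} channel labels for {n_channels} channels"
            )
        if len(set(self.channels)) != n_channels:
            raise ValueError("channel labels must be unique")
        if self.times.shape != (n_samples,):
            raise ValueError("times length must equal sample count")
        if n_samples >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must be uniform")
            if not np.isclose(dt[0], 1000.0 / self.sfreq, rtol=1e-6):
                raise ValueError("time-axis spacing inconsistent with sampling rate")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if self.conditions.shape != (n_epochs,):
            raise ValueError("one condition label per epoch required")

    # -- shape helpers -------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def condition_labels(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(str(c), None)
        return list(seen)

    # -- selection -----------------------------------------------------
    def select_condition(self, condition: str) -> "EpochSet":
        mask = self.conditions == condition
        if not mask.any():
            raise ValueError(f"no epochs with condition {condition!r}")
        return replace(
            self, data=self.data[mask].copy(), conditions=self.conditions[mask].copy()
        )

    def select_epochs(self, index: np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        return replace(
            self, data=self.data[index].copy(), conditions=self.conditions[index].copy()
        )

    def select_channels(self, labels: list[str]) -> "EpochSet":
        missing = [ch for ch in labels if ch not in self.channels]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        idx = [self.channels.index(ch) for ch in labels]
        return replace(self, data=self.data[:, idx].copy(), channels=list(labels))

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            conditions=self.conditions.copy(),
            channels=list(self.channels),
        )
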