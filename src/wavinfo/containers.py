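"""Core data container for labeled, epoched multichannel trials.

A :class:`TrialSet` is the universal input of the pipeline: a stack of
fixed-length epochs (one voltage trace per channel per trial), a class label
per trial, and the sampling metadata needed to convert between samples and
milliseconds. Time ``t = 0`` is stimulus onset; ``t0_ms`` is the epoch start
relative to onset (0 for purely post-stimulus epochs, negative when a
pre-stimulus baseline is included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialSet"]


@dataclass
class TrialSet:
    """Labeled, epoched multichannel recordings.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_trials, n_samples)``. All channels
        share trial alignment and length.
    labels:
        Integer class id per trial, shape ``(n_trials,)``.
    fs_hz:
        Sampling rate in Hz.
    t0_ms:
        Time of the first sample relative to stimulus onset, in ms.
    channels:
        Channel names, one per data row.
    provenance:
        Free-form metadata (seed, generator config, source files).
    """

    data: np.ndarray
    labels: np.ndarray
    fs_hz: float
    t0_ms: float = 0.0
    channels: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:  # single channel convenience
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_channels, n_trials, n_samples), got shape {self.data.shape}"
            )
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or len(self.labels) != self.data.shape[1]:
            raise ValueError(
                f"labels length {self.labels.shape} does not match n_trials {self.data.shape[1]}"
            )
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite values")
        if self.channels is None:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} data channels"
            )

    # -- shape accessors -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_ms(self) -> float:
        return self.n_samples / self.fs_hz * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0_ms + np.arange(self.n_samples) / self.fs_hz * 1000.0

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    # -- manipulation ----------------------------------------------------
    def select_channels(self, which: list[str] | list[int]) -> "TrialSet":
        """Return a TrialSet restricted to the given channels (names or indices)."""
        idx = [self.channels.index(w) if isinstance(w, str) else int(w) for w in which]
        return TrialSet(
            data=self.data[idx].copy(),
            labels=self.labels.copy(),
            fs_hz=self.fs_hz,
            t0_ms=self.t0_ms,
            channels=[self.channels[i] for i in idx],
            provenance=dict(self.provenance),
        )

    def with_labels(self, labels: np.ndarray) -> "TrialSet":
        """Same data with replaced labels (used by permutation tests)."""
        return TrialSet(
            data=self.data,
            labels=np.asarray(labels),
            fs_hz=self.fs_hz,
            t0_ms=self.t0_ms,
            channels=list(self.channels),
            provenance=dict(self.provenance),
        )

    def merge_channels(self, other: "TrialSet") -> "TrialSet":
        """Stack another TrialSet's channels onto this one.

        Both sets must share labels, sampling rate and epoch geometry; channel
        names are de-duplicated by suffixing.
        """
        if other.n_trials != self.n_trials or other.n_samples != self.n_samples:
            raise ValueError("cannot merge TrialSets with different trial geometry")
        if other.fs_hz != self.fs_hz or other.t0_ms != self.t0_ms:
            raise ValueError("cannot merge TrialSets with different sampling metadata")
        if not np.array_equal(other.labels, self.labels):
            raise ValueError("cannot merge TrialSets with different labels")
        names = list(self.channels)
        for name in other.channels:
            new = name
            k = 1
            while new in names:
                new = f"{name}_{k}"
                k += 1
            names.append(new)
        return TrialSet(
            data=np.concatenate([self.data, other.data], axis=0),
            labels=self.labels.copy(),
            fs_hz=self.fs_hz,
            t0_ms=self.t0_ms,
            channels=names,
            provenance=dict(self.provenance),
        )

    def class_indices(self) -> dict[int, np.ndarray]:
        """Trial indices per class, classes in sorted order."""
        return {int(c): np.flatnonzero(self.labels == c) for c in self.classes}
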