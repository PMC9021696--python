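"""In-memory containers for multichannel trial data.

The central object is :class:`TrialSet`, a labelled collection of epochs for
one modality with shape ``(n_trials, n_channels, n_samples)``.  EEG data is in
microvolts, haemoglobin concentration changes in micromolar.  A
:class:`MultimodalSession` bundles the simultaneously recorded EEG and fNIRS
trial sets of one recording session together with the shared class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

#: Integer label coding shared by the whole package.
LABEL_NAMES = {1: "left", 2: "right"}


@dataclass(frozen=True)
class EpochWindow:
    """Half-open time window ``[start, end)`` in seconds relative to the cue."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise InvalidInputError(
                f"epoch window end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class TrialSet:
    """Labelled multichannel epochs for a single modality.

    Parameters
    ----------
    data:
        Array ``(n_trials, n_channels, n_samples)``; must be finite.
    fs:
        Sampling rate in Hz.
    channel_names:
        Unique names, one per channel row.
    t0:
        Time of the first sample in seconds relative to the cue
        (sample ``i`` covers time ``t0 + i / fs``).
    labels:
        Optional integer class per trial (1 = left, 2 = right).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    t0: float = 0.0
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"trial data must be 3-D (trials, channels, samples); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("trial data contains NaN or Inf")
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[1]:
            raise InvalidInputError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidInputError("channel names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.data.shape[0],):
                raise InvalidInputError(
                    f"labels shape {self.labels.shape} does not match {self.data.shape[0]} trials"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the cue."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def sample_slice(self, window: EpochWindow) -> slice:
        """Sample index slice covering ``[window.start, window.end)``."""
        lo = int(np.round((window.start - self.t0) * self.fs))
        hi = int(np.round((window.end - self.t0) * self.fs))
        if lo < 0 or hi > self.n_samples:
            raise InvalidInputError(
                f"window [{window.start}, {window.end}) s outside trial span "
                f"[{self.t0}, {self.t0 + self.n_samples / self.fs}) s"
            )
        return slice(lo, hi)

    def with_data(self, data: np.ndarray, **changes) -> "TrialSet":
        """Copy with new data (and optionally fs / t0 / names / labels)."""
        labels = changes.pop("labels", None if self.labels is None else self.labels.copy())
        return TrialSet(
            data=data,
            fs=changes.pop("fs", self.fs),
            channel_names=changes.pop("channel_names", list(self.channel_names)),
            t0=changes.pop("t0", self.t0),
            labels=labels,
        )

    def subset(self, trial_idx: Sequence[int]) -> "TrialSet":
        idx = np.asarray(trial_idx, dtype=int)
        return self.with_data(
            self.data[idx].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
        )


@dataclass
class GroundTruth:
    """Generator ground truth: per-modality mixing matrices and which latent
    sources carry the class signal."""

    mixing_eeg: np.ndarray
    mixing_fnirs: np.ndarray
    discriminative_sources: np.ndarray = field(
        default_factory=lambda: np.array([0, 1], dtype=int)
    )

    def __post_init__(self) -> None:
        self.mixing_eeg = np.asarray(self.mixing_eeg, dtype=float)
        self.mixing_fnirs = np.asarray(self.mixing_fnirs, dtype=float)
        self.discriminative_sources = np.asarray(self.discriminative_sources, dtype=int)
        for name, a in (("eeg", self.mixing_eeg), ("fnirs", self.mixing_fnirs)):
            if np.linalg.matrix_rank(a) < a.shape[1]:
                raise InvalidInputError(f"{name} mixing matrix is column rank-deficient")


@dataclass
class MultimodalSession:
    """One simultaneously recorded EEG + fNIRS motor-imagery session."""

    eeg: TrialSet
    fnirs_hbo: TrialSet
    fnirs_hbr: TrialSet
    labels: np.ndarray
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.eeg.n_trials
        if self.fnirs_hbo.n_trials != n or self.fnirs_hbr.n_trials != n:
            raise InvalidInputError("EEG and fNIRS trial counts differ")
        if self.labels.shape != (n,):
            raise InvalidInputError(
                f"labels length {self.labels.shape[0]} does not match {n} trials"
            )

    @property
    def n_trials(self) -> int:
        return self.eeg.n_trials

    def subset(self, trial_idx: Sequence[int]) -> "MultimodalSession":
        idx = np.asarray(trial_idx, dtype=int)
        return MultimodalSession(
            eeg=self.eeg.subset(idx),
            fnirs_hbo=self.fnirs_hbo.subset(idx),
            fnirs_hbr=self.fnirs_hbr.subset(idx),
            labels=self.labels[idx].copy(),
            truth=self.truth,
        )
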