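"""ICA-based source-distribution channel matching between EEG and fNIRS.

The transfer method needs the two modalities expressed on channel sets of
equal size whose rows refer to comparable cortical territory.  The matching
procedure runs FastICA per modality, selects the two components that carry
the task:

* EEG: the two components whose class-conditional Welch power spectra (in dB)
  differ most on average over the 8-30 Hz band;
* fNIRS: the two components with the largest |task-window mean - rest-window
  mean| of the source signal (class contrast is too slow/weak in fNIRS, so a
  task-versus-rest contrast is used instead);

then ranks each modality's channels by their absolute mixing weight on the
selected components and pairs the rankings position by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import EpochWindow, TrialSet
from .errors import ConvergenceError, InvalidInputError

MI_BAND = (8.0, 30.0)

#: Default windows for the fNIRS task-versus-rest contrast (seconds relative
#: to the cue, within the 0-10 s fNIRS epoch): the haemodynamic response is
#: near its plateau late in the task and still near baseline just after cue.
FNIRS_TASK_WINDOW = EpochWindow(5.0, 10.0)
FNIRS_REST_WINDOW = EpochWindow(0.0, 2.5)


@dataclass
class ICADecomposition:
    """FastICA result on concatenated trials, components ordered by explained
    variance (mixing-column energy, sources having unit variance)."""

    mixing: np.ndarray          # (n_channels, n_components)
    unmixing: np.ndarray        # (n_components, n_channels)
    sources: np.ndarray         # (n_components, n_trials * n_samples)
    mean: np.ndarray            # per-channel mean removed before unmixing
    channel_names: list[str]
    fs: float
    n_trials: int
    n_samples: int
    t0: float = 0.0
    labels: np.ndarray | None = None
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.component_ids:
            self.component_ids = [f"IC_{i + 1}" for i in range(self.mixing.shape[1])]

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def trial_sources(self) -> np.ndarray:
        """Sources reshaped to (n_components, n_trials, n_samples)."""
        return self.sources.reshape(self.n_components, self.n_trials, self.n_samples)


@dataclass(frozen=True)
class ComponentSelection:
    """Indices of the two selected components and the scores of all.

    Selection is greedy by descending score; a candidate whose mixing column
    is nearly collinear with the first pick (|r| above the diversity
    threshold) is skipped, so the two picks describe distinct topographies
    even when ICA splits one physiological source over several components.
    """

    indices: tuple[int, int]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.indices[0] == self.indices[1]:
            raise InvalidInputError("selected component indices must be distinct")
        if not np.all(np.isfinite(self.scores)):
            raise InvalidInputError("component scores must be finite")


@dataclass(frozen=True)
class ChannelCorrespondence:
    """Ordered one-to-one pairing (eeg_channel, fnirs_channel)."""

    pairs: tuple[tuple[str, str], ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def eeg_channels(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def fnirs_channels(self) -> list[str]:
        return [p[1] for p in self.pairs]


def fastica_decompose(
    trials: TrialSet,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_restarts: int = 5,
    n_components: int | None = None,
) -> ICADecomposition:
    """FastICA (tanh contrast, symmetric updates) on trials concatenated
    along time.

    ``n_components`` below the channel count runs the decomposition on the
    leading PCA subspace — essential for fNIRS, whose slow autocorrelated
    signals carry far fewer effective samples than EEG.  Components are
    re-ordered by explained variance (descending column energy of the mixing
    matrix; sources are unit-variance).  Up to ``n_restarts`` seeded restarts
    are attempted on non-convergence before raising.
    """
    n_tr, n_ch, n_samp = trials.data.shape
    concat = trials.data.transpose(1, 0, 2).reshape(n_ch, -1)
    if concat.shape[1] <= n_ch:
        raise InvalidInputError("need more concatenated samples than channels")
    if n_components is None:
        n_components = n_ch
    if not 2 <= n_components <= n_ch:
        raise InvalidInputError(
            f"n_components must lie in [2, {n_ch}], got {n_components}"
        )

    last_error: Exception | None = None
    sources = None
    for attempt in range(n_restarts):
        ica = FastICA(
            n_components=n_components,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            whiten_solver="svd",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + attempt,
        )
        # accept a completed fit even when the iteration-limit warning
        # fires: the symmetric update's formal tolerance criterion is strict
        # while the estimate is usually serviceable; restart only on hard
        # numerical failure
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            try:
                sources = ica.fit_transform(concat.T).T
                break
            except (ValueError, np.linalg.LinAlgError) as exc:
                last_error = exc
    if sources is None:
        raise ConvergenceError(
            f"FastICA failed within {max_iter} iterations "
            f"after {n_restarts} restarts: {last_error}"
        )

    mixing = ica.mixing_
    unmixing = ica.components_
    order = np.argsort(-np.linalg.norm(mixing, axis=0), kind="stable")
    return ICADecomposition(
        mixing=mixing[:, order],
        unmixing=unmixing[order, :],
        sources=sources[order, :],
        mean=ica.mean_,
        channel_names=list(trials.channel_names),
        fs=trials.fs,
        n_trials=n_tr,
        n_samples=n_samp,
        t0=trials.t0,
        labels=None if trials.labels is None else trials.labels.copy(),
    )


def welch_psd(
    source: np.ndarray, fs: float, segment_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (density scaling) of a 1-D signal."""
    source = np.asarray(source, dtype=float)
    if segment_len > source.size:
        raise InvalidInputError(
            f"segment length {segment_len} exceeds signal length {source.size}"
        )
    freqs, psd = sp_signal.welch(source, fs=fs, nperseg=segment_len)
    return freqs, psd


def _psd_db_by_class(
    decomp: ICADecomposition, labels: np.ndarray, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component class-averaged Welch PSDs in dB, restricted to ``band``.

    Returns (psd_db, freqs) with psd_db shaped (n_components, 2, n_bins).
    """
    srcs = decomp.trial_sources()
    n_comp, n_tr, n_samp = srcs.shape
    nperseg = min(n_samp, 256)
    classes = np.unique(labels)
    freqs, _ = sp_signal.welch(srcs[0, 0], fs=decomp.fs, nperseg=nperseg)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    out = np.empty((n_comp, classes.size, int(keep.sum())))
    for ci, cls in enumerate(classes):
        sel = srcs[:, labels == cls, :]
        _, psd = sp_signal.welch(sel, fs=decomp.fs, nperseg=nperseg, axis=-1)
        mean_psd = psd.mean(axis=1)  # average over trials
        out[:, ci, :] = 10.0 * np.log10(np.maximum(mean_psd[:, keep], 1e-20))
    return out, freqs[keep]


#: Two components are considered duplicates of one source when their mixing
#: columns correlate more strongly than this.
DIVERSITY_THRESHOLD = 0.8


def _top_two(
    scores: np.ndarray,
    mixing: np.ndarray | None = None,
    diversity_threshold: float | None = None,
) -> ComponentSelection:
    """Greedy top-2 by score (ties -> lower index).

    With a mixing matrix and diversity threshold, the second pick skips
    candidates whose mixing column is nearly collinear with the first; if
    every candidate is collinear the plain runner-up is kept.
    """
    order = np.argsort(-scores, kind="stable")
    if mixing is None or diversity_threshold is None:
        return ComponentSelection(indices=(int(order[0]), int(order[1])), scores=scores)
    first = int(order[0])
    second = int(order[1])
    for cand in order[1:]:
        r = np.corrcoef(mixing[:, first], mixing[:, int(cand)])[0, 1]
        if abs(r) <= diversity_threshold:
            second = int(cand)
            break
    return ComponentSelection(indices=(first, second), scores=scores)


def select_discriminative_components_eeg(
    decomp: ICADecomposition,
    labels: np.ndarray | None = None,
    band: tuple[float, float] = MI_BAND,
) -> ComponentSelection:
    """Pick the two components whose left/right PSD curves differ most.

    The score is the mean over frequency bins in ``band`` of the absolute
    difference between the class-conditional Welch PSDs in dB.
    """
    if labels is None:
        labels = decomp.labels
    if labels is None:
        raise InvalidInputError("class labels required for EEG component selection")
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise InvalidInputError("exactly two classes required")
    psd_db, _ = _psd_db_by_class(decomp, labels, band)
    scores = np.abs(psd_db[:, 0, :] - psd_db[:, 1, :]).mean(axis=-1)
    return _top_two(scores, decomp.mixing, DIVERSITY_THRESHOLD)


def select_task_components_fnirs(
    decomp: ICADecomposition,
    task_window: EpochWindow = FNIRS_TASK_WINDOW,
    rest_window: EpochWindow = FNIRS_REST_WINDOW,
) -> ComponentSelection:
    """Pick the two components with the largest task-versus-rest source change.

    Score = |across-trial mean of (task-window mean - rest-window mean)|: the
    grand-average evoked concentration change.  An evoked response has a
    consistent sign across trials, so it accumulates, whereas slow
    physiological noise averages toward zero; taking the absolute value only
    after averaging is what separates the two (and stays invariant to the
    ICA sign ambiguity).
    """
    if not (task_window.end <= rest_window.start or rest_window.end <= task_window.start):
        raise InvalidInputError("task and rest windows must not overlap")
    srcs = decomp.trial_sources()
    ref = TrialSet(
        srcs.transpose(1, 0, 2),
        fs=decomp.fs,
        channel_names=decomp.component_ids,
        t0=decomp.t0,
    )
    task_sl = ref.sample_slice(task_window)
    rest_sl = ref.sample_slice(rest_window)
    diffs = srcs[:, :, task_sl].mean(axis=-1) - srcs[:, :, rest_sl].mean(axis=-1)
    scores = np.abs(diffs.mean(axis=-1))
    return _top_two(scores, decomp.mixing, DIVERSITY_THRESHOLD)


def rank_channels_by_weight(
    decomp: ICADecomposition, selection: ComponentSelection
) -> list[str]:
    """Order all channels by their weight on the selected components.

    Each selected mixing column is normalised to unit maximum absolute value;
    a channel's combined weight is the maximum of its normalised absolute
    weights across the selected components.  Channels are sorted descending,
    ties keeping original channel order (stable sort).
    """
    for idx in selection.indices:
        if not 0 <= idx < decomp.n_components:
            raise InvalidInputError(f"component index {idx} out of range")
    cols = np.abs(decomp.mixing[:, list(selection.indices)])
    peaks = cols.max(axis=0)
    peaks[peaks == 0] = 1.0
    combined = (cols / peaks).max(axis=1)
    order = np.argsort(-combined, kind="stable")
    return [decomp.channel_names[i] for i in order]


def match_channels(
    eeg_rank: list[str], fnirs_rank: list[str], n_pairs: int | None = None
) -> ChannelCorrespondence:
    """Pair the two channel rankings position by position."""
    if n_pairs is None:
        n_pairs = min(len(eeg_rank), len(fnirs_rank))
    if n_pairs > min(len(eeg_rank), len(fnirs_rank)):
        raise InvalidInputError(
            f"n_pairs={n_pairs} exceeds available channels "
            f"({len(eeg_rank)} EEG, {len(fnirs_rank)} fNIRS)"
        )
    pairs = tuple((eeg_rank[i], fnirs_rank[i]) for i in range(n_pairs))
    return ChannelCorrespondence(pairs=pairs)


#: Default fNIRS ICA model order: slow, heavily autocorrelated optical
#: signals support far fewer identifiable components than channels.
FNIRS_N_COMPONENTS = 6

#: Number of independently seeded fNIRS decompositions to compare.
FNIRS_N_RUNS = 3


def best_fnirs_decomposition(
    fnirs_hbo: TrialSet,
    seed: int = 0,
    n_components: int | None = FNIRS_N_COMPONENTS,
    n_runs: int = FNIRS_N_RUNS,
    task_window: EpochWindow = FNIRS_TASK_WINDOW,
    rest_window: EpochWindow = FNIRS_REST_WINDOW,
) -> tuple[ICADecomposition, ComponentSelection]:
    """Task-responsive fNIRS decomposition, best of ``n_runs`` seeded runs.

    FastICA is a non-convex optimisation and occasionally merges the two
    haemodynamic sources into one component.  Each run is scored by the
    smaller evoked-change score of its two (diverse) selected components — a
    run that found two distinct task-responsive topographies scores high,
    a run that merged them leaves a weak runner-up — and the best run wins.
    """
    if n_components is not None:
        n_components = min(n_components, fnirs_hbo.n_channels)
    best: tuple[ICADecomposition, ComponentSelection] | None = None
    best_quality = -np.inf
    for run in range(max(n_runs, 1)):
        dec = fastica_decompose(
            fnirs_hbo, seed=seed + 1000 * run, n_components=n_components
        )
        sel = select_task_components_fnirs(dec, task_window, rest_window)
        quality = min(sel.scores[sel.indices[0]], sel.scores[sel.indices[1]])
        if quality > best_quality:
            best_quality = quality
            best = (dec, sel)
    assert best is not None
    return best


def derive_correspondence(
    eeg: TrialSet,
    fnirs_hbo: TrialSet,
    labels: np.ndarray | None = None,
    seed: int = 0,
    n_pairs: int | None = None,
    task_window: EpochWindow = FNIRS_TASK_WINDOW,
    rest_window: EpochWindow = FNIRS_REST_WINDOW,
    fnirs_n_components: int | None = FNIRS_N_COMPONENTS,
) -> ChannelCorrespondence:
    """Full matching procedure: ICA per modality, component selection,
    channel ranking, positional pairing."""
    eeg_dec = fastica_decompose(eeg, seed=seed)
    fnirs_dec, fnirs_sel = best_fnirs_decomposition(
        fnirs_hbo, seed=seed, n_components=fnirs_n_components,
        task_window=task_window, rest_window=rest_window,
    )
    eeg_sel = select_discriminative_components_eeg(
        eeg_dec, labels if labels is not None else eeg.labels
    )
    eeg_rank = rank_channels_by_weight(eeg_dec, eeg_sel)
    fnirs_rank = rank_channels_by_weight(fnirs_dec, fnirs_sel)
    return match_channels(eeg_rank, fnirs_rank, n_pairs)
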