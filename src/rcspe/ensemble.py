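"""The R-CSP-E ensemble and its comparators.

Rather than tuning the two regularisation parameters, the ensemble evaluates
a fixed grid of (beta, gamma) pairs — by default

    beta  in {0, 0.01, 0.1, 0.2, 0.4, 0.6}
    gamma in {0, 0.001, 0.01, 0.1, 0.2}

(30 pairs) — fits one regularized filter bank per pair with the EEG
covariances mixed into the fNIRS ones, projects each pair's 2m log-variance
features to a single Fisher-LDA score, concatenates the 30 scores into the
trial representation and classifies with K-nearest-neighbours (k = 15,
city-block distance: per-dimension distances summed).

Comparators: classical CSP on one modality (2m features + KNN, no LDA),
R-CSP-CV (single best grid pair chosen by stratified inner cross-validation)
and the channel-wise HbO mean-amplitude baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .containers import EpochWindow, TrialSet
from .errors import DegenerateInputError, InvalidInputError
from .ica_matching import ChannelCorrespondence
from .preprocessing import select_channels
from .rcsp import (
    SpatialFilterBank,
    class_covariances,
    csp_filters,
    log_variance_features,
    regularized_class_covariance,
)

DEFAULT_BETAS = (0.0, 0.01, 0.1, 0.2, 0.4, 0.6)
DEFAULT_GAMMAS = (0.0, 0.001, 0.01, 0.1, 0.2)
DEFAULT_M = 5
DEFAULT_K = 15


@dataclass(frozen=True)
class RegularizationGrid:
    pairs: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.pairs)


def build_grid(
    betas=DEFAULT_BETAS, gammas=DEFAULT_GAMMAS
) -> RegularizationGrid:
    """Cartesian (beta, gamma) grid in beta-major order."""
    betas = tuple(float(b) for b in betas)
    gammas = tuple(float(g) for g in gammas)
    for v in betas + gammas:
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"regularization value {v} outside [0, 1]")
    return RegularizationGrid(pairs=tuple((b, g) for b in betas for g in gammas))


@dataclass
class LDAProjection:
    """One-dimensional Fisher discriminant ``x -> w.x - bias``."""

    weight: np.ndarray
    bias: float
    class_means: dict[int, np.ndarray]

    def project(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weight - self.bias


def fit_lda(features: np.ndarray, labels: np.ndarray) -> LDAProjection:
    """Fisher discriminant with a small ridge on the pooled covariance.

    ``w = (S_p + ridge I)^-1 (mu_1 - mu_2)``, ridge = 1e-6 tr(S_p)/d; bias is
    the projection of the midpoint of the class means.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise InvalidInputError("exactly two classes required")
    if x.shape[0] <= 2:
        raise InvalidInputError("need more than two samples")
    mus, covs, ns = [], [], []
    for cls in classes:
        xi = x[y == cls]
        mus.append(xi.mean(axis=0))
        covs.append(np.cov(xi, rowvar=False, ddof=1))
        ns.append(xi.shape[0])
    d = x.shape[1]
    pooled = (
        (ns[0] - 1) * np.atleast_2d(covs[0]) + (ns[1] - 1) * np.atleast_2d(covs[1])
    ) / (ns[0] + ns[1] - 2)
    ridge = 1e-6 * np.trace(pooled) / d
    try:
        w = np.linalg.solve(pooled + ridge * np.eye(d), mus[0] - mus[1])
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"singular pooled covariance: {exc}") from exc
    if not np.all(np.isfinite(w)):
        raise DegenerateInputError("non-finite LDA weight")
    bias = float(w @ (mus[0] + mus[1]) / 2.0)
    return LDAProjection(
        weight=w, bias=bias,
        class_means={int(c): m for c, m in zip(classes, mus)},
    )


def _validate_k(k: int, n_train: int) -> None:
    if k < 1 or k > n_train:
        raise InvalidInputError(f"k={k} must lie in [1, n_train={n_train}]")
    if k % 2 == 0 or k > 20:
        raise InvalidInputError("k must be an odd number not greater than 20")


def knn_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    k: int,
    metric: str = "cityblock",
) -> np.ndarray:
    """Majority vote over the k nearest training rows.

    Distance ties are broken toward the lower training index (stable sort);
    with two classes and odd k the vote itself cannot tie.
    """
    if metric not in ("cityblock", "euclidean"):
        raise InvalidInputError(f"unsupported metric '{metric}'")
    train_features = np.atleast_2d(train_features)
    test_features = np.atleast_2d(test_features)
    _validate_k(k, train_features.shape[0])
    dists = cdist(test_features, train_features, metric=metric)
    neighbors = np.argsort(dists, axis=1, kind="stable")[:, :k]
    votes = np.asarray(train_labels)[neighbors]
    out = np.empty(test_features.shape[0], dtype=int)
    for i, row in enumerate(votes):
        vals, counts = np.unique(row, return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


@dataclass
class RCSPEModel:
    """Fitted ensemble: one filter bank and LDA projection per grid pair."""

    grid: RegularizationGrid
    banks: list[SpatialFilterBank]
    ldas: list[LDAProjection]
    train_features: np.ndarray      # (n_train, len(grid))
    train_labels: np.ndarray
    k: int = DEFAULT_K
    metric: str = "cityblock"
    correspondence: ChannelCorrespondence | None = None
    m: int = DEFAULT_M


@dataclass
class CSPModel:
    """Classical CSP comparator: raw 2m log-variance features + KNN."""

    bank: SpatialFilterBank
    train_features: np.ndarray
    train_labels: np.ndarray
    k: int = DEFAULT_K
    metric: str = "cityblock"
    selected_pair: tuple[float, float] | None = None
    channel_names: list[str] = field(default_factory=list)


def _matched(trials: TrialSet, names: list[str]) -> TrialSet:
    return select_channels(trials, names)


def fit_rcspe(
    fnirs_train: TrialSet,
    eeg_train: TrialSet,
    correspondence: ChannelCorrespondence,
    grid: RegularizationGrid | None = None,
    m: int = DEFAULT_M,
    k: int = DEFAULT_K,
    metric: str = "cityblock",
) -> RCSPEModel:
    """Fit the full ensemble on matched-channel training data.

    fNIRS is the target modality, EEG the generic one; both are reduced to
    the correspondence's channel lists (in ranked order) before covariance
    estimation.
    """
    if correspondence.n_pairs == 0:
        raise InvalidInputError("empty channel correspondence")
    grid = grid or build_grid()
    fnirs = _matched(fnirs_train, correspondence.fnirs_channels)
    eeg = _matched(eeg_train, correspondence.eeg_channels)
    if fnirs.labels is None or eeg.labels is None:
        raise InvalidInputError("training trial sets must carry labels")
    if not np.array_equal(np.unique(fnirs.labels), np.unique(eeg.labels)):
        raise InvalidInputError("label alphabets differ across modalities")
    target = class_covariances(fnirs, normalize=True)
    generic = class_covariances(eeg, normalize=True)
    classes = target.classes

    banks: list[SpatialFilterBank] = []
    ldas: list[LDAProjection] = []
    columns = []
    for beta, gamma in grid.pairs:
        try:
            sig1 = regularized_class_covariance(target, generic, classes[0], beta, gamma)
            sig2 = regularized_class_covariance(target, generic, classes[1], beta, gamma)
            bank = csp_filters(sig1.matrix, sig2.matrix, m, beta=beta, gamma=gamma)
            feats = log_variance_features(fnirs, bank)
            lda = fit_lda(feats, fnirs.labels)
        except Exception as exc:
            raise type(exc)(f"(beta={beta}, gamma={gamma}): {exc}") from exc
        banks.append(bank)
        ldas.append(lda)
        columns.append(lda.project(feats))
    train_features = np.column_stack(columns)
    _validate_k(k, train_features.shape[0])
    return RCSPEModel(
        grid=grid, banks=banks, ldas=ldas,
        train_features=train_features, train_labels=fnirs.labels.copy(),
        k=k, metric=metric, correspondence=correspondence, m=m,
    )


def transform_rcspe(model: RCSPEModel, trials: TrialSet) -> np.ndarray:
    """Project trials into the (n, A) ensemble feature space."""
    assert model.correspondence is not None
    matched = _matched(trials, model.correspondence.fnirs_channels)
    cols = [
        lda.project(log_variance_features(matched, bank))
        for bank, lda in zip(model.banks, model.ldas)
    ]
    return np.column_stack(cols)


def knn_classify(
    model: RCSPEModel, test_features: np.ndarray, metric: str | None = None
) -> np.ndarray:
    """Classify pre-transformed ensemble features with the model's KNN store."""
    return knn_predict(
        model.train_features, model.train_labels, test_features,
        k=model.k, metric=metric or model.metric,
    )


def predict_rcspe(model: RCSPEModel, trials: TrialSet) -> np.ndarray:
    return knn_classify(model, transform_rcspe(model, trials))


def fit_csp_baseline(
    trials: TrialSet,
    m: int = DEFAULT_M,
    k: int = DEFAULT_K,
    metric: str = "cityblock",
) -> CSPModel:
    """Classical single-modality CSP + KNN on raw log-variance features."""
    covs = class_covariances(trials, normalize=True)
    classes = covs.classes
    bank = csp_filters(covs.average(classes[0]), covs.average(classes[1]), m)
    feats = log_variance_features(trials, bank)
    _validate_k(k, feats.shape[0])
    return CSPModel(
        bank=bank, train_features=feats, train_labels=trials.labels.copy(),
        k=k, metric=metric, channel_names=list(trials.channel_names),
    )


def predict_csp(model: CSPModel, trials: TrialSet) -> np.ndarray:
    if model.channel_names and model.channel_names != trials.channel_names:
        trials = _matched(trials, model.channel_names)
    feats = log_variance_features(trials, model.bank)
    return knn_predict(
        model.train_features, model.train_labels, feats, model.k, model.metric
    )


def fit_rcsp_cv_baseline(
    fnirs_train: TrialSet,
    eeg_train: TrialSet,
    correspondence: ChannelCorrespondence,
    grid: RegularizationGrid | None = None,
    m: int = DEFAULT_M,
    k: int = DEFAULT_K,
    metric: str = "cityblock",
    n_inner_folds: int = 5,
    seed: int = 0,
) -> CSPModel:
    """R-CSP-CV comparator: pick the single grid pair with the best stratified
    inner-CV accuracy on the training set, then refit it on all training data.

    Features are that pair's raw 2m log-variances (no LDA); ties go to the
    first pair in grid order.
    """
    if n_inner_folds < 2:
        raise InvalidInputError("need at least 2 inner folds")
    grid = grid or build_grid()
    fnirs = _matched(fnirs_train, correspondence.fnirs_channels)
    eeg = _matched(eeg_train, correspondence.eeg_channels)
    labels = fnirs.labels
    if labels is None:
        raise InvalidInputError("training trial sets must carry labels")
    skf = StratifiedKFold(n_splits=n_inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(labels.size), labels))

    accs = np.zeros(len(grid))
    for gi, (beta, gamma) in enumerate(grid.pairs):
        correct = total = 0
        for tr_idx, va_idx in splits:
            ftr, fva = fnirs.subset(tr_idx), fnirs.subset(va_idx)
            etr = eeg.subset(tr_idx)
            target = class_covariances(ftr, normalize=True)
            generic = class_covariances(etr, normalize=True)
            cls = target.classes
            s1 = regularized_class_covariance(target, generic, cls[0], beta, gamma)
            s2 = regularized_class_covariance(target, generic, cls[1], beta, gamma)
            bank = csp_filters(s1.matrix, s2.matrix, m, beta=beta, gamma=gamma)
            tr_feats = log_variance_features(ftr, bank)
            va_feats = log_variance_features(fva, bank)
            k_inner = min(k, tr_feats.shape[0] - (1 - tr_feats.shape[0] % 2))
            pred = knn_predict(tr_feats, ftr.labels, va_feats, k_inner, metric)
            correct += int((pred == fva.labels).sum())
            total += va_idx.size
        accs[gi] = correct / total
    best = int(np.argmax(accs))  # argmax takes the first maximum -> grid order
    beta, gamma = grid.pairs[best]

    target = class_covariances(fnirs, normalize=True)
    generic = class_covariances(eeg, normalize=True)
    cls = target.classes
    s1 = regularized_class_covariance(target, generic, cls[0], beta, gamma)
    s2 = regularized_class_covariance(target, generic, cls[1], beta, gamma)
    bank = csp_filters(s1.matrix, s2.matrix, m, beta=beta, gamma=gamma)
    feats = log_variance_features(fnirs, bank)
    return CSPModel(
        bank=bank, train_features=feats, train_labels=labels.copy(),
        k=k, metric=metric, selected_pair=(beta, gamma),
        channel_names=list(fnirs.channel_names),
    )


def hbo_channel_features(
    trials: TrialSet, window: EpochWindow | None = None
) -> np.ndarray:
    """Channel-wise mean HbO amplitude per trial (n_trials, n_channels)."""
    if window is None:
        data = trials.data
    else:
        data = trials.data[:, :, trials.sample_slice(window)]
    return data.mean(axis=-1)


@dataclass
class HbOModel:
    train_features: np.ndarray
    train_labels: np.ndarray
    k: int = DEFAULT_K
    metric: str = "cityblock"
    window: EpochWindow | None = None
    channel_names: list[str] = field(default_factory=list)


def fit_hbo_baseline(
    trials: TrialSet,
    k: int = DEFAULT_K,
    metric: str = "cityblock",
    window: EpochWindow | None = None,
) -> HbOModel:
    feats = hbo_channel_features(trials, window)
    _validate_k(k, feats.shape[0])
    return HbOModel(
        train_features=feats, train_labels=trials.labels.copy(), k=k,
        metric=metric, window=window, channel_names=list(trials.channel_names),
    )


def predict_hbo(model: HbOModel, trials: TrialSet) -> np.ndarray:
    if model.channel_names and model.channel_names != trials.channel_names:
        trials = _matched(trials, model.channel_names)
    feats = hbo_channel_features(trials, model.window)
    return knn_predict(
        model.train_features, model.train_labels, feats, model.k, model.metric
    )
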