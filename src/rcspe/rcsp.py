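"""Common spatial patterns and its cross-modal regularized variant.

Classical CSP builds, from the two class-average spatial covariance matrices
R1 and R2, a bank of spatial filters that maximise the variance of one class
while minimising the other.  The construction whitens the composite
covariance R = R1 + R2 via ``P = L^(-1/2) U^T`` (U, L its eigendecomposition),
diagonalises the whitened class covariance S1 = P R1 P^T (whose eigenvalues
l1 satisfy l1 + l2 = 1 with those of S2), and keeps the m eigenvectors at
each end of the spectrum: ``W = B~^T P`` with 2m rows.

The regularized variant replaces each class covariance with

    Sigma_c(beta, gamma) = (1 - gamma) Omega_c(beta)
                           + gamma / N * tr[Omega_c(beta)] * I,
    Omega_c(beta) = [(1 - beta) R_c + beta Rhat_c]
                    / [(1 - beta) M_c + beta Mhat_c],

where R_c is the sum of (trace-normalised) covariances of the M_c target
trials (fNIRS) and Rhat_c of the Mhat_c generic trials (EEG).  beta mixes in
the generic modality, gamma shrinks toward a scaled identity; gamma-shrinkage
preserves the trace exactly.  Per-trial covariances are trace-normalised so
that microvolt-scale EEG and micromolar-scale fNIRS are commensurable in the
beta-mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialSet
from .errors import DegenerateInputError, InvalidInputError


@dataclass
class CovarianceSet:
    """Per-class summed trial covariances with counts."""

    sum_cov: dict[int, np.ndarray]
    n_trials: dict[int, int]
    normalized: bool = True

    def average(self, class_id: int) -> np.ndarray:
        return self.sum_cov[class_id] / self.n_trials[class_id]

    @property
    def classes(self) -> list[int]:
        return sorted(self.sum_cov)

    @property
    def n_channels(self) -> int:
        return next(iter(self.sum_cov.values())).shape[0]


@dataclass(frozen=True)
class RegularizedCovariance:
    matrix: np.ndarray
    beta: float
    gamma: float


@dataclass
class SpatialFilterBank:
    """2m spatial filters: rows 0..m-1 are the largest-eigenvalue filters,
    rows m..2m-1 the smallest (ascending order within neither half reversed:
    the last m eigenvectors are kept in their spectral order)."""

    W: np.ndarray               # (2m, N)
    m: int
    eigenvalues: np.ndarray     # (2m,) whitened class-1 eigenvalues per row
    beta: float = 0.0
    gamma: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


def trial_covariance(trial: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Spatial covariance ``X X^T`` of one trial, optionally trace-normalised."""
    x = np.asarray(trial, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InvalidInputError("trial must be (channels, samples) with T > 1")
    cov = x @ x.T
    if normalize:
        tr = np.trace(cov)
        if tr == 0:
            raise DegenerateInputError("all-zero trial cannot be trace-normalised")
        cov = cov / tr
    return (cov + cov.T) / 2.0


def class_covariances(trials: TrialSet, normalize: bool = True) -> CovarianceSet:
    """Sum of per-trial covariances per class, with trial counts."""
    if trials.labels is None:
        raise InvalidInputError("labels required to build class covariances")
    classes = np.unique(trials.labels)
    if classes.size < 2:
        raise InvalidInputError("both classes must be present")
    sum_cov: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for cls in classes:
        idx = np.nonzero(trials.labels == cls)[0]
        acc = np.zeros((trials.n_channels, trials.n_channels))
        for i in idx:
            acc += trial_covariance(trials.data[i], normalize=normalize)
        sum_cov[int(cls)] = acc
        counts[int(cls)] = int(idx.size)
    return CovarianceSet(sum_cov=sum_cov, n_trials=counts, normalized=normalize)


def omega_hat(
    target: CovarianceSet, generic: CovarianceSet, class_id: int, beta: float
) -> np.ndarray:
    """Beta-weighted pooled average covariance of one class across modalities."""
    if not 0.0 <= beta <= 1.0:
        raise InvalidInputError("beta must lie in [0, 1]")
    r_c = target.sum_cov[class_id]
    r_hat = generic.sum_cov[class_id]
    if r_c.shape != r_hat.shape:
        raise InvalidInputError(
            f"dimension mismatch: target {r_c.shape} vs generic {r_hat.shape}"
        )
    denom = (1.0 - beta) * target.n_trials[class_id] + beta * generic.n_trials[class_id]
    if denom == 0:
        raise DegenerateInputError("zero effective trial count in beta-mixture")
    return ((1.0 - beta) * r_c + beta * r_hat) / denom


def regularize_covariance(omega: np.ndarray, gamma: float) -> RegularizedCovariance:
    """Shrink toward a scaled identity, preserving the trace exactly."""
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise InvalidInputError("omega must be square")
    if not 0.0 <= gamma <= 1.0:
        raise InvalidInputError("gamma must lie in [0, 1]")
    n = omega.shape[0]
    out = (1.0 - gamma) * omega + (gamma / n) * np.trace(omega) * np.eye(n)
    return RegularizedCovariance(matrix=out, beta=np.nan, gamma=gamma)


def regularized_class_covariance(
    target: CovarianceSet,
    generic: CovarianceSet,
    class_id: int,
    beta: float,
    gamma: float,
) -> RegularizedCovariance:
    """Full regularisation path for one class: beta-mixture then shrinkage."""
    omega = omega_hat(target, generic, class_id, beta)
    reg = regularize_covariance(omega, gamma)
    return RegularizedCovariance(matrix=reg.matrix, beta=beta, gamma=gamma)


def csp_filters(
    sigma1: np.ndarray,
    sigma2: np.ndarray,
    m: int,
    beta: float = 0.0,
    gamma: float = 0.0,
    allow_overlap: bool = False,
) -> SpatialFilterBank:
    """Spatial filter bank from a pair of class covariances.

    Whitens the composite covariance with the square-root convention
    ``P = L^(-1/2) U^T``, diagonalises the whitened class-1 covariance and
    keeps the eigenvectors with the m largest and m smallest eigenvalues.

    ``m`` is clamped to ``floor(N/2)`` so the two halves never overlap; pass
    ``allow_overlap=True`` to keep the requested m even when 2m > N (middle
    eigenvectors then appear in both halves, reproducing a 2m-dimensional
    feature vector on fewer channels).
    """
    s1 = np.asarray(sigma1, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 2 or s1.shape[0] != s1.shape[1]:
        raise InvalidInputError("sigma1 and sigma2 must be square and same shape")
    n = s1.shape[0]
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    if not allow_overlap:
        m = min(m, n // 2)
    elif m > n:
        raise InvalidInputError(f"m={m} exceeds channel count {n}")

    composite = (s1 + s2 + s1.T + s2.T) / 2.0
    evals, evecs = np.linalg.eigh(composite)
    # ascending from eigh -> reorder descending
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    if evals[-1] <= 0:
        raise DegenerateInputError(
            "composite covariance is singular; use gamma > 0 shrinkage"
        )
    if evals[0] / evals[-1] > 1e12:
        ridge = 1e-12 * np.trace(composite) / n
        evals = evals + ridge
    whitening = (evecs / np.sqrt(evals)).T  # P = L^(-1/2) U^T

    w1 = whitening @ s1 @ whitening.T
    w1 = (w1 + w1.T) / 2.0
    lam, b = np.linalg.eigh(w1)
    lam = lam[::-1]
    b = b[:, ::-1]
    sel = list(range(m)) + list(range(n - m, n))
    b_sel = b[:, sel]
    bank_w = b_sel.T @ whitening
    return SpatialFilterBank(
        W=bank_w, m=m, eigenvalues=lam[sel], beta=beta, gamma=gamma
    )


def log_variance_features(trials: TrialSet, bank: SpatialFilterBank) -> np.ndarray:
    """Normalised log-variance of each spatially filtered trial.

    ``f_ij = log( var(w_j x_i) / sum_j var(w_j x_i) )``; per trial the
    exponentials of the features sum to one.
    """
    if bank.n_channels != trials.n_channels:
        raise InvalidInputError(
            f"filter bank expects {bank.n_channels} channels, got {trials.n_channels}"
        )
    feats = np.empty((trials.n_trials, bank.W.shape[0]))
    for i in range(trials.n_trials):
        z = bank.W @ trials.data[i]
        v = z.var(axis=1)
        total = v.sum()
        if total == 0 or np.any(v == 0):
            raise DegenerateInputError(f"zero-variance projected trial {i}")
        feats[i] = np.log(v / total)
    return feats


def spatial_patterns(bank: SpatialFilterBank) -> np.ndarray:
    """Channel-space patterns (N x 2m): the pseudoinverse of the filter matrix,
    so ``W @ patterns = I``."""
    w = bank.W
    if np.linalg.matrix_rank(w) < w.shape[0]:
        raise DegenerateInputError("filter matrix is row rank-deficient")
    return np.linalg.pinv(w)
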