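"""Cross-validated accuracy estimation and published-table statistics.

``kfold_cv`` runs stratified k-fold cross-validation of one or more decoding
methods on a paired session; everything that is fitted — the ICA channel
matching, spatial filters, LDA projections and the KNN training store — is
fitted on the training folds only.

``independent_t_test`` is the pooled-variance two-sample Student's t used to
compare per-subject accuracy columns, and ``reproduce_printed_tables``
recomputes the published column means/SDs and the three pairwise t statistics
from the bundled per-subject accuracy tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .containers import MultimodalSession
from .ensemble import (
    DEFAULT_K,
    DEFAULT_M,
    RegularizationGrid,
    build_grid,
    fit_csp_baseline,
    fit_hbo_baseline,
    fit_rcsp_cv_baseline,
    fit_rcspe,
    predict_csp,
    predict_hbo,
    predict_rcspe,
)
from .errors import DegenerateInputError, InvalidInputError
from .ica_matching import derive_correspondence

METHODS = ("rcspe", "csp", "rcspcv", "hbo")


@dataclass
class CVResult:
    fold_accuracies: list[float]        # percentages
    n_folds: int
    seed: int
    method: str

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int


def kfold_cv(
    session: MultimodalSession,
    methods=("rcspe",),
    n_folds: int = 5,
    seed: int = 0,
    grid: RegularizationGrid | None = None,
    m: int = DEFAULT_M,
    k: int = DEFAULT_K,
    metric: str = "cityblock",
    n_inner_folds: int = 5,
) -> dict[str, CVResult]:
    """Stratified k-fold accuracy (%) per method, sharing folds and the
    per-fold ICA channel matching across methods."""
    if isinstance(methods, str):
        methods = (methods,)
    unknown = [mth for mth in methods if mth not in METHODS]
    if unknown:
        raise InvalidInputError(f"unknown method(s) {unknown}; choose from {METHODS}")
    if n_folds < 2:
        raise InvalidInputError("need at least 2 folds")
    grid = grid or build_grid()
    labels = session.labels
    # k assumes the canonical 48-trial training folds; clamp (to an odd
    # count) when a small session leaves fewer training trials than k
    min_train = labels.size - (labels.size // n_folds + labels.size % n_folds)
    if k > min_train:
        k = max(min_train - (1 - min_train % 2), 1)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_accs: dict[str, list[float]] = {mth: [] for mth in methods}
    needs_matching = any(mth in ("rcspe", "rcspcv") for mth in methods)

    for fold_i, (tr_idx, te_idx) in enumerate(
        skf.split(np.zeros(labels.size), labels)
    ):
        train = session.subset(tr_idx)
        test = session.subset(te_idx)
        if np.unique(train.labels).size < 2 or np.unique(test.labels).size < 2:
            raise DegenerateInputError(f"fold {fold_i}: a class is missing")
        corr = None
        if needs_matching:
            corr = derive_correspondence(
                train.eeg, train.fnirs_hbo, labels=train.labels, seed=seed + fold_i
            )
        for mth in methods:
            if mth == "rcspe":
                model = fit_rcspe(
                    train.fnirs_hbo, train.eeg, corr, grid=grid, m=m, k=k,
                    metric=metric,
                )
                pred = predict_rcspe(model, test.fnirs_hbo)
            elif mth == "csp":
                model = fit_csp_baseline(train.fnirs_hbo, m=m, k=k, metric=metric)
                pred = predict_csp(model, test.fnirs_hbo)
            elif mth == "rcspcv":
                model = fit_rcsp_cv_baseline(
                    train.fnirs_hbo, train.eeg, corr, grid=grid, m=m, k=k,
                    metric=metric, n_inner_folds=n_inner_folds, seed=seed + fold_i,
                )
                pred = predict_csp(model, test.fnirs_hbo)
            else:  # hbo
                model = fit_hbo_baseline(train.fnirs_hbo, k=k, metric=metric)
                pred = predict_hbo(model, test.fnirs_hbo)
            fold_accs[mth].append(100.0 * float((pred == test.labels).mean()))

    return {
        mth: CVResult(
            fold_accuracies=fold_accs[mth], n_folds=n_folds, seed=seed, method=mth
        )
        for mth in methods
    }


def independent_t_test(a, b, welch: bool = False) -> TTestResult:
    """Independent two-sample Student's t (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("need at least two samples per group")
    if not welch and a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(
                t=0.0, df=a.size + b.size - 2, p=1.0,
                mean_a=float(a.mean()), sd_a=0.0,
                mean_b=float(b.mean()), sd_b=0.0, n_a=a.size, n_b=b.size,
            )
        raise DegenerateInputError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = a.size + b.size - 2 if not welch else float(res.df)
    return TTestResult(
        t=float(res.statistic), df=int(df) if not welch else df,
        p=float(res.pvalue),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        n_a=int(a.size), n_b=int(b.size),
    )


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method column mean and sample SD (ddof=1) of an accuracy table."""
    if table.empty or table.shape[1] == 0:
        raise InvalidInputError("empty accuracy table")
    num = table.select_dtypes("number")
    if num.isna().any().any():
        raise InvalidInputError("accuracy table contains missing values")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def load_accuracy_table(name: str) -> pd.DataFrame:
    """Load a bundled per-subject accuracy table ('table1' or 'table2')."""
    fname = f"{name}_accuracies.csv"
    with resources.files("rcspe.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("subject")


def reproduce_printed_tables() -> dict:
    """Recompute the published column statistics and pairwise t-tests from
    the bundled per-subject accuracy tables.

    Returns a report dict with per-table column means/SDs and, for the
    second experiment, the three t-tests of each comparator against the
    ensemble method.
    """
    t1 = load_accuracy_table("table1")
    t2 = load_accuracy_table("table2")
    report: dict = {
        "table1": {
            col: {"mean": float(t1[col].mean()), "sd": float(t1[col].std(ddof=1))}
            for col in t1.columns
        },
        "table2": {
            col: {"mean": float(t2[col].mean()), "sd": float(t2[col].std(ddof=1))}
            for col in t2.columns
        },
        "t_tests": {},
    }
    for col in ("HbO", "CSP", "R-CSP-CV"):
        res = independent_t_test(t2[col], t2["R-CSP-E"])
        report["t_tests"][f"{col}_vs_R-CSP-E"] = {
            "t": res.t, "df": res.df, "p": res.p,
            "mean_a": res.mean_a, "sd_a": res.sd_a,
            "mean_b": res.mean_b, "sd_b": res.sd_b,
        }
    return report
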