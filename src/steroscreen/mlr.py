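"""Model-building machinery: collinearity screening, forward stepwise
multiple linear regression, and validation errors.

The workflow mirrors standard chemometric practice for small QSAR tables:

1. screen the descriptor pool with a *tolerance matrix* — entry (i, j) is
   ``1 - R^2`` of the simple regression of descriptor i on descriptor j —
   and greedily drop one member of every pair with tolerance below 0.1;
2. build the model by forward stepwise selection: at each step enter the
   candidate with the largest F-to-enter while its p-value is below
   ``p_enter`` (default 0.05; no removal step), recording the fraction of
   response variance each entered descriptor adds;
3. validate with an external-test-set RMSEP and/or a contiguous-block
   k-fold cross-validation (rows permuted once with a caller seed, then cut
   into k contiguous blocks; the *fixed* selected term set is refit on each
   training remainder — selection is not re-run per fold).

All fits are ordinary least squares with exact standard errors, overall F
and p; estimates agree with the textbook normal-equations solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qsar import QSARModel

log = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "CVResult",
    "OLSFit",
    "fit_ols",
    "tolerance_matrix",
    "collinearity_filter",
    "forward_stepwise",
    "external_rmsep",
    "blocked_cv",
]


@dataclass
class OLSFit:
    terms: tuple[str, ...]
    coefficients: np.ndarray        # per-term, excluding intercept
    intercept: float
    coef_se: np.ndarray
    intercept_se: float
    r2: float
    r2_adj: float
    f_stat: float
    p_value: float
    resid_se: float
    rss: float
    n: int


@dataclass
class FitResult:
    """Stepwise-fit outcome: the selected model plus per-step diagnostics.

    ``step_log`` holds (descriptor, added R-squared) pairs in entry order;
    the added fractions sum to the final R-squared.
    """

    model: QSARModel
    step_log: list[tuple[str, float]]
    n: int
    r2: float
    r2_adj: float
    f_stat: float
    p_value: float
    resid_se: float


@dataclass
class CVResult:
    rmsecv: float
    fold_assignments: np.ndarray    # per-sample fold index, original row order
    per_fold_rmse: list[float] = field(default_factory=list)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(X.shape[1])])


def fit_ols(X: pd.DataFrame, y: np.ndarray, terms: Sequence[str] | None = None) -> OLSFit:
    """Ordinary least squares of ``y`` on the named columns (all columns when
    ``terms`` is None), with intercept."""
    X = _as_frame(X)
    terms = tuple(terms) if terms is not None else tuple(X.columns)
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = np.column_stack([np.ones(n)] + [X[t].to_numpy(dtype=float) for t in terms])
    p = design.shape[1]
    if n <= p:
        raise ValueError(f"need n > number of parameters ({p}), got n={n}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - p
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    k = len(terms)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid if k else r2
    if k and rss > 0 and tss > 0:
        f_stat = (tss - rss) / k / sigma2
        p_value = float(stats.f.sf(f_stat, k, df_resid))
    else:
        f_stat, p_value = np.inf if k else 0.0, 0.0
    return OLSFit(terms=terms, coefficients=beta[1:], intercept=float(beta[0]),
                  coef_se=se[1:], intercept_se=float(se[0]), r2=r2, r2_adj=r2_adj,
                  f_stat=float(f_stat), p_value=p_value,
                  resid_se=float(np.sqrt(sigma2)), rss=rss, n=n)


# ---------------------------------------------------------------------------
# collinearity screening

def tolerance_matrix(X) -> pd.DataFrame:
    """Symmetric matrix of tolerances ``1 - R^2`` between descriptor pairs
    (diagonal 0).  A zero-variance column is an error naming the column."""
    X = _as_frame(X)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("tolerance_matrix needs >= 2 columns and >= 3 rows")
    values = X.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("tolerance_matrix: missing values are not allowed")
    sd = values.std(axis=0)
    dead = [c for c, s in zip(X.columns, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    corr = np.corrcoef(values, rowvar=False)
    tol = 1.0 - corr ** 2
    np.fill_diagonal(tol, 0.0)
    return pd.DataFrame(tol, index=X.columns, columns=X.columns)


def collinearity_filter(
    X,
    y: np.ndarray | None = None,
    threshold: float = 0.1,
) -> tuple[list[str], list[dict]]:
    """Greedily drop descriptors until no pair has tolerance below the
    threshold.

    At each step the currently worst pair (smallest tolerance) is resolved
    by dropping the member with the lower marginal |correlation| to the
    response; without a response, or on a tie, the lexicographically later
    name is dropped.  Returns the retained column names (input order) and a
    removal log.
    """
    X = _as_frame(X)
    retained = list(X.columns)
    removal_log: list[dict] = []
    if y is not None:
        y = np.asarray(y, dtype=float)
        relevance = {c: abs(np.corrcoef(X[c].to_numpy(dtype=float), y)[0, 1])
                     for c in retained}
    else:
        relevance = None
    while len(retained) >= 2:
        tol = tolerance_matrix(X[retained])
        arr = tol.to_numpy().copy()
        np.fill_diagonal(arr, np.inf)
        i, j = np.unravel_index(np.argmin(arr), arr.shape)
        if arr[i, j] >= threshold:
            break
        a, b = retained[i], retained[j]
        if relevance is not None and relevance[a] != relevance[b]:
            drop = a if relevance[a] < relevance[b] else b
        else:
            drop = max(a, b)  # lexicographic tie-break
        keep = b if drop == a else a
        removal_log.append({"dropped": drop, "kept": keep,
                            "tolerance": float(arr[i, j])})
        log.info("collinearity filter: dropped %r (tolerance %.4f with %r)",
                 drop, arr[i, j], keep)
        retained.remove(drop)
    return retained, removal_log


# ---------------------------------------------------------------------------
# forward stepwise selection

def forward_stepwise(X, y, p_enter: float = 0.05) -> FitResult:
    """Forward stepwise MLR: iteratively enter the candidate with the
    largest F-to-enter while its p-value is below ``p_enter``.

    When no candidate qualifies at the first step the result is the
    intercept-only model, with a warning.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.isnan(X.to_numpy(dtype=float)).any() or np.isnan(y).any():
        raise ValueError("forward_stepwise: missing values are not allowed")
    if n <= X.shape[1] + 2:
        raise ValueError(f"need n > candidate terms + 2 (n={n}, candidates={X.shape[1]})")

    selected: list[str] = []
    step_log: list[tuple[str, float]] = []
    tss = float(np.sum((y - y.mean()) ** 2))
    rss_current = tss
    r2_current = 0.0
    while True:
        candidates = [c for c in X.columns if c not in selected]
        if not candidates:
            break
        best = None
        for cand in candidates:
            trial = fit_ols(X, y, selected + [cand])
            df_resid = n - (len(selected) + 2)
            if trial.rss <= 0:
                f_enter, p_val = np.inf, 0.0
            else:
                f_enter = (rss_current - trial.rss) / (trial.rss / df_resid)
                p_val = float(stats.f.sf(f_enter, 1, df_resid))
            if best is None or f_enter > best[1]:
                best = (cand, f_enter, p_val, trial)
        cand, f_enter, p_val, trial = best
        if p_val >= p_enter:
            break
        selected.append(cand)
        step_log.append((cand, trial.r2 - r2_current))
        rss_current, r2_current = trial.rss, trial.r2
        if rss_current <= 0:
            break

    if not selected:
        log.warning("forward_stepwise: no candidate passed p_enter=%.3g; "
                    "returning intercept-only model", p_enter)
        model = QSARModel(name="stepwise", terms=(), coefficients=(),
                          intercept=float(y.mean()),
                          stats={"n": n, "r2": 0.0},
                          provenance="forward stepwise (no term entered)")
        resid_se = float(np.sqrt(tss / (n - 1))) if n > 1 else 0.0
        return FitResult(model=model, step_log=[], n=n, r2=0.0, r2_adj=0.0,
                         f_stat=0.0, p_value=1.0, resid_se=resid_se)

    final = fit_ols(X, y, selected)
    model = QSARModel(
        name="stepwise",
        terms=final.terms,
        coefficients=tuple(float(c) for c in final.coefficients),
        intercept=final.intercept,
        coef_se=tuple(float(s) for s in final.coef_se),
        intercept_se=final.intercept_se,
        stats={"n": n, "r2": final.r2, "r2_adj": final.r2_adj,
               "f": final.f_stat, "p": final.p_value, "resid_se": final.resid_se},
        provenance=f"forward stepwise MLR, p_enter={p_enter}",
    )
    return FitResult(model=model, step_log=step_log, n=n, r2=final.r2,
                     r2_adj=final.r2_adj, f_stat=final.f_stat,
                     p_value=final.p_value, resid_se=final.resid_se)


# ---------------------------------------------------------------------------
# validation

def external_rmsep(model: QSARModel, X_test, y_test) -> float:
    """Root-mean-square error of prediction on a held-out set."""
    X_test = _as_frame(X_test)
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) == 0:
        raise ValueError("external_rmsep: empty test set")
    missing = [t for t in model.terms if t not in X_test.columns]
    if missing:
        raise ValueError(f"test table lacks model term(s) {missing}")
    preds = np.array([model.predict(row) for row in X_test.to_dict("records")])
    return float(np.sqrt(np.mean((y_test - preds) ** 2)))


def blocked_cv(term_set: Sequence[str], X, y, k: int = 5, seed: int = 0) -> CVResult:
    """Contiguous-block k-fold cross-validation of a fixed term set.

    Rows are randomly permuted once (seeded), then cut into k contiguous
    blocks (the first ``n mod k`` blocks get one extra row; with n=60, k=5
    this is the 12/12/12/12/12 block structure).  For each fold the term set
    is refit by OLS on the remainder and the block is predicted; RMSECV
    pools all held-out squared errors.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    order = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, k)
    sizes = [base + 1 if f < extra else base for f in range(k)]
    folds, start = [], 0
    for size in sizes:
        folds.append(order[start:start + size])
        start += size

    assignments = np.empty(n, dtype=int)
    sq_errors = np.empty(n, dtype=float)
    per_fold = []
    for f, test_idx in enumerate(folds):
        assignments[test_idx] = f
        train_idx = np.setdiff1d(order, test_idx)
        fit = fit_ols(X.iloc[train_idx], y[train_idx], term_set)
        design = np.column_stack(
            [np.ones(len(test_idx))] +
            [X.iloc[test_idx][t].to_numpy(dtype=float) for t in term_set])
        preds = design @ np.concatenate([[fit.intercept], fit.coefficients])
        err2 = (y[test_idx] - preds) ** 2
        sq_errors[test_idx] = err2
        per_fold.append(float(np.sqrt(err2.mean())))
    return CVResult(rmsecv=float(np.sqrt(sq_errors.mean())),
                    fold_assignments=assignments, per_fold_rmse=per_fold)
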