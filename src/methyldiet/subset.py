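"""Best-subset regression via Furnival-Wilson branch and bound, plus the
refit-and-prune step that turns the chosen subset into score weights.

The search returns, for every subset size k up to ``k_max``, the predictor
set with provably minimal residual sum of squares.  Optimality is
certified by the monotone RSS bound: for any fixed set A and free pool F,
every subset S with A ⊆ S ⊆ A∪F satisfies RSS(S) ≥ RSS(A∪F), so whole
branches can be discarded against the incumbent without enumeration.
All models include an intercept (implemented by centering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla

from .errors import CollinearityError, EmptyModelError, InputError

_CRITERIA = ("AIC", "BIC", "AICc", "adjR2")


@dataclass
class SubsetSearchResult:
    """Per-size best subsets from the branch-and-bound search.

    ``subsets[k]`` holds the ids (or column indices when no ids were
    given) of the RSS-optimal size-k predictor set; ``rss[k]`` its RSS.
    ``n_evaluated`` counts RSS evaluations actually performed against the
    ``2**p`` subsets an exhaustive scan would need.
    """

    subsets: dict
    rss: dict
    tss: float
    n_evaluated: int
    n_total_subsets: int
    predictor_ids: list

    @property
    def sizes(self) -> list:
        return sorted(self.subsets)


def _as_matrix(X, predictor_ids):
    if isinstance(X, pd.DataFrame):
        ids = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        ids = list(predictor_ids) if predictor_ids is not None else list(range(Xv.shape[1]))
    if Xv.ndim != 2:
        raise InputError("X must be 2-dimensional")
    if len(ids) != Xv.shape[1]:
        raise InputError("predictor_ids length must match the number of columns")
    return Xv, ids


def _check_full_rank(Xc: np.ndarray, ids: Sequence) -> None:
    """Raise CollinearityError naming exactly-collinear columns."""
    n, p = Xc.shape
    norms = np.linalg.norm(Xc, axis=0)
    if np.any(norms == 0):
        bad = [str(ids[j]) for j in np.flatnonzero(norms == 0)]
        raise InputError(f"constant predictor column(s): {', '.join(bad)}")
    _, R, piv = sla.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        offenders = sorted(str(ids[j]) for j in piv[rank:])
        raise CollinearityError(
            f"exactly collinear predictor column(s): {', '.join(offenders)}"
        )


def leaps_and_bounds(
    X,
    y,
    k_max: Optional[int] = None,
    predictor_ids: Optional[Sequence] = None,
) -> SubsetSearchResult:
    """Certified best-subset search over all sizes 1..k_max.

    Parameters
    ----------
    X
        Predictor matrix (n x p), array or DataFrame.  Columns must be
        non-constant and not exactly collinear.
    y
        Response vector.
    k_max
        Largest subset size to report; defaults to min(p, n - 2).

    Returns the per-size RSS-optimal subsets, identical to exhaustive
    enumeration (the bound only discards provably dominated branches).
    """
    Xv, ids = _as_matrix(X, predictor_ids)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xv.shape
    if len(yv) != n:
        raise InputError("y length must match the number of rows of X")
    if p == 0:
        raise InputError("X has no columns")
    if k_max is None:
        k_max = min(p, n - 2)
    if k_max >= n:
        raise InputError(f"k_max = {k_max} must be smaller than n = {n}")
    if k_max < 1:
        raise InputError("k_max must be at least 1")
    k_max = min(k_max, p)
    if n <= p and k_max >= n - 1:
        raise InputError("need n > p, or k_max < n - 1")

    # Intercept handled by centering; subsets of a full-rank Gram stay
    # positive definite, so subset solves below cannot fail except by
    # numerical degeneracy (skipped with a warning).
    Xc = Xv - Xv.mean(axis=0)
    yc = yv - yv.mean()
    _check_full_rank(Xc, ids)

    # Order predictors by decreasing marginal |correlation| with y: good
    # incumbents early make the bound bite sooner.  Output is re-expressed
    # in the original ids regardless.
    norms = np.linalg.norm(Xc, axis=0)
    ynorm = np.linalg.norm(yc)
    marginal = np.abs(Xc.T @ yc) / (norms * max(ynorm, np.finfo(float).tiny))
    order = np.argsort(-marginal, kind="mergesort")
    Xo = Xc[:, order]

    G = Xo.T @ Xo
    c = Xo.T @ yc
    tss = float(yc @ yc)

    best_rss = np.full(k_max + 1, np.inf)
    best_set = [None] * (k_max + 1)
    n_eval = 0

    def rss_of(subset: tuple) -> float:
        nonlocal n_eval
        n_eval += 1
        idx = np.fromiter(subset, dtype=int)
        Gs = G[np.ix_(idx, idx)]
        cs = c[idx]
        try:
            cho = sla.cho_factor(Gs, check_finite=False)
            b = sla.cho_solve(cho, cs, check_finite=False)
        except sla.LinAlgError:
            warnings.warn(
                "numerically singular candidate subset skipped", stacklevel=3
            )
            return np.inf
        return max(tss - float(cs @ b), 0.0)

    def consider(subset: tuple, r: float) -> None:
        k = len(subset)
        if 1 <= k <= k_max and r < best_rss[k]:
            best_rss[k] = r
            best_set[k] = subset

    def search(fixed: tuple, free: tuple) -> None:
        if not free:
            return
        full = fixed + free
        bound = rss_of(full)  # lower bound for every subset between fixed and full
        consider(full, bound)
        lo = len(fixed) + 1
        hi = min(len(full) - 1, k_max)
        if not any(bound < best_rss[k] for k in range(lo, hi + 1)):
            return
        for i in range(len(free)):
            new_fixed = fixed + (free[i],)
            if len(new_fixed) <= k_max:
                consider(new_fixed, rss_of(new_fixed))
                if len(new_fixed) < k_max:
                    search(new_fixed, free[i + 1 :])

    search((), tuple(range(p)))

    subsets, rss = {}, {}
    for k in range(1, k_max + 1):
        if best_set[k] is None:
            continue
        orig = sorted(order[list(best_set[k])].tolist())
        subsets[k] = tuple(ids[j] for j in orig)
        rss[k] = float(best_rss[k])
    return SubsetSearchResult(
        subsets=subsets,
        rss=rss,
        tss=tss,
        n_evaluated=n_eval,
        n_total_subsets=2**p,
        predictor_ids=ids,
    )


def _criterion_value(criterion: str, rss: float, tss: float, n: int, k: int) -> float:
    """Model-selection score for a size-k subset (plus intercept).

    AIC/BIC/AICc use the Gaussian profile log-likelihood n*log(RSS/n) with
    k + 1 mean parameters; constant offsets common to all models are
    dropped.  adjR2 is returned negated so that every criterion is
    minimized.
    """
    if rss <= 0:
        rss = np.finfo(float).tiny
    if criterion == "AIC":
        return n * np.log(rss / n) + 2.0 * (k + 1)
    if criterion == "BIC":
        return n * np.log(rss / n) + np.log(n) * (k + 1)
    if criterion == "AICc":
        if n - k - 2 <= 0:
            return np.inf
        return n * np.log(rss / n) + 2.0 * (k + 1) + 2.0 * (k + 1) * (k + 2) / (n - k - 2)
    if criterion == "adjR2":
        if n - k - 1 <= 0:
            return np.inf
        return -(1.0 - (rss / (n - k - 1)) / (tss / (n - 1)))
    raise InputError(f"unknown criterion {criterion!r}; choose from {_CRITERIA}")


def choose_subset(result: SubsetSearchResult, n: int, criterion: str = "AIC") -> tuple:
    """Pick one subset across sizes by an information criterion.

    Ties break toward smaller size, then lexicographic predictor order.
    """
    if not result.subsets:
        raise EmptyModelError("subset search returned no candidate subsets")
    # iterating sizes in ascending order with strict-improvement replacement
    # breaks criterion ties toward the smaller subset
    best_val, best = np.inf, None
    for k in sorted(result.subsets):
        val = _criterion_value(criterion, result.rss[k], result.tss, n, k)
        if val < best_val:
            best_val, best = val, result.subsets[k]
    return best


def criterion_table(result: SubsetSearchResult, n: int, criterion: str = "AIC") -> pd.DataFrame:
    """Per-size RSS and criterion values (diagnostic companion to choose_subset)."""
    rows = []
    for k in sorted(result.subsets):
        rows.append(
            {
                "k": k,
                "rss": result.rss[k],
                criterion: _criterion_value(criterion, result.rss[k], result.tss, n, k),
                "subset": ",".join(map(str, result.subsets[k])),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    """An OLS fit of %BMIL on a set of CpG predictors (with intercept)."""

    predictor_ids: list
    coefficients: pd.Series
    standard_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    vif: pd.Series
    intercept: float
    intercept_se: float
    residual_df: int
    rss: float

    def __post_init__(self):
        k = len(self.predictor_ids)
        for s in (self.coefficients, self.standard_errors, self.t_values, self.p_values, self.vif):
            if len(s) != k:
                raise InputError("regression fit fields have inconsistent lengths")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: cpg, beta, sem, p, vif."""
        return pd.DataFrame(
            {
                "cpg": self.predictor_ids,
                "beta": self.coefficients.to_numpy(),
                "sem": self.standard_errors.to_numpy(),
                "p": self.p_values.to_numpy(),
                "vif": self.vif.to_numpy(),
            }
        )


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF of each column: 1 / (1 - R^2) of regressing it on the others
    (with intercept).  A single predictor has VIF exactly 1."""
    cols = list(X.columns)
    if len(cols) == 1:
        return pd.Series([1.0], index=cols)
    out = {}
    for col in cols:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _ols_fit(X: pd.DataFrame, y: np.ndarray) -> RegressionFit:
    design = sm.add_constant(X.to_numpy())
    res = sm.OLS(y, design).fit()
    ids = list(X.columns)
    return RegressionFit(
        predictor_ids=ids,
        coefficients=pd.Series(res.params[1:], index=ids),
        standard_errors=pd.Series(res.bse[1:], index=ids),
        t_values=pd.Series(res.tvalues[1:], index=ids),
        p_values=pd.Series(np.clip(res.pvalues[1:], np.finfo(float).tiny, 1.0), index=ids),
        vif=variance_inflation(X),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        residual_df=int(res.df_resid),
        rss=float(res.ssr),
    )


def refit_and_prune(
    X,
    y,
    subset: Sequence,
    p_keep: float = 0.19,
    vif_max: float = 10.0,
    predictor_ids: Optional[Sequence] = None,
) -> RegressionFit:
    """Refit OLS on ``subset`` and prune weak / collinear predictors.

    One pass drops predictors whose coefficient p-value is >= ``p_keep``
    (the retention rule is p < p_keep); then, while any VIF exceeds
    ``vif_max``, the predictor with the largest VIF is removed and the
    model refit.  Raises EmptyModelError if nothing survives.
    """
    Xv, ids = _as_matrix(X, predictor_ids)
    yv = np.asarray(y, dtype=float).ravel()
    subset = list(subset)
    if not subset:
        raise EmptyModelError("empty predictor subset")
    pos = {pid: j for j, pid in enumerate(ids)}
    missing = [str(s) for s in subset if s not in pos]
    if missing:
        raise InputError(f"subset members not among predictors: {', '.join(missing)}")
    if len(yv) <= len(subset) + 1:
        raise InputError("need n > |subset| + 1 observations")

    frame = pd.DataFrame(Xv[:, [pos[s] for s in subset]], columns=subset)
    fit = _ols_fit(frame, yv)

    keep = [pid for pid in subset if fit.p_values[pid] < p_keep]
    if not keep:
        raise EmptyModelError(
            f"no predictor reached p < {p_keep}; the score for this arm is empty"
        )
    if keep != subset:
        frame = frame[keep]
        fit = _ols_fit(frame, yv)

    while len(frame.columns) > 1 and fit.vif.max() > vif_max:
        worst = fit.vif.idxmax()
        frame = frame.drop(columns=[worst])
        fit = _ols_fit(frame, yv)
    return fit
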