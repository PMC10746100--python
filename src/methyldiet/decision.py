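"""Per-individual diet recommendation via a Z-test on predicted %BMIL.

For each participant, the fitted interaction model predicts %BMIL under
both diets at the participant's total methylation score (age and sex held
at their sample means).  The two predictions are compared with a Z
statistic; a significant difference recommends the diet with the greater
predicted loss (more negative %BMIL), otherwise either diet may be
prescribed.

The default combines the two prediction SEs as if independent,
z = (pred_MHP - pred_LF) / sqrt(se_MHP^2 + se_LF^2).  Because the two
predictions share every non-diet coefficient they are in fact positively
correlated, which makes the independent combination conservative; the
'full' mode uses the exact variance of the difference,
(x_LF - x_MHP)' Cov (x_LF - x_MHP), and is the calibrated choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InputError
from .interaction import DietResponseResults

_MODES = ("independent", "full")

REC_COLUMNS = ["id", "total", "pred_mhp", "se_mhp", "pred_lf", "se_lf", "z", "p", "category"]


@dataclass(frozen=True)
class DietRecommendation:
    """One participant's recommendation."""

    id: object
    total: float
    pred_mhp: float
    se_mhp: float
    pred_lf: float
    se_lf: float
    z: float
    p: float
    category: str


@dataclass
class PopulationSummary:
    """Counts per recommendation category and the undecided score region."""

    counts: dict
    undecided_intervals: list
    alpha: float

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "undecided_intervals": [list(iv) for iv in self.undecided_intervals],
            "alpha": self.alpha,
            "n": self.n,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _scores_frame(scores) -> pd.DataFrame:
    if isinstance(scores, pd.Series):
        return pd.DataFrame({"total": scores})
    if isinstance(scores, pd.DataFrame):
        if "total" not in scores.columns:
            raise InputError("score table must carry a 'total' column")
        return scores
    arr = np.asarray(scores, dtype=float).ravel()
    return pd.DataFrame({"total": arr})


def recommend_diet(
    fit: DietResponseResults,
    scores,
    alpha: float = 0.05,
    covariance_mode: str = "independent",
) -> pd.DataFrame:
    """Z-test diet assignment for every individual.

    Parameters
    ----------
    fit
        A fitted (or deserialized) interaction model.
    scores
        Score table indexed by participant id with a ``total`` column (a
        Series or bare array of totals also works).
    alpha
        Two-sided significance level; p > alpha yields category 'either'.
    covariance_mode
        'independent' (default, SEs combined as if uncorrelated) or
        'full' (exact variance of the prediction difference).

    Returns a frame with columns id, total, pred_mhp, se_mhp, pred_lf,
    se_lf, z, p, category.
    """
    if covariance_mode not in _MODES:
        raise InputError(f"unknown covariance_mode {covariance_mode!r}; choose from {_MODES}")
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must lie in (0, 1)")
    frame = _scores_frame(scores)
    totals = frame["total"].to_numpy(dtype=float)

    X_mhp = np.vstack([fit._design_row(t, "MHP") for t in totals])
    X_lf = np.vstack([fit._design_row(t, "LF") for t in totals])
    pred_mhp, se_mhp = fit._pred_se(X_mhp)
    pred_lf, se_lf = fit._pred_se(X_lf)

    diff = pred_mhp - pred_lf
    if covariance_mode == "independent":
        var_diff = se_mhp**2 + se_lf**2
    else:
        D = X_mhp - X_lf
        var_diff = np.einsum("ij,jk,ik->i", D, fit.cov.to_numpy(), D)
        var_diff = np.clip(var_diff, 0.0, None)

    zero_se = var_diff <= 0.0
    if np.any(zero_se & (diff != 0.0)):
        raise DegenerateFitError(
            "zero combined SE with unequal predictions; the fit cannot support the Z-test"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero_se, 0.0, diff / np.sqrt(np.where(zero_se, 1.0, var_diff)))
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    category = np.where(
        p > alpha, "either", np.where(pred_mhp < pred_lf, "MHP", "LF")
    )
    # exactly equal predictions can never be significant, but guard the
    # boundary anyway
    category = np.where((p <= alpha) & (diff == 0.0), "either", category)

    return pd.DataFrame(
        {
            "id": list(frame.index),
            "total": totals,
            "pred_mhp": pred_mhp,
            "se_mhp": se_mhp,
            "pred_lf": pred_lf,
            "se_lf": se_lf,
            "z": z,
            "p": p,
            "category": category,
        }
    )


def recommendations_as_records(recs: pd.DataFrame) -> List[DietRecommendation]:
    """View a recommendation frame as a list of typed records."""
    return [DietRecommendation(**row) for row in recs[REC_COLUMNS].to_dict("records")]


def summarize_population(
    recs: Union[pd.DataFrame, List[DietRecommendation]], alpha: float = 0.05
) -> PopulationSummary:
    """Category counts and the score interval(s) holding the undecided.

    Individuals are sorted by total score; each maximal run of consecutive
    'either' individuals is reported as the closed interval [min score,
    max score] of that run.
    """
    if isinstance(recs, list):
        recs = pd.DataFrame([vars(r) for r in recs])
    if recs.empty:
        raise InputError("no recommendations to summarize")
    counts = {cat: int((recs["category"] == cat).sum()) for cat in ("MHP", "LF", "either")}
    ordered = recs.sort_values("total", kind="mergesort")
    intervals = []
    run = []
    for _, row in ordered.iterrows():
        if row["category"] == "either":
            run.append(row["total"])
        elif run:
            intervals.append((float(min(run)), float(max(run))))
            run = []
    if run:
        intervals.append((float(min(run)), float(max(run))))
    return PopulationSummary(counts=counts, undecided_intervals=intervals, alpha=alpha)
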