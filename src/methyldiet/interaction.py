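"""The diet x methylation-score interaction model.

%BMIL is regressed on a diet indicator, the total methylation score,
their interaction, and the age/sex covariates:

    %BMIL_i = b0 + bD * diet_i + bT * score_i + bDT * diet_i * score_i
              + b_age * age_i + b_sex * sex_i + e_i

With a single outcome per participant a participant-level random
intercept is not identifiable separately from the residual, so the model
is fit as ordinary least squares on the identical fixed-effects design;
``fit(method='mixed')`` additionally runs the REML random-intercept fit
and reports its (degenerate, ~0) variance component as a diagnostic.

The API follows the statsmodels convention: a model object built from
data whose ``fit()`` returns a results object carrying estimates,
covariance, a ``summary()`` table, marginal predictions across the score
range and per-individual diet recommendations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import DIETS, PhenotypeTable
from .errors import DegenerateFitError, InputError
from .scoring import validate_score_table

TERMS = ["const", "diet", "score", "diet:score", "age", "sex"]


@dataclass
class MarginalPrediction:
    """Predicted %BMIL (with SE) for each diet across a score grid."""

    grid: np.ndarray
    pred_mhp: np.ndarray
    se_mhp: np.ndarray
    pred_lf: np.ndarray
    se_lf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.grid,
                "pred_mhp": self.pred_mhp,
                "se_mhp": self.se_mhp,
                "pred_lf": self.pred_lf,
                "se_lf": self.se_lf,
            }
        )


class DietResponseModel:
    """%BMIL ~ diet * total score (+ age + sex), one row per participant.

    Parameters
    ----------
    pct_bmil, total_score
        Outcome and biomarker, aligned element-wise.
    diet
        Arm labels, 'MHP'/'LF'.
    age, sex
        Optional adjustment covariates; sex as 'female'/'male' labels.
    diet_ref
        Arm coded 0 in the indicator (default 'MHP', so the diet
        coefficient is the LF offset at score 0).
    sex_ref
        Sex coded 0 (default 'female').
    ids
        Participant identifiers (used for the mixed-model grouping and
        carried into recommendations).
    """

    def __init__(
        self,
        pct_bmil,
        total_score,
        diet,
        age=None,
        sex=None,
        diet_ref: str = "MHP",
        sex_ref: str = "female",
        ids: Optional[Sequence] = None,
    ):
        y = np.asarray(pct_bmil, dtype=float).ravel()
        t = np.asarray(total_score, dtype=float).ravel()
        diet = np.asarray(diet, dtype=object).ravel()
        n = len(y)
        if not (len(t) == len(diet) == n):
            raise InputError("pct_bmil, total_score and diet must have equal length")
        if n <= 6:
            raise InputError("need more than 6 participants")
        if diet_ref not in DIETS:
            raise InputError(f"diet_ref must be one of {DIETS}")
        present = set(diet)
        if present != set(DIETS):
            raise InputError(
                f"both diet arms must be present; got {sorted(present)}"
            )
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
            raise InputError("non-finite outcome or score values")

        d = (diet != diet_ref).astype(float)
        cols = {"const": np.ones(n), "diet": d, "score": t, "diet:score": d * t}
        if age is not None:
            age = np.asarray(age, dtype=float).ravel()
            cols["age"] = age
        if sex is not None:
            sex = np.asarray(sex, dtype=object).ravel()
            bad = set(sex) - {"female", "male"}
            if bad:
                raise InputError(f"unknown sex labels: {sorted(bad)}")
            cols["sex"] = (sex != sex_ref).astype(float)

        design = pd.DataFrame(cols)
        for name in design.columns[1:]:
            if np.ptp(design[name].to_numpy()) == 0:
                raise InputError(f"degenerate design: column {name!r} is constant")
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            raise InputError("rank-deficient design matrix")

        self.endog = y
        self.design = design
        self.diet_ref = diet_ref
        self.sex_ref = sex_ref if sex is not None else None
        self.ids = list(ids) if ids is not None else list(range(n))
        self.score_range = (float(t.min()), float(t.max()))
        self.covariate_means = {
            name: float(design[name].mean()) for name in design.columns if name in ("age", "sex")
        }

    @classmethod
    def from_frames(
        cls,
        scores: pd.DataFrame,
        pheno: Union[PhenotypeTable, pd.DataFrame],
        adjust: bool = True,
        diet_ref: str = "MHP",
        sex_ref: str = "female",
    ) -> "DietResponseModel":
        """Build from a score table (indexed by id, column ``total``) and a
        phenotype table; rows are aligned on participant id."""
        validate_score_table(scores)
        frame = pheno.frame if isinstance(pheno, PhenotypeTable) else pheno
        merged = frame.merge(
            scores.reset_index()[["id", "total"]], on="id", how="inner", validate="1:1"
        )
        if len(merged) < len(frame):
            missing = set(frame["id"]) - set(merged["id"])
            raise InputError(f"scores missing for participants: {sorted(missing)[:5]}")
        return cls(
            pct_bmil=merged["pct_bmil"],
            total_score=merged["total"],
            diet=merged["diet"],
            age=merged["age"] if adjust else None,
            sex=merged["sex"] if adjust else None,
            diet_ref=diet_ref,
            sex_ref=sex_ref,
            ids=merged["id"],
        )

    def fit(self, method: str = "ols") -> "DietResponseResults":
        """Fit by OLS; ``method='mixed'`` also runs the REML
        random-intercept fit and records its variance component."""
        res = sm.OLS(self.endog, self.design.to_numpy()).fit()
        random_var = None
        if method == "mixed":
            random_var = self._random_intercept_variance()
        elif method != "ols":
            raise InputError(f"unknown fit method {method!r}")
        params = pd.Series(res.params, index=list(self.design.columns))
        cov = pd.DataFrame(
            res.cov_params(), index=list(self.design.columns), columns=list(self.design.columns)
        )
        return DietResponseResults(
            params=params,
            cov=cov,
            scale=float(res.scale),
            nobs=int(res.nobs),
            df_resid=int(res.df_resid),
            diet_ref=self.diet_ref,
            sex_ref=self.sex_ref,
            covariate_means=dict(self.covariate_means),
            score_range=self.score_range,
            model_p_value=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else None,
            rsquared=float(res.rsquared),
            random_intercept_var=random_var,
            ids=list(self.ids),
            _sm_results=res,
        )

    def _random_intercept_variance(self) -> float:
        """REML variance of a participant random intercept (diagnostic).

        With one observation per participant only the total variance
        sigma_re^2 + sigma_resid^2 is identified: the REML log-likelihood
        is exactly flat in the split, and the fixed effects equal OLS at
        every point of the ridge.  The flatness is verified numerically
        and the boundary solution (variance 0, fully absorbed into the
        residual) is reported; NaN signals that the check failed.
        """
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        exog = self.design.to_numpy()
        groups = np.asarray(self.ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = sm.MixedLM(self.endog, exog, groups=groups)
            try:
                mres = mixed.fit(reml=True)
                lls = [
                    mixed.loglike(
                        MixedLMParams.from_components(
                            fe_params=mres.fe_params, cov_re=np.array([[r]])
                        ),
                        profile_fe=True,
                    )
                    for r in (0.01, 1.0, 10.0)
                ]
            except Exception:
                return float("nan")
        if max(lls) - min(lls) < 1e-6 * max(1.0, abs(lls[0])):
            return 0.0
        return float(np.asarray(mres.cov_re)[0, 0])


@dataclass
class DietResponseResults:
    """Fitted diet x score interaction model.

    Serializable: ``to_json``/``from_json`` round-trip everything needed
    for marginal prediction and diet recommendation (coefficients, their
    covariance, codings, covariate means and the observed score range).
    """

    params: pd.Series
    cov: pd.DataFrame
    scale: float
    nobs: int
    df_resid: int
    diet_ref: str
    sex_ref: Optional[str]
    covariate_means: dict
    score_range: tuple
    model_p_value: Optional[float] = None
    rsquared: Optional[float] = None
    random_intercept_var: Optional[float] = None
    ids: Optional[list] = None
    _sm_results: object = field(default=None, repr=False, compare=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self.cov

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        from scipy import stats

        t = self.tvalues.abs()
        return pd.Series(
            np.clip(2.0 * stats.t.sf(t, df=self.df_resid), np.finfo(float).tiny, 1.0),
            index=self.params.index,
        )

    # ---- prediction -----------------------------------------------------

    def _design_row(self, score: float, diet: str) -> np.ndarray:
        """Design vector at one score for one diet, covariates at means."""
        d = 0.0 if diet == self.diet_ref else 1.0
        row = {"const": 1.0, "diet": d, "score": score, "diet:score": d * score}
        row.update(self.covariate_means)
        return np.array([row[name] for name in self.params.index])

    def _pred_se(self, X: np.ndarray):
        pred = X @ self.params.to_numpy()
        covm = self.cov.to_numpy()
        var = np.einsum("ij,jk,ik->i", X, covm, X)
        return pred, np.sqrt(np.clip(var, 0.0, None))

    def predict_marginals(
        self, grid=None, extrapolation_factor: float = 2.0
    ) -> MarginalPrediction:
        """Predicted %BMIL with SE for each diet across ``grid``.

        Predictions hold age at the sample mean and sex at its sample
        proportion; SE at each point is sqrt(x' Cov x).  ``grid`` defaults
        to 50 points spanning the observed score range; points outside
        ``extrapolation_factor`` times that range trigger a warning.
        """
        lo, hi = self.score_range
        if grid is None:
            grid = np.linspace(lo, hi, 50)
        grid = np.sort(np.asarray(grid, dtype=float).ravel())
        center = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        if half > 0 and np.any(np.abs(grid - center) > extrapolation_factor * half):
            warnings.warn(
                "grid extends beyond the configured extrapolation multiple of "
                "the observed score range; predictions there are extrapolations",
                stacklevel=2,
            )
        diets = {}
        for diet in DIETS:
            X = np.vstack([self._design_row(t, diet) for t in grid])
            diets[diet] = self._pred_se(X)
        return MarginalPrediction(
            grid=grid,
            pred_mhp=diets["MHP"][0],
            se_mhp=diets["MHP"][1],
            pred_lf=diets["LF"][0],
            se_lf=diets["LF"][1],
        )

    def recommend(self, scores, alpha: float = 0.05, covariance_mode: str = "independent"):
        """Per-individual diet recommendation; see
        :func:`methyldiet.decision.recommend_diet`."""
        from .decision import recommend_diet

        return recommend_diet(self, scores, alpha=alpha, covariance_mode=covariance_mode)

    # ---- reporting ------------------------------------------------------

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "t": self.tvalues,
                "P>|t|": self.pvalues,
            }
        )
        lines = [
            "Diet x methylation-score interaction model (%BMIL)",
            "=" * 58,
            f"n = {self.nobs}    df_resid = {self.df_resid}    "
            f"R^2 = {self.rsquared:.3f}" if self.rsquared is not None else f"n = {self.nobs}",
            f"diet coding: {self.diet_ref} = 0"
            + (f"    sex coding: {self.sex_ref} = 0" if self.sex_ref else ""),
            rows.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        if self.model_p_value is not None:
            lines.append(f"model p-value (F): {self.model_p_value:.3g}")
        if self.random_intercept_var is not None:
            lines.append(
                f"random-intercept variance (REML diagnostic): {self.random_intercept_var:.3g}"
            )
        return "\n".join(lines)

    # ---- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "cov": {
                "index": list(self.cov.index),
                "values": self.cov.to_numpy().tolist(),
            },
            "scale": self.scale,
            "nobs": self.nobs,
            "df_resid": self.df_resid,
            "diet_ref": self.diet_ref,
            "sex_ref": self.sex_ref,
            "covariate_means": self.covariate_means,
            "score_range": list(self.score_range),
            "model_p_value": self.model_p_value,
            "rsquared": self.rsquared,
            "random_intercept_var": self.random_intercept_var,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "DietResponseResults":
        names = d["cov"]["index"]
        params = pd.Series({k: d["params"][k] for k in names})
        cov = pd.DataFrame(np.asarray(d["cov"]["values"]), index=names, columns=names)
        return cls(
            params=params,
            cov=cov,
            scale=d["scale"],
            nobs=d["nobs"],
            df_resid=d["df_resid"],
            diet_ref=d["diet_ref"],
            sex_ref=d.get("sex_ref"),
            covariate_means=d.get("covariate_means", {}),
            score_range=tuple(d["score_range"]),
            model_p_value=d.get("model_p_value"),
            rsquared=d.get("rsquared"),
            random_intercept_var=d.get("random_intercept_var"),
        )

    @classmethod
    def from_json(cls, path) -> "DietResponseResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_interaction_model(
    scores: pd.DataFrame,
    pheno: Union[PhenotypeTable, pd.DataFrame],
    adjust: bool = True,
    diet_ref: str = "MHP",
    sex_ref: str = "female",
    method: str = "ols",
) -> DietResponseResults:
    """Convenience wrapper: build the model from frames and fit it."""
    return DietResponseModel.from_frames(
        scores, pheno, adjust=adjust, diet_ref=diet_ref, sex_ref=sex_ref
    ).fit(method=method)


def predict_marginals(fit: DietResponseResults, grid=None, **kwargs) -> MarginalPrediction:
    """Module-level alias for :meth:`DietResponseResults.predict_marginals`."""
    return fit.predict_marginals(grid, **kwargs)
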