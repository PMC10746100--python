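"""Weighted methylation sub-scores and the total score.

Each diet arm gets a sub-score: the sum over its selected CpGs of
methylation times the regression coefficient from that arm's pruned OLS
fit.  The total methylation score — the biomarker entering the
diet-interaction model — is the MHP sub-score minus the LF sub-score.
Sub-scores carry no intercept term.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .containers import DIETS, MethylationMatrix
from .errors import InputError, MissingProbeError
from .subset import RegressionFit

SCORE_COLUMNS = ["sub_mhp", "sub_lf", "total"]


@dataclass(frozen=True)
class DietScoreWeights:
    """CpG -> coefficient map defining one diet's weighted sub-score.

    Coefficients are in %BMIL per methylation unit.  Zero weights are not
    stored (a zero-weight probe contributes nothing and would only mask
    missing-data errors).
    """

    diet: str
    weights: Mapping[str, float]

    def __post_init__(self):
        if self.diet not in DIETS:
            raise InputError(f"unknown diet {self.diet!r}")
        cleaned = {}
        for pid, w in dict(self.weights).items():
            w = float(w)
            if not np.isfinite(w):
                raise InputError(f"non-finite weight for probe {pid!r}")
            if w != 0.0:
                cleaned[str(pid)] = w
        object.__setattr__(self, "weights", cleaned)

    @property
    def probe_ids(self) -> list:
        return list(self.weights)

    def __len__(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        return {"diet": self.diet, "weights": dict(self.weights)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "DietScoreWeights":
        if set(d) - {"diet", "weights"}:
            raise InputError(f"unexpected weight-file keys: {sorted(set(d) - {'diet', 'weights'})}")
        return cls(diet=d["diet"], weights=d["weights"])

    @classmethod
    def from_json(cls, path) -> "DietScoreWeights":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_weights(fit: RegressionFit, diet: str) -> DietScoreWeights:
    """Turn a pruned regression fit into score weights (intercept excluded,
    probe order preserved)."""
    if not fit.predictor_ids:
        raise InputError("cannot build weights from an empty fit")
    return DietScoreWeights(
        diet=diet,
        weights={pid: float(fit.coefficients[pid]) for pid in fit.predictor_ids},
    )


def compute_subscore(
    methylation: Union[Mapping[str, float], pd.Series],
    weights: DietScoreWeights,
    missing: str = "strict",
    cohort_means: Optional[Mapping[str, float]] = None,
) -> float:
    """Weighted sub-score of one methylation profile: sum_j w_j * m_j.

    ``missing='strict'`` (default) raises MissingProbeError listing absent
    probes; ``missing='impute'`` substitutes the cohort mean from
    ``cohort_means`` and warns.
    """
    if isinstance(methylation, pd.Series):
        methylation = methylation.to_dict()
    absent = [pid for pid in weights.probe_ids if pid not in methylation]
    if absent:
        if missing == "strict":
            raise MissingProbeError(absent)
        if missing != "impute":
            raise InputError(f"unknown missing-probe policy {missing!r}")
        if cohort_means is None or any(pid not in cohort_means for pid in absent):
            raise InputError("impute policy needs cohort_means covering the absent probes")
        warnings.warn(
            f"imputing cohort mean for {len(absent)} absent probe(s): "
            f"{', '.join(absent[:5])}",
            stacklevel=2,
        )
    total = 0.0
    for pid, w in weights.weights.items():
        value = methylation.get(pid)
        if value is None:
            value = cohort_means[pid]
        total += w * float(value)
    return total


def compute_total(sub_mhp: float, sub_lf: float) -> float:
    """Total methylation score: MHP sub-score minus LF sub-score."""
    return sub_mhp - sub_lf


def score_cohort(
    meth: MethylationMatrix,
    weights_mhp: DietScoreWeights,
    weights_lf: DietScoreWeights,
    missing: str = "strict",
    cohort_means: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Score every sample; returns a frame indexed by sample id with
    columns sub_mhp, sub_lf, total (total = sub_mhp - sub_lf exactly).

    Weighted probes absent from the matrix raise MissingProbeError under
    the strict policy; under ``missing='impute'`` each absent probe
    contributes its weight times the reference mean from ``cohort_means``.
    An empty weight set yields a sub-score of 0 for every sample.
    """
    if weights_mhp.diet != "MHP" or weights_lf.diet != "LF":
        raise InputError("weights_mhp must be MHP weights and weights_lf LF weights")
    out = {}
    for name, w in (("sub_mhp", weights_mhp), ("sub_lf", weights_lf)):
        if len(w) == 0:
            out[name] = np.zeros(meth.n_samples)
            continue
        absent = [pid for pid in w.probe_ids if pid not in meth.frame.columns]
        offset = 0.0
        if absent:
            if missing == "strict":
                raise MissingProbeError(absent)
            if missing != "impute":
                raise InputError(f"unknown missing-probe policy {missing!r}")
            if cohort_means is None or any(pid not in cohort_means for pid in absent):
                raise InputError("impute policy needs cohort_means covering the absent probes")
            warnings.warn(
                f"{name}: imputing reference mean for absent probe(s) "
                f"{', '.join(absent[:5])}",
                stacklevel=2,
            )
            offset = sum(w.weights[pid] * float(cohort_means[pid]) for pid in absent)
        present = [pid for pid in w.probe_ids if pid not in absent]
        vec = np.array([w.weights[pid] for pid in present])
        base = meth.frame[present].to_numpy() @ vec if present else np.zeros(meth.n_samples)
        out[name] = base + offset
    frame = pd.DataFrame(out, index=pd.Index(meth.sample_ids, name="id"))
    frame["total"] = frame["sub_mhp"] - frame["sub_lf"]
    return frame


def validate_score_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Check the score-table contract.

    ``total`` is required; the per-diet sub-scores are optional but must
    satisfy total = sub_mhp - sub_lf when both are present.
    """
    if "total" not in scores.columns:
        raise InputError("score table missing column: total")
    if not np.all(np.isfinite(scores["total"])):
        raise InputError("score table contains non-finite totals")
    if {"sub_mhp", "sub_lf"} <= set(scores.columns):
        if not np.allclose(
            scores["total"], scores["sub_mhp"] - scores["sub_lf"], atol=1e-9
        ):
            raise InputError("score table violates total = sub_mhp - sub_lf")
    return scores
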