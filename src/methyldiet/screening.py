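"""Probe screening: variability filter and per-diet Spearman correlation.

These are the first two selection stages of the pipeline: probes must be
dispersed across the cohort (sample SD above a threshold, 0.1 by default)
and, within each diet arm separately, rank-correlated with %BMIL at a
nominal significance level.  No multiple-testing correction is applied by
default, reproducing the original nominal-alpha screen; Benjamini-Hochberg
is available as an option.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DIETS, MethylationMatrix, PhenotypeTable
from .errors import InputError

_TINY = np.finfo(float).tiny


def probe_sd(meth: MethylationMatrix) -> pd.Series:
    """Sample standard deviation (n-1 denominator) of every probe."""
    if meth.n_samples < 2:
        raise InputError("standard deviation needs at least 2 samples")
    return meth.frame.std(axis=0, ddof=1)


def filter_by_sd(meth: MethylationMatrix, sd_min: float = 0.1) -> list:
    """Return probe ids with sample SD strictly greater than ``sd_min``.

    Column order of the matrix is preserved.  The threshold is strict:
    a probe at exactly ``sd_min`` is excluded.
    """
    sd = probe_sd(meth)
    return list(sd.index[sd.to_numpy() > sd_min])


def _rank_correlation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of every column of X against y (average ranks for ties).

    Columns with zero rank variance yield NaN.
    """
    rX = stats.rankdata(X, axis=0)
    ry = stats.rankdata(y)
    rX = rX - rX.mean(axis=0)
    ry = ry - ry.mean()
    num = rX.T @ ry
    denom = np.sqrt((rX**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / np.maximum(denom, _TINY), np.nan)
    return np.clip(rho, -1.0, 1.0, out=rho) if rho.size else rho


def _asymptotic_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation t = rho * sqrt((n-2)/(1-rho^2))."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # rho = +-1 gives t = inf and p = 0; keep p in (0, 1]
    return np.clip(p, _TINY, 1.0)


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided permutation p-value for Spearman rho (small n only).

    Enumerates all n! permutations of y; intended for n < 10 where the t
    approximation is unreliable.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise InputError("x and y must have equal length")
    if n > 9:
        raise InputError("exact permutation p-value is limited to n <= 9")
    rho_obs = _rank_correlation(x[:, None], y)[0]
    if np.isnan(rho_obs):
        return 1.0
    ry = stats.rankdata(y)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = _rank_correlation(x[:, None], ry[list(perm)])[0]
        if abs(rho) >= target:
            count += 1
        total += 1
    return count / total


@dataclass
class ScreeningResult:
    """Per-probe screening statistics and selection flags.

    ``table`` is indexed by probe id with columns sd, rho_mhp, p_mhp,
    rho_lf, p_lf, passed_sd, selected_mhp, selected_lf.
    """

    table: pd.DataFrame
    alpha: float
    sd_min: float

    def selected(self, diet: str) -> list:
        if diet not in DIETS:
            raise InputError(f"unknown diet {diet!r}")
        col = f"selected_{diet.lower()}"
        return list(self.table.index[self.table[col]])

    def candidates(self, diet: str, max_candidates: Optional[int] = None) -> list:
        """Selected probes for one arm, ordered by ascending p-value.

        ``max_candidates`` truncates the list (ties broken by probe id),
        bounding the cost of the downstream exact subset search.
        """
        col = f"p_{diet.lower()}"
        sel = self.table.loc[self.table[f"selected_{diet.lower()}"]]
        ordered = sel.sort_values([col], kind="mergesort").index
        ordered = sorted(ordered, key=lambda pid: (sel.loc[pid, col], pid))
        if max_candidates is not None:
            ordered = ordered[:max_candidates]
        return list(ordered)

    def to_tsv(self, path, header_comment: Optional[str] = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# alpha={self.alpha} sd_min={self.sd_min}\n")
            self.table.rename_axis("probe").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path, alpha: float = 0.05, sd_min: float = 0.1) -> "ScreeningResult":
        table = pd.read_csv(path, sep="\t", comment="#", index_col="probe")
        for col in ("passed_sd", "selected_mhp", "selected_lf"):
            table[col] = table[col].astype(bool)
        return cls(table=table, alpha=alpha, sd_min=sd_min)


def spearman_screen(
    meth: MethylationMatrix,
    pheno: PhenotypeTable,
    probes: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    sd_min: float = 0.1,
    method: str = "asymptotic",
    bh_correct: bool = False,
) -> ScreeningResult:
    """Per-diet Spearman screen of probe methylation against %BMIL.

    For each diet arm separately, computes Spearman rho (average-rank tie
    handling) between each probe and pct_bmil with a two-sided p-value,
    then flags probes selected at ``alpha``.  Probes whose methylation is
    constant within an arm have undefined rho there; they get p = 1 for
    that arm and a warning.

    Parameters
    ----------
    probes
        Probe ids to screen (typically the SD-filter survivors); defaults
        to every probe in the matrix.
    method
        'asymptotic' (t approximation, standard at n ~ 100) or 'exact'
        (full permutation enumeration, only for arms with n <= 9).
    bh_correct
        Apply Benjamini-Hochberg within each arm before flagging.  Off by
        default: the original screen used nominal p < alpha.
    """
    if probes is None:
        probes = meth.probe_ids
    probes = list(probes)
    unknown = [p for p in probes if p not in meth.frame.columns]
    if unknown:
        raise InputError(f"probes not in matrix: {', '.join(unknown[:5])}")
    sub = meth.frame[probes]
    pheno_aligned = pheno.aligned_to(meth.sample_ids)

    sd_all = sub.std(axis=0, ddof=1)
    out = pd.DataFrame(index=pd.Index(probes, name="probe"))
    out["sd"] = sd_all
    out["passed_sd"] = sd_all.to_numpy() > sd_min

    for diet in DIETS:
        mask = (pheno_aligned["diet"] == diet).to_numpy()
        n_arm = int(mask.sum())
        if n_arm < 4:
            raise InputError(f"{diet} arm has {n_arm} participants; need at least 4")
        X = sub.to_numpy()[mask]
        y = pheno_aligned.loc[mask, "pct_bmil"].to_numpy()
        rho = _rank_correlation(X, y)
        degenerate = np.isnan(rho)
        if method == "asymptotic":
            p = _asymptotic_p(np.where(degenerate, 0.0, rho), n_arm)
        elif method == "exact":
            p = np.array(
                [
                    1.0 if degenerate[j] else spearman_exact_p(X[:, j], y)
                    for j in range(X.shape[1])
                ]
            )
            p = np.clip(p, _TINY, 1.0)
        else:
            raise InputError(f"unknown p-value method {method!r}")
        if degenerate.any():
            bad = [probes[j] for j in np.flatnonzero(degenerate)[:5]]
            warnings.warn(
                f"{int(degenerate.sum())} probe(s) constant within the {diet} arm "
                f"(e.g. {', '.join(bad)}); rho undefined, p set to 1",
                stacklevel=2,
            )
            p[degenerate] = 1.0
        p_flag = p
        if bh_correct:
            p_flag = stats.false_discovery_control(p, method="bh")
        key = diet.lower()
        out[f"rho_{key}"] = rho
        out[f"p_{key}"] = p
        out[f"selected_{key}"] = out["passed_sd"].to_numpy() & (p_flag < alpha) & ~degenerate

    out = out[
        ["sd", "rho_mhp", "p_mhp", "rho_lf", "p_lf", "passed_sd", "selected_mhp", "selected_lf"]
    ]
    return ScreeningResult(table=out, alpha=alpha, sd_min=sd_min)
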