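"""In-memory containers: methylation matrix and phenotype table.

Both are thin, validating wrappers around :class:`pandas.DataFrame`; the
underlying frame is always reachable via ``.frame`` so the usual pandas
idioms stay available.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError

DIETS = ("MHP", "LF")
SEXES = ("female", "male")

PHENOTYPE_COLUMNS = ["id", "diet", "bmi_baseline", "bmi_final", "pct_bmil", "age", "sex"]


def _check_unique(values: Iterable, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise InputError(f"duplicate {what}: {', '.join(map(str, dupes))}")


class MethylationMatrix:
    """Samples x CpG probes matrix of (cell-composition adjusted) beta values.

    Parameters
    ----------
    values
        DataFrame with sample ids on the index and probe ids on the columns.
    strict_beta
        If True, assert every value lies in [0, 1].  Adjusted beta values can
        fall slightly outside the unit interval, so the default is False.
    """

    def __init__(self, values: pd.DataFrame, *, strict_beta: bool = False):
        if not isinstance(values, pd.DataFrame):
            raise InputError("methylation values must be a pandas DataFrame")
        _check_unique(values.index, "sample ids")
        _check_unique(values.columns, "probe ids")
        arr = values.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise InputError(
                f"non-finite methylation value at sample {values.index[i]!r}, "
                f"probe {values.columns[j]!r}"
            )
        if strict_beta and (arr.min() < 0.0 or arr.max() > 1.0):
            raise InputError("beta values outside [0, 1] with strict_beta=True")
        self.frame = values.astype(float)
        self.strict_beta = strict_beta

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def probe_ids(self) -> list:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def n_probes(self) -> int:
        return self.frame.shape[1]

    def subset_probes(self, probes: Iterable[str]) -> "MethylationMatrix":
        probes = list(probes)
        missing = [p for p in probes if p not in self.frame.columns]
        if missing:
            raise InputError(f"unknown probe ids: {', '.join(missing)}")
        return MethylationMatrix(self.frame[probes], strict_beta=self.strict_beta)

    def subset_samples(self, samples: Iterable[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.frame.loc[list(samples)], strict_beta=self.strict_beta)

    def __repr__(self) -> str:
        return f"MethylationMatrix({self.n_samples} samples x {self.n_probes} probes)"


class PhenotypeTable:
    """Per-participant phenotypes: diet arm, BMI trajectory, %BMIL, age, sex.

    %BMIL is stored as signed percent change, 100 * (BMI_final - BMI_baseline)
    / BMI_baseline, so weight loss is negative.  ``convention='loss_positive'``
    accepts tables where the sign was flipped (loss recorded as positive).
    """

    def __init__(self, frame: pd.DataFrame, *, convention: str = "signed",
                 check_consistency: bool = True, tol: float = 1e-6):
        if convention not in ("signed", "loss_positive"):
            raise InputError(f"unknown %BMIL convention {convention!r}")
        missing = [c for c in PHENOTYPE_COLUMNS if c not in frame.columns]
        if missing:
            raise InputError(f"phenotype table missing columns: {', '.join(missing)}")
        frame = frame[PHENOTYPE_COLUMNS].copy()
        _check_unique(frame["id"], "participant ids")
        if frame["diet"].isna().any():
            raise InputError("diet arm missing for some participants")
        bad_diet = set(frame["diet"]) - set(DIETS)
        if bad_diet:
            raise InputError(f"unknown diet labels: {sorted(bad_diet)}")
        bad_sex = set(frame["sex"].dropna()) - set(SEXES)
        if bad_sex:
            raise InputError(f"unknown sex labels: {sorted(bad_sex)}")
        if (frame["bmi_baseline"] <= 0).any():
            raise InputError("bmi_baseline must be positive")
        if check_consistency:
            full = frame.dropna(subset=["bmi_baseline", "bmi_final", "pct_bmil"])
            sign = 1.0 if convention == "signed" else -1.0
            recomputed = sign * 100.0 * (full["bmi_final"] - full["bmi_baseline"]) / full["bmi_baseline"]
            off = (recomputed - full["pct_bmil"]).abs() > tol * (1.0 + full["pct_bmil"].abs())
            if off.any():
                bad_id = full.loc[off, "id"].iloc[0]
                raise InputError(
                    f"pct_bmil inconsistent with BMI values (first offender: id {bad_id!r})"
                )
        self.frame = frame.reset_index(drop=True)
        self.convention = convention

    @property
    def ids(self) -> list:
        return list(self.frame["id"])

    def arm(self, diet: str) -> pd.DataFrame:
        if diet not in DIETS:
            raise InputError(f"unknown diet {diet!r}")
        return self.frame[self.frame["diet"] == diet]

    def arm_ids(self, diet: str) -> list:
        return list(self.arm(diet)["id"])

    def aligned_to(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Return the phenotype rows reordered to match ``sample_ids`` exactly."""
        idx = self.frame.set_index("id")
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise InputError(f"phenotypes missing for samples: {', '.join(map(str, missing))}")
        return idx.loc[sample_ids].reset_index()

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        n_mhp = int((self.frame["diet"] == "MHP").sum())
        return f"PhenotypeTable({len(self)} participants: {n_mhp} MHP / {len(self) - n_mhp} LF)"
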