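"""Delimited-text readers and writers for every pipeline artifact.

The pipeline starts after array preprocessing, so methylation comes in as
plain TSV (probe/sample ids in the first column, orientation selectable)
rather than any array-native format.  All writers can prepend ``#``
comment headers (package version, config hash, seed); all readers skip
them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, PhenotypeTable, PHENOTYPE_COLUMNS
from .errors import InputError, ParseError

ORIENTATIONS = ("samples_by_probes", "probes_by_samples")


def _read_table(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        raw = pd.read_csv(path, sep=sep, comment="#", index_col=0, dtype=str)
    except Exception as exc:  # malformed structure (ragged rows, empty file, ...)
        raise ParseError(f"{path}: {exc}") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique()[0]
        raise ParseError(f"{path}: duplicated id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].unique()[0]
        raise ParseError(f"{path}: duplicated column id {dup!r}")
    return raw


def _to_numeric(raw: pd.DataFrame, path) -> pd.DataFrame:
    converted = raw.apply(pd.to_numeric, errors="coerce")
    bad = converted.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell at row {raw.index[i]!r}, column {raw.columns[j]!r}: "
            f"{raw.iat[i, j]!r}"
        )
    if converted.isna().to_numpy().any():
        i, j = np.argwhere(converted.isna().to_numpy())[0]
        raise ParseError(f"{path}: empty cell at row {raw.index[i]!r}, column {raw.columns[j]!r}")
    # re-parse from the raw strings: astype uses the correctly rounded
    # converter, whereas pd.to_numeric's fast path can be off by one ulp
    return raw.astype(float)


def read_methylation(
    path,
    orientation: str = "samples_by_probes",
    strict_beta: bool = False,
) -> MethylationMatrix:
    """Read a methylation TSV.

    ``orientation`` names the layout of the file: 'samples_by_probes'
    (rows are samples) or 'probes_by_samples' (rows are probes; the matrix
    is transposed on read so the in-memory object is always samples x
    probes).
    """
    if orientation not in ORIENTATIONS:
        raise InputError(f"unknown orientation {orientation!r}; choose from {ORIENTATIONS}")
    values = _to_numeric(_read_table(path, sep="\t"), path)
    if orientation == "probes_by_samples":
        values = values.T
    values = values.rename_axis(index=None, columns=None)
    return MethylationMatrix(values, strict_beta=strict_beta)


def write_methylation(
    meth: MethylationMatrix,
    path,
    orientation: str = "samples_by_probes",
    header_comment: Optional[str] = None,
) -> None:
    if orientation not in ORIENTATIONS:
        raise InputError(f"unknown orientation {orientation!r}; choose from {ORIENTATIONS}")
    frame = meth.frame if orientation == "samples_by_probes" else meth.frame.T
    label = "sample_id" if orientation == "samples_by_probes" else "probe_id"
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        # %.17g round-trips IEEE doubles exactly
        frame.rename_axis(label).to_csv(fh, sep="\t", float_format="%.17g")


def read_phenotypes(path, convention: str = "signed") -> PhenotypeTable:
    """Read the phenotype CSV (columns id,diet,bmi_baseline,bmi_final,
    pct_bmil,age,sex)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in PHENOTYPE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {', '.join(missing)}")
    for col in ("bmi_baseline", "bmi_final", "pct_bmil", "age"):
        try:
            frame[col] = pd.to_numeric(frame[col]).astype(float)
        except Exception as exc:
            raise ParseError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    frame["id"] = frame["id"].astype(str)
    return PhenotypeTable(frame, convention=convention)


def write_phenotypes(pheno: PhenotypeTable, path, header_comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pheno.frame.to_csv(fh, index=False, float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    from .scoring import SCORE_COLUMNS, validate_score_table

    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "id" not in frame.columns:
        raise ParseError(f"{path}: missing 'id' column")
    frame["id"] = frame["id"].astype(str)
    frame = frame.set_index("id")
    frame = frame.astype({c: float for c in frame.columns if c in SCORE_COLUMNS})
    return validate_score_table(frame)


def write_scores(scores: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        scores.rename_axis("id").to_csv(fh, float_format="%.17g")


def read_recommendations(path) -> pd.DataFrame:
    from .decision import REC_COLUMNS

    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in REC_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {', '.join(missing)}")
    numeric = [c for c in REC_COLUMNS if c not in ("id", "category")]
    frame = frame.astype({c: float for c in numeric})
    frame["id"] = frame["id"].astype(str)
    return frame


def write_recommendations(recs: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        recs.to_csv(fh, index=False, float_format="%.17g")


def write_fit_table(fit, path, header_comment: Optional[str] = None) -> None:
    """Write a per-diet regression fit table (cpg, beta, sem, p, vif)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fit.to_frame().to_csv(fh, sep="\t", index=False)
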