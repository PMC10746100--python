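import numpy as np
import pandas as pd
import pytest

from methyldiet import MethylationMatrix, PhenotypeTable


def make_phenotypes(diet, pct_bmil, age=None, sex=None, ids=None):
    """Build a consistent PhenotypeTable from raw arrays (BMI trajectory
    derived from %BMIL so the internal consistency check holds)."""
    n = len(diet)
    ids = list(ids) if ids is not None else [f"S{i:04d}" for i in range(n)]
    pct = np.asarray(pct_bmil, dtype=float)
    baseline = np.full(n, 30.0)
    return PhenotypeTable(
        pd.DataFrame(
            {
                "id": ids,
                "diet": list(diet),
                "bmi_baseline": baseline,
                "bmi_final": baseline * (1.0 + pct / 100.0),
                "pct_bmil": pct,
                "age": age if age is not None else np.full(n, 45.0),
                "sex": sex if sex is not None else ["female"] * n,
            }
        )
    )


def make_matrix(values, sample_ids=None, probe_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i:04d}" for i in range(n)]
    probe_ids = probe_ids or [f"cg{i:08d}" for i in range(p)]
    return MethylationMatrix(pd.DataFrame(values, index=sample_ids, columns=probe_ids))


@pytest.fixture
def small_cohort():
    """Deterministic 40-sample, 12-probe cohort with both diet arms."""
    rng = np.random.default_rng(42)
    n, p = 40, 12
    meth = make_matrix(rng.beta(2, 2, size=(n, p)))
    diet = np.where(rng.random(n) < 0.5, "MHP", "LF")
    pct = -10 + 8.0 * meth.values[:, 0] + rng.normal(0, 1, n)
    pheno = make_phenotypes(
        diet,
        pct,
        age=rng.uniform(20, 65, n),
        sex=np.where(rng.random(n) < 0.5, "female", "male"),
        ids=meth.sample_ids,
    )
    return meth, pheno
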