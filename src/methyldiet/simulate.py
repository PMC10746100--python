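"""Synthetic EWAS-style cohorts with diet-specific methylation effects.

The generator emulates the structure the downstream pipeline assumes: a
large CpG pool of which only a designated fraction is dispersed (sample SD
above 0.1), two diet arms, and a small set of arm-specific CpGs whose
baseline methylation is linearly associated with the percentage of BMI
loss (%BMIL).  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, PhenotypeTable
from .errors import ConfigurationError

# Beta-mixture shape parameters.  High-variance probes draw from a symmetric
# intermediate component (population SD ~0.22, so the sample SD at n~200
# exceeds 0.1 essentially always); the remaining probes sit near 0 or 1
# with population SD ~0.02.
_HIGH_VAR_SHAPE = (2.0, 2.0)
_LOW_VAR_SHAPE = (1.0, 40.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    n_individuals
        Cohort size.
    frac_mhp
        Probability of assignment to the moderately-high-protein arm.
    n_cpgs
        Total probe pool size.
    n_high_var
        Number of probes drawn from the dispersed mixture component
        (population SD well above the 0.1 screening threshold).
    n_effect_mhp, n_effect_lf
        Number of CpGs causally tied to %BMIL within each arm.  The two
        effect sets are disjoint, mirroring the absence of overlap between
        the per-diet association lists observed on real cohorts.
    effect_size_range
        Magnitude range of the per-unit-methylation %BMIL slopes; each
        slope gets a random sign.
    intercept_pct
        Mean %BMIL (signed percent change; negative = loss).
    noise_sd
        SD of the Gaussian residual added to %BMIL, in percent points.
    beta_noise_sd
        SD of technical noise added to beta values before clipping.
    age_range
        Uniform age range, years.
    seed
        Seed for every random draw.
    positive_loss
        Flip the %BMIL sign convention so that loss is positive.
    clip_beta
        Clip beta values to [0, 1] after noise injection; disable to mimic
        cell-composition-adjustment residues slightly outside the unit
        interval.
    """

    n_individuals: int = 201
    frac_mhp: float = 93 / 201
    n_cpgs: int = 2000
    n_high_var: int = 300
    n_effect_mhp: int = 5
    n_effect_lf: int = 5
    effect_size_range: tuple = (3.4, 9.9)
    intercept_pct: float = -10.0
    noise_sd: float = 2.5
    beta_noise_sd: float = 0.01
    age_range: tuple = (18.0, 67.0)
    seed: int = 0
    positive_loss: bool = False
    clip_beta: bool = True

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("n_individuals must be at least 2")
        if not (0.0 < self.frac_mhp < 1.0):
            raise ConfigurationError("frac_mhp must lie in (0, 1)")
        if self.n_effect_mhp < 0 or self.n_effect_lf < 0:
            raise ConfigurationError("effect CpG counts must be non-negative")
        if self.n_effect_mhp + self.n_effect_lf > self.n_high_var:
            raise ConfigurationError(
                "n_effect_mhp + n_effect_lf must not exceed n_high_var "
                "(effect CpGs are drawn from the high-variance pool)"
            )
        if self.n_high_var > self.n_cpgs:
            raise ConfigurationError("n_high_var must not exceed n_cpgs")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.beta_noise_sd < 0:
            raise ConfigurationError("beta_noise_sd must be non-negative")
        lo, hi = self.effect_size_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("effect_size_range must satisfy 0 <= lo <= hi")
        lo, hi = self.age_range
        if hi < lo:
            raise ConfigurationError("age_range must satisfy lo <= hi")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_size_range"] = list(d["effect_size_range"])
        d["age_range"] = list(d["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("effect_size_range", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def obekit_like_config(**overrides) -> SimulationConfig:
    """Config mirroring the reference weight-loss cohort: 201 participants
    (93 MHP / 108 LF), 1233 dispersed probes, 15 MHP and 11 LF effect CpGs.

    The probe pool defaults to 5000: the full EPIC array carries ~850k
    probes, but only the dispersed minority survives the SD filter, so a
    desk-scale pool with the same number of SD-filter survivors preserves
    every downstream property.  Effect-slope magnitudes span the range of
    the published regression coefficients (3.4-9.9 %BMIL per methylation
    unit).
    """
    cfg = SimulationConfig(
        n_individuals=201,
        frac_mhp=93 / 201,
        n_cpgs=5000,
        n_high_var=1233,
        n_effect_mhp=15,
        n_effect_lf=11,
        effect_size_range=(3.4, 9.9),
        intercept_pct=-10.0,
        noise_sd=2.5,
        age_range=(18.0, 67.0),
    )
    return cfg.replace(**overrides) if overrides else cfg


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to build it."""

    methylation: MethylationMatrix
    phenotypes: PhenotypeTable
    truth: dict
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, out_dir) -> dict:
        """Write methylation TSV, phenotype CSV and truth JSON; return paths."""
        from . import io as _io

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "methylation": out_dir / "methylation.tsv",
            "phenotypes": out_dir / "phenotypes.csv",
            "truth": out_dir / "truth.json",
        }
        _io.write_methylation(self.methylation, paths["methylation"])
        _io.write_phenotypes(self.phenotypes, paths["phenotypes"])
        payload = dict(self.truth)
        if self.config is not None:
            payload["config"] = self.config.to_dict()
        paths["truth"].write_text(json.dumps(payload, indent=2))
        return {k: str(v) for k, v in paths.items()}


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort.

    Beta values come from a Beta-mixture (intermediate component for the
    designated high-variance probes, near-0/near-1 components for the
    rest) with optional technical noise and clipping.  %BMIL is
    ``intercept + sum_j slope_j * m_ij + noise`` where the sum runs over
    the effect CpGs of the individual's own arm and ``m_ij`` is the
    observed (noisy, clipped) beta value, so the truth record reproduces
    the outcome exactly when ``noise_sd -> 0``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_cpgs

    probe_ids = np.array([f"cg{i:08d}" for i in range(p)])
    sample_ids = [f"S{i:04d}" for i in range(n)]

    high_var_idx = rng.choice(p, size=config.n_high_var, replace=False)
    high_var_mask = np.zeros(p, dtype=bool)
    high_var_mask[high_var_idx] = True

    betas = np.empty((n, p))
    a, b = _HIGH_VAR_SHAPE
    betas[:, high_var_mask] = rng.beta(a, b, size=(n, config.n_high_var))
    n_low = p - config.n_high_var
    low = rng.beta(*_LOW_VAR_SHAPE, size=(n, n_low))
    # half of the concentrated probes sit near 1 instead of near 0
    flip = rng.random(n_low) < 0.5
    low[:, flip] = 1.0 - low[:, flip]
    betas[:, ~high_var_mask] = low

    if config.beta_noise_sd > 0:
        betas = betas + rng.normal(0.0, config.beta_noise_sd, size=betas.shape)
    if config.clip_beta:
        np.clip(betas, 0.0, 1.0, out=betas)

    n_eff = config.n_effect_mhp + config.n_effect_lf
    eff_idx = rng.choice(high_var_idx, size=n_eff, replace=False)
    eff_mhp = eff_idx[: config.n_effect_mhp]
    eff_lf = eff_idx[config.n_effect_mhp:]

    lo, hi = config.effect_size_range
    signs = rng.choice([-1.0, 1.0], size=n_eff)
    slopes = signs * rng.uniform(lo, hi, size=n_eff)
    slopes_mhp = slopes[: config.n_effect_mhp]
    slopes_lf = slopes[config.n_effect_mhp:]

    diet = np.where(rng.random(n) < config.frac_mhp, "MHP", "LF")

    signal = np.zeros(n)
    is_mhp = diet == "MHP"
    if config.n_effect_mhp:
        signal[is_mhp] = betas[np.ix_(is_mhp, eff_mhp)] @ slopes_mhp
    if config.n_effect_lf:
        signal[~is_mhp] = betas[np.ix_(~is_mhp, eff_lf)] @ slopes_lf
    pct_bmil = config.intercept_pct + signal + rng.normal(0.0, config.noise_sd, size=n)
    signed = pct_bmil.copy()
    if config.positive_loss:
        pct_bmil = -pct_bmil

    age = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    bmi_baseline = rng.uniform(25.0, 40.0, size=n)
    bmi_final = bmi_baseline * (1.0 + signed / 100.0)

    meth = MethylationMatrix(
        pd.DataFrame(betas, index=sample_ids, columns=probe_ids),
        strict_beta=config.clip_beta,
    )
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "id": sample_ids,
                "diet": diet,
                "bmi_baseline": bmi_baseline,
                "bmi_final": bmi_final,
                "pct_bmil": pct_bmil,
                "age": age,
                "sex": sex,
            }
        ),
        convention="loss_positive" if config.positive_loss else "signed",
    )
    truth = {
        "MHP": {
            "cpgs": list(probe_ids[eff_mhp]),
            "slopes": slopes_mhp.tolist(),
            "intercept": config.intercept_pct,
            "noise_sd": config.noise_sd,
        },
        "LF": {
            "cpgs": list(probe_ids[eff_lf]),
            "slopes": slopes_lf.tolist(),
            "intercept": config.intercept_pct,
            "noise_sd": config.noise_sd,
        },
        "high_variance_cpgs": list(probe_ids[np.sort(high_var_idx)]),
    }
    return SyntheticCohort(methylation=meth, phenotypes=pheno, truth=truth, config=config)
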