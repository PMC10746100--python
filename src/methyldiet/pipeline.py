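"""End-to-end orchestration: simulate/load -> screen -> select -> score ->
fit -> recommend, with every intermediate artifact written to disk.

Runs are fully deterministic given the config (including its seed): no
timestamps enter any output, so two runs of the same config produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as _io
from .containers import DIETS, MethylationMatrix, PhenotypeTable
from .decision import recommend_diet, summarize_population
from .errors import ConfigurationError, EmptyModelError, MethyldietError
from .interaction import fit_interaction_model
from .scoring import DietScoreWeights, build_weights, score_cohort
from .screening import filter_by_sd, spearman_screen
from .simulate import SimulationConfig, generate_cohort
from .subset import choose_subset, leaps_and_bounds, refit_and_prune

_CRITERIA = ("AIC", "BIC", "AICc", "adjR2")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    Either ``simulate`` (a :class:`SimulationConfig`) or both ``meth_path``
    and ``pheno_path`` must be given.  ``max_candidates`` bounds how many
    screened CpGs (ordered by ascending screening p-value) enter the exact
    best-subset search, keeping its certified-exhaustive cost bounded.
    """

    out_dir: str = "methyldiet_run"
    simulate: Optional[SimulationConfig] = None
    meth_path: Optional[str] = None
    pheno_path: Optional[str] = None
    orientation: str = "samples_by_probes"
    sd_min: float = 0.1
    alpha_screen: float = 0.05
    screen_method: str = "asymptotic"
    bh_correct: bool = False
    max_candidates: int = 18
    criterion: str = "AIC"
    p_keep: float = 0.19
    vif_max: float = 10.0
    adjust: bool = True
    diet_ref: str = "MHP"
    sex_ref: str = "female"
    alpha_decision: float = 0.05
    covariance_mode: str = "independent"
    grid_points: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and not (self.meth_path and self.pheno_path):
            raise ConfigurationError(
                "config needs either a 'simulate' block or both meth_path and pheno_path"
            )
        if self.simulate is not None:
            self.simulate.validate()
        for name, val in (("alpha_screen", self.alpha_screen), ("alpha_decision", self.alpha_decision)):
            if not (0.0 <= val < 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if self.sd_min < 0:
            raise ConfigurationError("sd_min must be non-negative")
        if self.criterion not in _CRITERIA:
            raise ConfigurationError(f"criterion must be one of {_CRITERIA}")
        if not (0.0 < self.p_keep <= 1.0):
            raise ConfigurationError("p_keep must lie in (0, 1]")
        if self.vif_max < 1.0:
            raise ConfigurationError("vif_max below 1 would remove every predictor")
        if self.max_candidates < 1:
            raise ConfigurationError("max_candidates must be at least 1")
        if self.covariance_mode not in ("independent", "full"):
            raise ConfigurationError("covariance_mode must be 'independent' or 'full'")
        if self.diet_ref not in DIETS:
            raise ConfigurationError(f"diet_ref must be one of {DIETS}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(payload)

    def config_hash(self) -> str:
        """Fingerprint of the scientific parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@contextmanager
def _stage(name: str):
    try:
        yield
    except MethyldietError as exc:
        if not getattr(exc, "_stage_tagged", False):
            exc._stage_tagged = True
            exc.stage = name
            exc.args = (f"[stage: {name}] {exc}",)
        raise


def train_diet_weights(
    meth: MethylationMatrix,
    pheno: PhenotypeTable,
    screening,
    diet: str,
    criterion: str = "AIC",
    p_keep: float = 0.19,
    vif_max: float = 10.0,
    max_candidates: int = 18,
):
    """Select the best CpG subset for one arm and return (weights, fit).

    Candidates are that arm's screened CpGs (ascending p-value, truncated
    at ``max_candidates``); the certified best-subset search plus
    criterion choice plus p/VIF pruning yields the final regression fit,
    whose coefficients become the score weights.
    """
    candidates = screening.candidates(diet, max_candidates=max_candidates)
    if not candidates:
        raise EmptyModelError(f"no CpGs selected by the screen for the {diet} arm")
    arm_ids = pheno.arm_ids(diet)
    X = meth.frame.loc[arm_ids, candidates]
    y = pheno.arm(diet).set_index("id").loc[arm_ids, "pct_bmil"].to_numpy()
    search = leaps_and_bounds(X, y)
    subset = choose_subset(search, n=len(arm_ids), criterion=criterion)
    fit = refit_and_prune(X, y, subset, p_keep=p_keep, vif_max=vif_max)
    return build_weights(fit, diet), fit


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.out_dir``.

    Returns the manifest: artifact name -> path, plus headline numbers
    (per-arm counts, recommendation counts).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    tag = f"methyldiet {__version__} config={config.config_hash()} seed={config.seed}"
    manifest = {"config_hash": config.config_hash(), "seed": config.seed, "artifacts": {}}

    def record(name, path):
        manifest["artifacts"][name] = str(path)

    with _stage("input"):
        if config.simulate is not None:
            sim_cfg = config.simulate.replace(seed=config.seed)
            cohort = generate_cohort(sim_cfg)
            paths = cohort.write(out)
            for k, v in paths.items():
                record(k, v)
            meth, pheno = cohort.methylation, cohort.phenotypes
        else:
            meth = _io.read_methylation(config.meth_path, orientation=config.orientation)
            pheno = _io.read_phenotypes(config.pheno_path)

    with _stage("screen"):
        survivors = filter_by_sd(meth, sd_min=config.sd_min)
        screening = spearman_screen(
            meth,
            pheno,
            probes=survivors,
            alpha=config.alpha_screen,
            sd_min=config.sd_min,
            method=config.screen_method,
            bh_correct=config.bh_correct,
        )
        screen_path = out / "screen.tsv"
        screening.to_tsv(screen_path, header_comment=tag)
        record("screen", screen_path)

    weights = {}
    with _stage("select"):
        for diet in DIETS:
            w, fit = train_diet_weights(
                meth,
                pheno,
                screening,
                diet,
                criterion=config.criterion,
                p_keep=config.p_keep,
                vif_max=config.vif_max,
                max_candidates=config.max_candidates,
            )
            weights[diet] = w
            fit_path = out / f"fit_{diet.lower()}.tsv"
            _io.write_fit_table(fit, fit_path, header_comment=tag)
            record(f"fit_{diet.lower()}", fit_path)
            w_path = out / f"weights_{diet.lower()}.json"
            w.to_json(w_path)
            record(f"weights_{diet.lower()}", w_path)

    with _stage("score"):
        scores = score_cohort(meth, weights["MHP"], weights["LF"])
        scores_path = out / "scores.csv"
        _io.write_scores(scores, scores_path, header_comment=tag)
        record("scores", scores_path)

    with _stage("fit"):
        results = fit_interaction_model(
            scores,
            pheno,
            adjust=config.adjust,
            diet_ref=config.diet_ref,
            sex_ref=config.sex_ref,
        )
        fit_path = out / "fit.json"
        results.to_json(fit_path)
        record("fit", fit_path)
        marg = results.predict_marginals(np.linspace(*results.score_range, config.grid_points))
        marg_path = out / "marginals.csv"
        with open(marg_path, "w") as fh:
            fh.write(f"# {tag}\n")
            marg.to_frame().to_csv(fh, index=False)
        record("marginals", marg_path)

    with _stage("recommend"):
        recs = recommend_diet(
            results,
            scores,
            alpha=config.alpha_decision,
            covariance_mode=config.covariance_mode,
        )
        recs_path = out / "recommendations.csv"
        _io.write_recommendations(recs, recs_path, header_comment=tag)
        record("recommendations", recs_path)
        summary = summarize_population(recs, alpha=config.alpha_decision)
        summary_path = out / "summary.json"
        summary.to_json(summary_path)
        record("summary", summary_path)

    manifest["n_weights_mhp"] = len(weights["MHP"])
    manifest["n_weights_lf"] = len(weights["LF"])
    manifest["counts"] = summary.counts

    log_path = out / "run_log.json"
    log_path.write_text(
        json.dumps(
            {"version": __version__, "config": config.to_dict(), "config_hash": config.config_hash(), "seed": config.seed},
            indent=2,
            sort_keys=True,
        )
    )
    record("run_log", log_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
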