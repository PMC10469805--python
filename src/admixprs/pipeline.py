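"""End-to-end pipeline: simulate/load -> harmonize -> candidate grid ->
CV selection -> PRSsum (with and without the APOE region) -> association.

Stages communicate through serialized files under the output directory,
and a JSON manifest records seeds, input hashes, and output hashes so a
rerun with the same config reproduces outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import compute_pcs, run_primary_analysis, subgroup_association
from .engine import (
    DEFAULT_P_THRESHOLDS,
    DEFAULT_R2_GRID,
    DEFAULT_WINDOW_GRID_KB,
    PRSModel,
    build_candidate_grid,
    exclude_model_region,
    score,
)
from .panel import GenotypePanel
from .selection import partition_unrelated, prssum, select_best, standardize
from .sim import (
    DEFAULT_GWAS_SUITE,
    SimulationConfig,
    simulate_cohort_phenotypes,
    simulate_gwas_suite,
    simulate_kinship_pairs,
    simulate_panel,
)
from .sumstats import GenomicRegion, harmonize, read_sumstats

logger = logging.getLogger(__name__)


class PipelineValidationError(ValueError):
    """Invalid or incomplete configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 1
    simulate: dict | None = None  # SimulationConfig overrides; None = use inputs
    sumstats_paths: dict[str, str] = field(default_factory=dict)
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    kinship_path: str | None = None
    maf_min: float = 0.01
    apoe_region: dict = field(
        default_factory=lambda: {"chromosome": "19", "center": 44908822, "width": 1_000_000}
    )
    r2_grid: tuple = DEFAULT_R2_GRID
    window_grid_kb: tuple = DEFAULT_WINDOW_GRID_KB
    p_thresholds: tuple = DEFAULT_P_THRESHOLDS
    k_subsets: int = 4
    n_pcs: int = 5
    covariates: tuple = (
        "age_baseline",
        "time_between_visits",
        "sex",
        "education",
        "center",
    )
    cluster_var: str | None = "household_id"
    sensitivity: bool = True
    subgroup_min_prop: float = 0.2

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineValidationError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise PipelineValidationError("config must set out_dir")
        return cls(**raw)

    def region(self) -> GenomicRegion:
        r = self.apoe_region
        if "start" in r and "end" in r:
            return GenomicRegion(str(r["chromosome"]), int(r["start"]), int(r["end"]))
        return GenomicRegion.from_center(
            str(r["chromosome"]), int(r["center"]), int(r["width"])
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "inputs": {},
        "outputs": {},
    }
    region = config.region()

    def stage(name):
        logger.info("pipeline stage: %s", name)
        manifest["stages"].append(name)

    try:
        if config.simulate is not None:
            stage("simulate")
            sim_dir = os.path.join(config.out_dir, "inputs")
            os.makedirs(sim_dir, exist_ok=True)
            overrides = dict(config.simulate)
            suite = overrides.pop("gwas_suite", DEFAULT_GWAS_SUITE)
            overrides.setdefault("seed", config.seed)
            sim_cfg = SimulationConfig(**overrides)
            panel, truth = simulate_panel(sim_cfg)
            cohort = simulate_cohort_phenotypes(panel, truth, sim_cfg)
            kinship = simulate_kinship_pairs(
                panel.sample_ids, seed=sim_cfg.seed + 7
            )
            gwas = simulate_gwas_suite(truth, panel, suite=suite, seed=sim_cfg.seed)
            config.genotypes_path = os.path.join(sim_dir, "genotypes.vcf")
            panel.to_vcf(config.genotypes_path)
            config.phenotypes_path = os.path.join(sim_dir, "phenotypes.tsv")
            _write_tsv(cohort, config.phenotypes_path)
            config.kinship_path = os.path.join(sim_dir, "kinship.tsv")
            _write_tsv(kinship, config.kinship_path)
            config.sumstats_paths = {}
            for name, ss in gwas.items():
                p = os.path.join(sim_dir, f"sumstats_{name}.tsv")
                ss.write(p)
                config.sumstats_paths[name] = p
            truth.causal_variants.to_csv(
                os.path.join(sim_dir, "truth_causal.tsv"), sep="\t", index=False
            )
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    for label, path in [
        ("genotypes", config.genotypes_path),
        ("phenotypes", config.phenotypes_path),
        ("kinship", config.kinship_path),
        *[(f"sumstats:{n}", p) for n, p in config.sumstats_paths.items()],
    ]:
        if path is None or not os.path.exists(path):
            raise PipelineValidationError(f"missing input file for {label}: {path}")
        manifest["inputs"][label] = {"path": path, "sha256": _sha256(path)}
    if not config.sumstats_paths:
        raise PipelineValidationError("no summary-statistics inputs configured")

    try:
        stage("load")
        panel = GenotypePanel.from_vcf(config.genotypes_path)
        cohort = pd.read_csv(config.phenotypes_path, sep="\t")
        kinship = pd.read_csv(config.kinship_path, sep="\t")
        gwas = {
            name: read_sumstats(path, gwas_name=name)
            for name, path in config.sumstats_paths.items()
        }

        stage("pcs")
        pcs = compute_pcs(panel, config.n_pcs)
        cohort = cohort.merge(
            pcs, left_on="sample_id", right_index=True, how="left"
        )
        covariates = tuple(config.covariates) + tuple(pcs.columns)

        stage("harmonize")
        harmonized = {
            name: harmonize(ss, panel, config.maf_min) for name, ss in gwas.items()
        }
        for name, ss in harmonized.items():
            ss.write(os.path.join(config.out_dir, f"harmonized_{name}.tsv"))

        stage("select")
        partition = partition_unrelated(
            list(cohort["sample_id"]), kinship, k=config.k_subsets, seed=config.seed
        )
        selected: dict[str, PRSModel] = {}
        for name, ss in harmonized.items():
            candidates = build_candidate_grid(
                ss,
                panel,
                r2_set=config.r2_grid,
                window_set=config.window_grid_kb,
                p_set=config.p_thresholds,
            )
            model, report = select_best(
                candidates, panel, cohort, partition, covariates=covariates
            )
            selected[name] = model
            _write_tsv(
                report, os.path.join(config.out_dir, f"selection_{name}.tsv")
            )
            model.write(os.path.join(config.out_dir, f"selected_{name}.txt"))

        stage("prssum")
        with_scores, without_scores = [], []
        score_sets: dict[str, dict] = {}
        for name, model in selected.items():
            sv = standardize(score(panel, model))
            model_no = exclude_model_region(model, region)
            score_sets[name] = {"with_apoe": sv.standardized}
            with_scores.append(sv)
            if not model_no.degenerate:
                sv_no = standardize(score(panel, model_no))
                score_sets[name]["without_apoe"] = sv_no.standardized
                without_scores.append(sv_no)
                model_no.write(
                    os.path.join(config.out_dir, f"selected_{name}_noapoe.txt")
                )
        prssum_with = prssum(with_scores)
        score_sets["PRSsum"] = {"with_apoe": prssum_with.standardized}
        if len(without_scores) == len(with_scores):
            score_sets["PRSsum"]["without_apoe"] = prssum(without_scores).standardized
        scores_out = pd.DataFrame({"sample_id": panel.sample_ids})
        for name, pair in score_sets.items():
            for which, vals in pair.items():
                scores_out[f"{name}_{which}"] = vals
        _write_tsv(scores_out, os.path.join(config.out_dir, "scores.tsv"))

        stage("associate")
        results = run_primary_analysis(
            cohort,
            score_sets,
            covariates=covariates,
            cluster_var=config.cluster_var,
            sensitivity=config.sensitivity,
        )
        _write_tsv(results, os.path.join(config.out_dir, "associations.tsv"))
        sub_rows = []
        prs_col = np.asarray(score_sets["PRSsum"]["with_apoe"])
        sub_rows.append(
            subgroup_association(
                cohort, prs_col, ("background",), covariates=covariates
            )
        )
        for anc in [c.removeprefix("anc_") for c in cohort.columns if c.startswith("anc_")]:
            sub_rows.append(
                subgroup_association(
                    cohort,
                    prs_col,
                    ("ancestry", anc, config.subgroup_min_prop),
                    covariates=covariates,
                )
            )
        _write_tsv(
            pd.concat(sub_rows, ignore_index=True),
            os.path.join(config.out_dir, "subgroups.tsv"),
        )
    except PipelineValidationError:
        raise
    except Exception as exc:
        raise StageError(
            f"stage '{manifest['stages'][-1]}' failed: {exc}"
        ) from exc

    for fname in sorted(os.listdir(config.out_dir)):
        fpath = os.path.join(config.out_dir, fname)
        if os.path.isfile(fpath) and fname != "manifest.json":
            manifest["outputs"][fname] = _sha256(fpath)
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
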