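"""End-to-end pipeline: simulate/ingest -> QC -> BLUEs -> GBLUP -> CV -> selection.

A :class:`PipelineConfig` (readable from YAML) drives the full analysis and
writes a bundle of artifacts to the output directory:

* ``genotypes.csv`` / ``qc_report.json`` / ``kernel.csv``
* ``blues.csv``, ``h2.json``, ``condition_correlations.json``
* ``variance_proportions.csv`` (per trait x model)
* ``cv_records.csv``, ``cv_summary.csv``, ``model_letters.csv``
* ``selection.csv``, ``differentials.csv``
* ``summary.json`` (machine-readable roll-up) and ``report.md``

Every stage derives its random stream from the global seed with a fixed
per-stage offset, so re-running a stage (or the whole pipeline) with the
same configuration is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from ._util import stage_rng
from .cv import CV_MCMC, compare_models, make_folds, run_cv
from .errors import AlugsError, ConfigurationError
from .gblup import fit_model, gebv_frame, variance_proportions
from .genotypes import GenotypeMatrix
from .index import (
    GSI_WEIGHTS, PSI_WEIGHTS, blues_wide, build_gsi, build_psi, compute_iyld,
    select_top, selection_differential,
)
from .qc import compute_linear_kernel, filter_snps, impute_missing
from .simulate import SimulationConfig, simulate_dataset
from .spatial import compute_blues, correlate_conditions, estimate_h2, fit_single_trial
from .vcfio import read_dosage_csv, read_vcf, write_dosage_csv, write_kernel_csv

log = logging.getLogger("alugs")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    outdir: str
    seed: int = 0
    # data source: either a simulation block or file paths
    simulation: Optional[Dict] = None
    genotypes_vcf: Optional[str] = None
    genotypes_csv: Optional[str] = None
    plots_csv: Optional[str] = None
    # QC
    max_missing: float = 0.2
    min_depth: int = 10
    min_maf: float = 0.025
    # analysis
    traits: Sequence[str] = ("FL", "PH", "YLD", "ZN")
    target: str = "ALU"
    secondary: str = "LIM"
    models: Sequence[str] = ("SM", "MM", "MDs", "MDe")
    smooth: str = "tensor_spline"
    cv_k: int = 5
    cv_repetitions: int = 10
    mcmc: Dict[str, int] = field(default_factory=lambda: dict(CV_MCMC))
    gsi_weights: Dict[str, float] = field(default_factory=lambda: dict(GSI_WEIGHTS))
    psi_weights: Dict[str, float] = field(default_factory=lambda: dict(PSI_WEIGHTS))
    selection_fraction: float = 0.10

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        has_files = self.plots_csv and (self.genotypes_vcf or self.genotypes_csv)
        if self.simulation is None and not has_files:
            raise ConfigurationError(
                "config must provide either a simulation block or genotype+plot files")
        for p in (self.genotypes_vcf, self.genotypes_csv, self.plots_csv):
            if p and not os.path.exists(p):
                raise ConfigurationError(f"input file does not exist: {p}")
        for m in self.models:
            if m not in ("SM", "MM", "MDs", "MDe"):
                raise ConfigurationError(f"unknown model {m!r}")


def validate_inputs(genotypes: GenotypeMatrix, plots: pd.DataFrame) -> List[str]:
    """Cross-check entry ids between genotype and phenotype tables.

    Returns one warning per orphan id; raises when the id sets are disjoint
    (nothing could be analyzed).
    """
    geno_ids = set(genotypes.line_ids)
    pheno_ids = set(plots.loc[~plots["is_check"].astype(bool), "entry_id"])
    issues = [f"genotyped line {i} has no phenotype records" for i in sorted(geno_ids - pheno_ids)]
    issues += [f"phenotyped entry {i} has no genotype" for i in sorted(pheno_ids - geno_ids)]
    if not geno_ids & pheno_ids:
        raise ConfigurationError("genotype and phenotype entry ids are disjoint")
    return issues


def _dump_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage and return the machine-readable summary dict."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    t_start = time.time()
    summary: Dict = {"version": __version__, "seed": config.seed, "stages": []}

    def stage(name):
        # wall time goes to the log only; summary.json stays bit-reproducible
        log.info("stage %s (seed %d, t=%.1fs)", name, config.seed, time.time() - t_start)
        summary["stages"].append(name)

    # ------------------------------------------------------------ data
    stage("data")
    truth = None
    if config.simulation is not None:
        sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed})
        genotypes, truth, plots = simulate_dataset(sim_cfg)
        write_dosage_csv(genotypes, os.path.join(config.outdir, "genotypes.csv"))
        plots.to_csv(os.path.join(config.outdir, "plots.csv"), index=False)
    else:
        genotypes = (read_vcf(config.genotypes_vcf) if config.genotypes_vcf
                     else read_dosage_csv(config.genotypes_csv))
        plots = pd.read_csv(config.plots_csv)
    issues = validate_inputs(genotypes, plots)
    for msg in issues:
        log.warning(msg)
    summary["input_issues"] = issues

    # -------------------------------------------------------------- qc
    stage("qc")
    filtered, report = filter_snps(genotypes, max_missing=config.max_missing,
                                   min_depth=config.min_depth, min_maf=config.min_maf)
    complete = impute_missing(filtered, method="marker_mean")
    kernel = compute_linear_kernel(complete)
    _dump_json(report.to_dict(), os.path.join(config.outdir, "qc_report.json"))
    write_kernel_csv(kernel, os.path.join(config.outdir, "kernel.csv"))
    summary["qc"] = report.to_dict()

    # ----------------------------------------------------------- blues
    stage("blues")
    conditions = [config.target, config.secondary]
    blues = compute_blues(plots, config.traits, conditions, smooth=config.smooth)
    blues.to_csv(os.path.join(config.outdir, "blues.csv"), index=False)
    h2 = {}
    for cond in conditions:
        for trait in config.traits:
            fit = fit_single_trial(plots, trait, genotype_as="random",
                                   smooth=config.smooth, condition=cond)
            h2[f"{trait}_{cond}"] = estimate_h2(fit)
    _dump_json(h2, os.path.join(config.outdir, "h2.json"))
    corrs = {t: correlate_conditions(blues, t, method="spearman",
                                     conditions=(config.target, config.secondary))[0]
             for t in config.traits}
    _dump_json(corrs, os.path.join(config.outdir, "condition_correlations.json"))
    summary["h2"] = h2
    summary["condition_correlations"] = corrs

    # entries with genotype + both-condition phenotypes enter GS
    fam_ids = [l for l in kernel.line_ids
               if l in set(blues.loc[~blues["is_check"].astype(bool), "entry_id"])]
    kernel_fam = kernel.reorder(fam_ids)

    # ------------------------------------------------------------- fit
    stage("fit")
    varprops_rows = []
    mm_fits = {}
    sm_lim_fits = {}
    for trait in config.traits:
        for model in config.models:
            conds = (config.target,) if model == "SM" else (config.target, config.secondary)
            fit = fit_model(model, blues, kernel_fam, trait, conds,
                            seed=int(stage_rng(config.seed, 10).integers(2**31)),
                            **config.mcmc)
            props = variance_proportions(fit)
            for comp, share in props.items():
                varprops_rows.append({"trait": trait, "model": model,
                                      "component": comp, "share": share})
            if model == "MM":
                mm_fits[trait] = fit
        # SM in the secondary condition backs the phenotypic index
        sm_lim_fits[trait] = fit_model(
            "SM", blues, kernel_fam, trait, (config.secondary,),
            seed=int(stage_rng(config.seed, 11).integers(2**31)), **config.mcmc)
    varprops = pd.DataFrame(varprops_rows)
    varprops.to_csv(os.path.join(config.outdir, "variance_proportions.csv"), index=False)

    # -------------------------------------------------------------- cv
    stage("cv")
    plan = make_folds(fam_ids, config.cv_k, config.cv_repetitions,
                      seed=int(stage_rng(config.seed, 12).integers(2**31)))
    cv_frames, letters_frames = [], []
    for trait in config.traits:
        if "SM" in config.models:
            cv_frames.append(run_cv(blues, kernel_fam, trait, "single_env", ["SM"],
                                    plan, mcmc=config.mcmc, target=config.target,
                                    secondary=config.secondary).records)
        multi = [m for m in config.models if m != "SM"]
        if multi:
            res = run_cv(blues, kernel_fam, trait, "multi_env", multi, plan,
                         mcmc=config.mcmc, target=config.target,
                         secondary=config.secondary)
            cv_frames.append(res.records)
    from .cv import CVResult

    cv_all = CVResult(records=pd.concat(cv_frames, ignore_index=True))
    cv_all.records.to_csv(os.path.join(config.outdir, "cv_records.csv"), index=False)
    cv_summary = cv_all.summary()
    cv_summary.to_csv(os.path.join(config.outdir, "cv_summary.csv"), index=False)
    for trait in config.traits:
        letters = compare_models(cv_all, trait)
        letters.insert(0, "trait", trait)
        letters_frames.append(letters)
    pd.concat(letters_frames, ignore_index=True).to_csv(
        os.path.join(config.outdir, "model_letters.csv"), index=False)
    summary["cv"] = {
        f"{r.trait}_{r.model}": round(float(r.mean_pa), 4)
        for r in cv_summary.itertuples()
    }

    # ------------------------------------------------------- selection
    stage("selection")
    iyld = compute_iyld(blues, conditions=(config.target, config.secondary),
                        on_nonpositive="drop")
    blues_target = blues_wide(blues, config.target, config.traits).loc[fam_ids]
    blues_secondary = blues_wide(blues, config.secondary, config.traits).loc[fam_ids]
    gebv_mm = pd.DataFrame({
        t: mm_fits[t].effects["g"].add(mm_fits[t].effects["l"]).reindex(fam_ids)
        for t in config.traits})
    gebv_sm_lim = pd.DataFrame({
        t: sm_lim_fits[t].effects["g"].add(sm_lim_fits[t].effects["l"]).reindex(fam_ids)
        for t in config.traits})
    gsi_w = {t: config.gsi_weights.get(t, 0.0) for t in config.traits}
    psi_w = {**{t: config.psi_weights.get(t, 0.0) for t in config.traits},
             "iYLD": config.psi_weights.get("iYLD", 0.5)}
    gsi = build_gsi(blues_target, gebv_mm, weights=gsi_w,
                    fraction=config.selection_fraction)
    psi = build_psi(blues_secondary, gebv_sm_lim, iyld.reindex(fam_ids),
                    weights=psi_w, fraction=config.selection_fraction)
    trait_values = blues_target.copy()
    trait_values["iYLD"] = iyld.reindex(fam_ids)
    diff_rows = []
    for res in (gsi, psi):
        res.differentials = selection_differential(res.selected, trait_values)
        for trait, s in res.differentials.items():
            diff_rows.append({"index": res.name, "trait": trait, "S": s})
    sel = pd.DataFrame({
        "entry_id": fam_ids,
        "gsi_score": gsi.scores.reindex(fam_ids),
        "psi_score": psi.scores.reindex(fam_ids),
        "gsi_selected": [e in set(gsi.selected) for e in fam_ids],
        "psi_selected": [e in set(psi.selected) for e in fam_ids],
    })
    sel.to_csv(os.path.join(config.outdir, "selection.csv"), index=False)
    pd.DataFrame(diff_rows).to_csv(os.path.join(config.outdir, "differentials.csv"), index=False)
    summary["selection"] = {
        "n_selected": gsi.n_selected,
        "gsi_S": {k: round(float(v), 4) for k, v in gsi.differentials.items()},
        "psi_S": {k: round(float(v), 4) for k, v in psi.differentials.items()},
    }

    # ---------------------------------------------------------- report
    _dump_json(summary, os.path.join(config.outdir, "summary.json"))
    _write_report(config, summary, h2, cv_summary, varprops, os.path.join(config.outdir, "report.md"))
    log.info("pipeline done in %.1fs", time.time() - t_start)
    return summary


def _write_report(config, summary, h2, cv_summary, varprops, path):
    lines = ["# Pipeline report", "",
             f"Seed {config.seed}; package version {summary['version']}.", "",
             "## Heritability per trait and condition", ""]
    for k, v in sorted(h2.items()):
        lines.append(f"- H2({k}) = {v:.3f}")
    lines += ["", "## Predictive abilities (mean over folds)", "", "```",
              cv_summary.round(4).to_string(index=False), "```", "",
              "## Variance proportions", "", "```",
              varprops.pivot_table(index=["trait", "component"], columns="model",
                                   values="share").round(3).to_string(), "```", "",
              "## Selection differentials", ""]
    for idx_name, diffs in (("GSi", summary["selection"]["gsi_S"]),
                            ("PSi", summary["selection"]["psi_S"])):
        lines.append(f"- {idx_name}: " + ", ".join(f"{t}: {s:+.3g}" for t, s in diffs.items()))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
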