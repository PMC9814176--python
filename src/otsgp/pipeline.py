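"""End-to-end orchestration: QC -> hybrids -> kernels -> design -> fit -> economics.

A :class:`PipelineConfig` names the inputs (or asks for a simulated dataset),
the design/model choices and a single global seed; :func:`run_pipeline`
executes the stages in order, writes every artifact as a long-format CSV under
the output directory, and finishes with a ``manifest.json`` listing each file
with its SHA-256 content hash — identical config + seed gives an identical
manifest.  Stage seeds are fanned out from the global seed by a fixed counter
(``seed * 1000 + offset``) so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evalecon, gblup, otsdesign
from .enviro import env_kernel, read_weather_csv, scale_ec_matrix, summarize_env_covariates
from .kernels import build_composite_kernel, kernel_spectrum
from .markers import (additive_grm, allele_stats, dominance_grm, qc_markers,
                      read_cross_plan, read_marker_table, synthesize_hybrids, MarkerMatrix)
from .stage1 import (BlueTable, PlotRecords, estimate_heritability, fit_stage1_blues,
                     standardize_traits, trait_covariance)
from .synthdata import SimConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_SEED_OFFSETS"]

#: fixed per-stage seed offsets (global_seed * 1000 + offset)
STAGE_SEED_OFFSETS = {"simulate": 0, "ga_sample_1": 1, "ga_sample_2": 2, "ga_sample_3": 3,
                      "random_design": 10, "gibbs": 20, "cv": 30}


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 1
    # inputs: either simulate=True or the four file paths
    simulate: bool = True
    sim: SimConfig | None = None
    markers_csv: str | None = None
    cross_plan_csv: str | None = None
    phenotypes_csv: str | None = None
    weather_csv: str | None = None
    # stage options
    max_missing_rate: float = 0.05
    min_maf: float = 0.05
    blocks: str = "blocks_fixed"          # stage-1 design
    kernel: str = "GWT"                   # "GET" | "GWT"
    scenario: str = "OTS1"                # OTS1 | OTS2 | OTS3 | RANDOM
    model: str = "M4"
    trait_mode: str = "multi"
    apy_threshold: float = 0.98
    lambda_ratio: float = 1.0
    n_ga_samples: int = 3
    ga: otsdesign.GaConfig | None = None
    gibbs: gblup.GibbsConfig | None = None
    unit_costs: dict = field(default_factory=lambda: dict(evalecon.DEFAULT_UNIT_COSTS))
    genotyping_usd_per_sample: float = 20.0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest[path.name] = _sha256(path)


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        sim_cfg = cfg.sim or SimConfig(seed=cfg.stage_seed("simulate"))
        ds = simulate_dataset(sim_cfg)
        return ds.combined, ds.cross_plan, ds.plots, ds.weather
    if not (cfg.markers_csv and cfg.cross_plan_csv and cfg.phenotypes_csv and cfg.weather_csv):
        raise FileNotFoundError("pipeline needs markers, cross plan, phenotypes and weather files")
    for p in (cfg.markers_csv, cfg.cross_plan_csv, cfg.phenotypes_csv, cfg.weather_csv):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file missing: {p}")
    parents = read_marker_table(cfg.markers_csv, role="parent")
    plan = read_cross_plan(cfg.cross_plan_csv)
    plots = PlotRecords(pd.read_csv(cfg.phenotypes_csv))
    weather = read_weather_csv(cfg.weather_csv)
    hybrids = synthesize_hybrids(parents, plan)
    combined = MarkerMatrix(
        parents.individual_ids + hybrids.individual_ids,
        parents.marker_ids,
        np.vstack([parents.dosage, hybrids.dosage]),
        ["parent"] * parents.n_individuals + ["hybrid"] * hybrids.n_individuals,
    )
    return combined, plan, plots, weather


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    try:
        combined, plan, plots, weather = _load_inputs(cfg)
    except Exception as err:
        raise RuntimeError(f"stage 'inputs' failed: {err}") from err

    # QC + relationship matrices on the hybrid panel
    qcd = qc_markers(combined, cfg.max_missing_rate, cfg.min_maf, drop_het_parents=True)
    hybrid_ids = qcd.ids_with_role("hybrid")
    hybrids = qcd.subset_individuals(hybrid_ids)
    stats = allele_stats(hybrids)
    g_a = additive_grm(hybrids, stats)
    g_d = dominance_grm(hybrids, stats)
    _write(pd.DataFrame({"rule": [s.split(":")[0] for s in qcd.qc_log],
                         "log": qcd.qc_log}), out / "qc_log.csv", manifest)
    _write(pd.DataFrame(g_a.matrix, index=hybrid_ids, columns=hybrid_ids).reset_index()
           .rename(columns={"index": "genotype"}), out / "grm_additive.csv", manifest)

    # enviromic kernel
    ecs = scale_ec_matrix(summarize_env_covariates(weather))
    k_e = env_kernel(ecs)
    _write(ecs.to_frame().reset_index().rename(columns={"index": "env"}),
           out / "env_covariates.csv", manifest)
    _write(pd.DataFrame(k_e.matrix, index=k_e.environment_ids, columns=k_e.environment_ids)
           .reset_index().rename(columns={"index": "env"}), out / "env_kernel.csv", manifest)

    # stage 1: BLUEs per environment, standardized; H2; trait covariance
    blues = fit_stage1_blues(plots, design=cfg.blocks, scope="per_environment")
    blues.data = blues.data[blues.data["genotype"].isin(hybrid_ids)].reset_index(drop=True)
    blues_std = standardize_traits(blues)
    h2 = estimate_heritability(plots).heritability
    tsum = trait_covariance(blues_std)
    _write(blues_std.data, out / "blues.csv", manifest)
    _write(pd.DataFrame({"trait": list(h2), "H2": list(h2.values())}),
           out / "heritability.csv", manifest)
    _write(tsum.covariance.reset_index(), out / "trait_covariance.csv", manifest)

    traits = tsum.traits
    env_ids = k_e.environment_ids
    sigma_t = tsum.covariance.to_numpy()
    env_part = k_e if cfg.kernel == "GWT" else len(env_ids)
    kernel = build_composite_kernel(g_a, env_part, sigma_t, kind=cfg.kernel,
                                    environment_ids=env_ids, trait_ids=traits)
    spectrum = kernel_spectrum(kernel)
    n_core = otsdesign.apy_core_size(spectrum, cfg.apy_threshold)

    # training designs: three GA samples -> OTS1/2/3, or a size-matched random set
    check = hybrid_ids[0]
    designs: list[otsdesign.TrainingDesign]
    if cfg.scenario == "RANDOM":
        designs = [otsdesign.random_design(kernel, n_core, seed=cfg.stage_seed("random_design"),
                                           check_genotype=check)]
    else:
        ga = cfg.ga or otsdesign.GaConfig()
        samples = []
        for i in range(1, cfg.n_ga_samples + 1):
            ga_i = otsdesign.GaConfig(**{**ga.__dict__, "seed": cfg.stage_seed(f"ga_sample_{i}")})
            samples.append(otsdesign.optimize_training_set(
                kernel, n_core, ga_i, check_genotype=check, lambda_ratio=cfg.lambda_ratio))
        if cfg.scenario == "OTS1":
            designs = samples
        elif cfg.scenario == "OTS2":
            designs = otsdesign.combine_designs(samples, "pairwise_union")
        elif cfg.scenario == "OTS3":
            designs = otsdesign.combine_designs(samples, "full_union")
        else:
            raise RuntimeError(f"stage 'design': unknown scenario {cfg.scenario!r}")
    panel_cells = kernel.cell_ids()
    for i, d in enumerate(designs, 1):
        _write(d.to_frame(panel_cells), out / f"design_{cfg.scenario}_{i}.csv", manifest)

    # fit + predict + evaluate the first design
    design = designs[0]
    spec = gblup.ModelSpec(model=cfg.model, trait_mode=cfg.trait_mode, sigma_t=sigma_t)
    terms = gblup.build_model_terms(spec, g_a, g_d, k_e, env_ids, traits)
    train = design.all_cells
    y_train = BlueTable(blues_std.data[
        [(g, e, t) in train for g, e, t in
         zip(blues_std.data["genotype"], blues_std.data["env"], blues_std.data["trait"])]
    ].reset_index(drop=True), standardized=True)
    gibbs = cfg.gibbs or gblup.GibbsConfig(iterations=2000, burn_in=500,
                                           seed=cfg.stage_seed("gibbs"))
    fit = gblup.fit_gblup(y_train, spec, terms, gibbs)
    pred = gblup.predict_cells(fit)
    _write(pred, out / "predictions.csv", manifest)
    _write(pd.DataFrame({"component": list(fit.variance_components),
                         "posterior_mean": list(fit.variance_components.values()),
                         "ess": [fit.ess[c] for c in fit.variance_components]}),
           out / "variance_components.csv", manifest)

    test_cells = set(panel_cells) - set(train)
    pa = evalecon.prediction_ability(pred, blues_std, test_cells)
    _write(pa.per_trait_env.assign(level="trait_env"), out / "prediction_ability.csv", manifest)

    econ = evalecon.cost_model(design, cfg.unit_costs, cfg.genotyping_usd_per_sample,
                               n_samples=len(qcd.ids_with_role("parent")),
                               scenario=cfg.scenario)
    h2_safe = {t: min(max(h2[t], 1e-6), 1.0) for t in traits}
    report = evalecon.response_per_investment(pa, h2_safe, econ)
    _write(pd.DataFrame([{
        "scenario": report.scenario, "kernel": cfg.kernel, "model": cfg.model,
        "apy_core_size": n_core, "design_size": design.size,
        "check_cells": len(design.check_cells),
        "phenotyping_cost": report.phenotyping_cost,
        "genotyping_cost": report.genotyping_cost,
        "mean_accuracy": report.mean_accuracy,
        "gain_per_10000_usd": report.gain_per_budget,
        "pa_across_traits": pa.across_traits,
    }]), out / "economics.csv", manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
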