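"""Canned study routines on a synthetic panel: model comparison and design benchmarks.

These tie the modules together the way the full analysis uses them: stage-1
BLUEs and trait covariance feed Kronecker kernels, the spectral rule sets the
phenotyping budget, the GA picks the cells, the Bayesian models predict the
rest, and prediction ability is scored per trait x environment on the held-out
cells.  Runs are deterministic given their seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .evalecon import prediction_ability
from .gblup import GibbsConfig, ModelSpec, build_model_terms, fit_gblup, predict_cells
from .kernels import build_composite_kernel, kernel_spectrum
from .markers import additive_grm, allele_stats, dominance_grm
from .otsdesign import GaConfig, apy_core_size, optimize_training_set, random_design
from .stage1 import BlueTable, fit_stage1_blues, standardize_traits, trait_covariance
from .synthdata import SimulatedDataset

__all__ = ["PanelData", "prepare_panel", "model_comparison_cv1", "ots_vs_random"]


@dataclass
class PanelData:
    blues: BlueTable
    g_a: object
    g_d: object
    k_e: object
    sigma_t: np.ndarray
    traits: list[str]
    genotypes: list[str]
    env_ids: list[str]


def prepare_panel(ds: SimulatedDataset, design: str = "blocks_fixed") -> PanelData:
    """Stage-1 BLUEs, relationship matrices and trait covariance for a dataset."""
    blues = standardize_traits(fit_stage1_blues(ds.plots, design=design))
    hyb = ds.hybrids
    stats = allele_stats(hyb)
    ts = trait_covariance(blues)
    return PanelData(
        blues=blues,
        g_a=additive_grm(hyb, stats),
        g_d=dominance_grm(hyb, stats),
        k_e=ds.k_e,
        sigma_t=ts.covariance.to_numpy(),
        traits=ts.traits,
        genotypes=hyb.individual_ids,
        env_ids=ds.k_e.environment_ids,
    )


def _restrict(blues: BlueTable, cells: set) -> BlueTable:
    df = blues.data
    mask = [(g, e, t) in cells for g, e, t in zip(df["genotype"], df["env"], df["trait"])]
    return BlueTable(df[mask].reset_index(drop=True), standardized=blues.standardized)


def model_comparison_cv1(
    panel: PanelData,
    models: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5"),
    trait: str = "GY",
    n_seeds: int = 10,
    iterations: int = 2_000,
    train_fraction: float = 0.70,
    base_seed: int = 0,
) -> dict[str, float]:
    """Mean CV1 prediction ability per model, single-trait, over seeded partitions.

    Each seed holds out 30% of genotypes entirely (their BLUEs are never seen);
    PA is the within-environment Pearson correlation on held-out genotypes,
    averaged over environments and seeds.
    """
    genos = panel.genotypes
    bt = BlueTable(panel.blues.data[panel.blues.data["trait"] == trait]
                   .reset_index(drop=True), standardized=True)
    out = {m: [] for m in models}
    for seed in range(base_seed, base_seed + n_seeds):
        rng = np.random.default_rng(seed)
        n_train = int(round(train_fraction * len(genos)))
        perm = rng.permutation(len(genos))
        train_g = {genos[i] for i in perm[:n_train]}
        ytr = BlueTable(bt.data[bt.data["genotype"].isin(train_g)]
                        .reset_index(drop=True), standardized=True)
        test_cells = {(g, e, trait) for g in genos for e in panel.env_ids
                      if g not in train_g}
        for model in models:
            spec = ModelSpec(model=model, trait_mode="single")
            terms = build_model_terms(spec, panel.g_a, panel.g_d, panel.k_e,
                                      panel.env_ids)
            fit = fit_gblup(ytr, spec, terms,
                            GibbsConfig(iterations=iterations,
                                        burn_in=max(200, iterations // 4), seed=seed))
            pred = predict_cells(fit, trait=trait)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = prediction_ability(pred, bt, test_cells)
            out[model].append(rep.across_traits)
    return {m: float(np.mean(v)) for m, v in out.items()}


def ots_vs_random(
    panel: PanelData,
    kernel_kind: str = "GET",
    model: str = "M4",
    n_seeds: int = 10,
    iterations: int = 2_000,
    ga: GaConfig | None = None,
    apy_threshold: float = 0.98,
    base_seed: int = 0,
) -> dict:
    """Optimized vs size-matched random training designs at the spectral budget.

    Returns the budget, per-seed and mean PA for both design families, each
    design evaluated by a multi-trait fit (known Sigma_T) predicting every
    unphenotyped cell.  The first genotype serves as the always-phenotyped check.
    """
    env_part = panel.k_e if kernel_kind == "GWT" else len(panel.env_ids)
    kern = build_composite_kernel(panel.g_a, env_part, panel.sigma_t, kind=kernel_kind,
                                  environment_ids=panel.env_ids, trait_ids=panel.traits)
    n_core = apy_core_size(kernel_spectrum(kern), apy_threshold)
    check = panel.genotypes[0]
    spec = ModelSpec(model=model, trait_mode="multi", sigma_t=panel.sigma_t)
    terms = build_model_terms(spec, panel.g_a, panel.g_d, panel.k_e,
                              panel.env_ids, panel.traits)
    panel_cells = kern.cell_ids()
    base_ga = ga or GaConfig(population_size=16, max_generations=25, patience=10,
                             look_ahead_samples=30)

    def pa_of(design, gibbs_seed):
        train = design.all_cells
        ytr = _restrict(panel.blues, set(train))
        fit = fit_gblup(ytr, spec, terms,
                        GibbsConfig(iterations=iterations,
                                    burn_in=max(200, iterations // 4), seed=gibbs_seed))
        pred = predict_cells(fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return prediction_ability(pred, panel.blues,
                                      set(panel_cells) - set(train)).across_traits

    ots_pa, rnd_pa, fitness = [], [], []
    for seed in range(base_seed, base_seed + n_seeds):
        cfg = GaConfig(**{**base_ga.__dict__, "seed": seed})
        d = optimize_training_set(kern, n_core, cfg, check_genotype=check)
        r = random_design(kern, n_core, seed=900 + seed, check_genotype=check)
        ots_pa.append(pa_of(d, 77 + seed))
        rnd_pa.append(pa_of(r, 77 + seed))
        fitness.append(d.provenance["fitness"])
    return {
        "kernel": kernel_kind,
        "budget": n_core,
        "panel_cells": len(panel_cells),
        "ots_pa": ots_pa,
        "random_pa": rnd_pa,
        "ots_mean_pa": float(np.mean(ots_pa)),
        "random_mean_pa": float(np.mean(rnd_pa)),
        "ga_fitness": fitness,
    }
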