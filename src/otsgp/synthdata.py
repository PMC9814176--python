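"""Synthetic hybrid-trial generator with known genetic architecture.

Emulates the structure the pipeline assumes: inbred founders genotyped at
biallelic SNPs, F1 hybrids from a (partial) diallel, q trial environments
described by daily weather, three correlated traits with additive + dominance
+ genotype-by-environment genetic values, and plot records under an RCBD or an
augmented block design with replicated checks.  G x E deviations are drawn
with covariance K_E across environments by default, so enviromic similarity
genuinely structures the interaction, and the residual variance is calibrated
from the realized components so the entry-mean heritability hits its target.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enviro import (EnviroCovariates, EnvKernel, WeatherTable, env_kernel,
                     scale_ec_matrix, summarize_env_covariates)
from .markers import MarkerMatrix, synthesize_hybrids
from .stage1 import PlotRecords

__all__ = ["SimConfig", "TruthRecord", "SimulatedDataset", "simulate_dataset", "golden_fixture"]

_HEL_LIKE_CORR = np.array([
    [1.0, -0.5, -0.5],
    [-0.5, 1.0, 0.8],
    [-0.5, 0.8, 1.0],
])


@dataclass
class SimConfig:
    n_parents: int = 12
    cross_design: str = "partial_diallel"   # "full_diallel" | "partial_diallel"
    diallel_fraction: float = 0.6
    n_markers: int = 400
    freq_range: tuple[float, float] = (0.05, 0.95)
    founder_groups: int = 3                 # ancestral groups (1 = unstructured)
    founder_fst: float = 0.25               # Balding-Nichols divergence of groups
    q_envs: int = 3
    n_traits: int = 3
    trait_names: tuple[str, ...] = ("GY", "PH", "EH")
    genetic_correlation: np.ndarray = field(default_factory=lambda: _HEL_LIKE_CORR.copy())
    heritabilities: tuple[float, ...] = (0.62, 0.78, 0.80)
    dominance_ratio: float = 0.15
    gxe_ratio: float = 0.3                  # var(GxE) / var(main genetic)
    gxe_structure: str = "K_E"              # "K_E" | "compound_symmetry"
    rho_e: float = 0.2                      # env-effect correlation (CS structure)
    block_design: str = "rcbd"              # "rcbd" | "augmented"
    n_blocks: int = 2
    block_size: int = 10                    # entries per augmented block
    n_checks: int = 2                       # replicated checks (augmented)
    block_sd: float = 0.5
    env_mean_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.genetic_correlation, float)
        if corr.shape != (self.n_traits, self.n_traits):
            raise ValueError("genetic correlation matrix does not match n_traits")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("genetic correlation matrix needs a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("genetic correlation matrix is not PSD")
        if any(not 0.0 < h <= 1.0 for h in self.heritabilities):
            raise ValueError("heritabilities must be in (0, 1]")  # 1 = noiseless limit
        if len(self.heritabilities) != self.n_traits:
            raise ValueError("one heritability per trait required")


@dataclass
class TruthRecord:
    true_values: pd.DataFrame         # genotype, env, trait, additive, dominance, gxe, total
    variance_components: dict         # trait -> {"V_g", "V_a", "V_d", "V_ge", "V_e"}
    h2_target: dict
    env_means: dict
    k_e: EnvKernel | None = None


@dataclass
class SimulatedDataset:
    parents: MarkerMatrix
    hybrids: MarkerMatrix
    combined: MarkerMatrix            # parents + hybrids in one matrix
    weather: WeatherTable
    covariates: EnviroCovariates      # scaled
    k_e: EnvKernel
    plots: PlotRecords
    truth: TruthRecord
    cross_plan: list[tuple[str, str, str]]


def _simulate_weather(rng: np.random.Generator, env_ids: list[str], n_days: int = 121) -> WeatherTable:
    rows = []
    for env in env_ids:
        base_t = rng.uniform(18.0, 28.0)
        amp = rng.uniform(2.0, 5.0)
        rain_rate = rng.uniform(1.0, 8.0)
        base_rh = rng.uniform(55.0, 85.0)
        days = np.arange(n_days)
        tmean = base_t + amp * np.sin(2 * np.pi * days / n_days + rng.uniform(0, np.pi)) \
            + rng.normal(0, 1.0, n_days)
        rainfall = rng.gamma(shape=0.8, scale=rain_rate, size=n_days)
        humidity = np.clip(base_rh + rng.normal(0, 5.0, n_days), 20, 100)
        for d in days:
            rows.append({"env": env, "day": int(d), "tmean": tmean[d],
                         "rainfall": rainfall[d], "humidity": humidity[d]})
    return WeatherTable(pd.DataFrame(rows))


def _scale_to(x: np.ndarray, target_var: float) -> np.ndarray:
    v = x.var()
    return x if v == 0 else x * np.sqrt(target_var / v)


def _impose_correlation(x: np.ndarray, target_corr: np.ndarray) -> np.ndarray:
    """Re-mix columns so the realized correlation equals the target exactly.

    Hybrid genotypes span only the parental subspace, so the raw correlation
    of marker-driven values scatters around the target; re-mixing keeps each
    column a linear combination of marker effects while pinning the realized
    correlation.  Columns come back with unit variance.
    """
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (len(xc) - 1)
    white = xc @ np.linalg.inv(np.linalg.cholesky(cov)).T
    out = white @ np.linalg.cholesky(target_corr + 1e-10 * np.eye(len(target_corr))).T
    return out / out.std(axis=0, ddof=0)


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Generate (markers, weather/ECs, plots, truth) for one synthetic study."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    traits = list(cfg.trait_names[: cfg.n_traits])
    env_ids = [f"E{i + 1}" for i in range(cfg.q_envs)]

    # founders: inbred dosages 0/2; ancestral groups diverge by Balding-Nichols
    # drift around shared ancestral frequencies (breeding panels are structured,
    # which is what gives the genomic kernel its decaying spectrum)
    p = rng.uniform(*cfg.freq_range, size=cfg.n_markers)
    parent_ids = [f"P{i + 1:03d}" for i in range(cfg.n_parents)]
    if cfg.founder_groups > 1 and cfg.founder_fst > 0:
        f = cfg.founder_fst
        group_freqs = [np.clip(rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f), 0.01, 0.99)
                       for _ in range(cfg.founder_groups)]
        membership = rng.integers(cfg.founder_groups, size=cfg.n_parents)
        parent_dosage = np.array(
            [2.0 * (rng.random(cfg.n_markers) < group_freqs[g]) for g in membership])
    else:
        parent_dosage = 2.0 * (rng.random((cfg.n_parents, cfg.n_markers)) < p)
    parents = MarkerMatrix(parent_ids, [f"M{j + 1:05d}" for j in range(cfg.n_markers)],
                           parent_dosage, ["parent"] * cfg.n_parents)

    pairs = list(itertools.combinations(parent_ids, 2))
    if cfg.cross_design == "partial_diallel":
        n_cross = max(2, int(round(cfg.diallel_fraction * len(pairs))))
        idx = rng.choice(len(pairs), size=min(n_cross, len(pairs)), replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    cross_plan = [(m, f, f"H{i + 1:03d}") for i, (m, f) in enumerate(pairs)]
    hybrids = synthesize_hybrids(parents, cross_plan)
    hybrid_ids = hybrids.individual_ids
    n_h = len(hybrid_ids)

    combined = MarkerMatrix(
        parent_ids + hybrid_ids,
        parents.marker_ids,
        np.vstack([parents.dosage, hybrids.dosage]),
        ["parent"] * cfg.n_parents + ["hybrid"] * n_h,
    )

    weather = _simulate_weather(rng, env_ids)
    ecs = scale_ec_matrix(summarize_env_covariates(weather))
    k_e = env_kernel(ecs)

    # genetic values on the standardized trait scale (main genetic variance = 1)
    x = hybrids.dosage
    p_hyb = x.mean(axis=0) / 2.0
    w_c = x - 2.0 * p_hyb
    het = (x == 1.0).astype(float)
    corr_l = np.linalg.cholesky(np.asarray(cfg.genetic_correlation, float) + 1e-10 * np.eye(cfg.n_traits))
    add_eff = rng.standard_normal((cfg.n_markers, cfg.n_traits)) @ corr_l.T
    dom_eff = rng.standard_normal((cfg.n_markers, cfg.n_traits))
    if cfg.gxe_structure == "K_E":
        env_l = np.linalg.cholesky(k_e.matrix + 1e-8 * np.eye(cfg.q_envs))
    elif cfg.gxe_structure == "compound_symmetry":
        cs = np.full((cfg.q_envs, cfg.q_envs), cfg.rho_e) + (1 - cfg.rho_e) * np.eye(cfg.q_envs)
        env_l = np.linalg.cholesky(cs)
    else:
        raise ValueError(f"unknown gxe_structure {cfg.gxe_structure!r}")

    env_means = {t: dict(zip(env_ids, rng.normal(0, cfg.env_mean_sd, cfg.q_envs))) for t in traits}
    vc: dict[str, dict[str, float]] = {}
    corr = np.asarray(cfg.genetic_correlation, float)
    v_a, v_d = 1.0 - cfg.dominance_ratio, cfg.dominance_ratio
    a_raw = w_c @ add_eff
    d_raw = het @ dom_eff
    if cfg.n_traits > 1:
        a_mat = _impose_correlation(a_raw, corr) * np.sqrt(v_a)
        d_mat = _impose_correlation(d_raw, corr) * np.sqrt(v_d)
    else:
        a_mat = _scale_to(a_raw - a_raw.mean(axis=0), v_a)
        d_mat = _scale_to(d_raw - d_raw.mean(axis=0), v_d)
    # orthogonalize dominance against additive per trait: the main genetic
    # variance is then exactly v_a + v_d = 1, keeping the residual calibration
    # feasible for every seed
    for t_i in range(cfg.n_traits):
        a_t = a_mat[:, t_i]
        d_t = d_mat[:, t_i] - a_t * (a_t @ d_mat[:, t_i]) / (a_t @ a_t)
        d_mat[:, t_i] = _scale_to(d_t, v_d)
    ge_mat = np.empty((n_h, cfg.q_envs, cfg.n_traits))
    for t_i, trait in enumerate(traits):
        ge = w_c @ (rng.standard_normal((cfg.n_markers, cfg.q_envs)) @ env_l.T)
        ge = _scale_to(ge - ge.mean(), cfg.gxe_ratio)
        ge_mat[:, :, t_i] = ge
        a, d = a_mat[:, t_i], d_mat[:, t_i]
        vc[trait] = {"V_a": float(a.var()), "V_d": float(d.var()),
                     "V_g": float((a + d).var()), "V_ge": float(ge.var())}

    # Residual calibrated so the classical entry-mean H2 hits its target.
    # K_E rows sum to zero (centered ECs), so K_E-driven interactions are pure
    # (sum-to-zero within genotype): map to the classical iid-interaction frame
    # before applying  H2 = s2g / (s2g + s2ge/E + s2e/(E R)).
    n_rep = cfg.n_blocks if cfg.block_design == "rcbd" else 1
    e_n = cfg.q_envs
    v_e = {}
    for trait, h2 in zip(traits, cfg.heritabilities):
        v_g = vc[trait]["V_g"]
        v_ge = vc[trait]["V_ge"]
        if cfg.gxe_structure == "K_E" and e_n > 1:
            s2ge = v_ge * e_n / (e_n - 1)
            s2g = v_g - v_ge / (e_n - 1)
        else:
            s2g = v_g + cfg.rho_e * v_ge
            s2ge = (1.0 - cfg.rho_e) * v_ge
        if s2g <= 0:
            raise ValueError(f"gxe_ratio {cfg.gxe_ratio} leaves no main genetic variance")
        ve = e_n * n_rep * (s2g / h2 - s2g - s2ge / e_n)
        if abs(ve) < 1e-12:
            ve = 0.0  # noiseless limit (h2 = 1, no GxE)
        if ve < 0:
            raise ValueError(
                f"heritability target {h2} for {trait} infeasible with gxe_ratio {cfg.gxe_ratio}")
        v_e[trait] = ve
        vc[trait].update({"V_e": float(ve), "s2g_classical": float(s2g),
                          "s2ge_classical": float(s2ge)})

    truth_rows = []
    for g_i, g in enumerate(hybrid_ids):
        for e_i, env in enumerate(env_ids):
            for t_i, trait in enumerate(traits):
                truth_rows.append({
                    "genotype": g, "env": env, "trait": trait,
                    "additive": a_mat[g_i, t_i], "dominance": d_mat[g_i, t_i],
                    "gxe": ge_mat[g_i, e_i, t_i],
                    "total": a_mat[g_i, t_i] + d_mat[g_i, t_i] + ge_mat[g_i, e_i, t_i],
                })
    truth = pd.DataFrame(truth_rows)

    # plot layout
    plot_rows = []
    check_ids = set(hybrid_ids[: cfg.n_checks]) if cfg.block_design == "augmented" else set()
    for e_i, env in enumerate(env_ids):
        if cfg.block_design == "rcbd":
            layout = [(f"B{b + 1}", hybrid_ids) for b in range(cfg.n_blocks)]
        else:
            entries = [h for h in hybrid_ids if h not in check_ids]
            n_blk = int(np.ceil(len(entries) / cfg.block_size))
            layout = []
            for b in range(n_blk):
                blk_entries = entries[b * cfg.block_size:(b + 1) * cfg.block_size]
                layout.append((f"B{b + 1}", list(check_ids) + blk_entries))
        for block, members in layout:
            b_eff = {t: rng.normal(0, cfg.block_sd) for t in traits}
            for g in members:
                g_i = hybrid_ids.index(g)
                rec = {"genotype": g, "env": env, "block": block, "is_check": g in check_ids}
                for t_i, trait in enumerate(traits):
                    gv = a_mat[g_i, t_i] + d_mat[g_i, t_i] + ge_mat[g_i, e_i, t_i]
                    rec[trait] = (env_means[trait][env] + b_eff[trait] + gv
                                  + rng.normal(0, np.sqrt(v_e[trait])))
                plot_rows.append(rec)
    plots = PlotRecords(pd.DataFrame(plot_rows))

    return SimulatedDataset(
        parents=parents, hybrids=hybrids, combined=combined,
        weather=weather, covariates=ecs, k_e=k_e, plots=plots,
        truth=TruthRecord(
            true_values=truth, variance_components=vc,
            h2_target=dict(zip(traits, cfg.heritabilities)),
            env_means=env_means, k_e=k_e,
        ),
        cross_plan=cross_plan,
    )


def _toy6_kernel():
    """Fixed 6-cell composite kernel with its exhaustively PEV-optimal pair."""
    from .kernels import CompositeKernel
    from .otsdesign import pev_mean

    rng = np.random.default_rng(20_240_601)
    a = rng.standard_normal((3, 4))
    g = a @ a.T / 4 + 0.5 * np.eye(3)
    b = rng.standard_normal((2, 3))
    e = b @ b.T / 3 + 0.5 * np.eye(2)
    kernel = CompositeKernel(
        [("Sigma_G", g, ["G1", "G2", "G3"]), ("Sigma_E", e, ["E1", "E2"]),
         ("Sigma_T", np.eye(1), ["T1"])],
        kind="custom",
    )
    cells = kernel.cell_ids()
    best_pair, best_f = None, np.inf
    for pair in itertools.combinations(cells, 2):
        f = pev_mean(kernel, frozenset(pair), lambda_ratio=1.0)
        if f < best_f:
            best_pair, best_f = frozenset(pair), f
    return {"kernel": kernel, "optimal_pair": best_pair, "optimal_fitness": best_f}


def golden_fixture(name: str):
    """Fixed-seed reference datasets: 'toy6', 'mini-hel', 'mini-usp'.

    'mini-hel' is a 30-hybrid x 3-env x 3-trait RCBD panel with strong
    K_E-driven G x E; 'mini-usp' is a 50-hybrid x 4-env x 3-trait augmented
    panel; 'toy6' is a 6-cell kernel whose optimal training pair is found by
    exhaustive search when the fixture is built.
    """
    if name == "toy6":
        return _toy6_kernel()
    if name == "mini-hel":
        cfg = SimConfig(n_parents=10, diallel_fraction=30 / 45, n_markers=300,
                        q_envs=3, gxe_ratio=0.8, heritabilities=(0.45, 0.5, 0.5), seed=11)
        return simulate_dataset(cfg)
    if name == "mini-usp":
        cfg = SimConfig(n_parents=11, diallel_fraction=50 / 55, n_markers=300,
                        q_envs=4, heritabilities=(0.56, 0.80, 0.82), gxe_ratio=0.2,
                        block_design="augmented", block_size=12, seed=22)
        return simulate_dataset(cfg)
    raise KeyError(f"unknown fixture {name!r}")
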