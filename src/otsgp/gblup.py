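"""Multi-kernel Bayesian GBLUP for multi-environment (and multi-trait) panels.

Five nested models over (genotype, environment[, trait]) cells:

    M1  env means + additive (A) + dominance (D) main effects
    M2  M1 + additive x environment (AE) + dominance x environment (DE)
    M3  M1 + enviromic main effect (W)
    M4  M3 + AE + DE
    M5  M3 + additive x enviromic (AW) + dominance x enviromic (DW)

Under genotype-major cell ordering each term's cell-level covariance is a
Kronecker product: A = G_a (x) J_q, AE = G_a (x) I_q, W = J_g (x) K_E,
AW = G_a (x) K_E (J = all-ones), and the multi-trait mode appends the known
trait covariance Sigma_T as a trailing Kronecker factor.  Fitting is by Gibbs
sampling: each term's coefficients are sampled in the eigenbasis of its
observed-cell covariance (where the full conditional is diagonal), variance
components from scaled-inverse-chi-square full conditionals, environment(-by-
trait) means with a flat prior.  Missing cells are handled by restricting the
likelihood to observed cells; unobserved cells are predicted through the
kernel cross-covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enviro import EnvKernel
from .kernels import CompositeKernel
from .markers import GenomicRelationship
from .stage1 import BlueTable

__all__ = ["ModelSpec", "GibbsConfig", "GblupFit", "build_model_terms", "fit_gblup",
           "predict_cells", "MODEL_TERMS"]

#: random-term families per model id
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M1": ("A", "D"),
    "M2": ("A", "D", "AE", "DE"),
    "M3": ("A", "D", "W"),
    "M4": ("A", "D", "W", "AE", "DE"),
    "M5": ("A", "D", "W", "AW", "DW"),
}


@dataclass
class ModelSpec:
    model: str = "M1"
    trait_mode: str = "single"       # "single" | "multi"
    sigma_t: np.ndarray | None = None  # known trait covariance (multi mode)
    sigma_t_mode: str = "fixed"      # "fixed" | "plugin" (estimate from observed cells)

    def __post_init__(self) -> None:
        if self.model not in MODEL_TERMS:
            raise ValueError(f"unknown model {self.model!r} (M1..M5)")
        if self.trait_mode not in ("single", "multi"):
            raise ValueError("trait_mode must be 'single' or 'multi'")

    @property
    def term_names(self) -> tuple[str, ...]:
        return MODEL_TERMS[self.model]


@dataclass
class GibbsConfig:
    iterations: int = 10_000
    burn_in: int = 1_000
    thinning: int = 2
    prior_df: float = 5.0
    seed: int = 0
    #: variance components to hold fixed, e.g. {"A": 1.0, "residual": 1.0}
    fix_variances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class GblupFit:
    panel_cells: list[tuple]
    genetic_mean: np.ndarray      # posterior mean total genetic value per cell
    genetic_sd: np.ndarray
    fixed_effects: dict           # (env[, trait]) -> posterior mean intercept
    variance_components: dict     # term -> posterior mean variance
    ess: dict                     # term -> effective sample size of its variance chain
    spec: ModelSpec = None
    n_draws: int = 0

    def cell_index(self) -> dict:
        return {c: i for i, c in enumerate(self.panel_cells)}


def _term_factors(name: str, g_a: np.ndarray, g_d: np.ndarray, k_e: np.ndarray | None,
                  n_g: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    J_q = np.ones((q, q))
    J_g = np.ones((n_g, n_g))
    I_q = np.eye(q)
    table = {
        "A": (g_a, J_q), "D": (g_d, J_q),
        "AE": (g_a, I_q), "DE": (g_d, I_q),
        "W": (J_g, k_e), "AW": (g_a, k_e), "DW": (g_d, k_e),
    }
    if name not in table:
        raise ValueError(f"unknown term {name!r}")
    gf, ef = table[name]
    if ef is None:
        raise ValueError(f"term {name} needs an enviromic kernel K_E")
    return gf, ef


def build_model_terms(
    spec: ModelSpec,
    g_a: GenomicRelationship | np.ndarray,
    g_d: GenomicRelationship | np.ndarray,
    k_e: EnvKernel | np.ndarray | None,
    environment_ids: list[str],
    trait_ids: list[str] | None = None,
) -> list[tuple[str, CompositeKernel]]:
    """Cell-level Kronecker covariance structure for each random term."""
    ga_mat, g_ids = ((g_a.matrix, g_a.individual_ids) if isinstance(g_a, GenomicRelationship)
                     else (np.asarray(g_a, float), None))
    gd_mat = g_d.matrix if isinstance(g_d, GenomicRelationship) else np.asarray(g_d, float)
    if g_ids is None:
        g_ids = [f"G{i}" for i in range(ga_mat.shape[0])]
    ke_mat = None
    if k_e is not None:
        ke_mat = k_e.matrix if isinstance(k_e, EnvKernel) else np.asarray(k_e, float)
    n_g, q = len(g_ids), len(environment_ids)
    multi = spec.trait_mode == "multi"
    if multi:
        if trait_ids is None:
            raise ValueError("multi-trait mode needs trait ids")
        if spec.sigma_t is None:
            raise ValueError("multi-trait mode needs the trait covariance Sigma_T")
    terms = []
    for name in spec.term_names:
        gf, ef = _term_factors(name, ga_mat, gd_mat, ke_mat, n_g, q)
        factors = [("G", gf, g_ids), ("E", ef, list(environment_ids))]
        if multi:
            factors.append(("T", np.asarray(spec.sigma_t, float), list(trait_ids)))
        terms.append((name, CompositeKernel(factors, kind="custom")))
    return terms


def sigma_t_from_blues(y: BlueTable) -> tuple[np.ndarray, list[str]]:
    """Empirical trait covariance of a BLUE table (the 'estimated' Sigma_T path)."""
    from .stage1 import trait_covariance

    ts = trait_covariance(y)
    cov = ts.covariance
    return cov.to_numpy(), [str(t) for t in cov.columns]


def _observed_vector(y: BlueTable, spec: ModelSpec, environment_ids, trait_ids):
    df = y.data.dropna(subset=["value"]).copy()
    df["genotype"] = df["genotype"].astype(str)
    df["env"] = df["env"].astype(str)
    df["trait"] = df["trait"].astype(str)
    if spec.trait_mode == "single":
        traits = sorted(df["trait"].unique())
        if len(traits) != 1:
            raise ValueError("single-trait mode expects exactly one trait in y")
    obs_cells = list(zip(df["genotype"], df["env"], df["trait"]))
    return df["value"].to_numpy(float), obs_cells


def _ess(chain: np.ndarray) -> float:
    """Effective sample size by the initial positive sequence estimator."""
    x = np.asarray(chain, float)
    n = len(x)
    if n < 4 or x.var() <= 1e-20 * (1.0 + x.mean() ** 2):  # numerically constant
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else acf[2 * k - 1]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def fit_gblup(y: BlueTable, spec: ModelSpec,
              terms: list[tuple[str, CompositeKernel]],
              cfg: GibbsConfig | None = None) -> GblupFit:
    """Gibbs sampler over the observed cells of ``y``; predicts every panel cell.

    ``terms`` come from :func:`build_model_terms`; all terms must share the
    panel (genotype, environment[, trait]) grid.  Prior scale splits var(y)
    equally between the random terms and the residual.  Seed-deterministic.
    """
    cfg = cfg or GibbsConfig()
    rng = np.random.default_rng(cfg.seed)
    kernel0 = terms[0][1]
    g_ids = kernel0.factors[0][2]
    env_ids = kernel0.factors[1][2]
    multi = spec.trait_mode == "multi"
    trait_ids = kernel0.factors[2][2] if multi else None

    y_obs, obs_cells3 = _observed_vector(y, spec, env_ids, trait_ids)
    n_obs = len(y_obs)
    if n_obs == 0:
        raise ValueError("no observed cells")
    obs_traits = sorted({c[2] for c in obs_cells3})
    if not multi:
        trait_ids = obs_traits
    # kernel cells: (g, e) in single mode, (g, e, t) in multi mode
    obs_cells = [c if multi else c[:2] for c in obs_cells3]
    for c, c3 in zip(obs_cells, obs_cells3):
        if c3[0] not in g_ids:
            raise ValueError(f"genotype {c3[0]!r} not in the kernel panel")
        if c3[1] not in env_ids:
            raise ValueError(f"environment {c3[1]!r} not in the kernel panel")
    seen_envs = {c[1] for c in obs_cells}
    missing_envs = set(env_ids) - seen_envs
    if missing_envs:
        raise ValueError(f"environments with no observed cells: {sorted(missing_envs)}")

    # fixed-effect groups: env (single) or env x trait (multi)
    fx_keys = sorted({(c3[1], c3[2]) if multi else (c3[1],) for c3 in obs_cells3})
    fx_map = {k: i for i, k in enumerate(fx_keys)}
    fx_of_obs = np.array([fx_map[(c3[1], c3[2]) if multi else (c3[1],)] for c3 in obs_cells3])
    fx_counts = np.bincount(fx_of_obs, minlength=len(fx_keys)).astype(float)

    # per-term eigenbasis on the observed cells
    var_y = float(np.var(y_obs)) or 1.0
    n_terms = len(terms)
    bases = []
    for name, k in terms:
        K_obs = k.submatrix(obs_cells)
        d, E = np.linalg.eigh((K_obs + K_obs.T) / 2.0)
        keep = d > max(1e-10, 1e-12 * d.max())
        d, E = d[keep], E[:, keep]
        phi = E * np.sqrt(d)
        bases.append({"name": name, "kernel": k, "d": d, "phi": phi,
                      "beta": np.zeros(len(d)),
                      "S0": var_y * 0.5 / n_terms})
    S0_e = var_y * 0.5
    df0 = cfg.prior_df

    sig = {b["name"]: b["S0"] for b in bases}
    sig_e = S0_e
    for k_, v in cfg.fix_variances.items():
        if k_ == "residual":
            sig_e = float(v)
        elif k_ in sig:
            sig[k_] = float(v)
        else:
            raise ValueError(f"unknown variance component {k_!r}")

    beta_fx = np.zeros(len(fx_keys))
    resid = y_obs.copy()

    n_save = -((cfg.iterations - cfg.burn_in) // -cfg.thinning)  # ceil
    sum_beta = [np.zeros_like(b["beta"]) for b in bases]
    sum_u = np.zeros(n_obs)
    panel_cells = kernel0.cell_ids()
    n_cells = len(panel_cells)
    sum_g = np.zeros(n_cells)
    sumsq_g = np.zeros(n_cells)
    sum_fx = np.zeros(len(fx_keys))
    var_chains = {b["name"]: np.empty(n_save) for b in bases}
    var_chains["residual"] = np.empty(n_save)
    # projection to all panel cells: P_r = K(all, obs) E d^{-1/2}
    projections = []
    for b in bases:
        K_all_obs = b["kernel"].submatrix(panel_cells, obs_cells)
        projections.append(K_all_obs @ (b["phi"] / b["d"]))  # = K E d^{-1/2} ... see below

    # note: phi = E sqrt(d) so phi / d = E d^{-1/2}; u_all = K_all,obs K_obs^+ u_obs
    saved = 0
    for it in range(cfg.iterations):
        # random-term coefficients (diagonal full conditionals in the eigenbasis)
        for b in bases:
            phi, d = b["phi"], b["d"]
            resid += phi @ b["beta"]
            prec = d / sig_e + 1.0 / sig[b["name"]]
            mean = (phi.T @ resid) / sig_e / prec
            b["beta"] = mean + rng.standard_normal(len(d)) / np.sqrt(prec)
            resid -= phi @ b["beta"]
        # fixed environment(-by-trait) means, flat prior
        resid += beta_fx[fx_of_obs]
        mean_fx = np.bincount(fx_of_obs, weights=resid, minlength=len(fx_keys)) / fx_counts
        beta_fx = mean_fx + rng.standard_normal(len(fx_keys)) * np.sqrt(sig_e / fx_counts)
        resid -= beta_fx[fx_of_obs]
        # variance components
        for b in bases:
            nm = b["name"]
            if nm not in cfg.fix_variances:
                ssq = b["beta"] @ b["beta"]
                m_r = len(b["d"])
                sig[nm] = (df0 * b["S0"] + ssq) / rng.chisquare(df0 + m_r)
            if not np.isfinite(sig[nm]):
                raise FloatingPointError(f"divergent variance draw for {nm} at iteration {it}")
        if "residual" not in cfg.fix_variances:
            sig_e = (df0 * S0_e + resid @ resid) / rng.chisquare(df0 + n_obs)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            u_tot_obs = y_obs - resid - beta_fx[fx_of_obs]
            sum_u += u_tot_obs
            g_all = np.zeros(n_cells)
            for P, b in zip(projections, bases):
                g_all += P @ b["beta"]
            sum_g += g_all
            sumsq_g += g_all**2
            sum_fx += beta_fx
            for b, sb in zip(bases, sum_beta):
                sb += b["beta"]
            for nm in sig:
                var_chains[nm][saved] = sig[nm]
            var_chains["residual"][saved] = sig_e
            saved += 1

    g_mean = sum_g / saved
    g_sd = np.sqrt(np.maximum(sumsq_g / saved - g_mean**2, 0.0))
    fixed = {k: sum_fx[i] / saved for k, i in fx_map.items()}
    vc = {nm: float(np.mean(ch[:saved])) for nm, ch in var_chains.items()}
    ess = {nm: _ess(ch[:saved]) for nm, ch in var_chains.items()}
    return GblupFit(
        panel_cells=panel_cells,
        genetic_mean=g_mean,
        genetic_sd=g_sd,
        fixed_effects=fixed,
        variance_components=vc,
        ess=ess,
        spec=spec,
        n_draws=saved,
    )


def predict_cells(fit: GblupFit, cells: list[tuple] | None = None,
                  trait: str | None = None) -> pd.DataFrame:
    """Posterior-mean genetic value + environment mean for every requested cell.

    Cells are (genotype, env) tuples in single-trait mode (pass ``trait`` for
    labeling) and (genotype, env, trait) in multi-trait mode.  Unknown cells
    raise.  Never-observed genotypes still get predictions through the kernel.
    """
    index = fit.cell_index()
    if cells is None:
        cells = fit.panel_cells
    multi = fit.spec is not None and fit.spec.trait_mode == "multi"
    rows = []
    for c in cells:
        if c not in index:
            raise KeyError(f"cell {c!r} not in the fitted panel")
        i = index[c]
        fx_key = (c[1], c[2]) if multi else (c[1],)
        fx = fit.fixed_effects.get(fx_key, 0.0)
        rows.append({
            "genotype": c[0], "env": c[1],
            "trait": c[2] if multi else (trait or "trait"),
            "genetic_value": fit.genetic_mean[i],
            "predicted": fx + fit.genetic_mean[i],
            "sd": fit.genetic_sd[i],
        })
    return pd.DataFrame(rows)
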