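"""Stage-1 phenotypic analysis: trait scaling, per-environment BLUEs, H2.

The two-step analysis first adjusts plot records to genotype means (BLUEs) per
environment and trait, with the block structure matching the trial design:
fixed blocks for an RCBD with few blocks, random blocks for augmented designs
(block variance estimated by 1-D profile REML).  Ear height is re-expressed as
the negated distance to an 80 cm ideotype so its selection direction opposes
grain yield; all traits are then z-scored across the whole BLUE table before
entering genomic prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "PlotRecords",
    "BlueTable",
    "TraitSummary",
    "transform_ear_height",
    "standardize_traits",
    "fit_stage1_blues",
    "estimate_heritability",
    "trait_covariance",
]


@dataclass
class PlotRecords:
    """Plot-level phenotypes: long table with one row per plot.

    Columns: genotype, env, block, is_check, one column per trait (NaN allowed).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"genotype", "env", "block"}
        if not need.issubset(self.data.columns):
            raise ValueError("plot records need genotype/env/block columns")
        if "is_check" not in self.data.columns:
            self.data = self.data.assign(is_check=False)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("genotype", "env", "block", "is_check")]

    @property
    def environment_ids(self) -> list[str]:
        return sorted(self.data["env"].astype(str).unique())


@dataclass
class BlueTable:
    """Long table of genotype x environment x trait adjusted means."""

    data: pd.DataFrame  # columns: genotype, env, trait, value
    standardized: bool = False
    fit_info: dict = field(default_factory=dict)  # (env, trait) -> variance estimates

    def __post_init__(self) -> None:
        need = {"genotype", "env", "trait", "value"}
        if not need.issubset(self.data.columns):
            raise ValueError("BLUE table needs genotype/env/trait/value columns")
        dup = self.data.duplicated(subset=["genotype", "env", "trait"])
        if dup.any():
            raise ValueError("duplicate (genotype, env, trait) cells in BLUE table")

    def wide(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        return sub.pivot(index="genotype", columns="env", values="value")

    def value(self, genotype, env, trait) -> float:
        sub = self.data
        m = (sub["genotype"] == genotype) & (sub["env"] == env) & (sub["trait"] == trait)
        v = sub.loc[m, "value"]
        return float(v.iloc[0]) if len(v) else np.nan


@dataclass
class TraitSummary:
    traits: list[str]
    heritability: dict[str, float] | None = None
    correlation: pd.DataFrame | None = None
    covariance: pd.DataFrame | None = None


def transform_ear_height(eh_cm: float | np.ndarray, ideotype_cm: float = 80.0):
    """Negated absolute distance to the ideotype: -(|EH - ideotype|).

    The result is <= 0, equals 0 only at the ideotype, and forces a negative
    correlation with yield wherever the raw trait correlates positively.
    """
    eh = np.asarray(eh_cm, dtype=float)
    if np.any(eh[~np.isnan(eh)] < 0):
        raise ValueError("ear height must be non-negative")
    out = -np.abs(eh - ideotype_cm)
    return float(out) if np.isscalar(eh_cm) else out


def standardize_traits(b: BlueTable) -> BlueTable:
    """Z-score each trait across all its cells; missing cells stay missing."""
    df = b.data.copy()
    for trait, sub in df.groupby("trait"):
        vals = sub["value"].dropna()
        if len(vals) < 2:
            raise ValueError(f"trait {trait}: need >= 2 non-missing values")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait {trait}: zero variance, cannot standardize")
        df.loc[sub.index, "value"] = (sub["value"] - vals.mean()) / sd
    return BlueTable(df, standardized=True, fit_info=dict(b.fit_info))


# ---------------------------------------------------------------------------
# stage-1 mixed-model machinery


def _design(sub: pd.DataFrame, trait: str):
    """Dummy design for one env x trait: intercept + genotype + block classes."""
    y = sub[trait].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    sub, y = sub.loc[ok], y[ok]
    genos = sorted(sub["genotype"].astype(str).unique())
    blocks = sorted(sub["block"].astype(str).unique())
    g_idx = sub["genotype"].astype(str).map({g: i for i, g in enumerate(genos)}).to_numpy()
    b_idx = sub["block"].astype(str).map({b: i for i, b in enumerate(blocks)}).to_numpy()
    n = len(sub)
    Xg = np.zeros((n, len(genos) - 1))
    for j in range(1, len(genos)):
        Xg[g_idx == j, j - 1] = 1.0
    X = np.column_stack([np.ones(n), Xg])
    Zb = np.zeros((n, len(blocks)))
    Zb[np.arange(n), b_idx] = 1.0
    return y, X, Zb, genos, blocks


def _blues_from_coefs(beta: np.ndarray, genos: list[str], block_mean: float) -> dict[str, float]:
    mu = beta[0]
    out = {genos[0]: mu + block_mean}
    for j, g in enumerate(genos[1:], start=1):
        out[g] = mu + beta[j] + block_mean
    return out


def _fit_fixed_blocks(y, X, Zb, genos):
    """OLS with genotype and block as fixed classes; BLUE = LS-mean over blocks."""
    Xb = Zb[:, 1:]  # first block is the reference level
    Xfull = np.column_stack([X, Xb])
    beta, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    p = X.shape[1]
    block_effects = np.concatenate([[0.0], beta[p:]])
    resid = y - Xfull @ beta
    dof = len(y) - np.linalg.matrix_rank(Xfull)
    s2e = float(resid @ resid / dof) if dof > 0 else np.nan
    return _blues_from_coefs(beta, genos, block_effects.mean()), {"sigma2_e": s2e, "sigma2_block": None}


def _reml_profile(y, X, Zb):
    """Profile restricted log-likelihood pieces for V = sigma2_e (I + gamma ZZ')."""
    n, p = X.shape
    k_b = Zb.sum(axis=0)  # plots per block
    X1 = Zb.T @ X  # per-block column sums of X
    y1 = Zb.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y

    def pieces(gamma: float):
        c = gamma / (1.0 + gamma * k_b)
        XtWX = XtX - (X1.T * c) @ X1
        XtWy = Xty - X1.T @ (c * y1)
        ytWy = yty - c @ (y1**2)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - beta @ XtWy
        logdet_H = np.log1p(gamma * k_b).sum()
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return None
        return beta, rss, logdet_H, logdet_XtWX

    def neg_restricted_ll(log_gamma: float) -> float:
        out = pieces(np.exp(log_gamma))
        if out is None:
            return np.inf
        _, rss, logdet_H, logdet_XtWX = out
        if rss <= 0:
            return np.inf
        s2e = rss / (n - p)
        return 0.5 * ((n - p) * np.log(s2e) + logdet_H + logdet_XtWX + (n - p))

    return pieces, neg_restricted_ll


def _fit_random_blocks(y, X, Zb, genos):
    """Genotype fixed, blocks random; 1-D profile REML over gamma = s2_b/s2_e."""
    n, p = X.shape
    pieces, nll = _reml_profile(y, X, Zb)
    res = minimize_scalar(nll, bounds=(np.log(1e-6), np.log(1e6)), method="bounded",
                          options={"xatol": 1e-6})
    gamma = float(np.exp(res.x))
    if nll(np.log(1e-6)) <= res.fun:  # boundary: no block variance
        gamma = 1e-6
    beta, rss, *_ = pieces(gamma)
    s2e = float(rss / (n - p))
    blues = _blues_from_coefs(beta, genos, 0.0)  # random block effects have mean 0
    return blues, {"sigma2_e": s2e, "sigma2_block": gamma * s2e, "gamma": gamma}


def fit_stage1_blues(
    p: PlotRecords,
    design: str = "blocks_fixed",
    scope: str = "per_environment",
) -> BlueTable:
    """Genotype BLUEs per environment x trait (or jointly across environments).

    ``blocks_fixed`` solves ordinary least squares with genotype and block as
    fixed classes (RCBD-style); ``blocks_random`` profiles the restricted
    likelihood over the block-to-residual variance ratio (augmented-design
    style), with checks simply entering the genotype class.  BLUEs are the
    genotype least-squares means.
    """
    if design not in ("blocks_fixed", "blocks_random"):
        raise ValueError(f"unknown design {design!r}")
    if scope not in ("per_environment", "across_environments"):
        raise ValueError(f"unknown scope {scope!r}")
    rows = []
    info: dict = {}
    groups = (
        [(env, sub) for env, sub in p.data.groupby("env")]
        if scope == "per_environment"
        else [("_all_", p.data)]
    )
    for env, sub in groups:
        for trait in p.traits:
            if sub[trait].notna().sum() == 0:
                continue
            y, X, Zb, genos, _ = _design(sub, trait)
            if X.shape[0] <= X.shape[1]:
                raise ValueError(f"singular design for env {env}, trait {trait}")
            if design == "blocks_fixed":
                blues, vc = _fit_fixed_blocks(y, X, Zb, genos)
            else:
                blues, vc = _fit_random_blocks(y, X, Zb, genos)
            info[(env, trait)] = vc
            all_genos = set(sub["genotype"].astype(str))
            missing = all_genos - set(blues)
            if missing:
                warnings.warn(f"env {env} trait {trait}: non-estimable genotypes {sorted(missing)[:3]}")
            for g, v in blues.items():
                rows.append({"genotype": g, "env": env, "trait": trait, "value": v})
    return BlueTable(pd.DataFrame(rows), standardized=False, fit_info=info)


def estimate_heritability(p: PlotRecords) -> TraitSummary:
    """Entry-mean broad-sense heritability per trait.

    Variance components come from a genotype-random two-way decomposition on
    the genotype x environment cell-mean table (method of moments), after
    removing block means within environments.  The entry-mean formula is

        H2 = s2_g / (s2_g + s2_ge / n_E + s2_e / (n_E * n_rep)),

    with n_E and n_rep the (harmonic-mean) numbers of environments and
    replicates.  Negative component estimates are truncated at zero.
    """
    h2: dict[str, float] = {}
    for trait in p.traits:
        df = p.data[["genotype", "env", "block", trait]].dropna().copy()
        df["genotype"] = df["genotype"].astype(str)
        if df.empty:
            h2[trait] = np.nan
            continue
        n_env = df["env"].nunique()
        reps = df.groupby(["genotype", "env"]).size()
        if n_env < 2 and (reps < 2).all():
            raise ValueError("need >= 2 environments or >= 2 replicates")
        # remove block contrasts within environments (exact for balanced RCBD)
        eb = df.groupby(["env", "block"])[trait].transform("mean")
        em = df.groupby("env")[trait].transform("mean")
        df["adj"] = df[trait] - eb + em

        # residual: pooled within-cell variance (cells with >= 2 reps)
        cell = df.groupby(["genotype", "env"])["adj"]
        within_ss = cell.apply(lambda v: ((v - v.mean()) ** 2).sum()).sum()
        within_df = (reps - 1).sum()
        s2e = within_ss / within_df if within_df > 0 else 0.0
        if within_df == 0:
            warnings.warn("no replicated cells: residual variance taken as 0")
        r_h = len(reps) / (1.0 / reps).sum()  # harmonic mean reps per cell

        means = df.groupby(["genotype", "env"])["adj"].mean().unstack()
        means = means.dropna(axis=0, how="any")  # genotypes in all envs
        g_n, e_n = means.shape
        if g_n < 2:
            raise ValueError("need >= 2 genotypes present in all environments")
        row_m = means.mean(axis=1)
        ms_g = e_n * ((row_m - row_m.mean()) ** 2).sum() / (g_n - 1)
        if e_n > 1:
            resid = means.sub(row_m, axis=0).sub(means.mean(axis=0), axis=1) + means.values.mean()
            ms_int = (resid**2).values.sum() / ((g_n - 1) * (e_n - 1))
            s2ge = max(ms_int - s2e / r_h, 0.0)
            s2g = max((ms_g - ms_int) / e_n, 0.0)
        else:
            s2ge = 0.0
            s2g = max(ms_g - s2e / r_h, 0.0)
        denom = s2g + s2ge / e_n + s2e / (e_n * r_h)
        h2[trait] = float(np.clip(s2g / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return TraitSummary(traits=list(p.traits), heritability=h2)


def trait_covariance(b: BlueTable) -> TraitSummary:
    """Pairwise-complete Pearson correlations and covariance of the BLUE table."""
    wide = b.data.pivot_table(
        index=["genotype", "env"], columns="trait", values="value", aggfunc="first"
    )
    traits = list(wide.columns)
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1:]:
            if wide[[t1, t2]].dropna().shape[0] < 3:
                raise ValueError(f"fewer than 3 complete pairs for traits {t1}/{t2}")
    corr = wide.corr(min_periods=3)
    cov = wide.cov(min_periods=3)
    return TraitSummary(traits=traits, correlation=corr, covariance=cov)
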