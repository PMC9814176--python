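"""Cross-validation, prediction ability, reporting arithmetic, and economics.

CV1 holds out whole genotypes (never phenotyped anywhere); CV2 holds out cells
so every genotype keeps at least one training cell in some environment.
Prediction ability (PA) is the Pearson correlation between predictions and
BLUEs of test cells within each trait x environment group, averaged per trait
and across traits.  The economics converts PA into response to selection per
fixed budget: accuracy = PA / sqrt(H2) per trait, cost = phenotyping the
training cells (4 USD/plot for grain yield, 2 USD/plot for plant and ear
height) plus genotyping (20 USD per sample), and gain = mean accuracy / total
cost, re-based to 10,000 USD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .otsdesign import TrainingDesign
from .stage1 import BlueTable

__all__ = [
    "CvPartition",
    "PaReport",
    "EconReport",
    "DEFAULT_UNIT_COSTS",
    "make_cv_partitions",
    "prediction_ability",
    "percent_change",
    "round_half_up",
    "cost_model",
    "response_per_investment",
]

DEFAULT_UNIT_COSTS = {"GY": 4.0, "PH": 2.0, "EH": 2.0}
GENOTYPING_USD_PER_SAMPLE = 20.0


@dataclass
class CvPartition:
    scheme: str                 # "CV1" | "CV2"
    replicate: int
    train_cells: frozenset      # (genotype, env, trait)
    test_cells: frozenset


@dataclass
class PaReport:
    """PA per trait x environment, per trait, and across traits."""

    per_trait_env: pd.DataFrame      # columns trait, env, pa, sd
    per_trait: pd.DataFrame          # columns trait, pa, sd
    across_traits: float
    n_partitions: int = 1


@dataclass
class EconReport:
    scenario: str
    phenotyping_cost: float
    genotyping_cost: float
    reps_per_cell: int = 1
    per_trait_accuracy: dict = field(default_factory=dict)
    mean_accuracy: float = np.nan
    gain_per_budget: float = np.nan
    budget: float = 10_000.0

    @property
    def total_cost(self) -> float:
        return self.phenotyping_cost + self.genotyping_cost


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (report convention; numpy rounds half-even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def make_cv_partitions(
    panel_cells: list[tuple],
    scheme: str = "CV1",
    n_partitions: int = 50,
    train_fraction: float = 0.70,
    seed: int = 0,
) -> list[CvPartition]:
    """Random 70/30 partitions: genotypes for CV1, cells (stratified) for CV2."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if scheme not in ("CV1", "CV2"):
        raise ValueError("scheme must be CV1 or CV2")
    rng = np.random.default_rng(seed)
    genotypes = sorted({c[0] for c in panel_cells})
    by_geno: dict[str, list[tuple]] = {g: [] for g in genotypes}
    for c in panel_cells:
        by_geno[c[0]].append(c)
    out = []
    for rep in range(1, n_partitions + 1):
        if scheme == "CV1":
            n_train = int(round(train_fraction * len(genotypes)))
            perm = rng.permutation(len(genotypes))
            train_g = {genotypes[i] for i in perm[:n_train]}
            train = frozenset(c for c in panel_cells if c[0] in train_g)
        else:
            if min(len(v) for v in by_geno.values()) < 2:
                raise ValueError("CV2 needs >= 2 cells per genotype for stratification")
            train_set = set()
            for g in genotypes:
                cells = by_geno[g]
                n_keep = max(1, int(round(train_fraction * len(cells))))
                idx = rng.permutation(len(cells))[:n_keep]
                train_set.update(cells[i] for i in idx)
            train = frozenset(train_set)
        test = frozenset(panel_cells) - train
        out.append(CvPartition(scheme, rep, train, test))
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def prediction_ability(
    pred: pd.DataFrame,
    observed: BlueTable,
    test_cells,
    min_group: int = 3,
) -> PaReport:
    """PA within trait x environment on test cells, averaged per trait and overall.

    ``pred`` is a long table (genotype, env, trait, predicted).  Groups with
    fewer than ``min_group`` cells or zero variance are dropped with a warning.
    """
    test = set(test_cells)
    obs = observed.data.dropna(subset=["value"])
    merged = obs.merge(pred, on=["genotype", "env", "trait"], how="inner")
    merged = merged[[(g, e, t) in test for g, e, t in
                     zip(merged["genotype"], merged["env"], merged["trait"])]]
    rows = []
    for (trait, env), grp in merged.groupby(["trait", "env"]):
        if len(grp) < min_group:
            warnings.warn(f"group {trait}/{env}: fewer than {min_group} test cells, dropped")
            continue
        if grp["value"].std() == 0 or grp["predicted"].std() == 0:
            warnings.warn(f"group {trait}/{env}: zero variance, dropped")
            continue
        rows.append({"trait": trait, "env": env,
                     "pa": _pearson(grp["value"].to_numpy(), grp["predicted"].to_numpy())})
    if not rows:
        raise ValueError("no trait x environment group with enough test cells")
    pte = pd.DataFrame(rows).assign(sd=np.nan)
    per_trait = pte.groupby("trait", as_index=False)["pa"].mean().assign(sd=np.nan)
    return PaReport(
        per_trait_env=pte,
        per_trait=per_trait,
        across_traits=float(per_trait["pa"].mean()),
    )


def average_pa_reports(reports: list[PaReport]) -> PaReport:
    """Average PA over partitions, with sd over partitions."""
    pte = pd.concat([r.per_trait_env for r in reports])
    g = pte.groupby(["trait", "env"], as_index=False)["pa"].agg(["mean", "std"])
    pte_avg = g.rename(columns={"mean": "pa", "std": "sd"})
    pt = pd.concat([r.per_trait for r in reports])
    g2 = pt.groupby("trait", as_index=False)["pa"].agg(["mean", "std"])
    pt_avg = g2.rename(columns={"mean": "pa", "std": "sd"})
    return PaReport(
        per_trait_env=pte_avg,
        per_trait=pt_avg,
        across_traits=float(np.mean([r.across_traits for r in reports])),
        n_partitions=len(reports),
    )


def percent_change(old: float, new: float, decimals: int | None = 1) -> float:
    """100 * (new - old) / old, half-up rounded to ``decimals`` (None = exact)."""
    if old == 0:
        raise ZeroDivisionError("percent change from zero baseline")
    pct = 100.0 * (new - old) / old
    return pct if decimals is None else round_half_up(pct, decimals)


def cost_model(
    design: TrainingDesign,
    unit_costs: dict[str, float] | None = None,
    genotyping_usd_per_sample: float = GENOTYPING_USD_PER_SAMPLE,
    n_samples: int = 0,
    reps_per_cell: int = 1,
    include_check_cells: bool = True,
    scenario: str = "",
) -> EconReport:
    """Phenotyping cost = sum over cells of the trait's plot cost x replicates;
    genotyping cost = per-sample price x number of genotyped samples (the
    parental lines under the in-silico hybrid convention, or all hybrids)."""
    unit_costs = unit_costs or DEFAULT_UNIT_COSTS
    cells = design.all_cells if include_check_cells else design.cells
    pheno = 0.0
    for _, _, trait in cells:
        if trait not in unit_costs:
            raise KeyError(f"no unit cost for trait {trait!r}")
        pheno += unit_costs[trait] * reps_per_cell
    return EconReport(
        scenario=scenario or design.provenance.get("scenario", ""),
        phenotyping_cost=pheno,
        genotyping_cost=genotyping_usd_per_sample * n_samples,
        reps_per_cell=reps_per_cell,
    )


def response_per_investment(
    pa: PaReport | dict[str, float],
    h2: dict[str, float],
    econ: EconReport,
    budget: float = 10_000.0,
    phenotypic_selection: bool = False,
) -> EconReport:
    """Gain per ``budget`` USD = mean(PA_t / sqrt(H2_t)) / total cost x budget.

    Phenotypic-selection mode sets PA_t = 1 for every trait and drops the
    genotyping cost (only phenotyping is paid for).  Note accuracy = 1/sqrt(H2)
    then exceeds 1 — that is the printed recipe, kept as-is.
    """
    pa_by_trait = (dict(zip(pa.per_trait["trait"], pa.per_trait["pa"]))
                   if isinstance(pa, PaReport) else dict(pa))
    acc = {}
    for trait, h in h2.items():
        if not 0.0 < h <= 1.0:
            raise ValueError(f"H2 for {trait} must be in (0, 1]")
        pa_t = 1.0 if phenotypic_selection else pa_by_trait[trait]
        acc[trait] = pa_t / np.sqrt(h)
    total = econ.phenotyping_cost + (0.0 if phenotypic_selection else econ.genotyping_cost)
    if total <= 0:
        raise ValueError("total cost must be positive")
    mean_acc = float(np.mean(list(acc.values())))
    return EconReport(
        scenario=econ.scenario + ("/PS" if phenotypic_selection else ""),
        phenotyping_cost=econ.phenotyping_cost,
        genotyping_cost=0.0 if phenotypic_selection else econ.genotyping_cost,
        reps_per_cell=econ.reps_per_cell,
        per_trait_accuracy=acc,
        mean_accuracy=mean_acc,
        gain_per_budget=mean_acc / total * budget,
        budget=budget,
    )
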