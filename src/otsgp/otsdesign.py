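"""Training-set design: APY spectral sizing and genetic-algorithm cell selection.

The budget n is the number of leading eigenvalues of the composite kernel
needed to explain a fraction (default 98%) of its total variance — the
spectral core-size rule.  Which n cells to phenotype is then decided by a
look-ahead genetic algorithm with a tabu memory (LA-GA-T style) minimizing the
mean GBLUP prediction error variance of the unphenotyped cells,

    PEV-mean(T) = mean over i not in T of  K_ii - K_iT (K_TT + lambda I)^-1 K_Ti,

on the unit-genetic-variance scale with lambda the residual-to-genetic
variance ratio.  A check genotype's full environment x trait cells ride along
outside the budget to connect environments.  Optimized designs are assembled
into three scenarios: the raw samples (OTS 1), pairwise unions (OTS 2) and the
full union (OTS 3), mirrored by size-matched random controls.
"""

from __future__ import annotations

import itertools
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import CompositeKernel, KernelSpectrum

__all__ = [
    "TrainingDesign",
    "GaConfig",
    "apy_core_size",
    "pev_mean",
    "optimize_training_set",
    "combine_designs",
    "random_design",
]

Cell = tuple[str, ...]


@dataclass
class TrainingDesign:
    cells: frozenset
    check_genotype: str | None = None
    check_cells: frozenset = frozenset()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = frozenset(self.cells)
        self.check_cells = frozenset(self.check_cells)
        if not (self.cells | self.check_cells):
            raise ValueError("training design must contain at least one cell")

    @property
    def all_cells(self) -> frozenset:
        return self.cells | self.check_cells

    @property
    def size(self) -> int:
        """Budget size, excluding check cells."""
        return len(self.cells)

    def to_frame(self, panel_cells: list[Cell]) -> pd.DataFrame:
        """Long 0/1 selection table over the full panel (tabular heatmap)."""
        sel = self.all_cells
        return pd.DataFrame(
            [{"genotype": g, "env": e, "trait": t, "selected": int((g, e, t) in sel)}
             for (g, e, t) in panel_cells]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, check_genotype: str | None = None,
                   provenance: dict | None = None) -> "TrainingDesign":
        sel = df[df["selected"] == 1]
        cells = {(str(r.genotype), str(r.env), str(r.trait)) for r in sel.itertuples()}
        checks = frozenset(c for c in cells if check_genotype is not None and c[0] == check_genotype)
        return cls(cells=frozenset(cells) - checks, check_genotype=check_genotype,
                   check_cells=checks, provenance=provenance or {})


@dataclass
class GaConfig:
    population_size: int = 24
    max_generations: int = 60
    patience: int = 15
    elite: int = 2
    mutation_rate: float = 0.05
    tournament: int = 3
    tabu_capacity: int = 10_000
    look_ahead_cap: int = 200   # exhaustive steepest swap when n*(m-n) <= cap
    look_ahead_samples: int = 40  # sampled swap pairs otherwise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")


def apy_core_size(s: KernelSpectrum | np.ndarray, threshold: float = 0.98) -> int:
    """Smallest n whose n largest eigenvalues reach ``threshold`` of the total."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ev = s.eigenvalues if isinstance(s, KernelSpectrum) else np.asarray(s, dtype=float)
    ev = np.sort(ev)[::-1]
    total = ev.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("eigenvalues must be finite with positive total")
    cum = np.cumsum(ev)
    return int(np.searchsorted(cum, threshold * total - 1e-12 * total) + 1)


class _PevEvaluator:
    """PEV-mean over the untrained complement, with check cells always trained."""

    def __init__(self, k: CompositeKernel, lambda_ratio: float,
                 check_cells: frozenset = frozenset()):
        if lambda_ratio <= 0:
            raise ValueError("lambda_ratio must be positive")
        self.k = k
        self.lam = lambda_ratio
        self.check_cells = sorted(check_cells)
        self.panel = k.cell_ids()
        self.diag = {c: k.entry(c, c) for c in self.panel}

    def __call__(self, cells: frozenset) -> float:
        train = sorted(cells) + self.check_cells
        if not train:
            raise ValueError("training set must be non-empty")
        untrained = [c for c in self.panel if c not in cells and c not in self.check_cells]
        if not untrained:
            return 0.0
        ktt = self.k.submatrix(train)
        ktt[np.diag_indices_from(ktt)] += self.lam
        kut = self.k.submatrix(untrained, train)
        try:
            sol = np.linalg.solve(ktt, kut.T)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"singular K_TT + lambda I: {err}") from err
        pev = np.array([self.diag[c] for c in untrained]) - np.einsum("ij,ji->i", kut, sol)
        return float(pev.mean())


def pev_mean(
    k: CompositeKernel,
    training_cells,
    lambda_ratio: float = 1.0,
    check_cells: frozenset = frozenset(),
) -> float:
    """Mean prediction error variance of cells outside the training set."""
    cells = frozenset(training_cells)
    panel = set(k.cell_ids())
    unknown = cells - panel
    if unknown:
        raise ValueError(f"cells not in panel: {sorted(unknown)[:3]}")
    return _PevEvaluator(k, lambda_ratio, check_cells)(cells)


def _check_cells_for(k: CompositeKernel, check_genotype: str | None) -> frozenset:
    if check_genotype is None:
        return frozenset()
    _, _, g_ids = k.factors[0]
    if check_genotype not in g_ids:
        raise ValueError(f"check genotype {check_genotype!r} not in panel")
    return frozenset(c for c in k.cell_ids() if c[0] == check_genotype)


def optimize_training_set(
    k: CompositeKernel,
    n: int,
    cfg: GaConfig | None = None,
    check_genotype: str | None = None,
    lambda_ratio: float = 1.0,
) -> TrainingDesign:
    """Select n training cells minimizing PEV-mean by a look-ahead GA with tabu.

    Generational loop with elitism; set-union crossover down-sampled uniformly
    back to size n; per-cell swap mutation; a bounded FIFO tabu memory of
    visited solutions whose fitness is reused instead of re-evaluated; and a
    look-ahead step — one steepest single-swap refinement of the elite each
    generation.  Deterministic for a fixed seed.
    """
    cfg = cfg or GaConfig()
    rng = np.random.default_rng(cfg.seed)
    check_cells = _check_cells_for(k, check_genotype)
    candidates = [c for c in k.cell_ids() if c not in check_cells]
    m = len(candidates)
    if not 0 < n <= m:
        raise ValueError(f"budget n={n} must be in 1..{m}")
    evaluate = _PevEvaluator(k, lambda_ratio, check_cells)

    tabu: OrderedDict[frozenset, float] = OrderedDict()

    def fitness(cells: frozenset) -> float:
        if cells in tabu:
            tabu.move_to_end(cells)
            return tabu[cells]
        f = evaluate(cells)
        tabu[cells] = f
        if len(tabu) > cfg.tabu_capacity:
            tabu.popitem(last=False)
        return f

    def random_subset() -> frozenset:
        return frozenset(candidates[i] for i in rng.choice(m, size=n, replace=False))

    def mutate(cells: frozenset) -> frozenset:
        cells = set(cells)
        outside = [c for c in candidates if c not in cells]
        for c in list(cells):
            if outside and rng.random() < cfg.mutation_rate:
                j = int(rng.integers(len(outside)))
                cells.remove(c)
                cells.add(outside.pop(j))
                outside.append(c)
        return frozenset(cells)

    def crossover(a: frozenset, b: frozenset) -> frozenset:
        union = list(a | b)
        if len(union) <= n:
            picked = set(union)
            outside = [c for c in candidates if c not in picked]
            extra = rng.choice(len(outside), size=n - len(picked), replace=False)
            picked.update(outside[i] for i in extra)
            return frozenset(picked)
        idx = rng.choice(len(union), size=n, replace=False)
        return frozenset(union[i] for i in idx)

    def steepest_swap(cells: frozenset, f0: float) -> tuple[frozenset, float]:
        inside = sorted(cells)
        outside = [c for c in candidates if c not in cells]
        pairs = list(itertools.product(range(len(inside)), range(len(outside))))
        if len(pairs) > cfg.look_ahead_cap:
            idx = rng.choice(len(pairs), size=min(cfg.look_ahead_samples, len(pairs)),
                             replace=False)
            pairs = [pairs[i] for i in idx]
        best, best_f = cells, f0
        for i, j in pairs:
            trial = frozenset(set(cells) - {inside[i]} | {outside[j]})
            f = fitness(trial)
            if f < best_f:
                best, best_f = trial, f
        return best, best_f

    pop = [random_subset() for _ in range(cfg.population_size)]
    fits = [fitness(s) for s in pop]
    best_idx = int(np.argmin(fits))
    best, best_f = pop[best_idx], fits[best_idx]
    stall = 0
    for _gen in range(cfg.max_generations):
        order = np.argsort(fits)
        elites = [pop[i] for i in order[: cfg.elite]]
        # look-ahead: steepest single-swap refinement of the best elite
        refined, refined_f = steepest_swap(elites[0], fits[order[0]])
        elites[0] = refined
        children = list(elites)
        while len(children) < cfg.population_size:
            def pick() -> frozenset:
                idx = rng.choice(len(pop), size=min(cfg.tournament, len(pop)), replace=False)
                return pop[min(idx, key=lambda i: fits[i])]
            children.append(mutate(crossover(pick(), pick())))
        pop = children
        fits = [fitness(s) for s in pop]
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_f - 1e-12:
            best, best_f = pop[gen_best], fits[gen_best]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return TrainingDesign(
        cells=best,
        check_genotype=check_genotype,
        check_cells=check_cells,
        provenance={"kernel": k.kind, "seed": cfg.seed, "scenario": "OTS1",
                    "fitness": best_f, "lambda_ratio": lambda_ratio},
    )


def combine_designs(samples: list[TrainingDesign], mode: str = "pairwise_union") -> list[TrainingDesign]:
    """OTS 2 (pairwise unions of the samples) or OTS 3 (one full union)."""
    if not samples:
        raise ValueError("no designs to combine")
    kinds = {d.provenance.get("kernel") for d in samples}
    if len(kinds) > 1:
        raise ValueError("designs come from different kernels")
    checks = {d.check_genotype for d in samples}
    if len(checks) > 1:
        raise ValueError("designs use different check genotypes")

    def union(ds: list[TrainingDesign], label: str) -> TrainingDesign:
        cells = frozenset().union(*(d.cells for d in ds))
        check_cells = frozenset().union(*(d.check_cells for d in ds))
        return TrainingDesign(cells=cells, check_genotype=ds[0].check_genotype,
                              check_cells=check_cells,
                              provenance={**ds[0].provenance, "scenario": label})

    if mode == "pairwise_union":
        return [union(list(pair), "OTS2") for pair in itertools.combinations(samples, 2)]
    if mode == "full_union":
        return [union(list(samples), "OTS3")]
    raise ValueError(f"unknown mode {mode!r}")


def random_design(
    k: CompositeKernel,
    n: int,
    seed: int = 0,
    check_genotype: str | None = None,
) -> TrainingDesign:
    """Uniform size-n cell sample (no replacement) plus check cells."""
    rng = np.random.default_rng(seed)
    check_cells = _check_cells_for(k, check_genotype)
    candidates = [c for c in k.cell_ids() if c not in check_cells]
    if not 0 < n <= len(candidates):
        raise ValueError(f"budget n={n} must be in 1..{len(candidates)}")
    idx = rng.choice(len(candidates), size=n, replace=False)
    return TrainingDesign(
        cells=frozenset(candidates[i] for i in idx),
        check_genotype=check_genotype,
        check_cells=check_cells,
        provenance={"kernel": k.kind, "seed": seed, "scenario": "RANDOM"},
    )
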