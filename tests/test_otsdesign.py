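"""APY sizing, PEV-mean, the look-ahead GA, and design assembly."""

import itertools

import numpy as np
import pytest

from otsgp.kernels import CompositeKernel, kernel_spectrum
from otsgp.otsdesign import (GaConfig, TrainingDesign, apy_core_size, combine_designs,
                             optimize_training_set, pev_mean, random_design)


def _small_kernel(rng, n_g=3, q=2):
    a = rng.standard_normal((n_g, n_g + 2))
    g = a @ a.T / (n_g + 2)
    return CompositeKernel([("Sigma_G", g, [f"G{i}" for i in range(n_g)]),
                            ("Sigma_E", np.eye(q), [f"E{i}" for i in range(q)])])


class TestApyCoreSize:
    def test_cumulative_sum_hand_example(self):
        assert apy_core_size(np.array([50.0, 30.0, 19.0, 1.0]), 0.98) == 3

    def test_identity_kernel_needs_98_of_100(self):
        assert apy_core_size(np.ones(100), 0.98) == 98

    def test_rank_one(self):
        assert apy_core_size(np.array([5.0, 0.0, 0.0])) == 1

    @pytest.mark.parametrize("threshold", [0.0, 1.5, -0.1])
    def test_threshold_domain(self, threshold):
        with pytest.raises(ValueError):
            apy_core_size(np.ones(3), threshold)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            a = rng.standard_normal((n, n))
            mat = a @ a.T
            ev = np.linalg.eigvalsh(mat)[::-1]
            expected = 1 + int(np.argmax(np.cumsum(ev) >= 0.98 * ev.sum() - 1e-12 * ev.sum()))
            assert apy_core_size(ev, 0.98) == expected


class TestPevMean:
    def test_identity_kernel_hand_inversion(self):
        k = CompositeKernel([("G", np.eye(2), ["G0", "G1"]), ("E", np.eye(1), ["E0"])])
        assert pev_mean(k, {("G0", "E0")}, 1.0) == pytest.approx(1.0)

    def test_ones_kernel_hand_inversion(self):
        k = CompositeKernel([("G", np.ones((2, 2)), ["G0", "G1"]), ("E", np.eye(1), ["E0"])])
        assert pev_mean(k, {("G0", "E0")}, 1.0) == pytest.approx(0.5)

    def test_all_cells_trained_gives_zero(self, rng):
        k = _small_kernel(rng)
        assert pev_mean(k, set(k.cell_ids()), 1.0) == 0.0

    def test_unknown_cell_rejected(self, rng):
        k = _small_kernel(rng)
        with pytest.raises(ValueError, match="not in panel"):
            pev_mean(k, {("G9", "E0")}, 1.0)

    def test_monotone_under_inclusion_on_fixed_evaluation_set(self, rng):
        """Adding a training cell never increases any cell's PEV (oracle check)."""
        for _ in range(10):
            k = _small_kernel(rng, n_g=4, q=2)
            cells = k.cell_ids()
            lam = 0.7

            def pev_on(eval_cells, train):
                train = sorted(train)
                ktt = k.submatrix(train)
                ktt[np.diag_indices_from(ktt)] += lam
                kut = k.submatrix(eval_cells, train)
                diag = np.array([k.entry(c, c) for c in eval_cells])
                return diag - np.einsum("ij,ji->i", kut, np.linalg.solve(ktt, kut.T))

            train = set(cells[:2])
            extra = cells[3]
            eval_cells = [c for c in cells if c not in train and c != extra]
            before = pev_on(eval_cells, train)
            after = pev_on(eval_cells, train | {extra})
            assert (after <= before + 1e-9).all()
            # pev_mean agrees with the oracle on its own (complement) eval set
            full_eval = [c for c in cells if c not in train]
            assert pev_mean(k, train, lam) == pytest.approx(
                pev_on(full_eval, train).mean(), abs=1e-10)


class TestGa:
    def test_finds_exhaustive_optimum_on_toy_kernel(self, toy6):
        k, best_f = toy6["kernel"], toy6["optimal_fitness"]
        d = optimize_training_set(k, 2, GaConfig(seed=3, population_size=10,
                                                 max_generations=15))
        assert d.provenance["fitness"] == pytest.approx(best_f, abs=1e-12)
        assert d.cells == toy6["optimal_pair"]

    def test_full_budget_returns_all_cells_with_zero_fitness(self, toy6):
        k = toy6["kernel"]
        d = optimize_training_set(k, 6, GaConfig(seed=0, population_size=4,
                                                 max_generations=3))
        assert d.cells == frozenset(k.cell_ids())
        assert d.provenance["fitness"] == 0.0

    def test_seed_deterministic(self, toy6):
        k = toy6["kernel"]
        a = optimize_training_set(k, 3, GaConfig(seed=9))
        b = optimize_training_set(k, 3, GaConfig(seed=9))
        assert a.cells == b.cells and a.provenance["fitness"] == b.provenance["fitness"]

    def test_beats_median_of_random_designs(self, rng):
        k = _small_kernel(rng, n_g=6, q=3)
        n = 5
        d = optimize_training_set(k, n, GaConfig(seed=1, population_size=12,
                                                 max_generations=20))
        rand_f = [pev_mean(k, random_design(k, n, seed=s).cells, 1.0) for s in range(100)]
        assert d.provenance["fitness"] <= np.median(rand_f)

    def test_check_cells_outside_budget(self, rng):
        k = _small_kernel(rng, n_g=4, q=2)
        d = optimize_training_set(k, 2, GaConfig(seed=0), check_genotype="G0")
        assert d.size == 2
        assert d.check_cells == {("G0", "E0"), ("G0", "E1")}
        assert all(c[0] != "G0" for c in d.cells)

    def test_invalid_budget_rejected(self, toy6):
        with pytest.raises(ValueError):
            optimize_training_set(toy6["kernel"], 0, GaConfig(seed=0))
        with pytest.raises(ValueError):
            optimize_training_set(toy6["kernel"], 7, GaConfig(seed=0))


class TestCombineAndRandom:
    def _design(self, cells, scenario="OTS1"):
        return TrainingDesign(cells=frozenset(cells),
                              provenance={"kernel": "GET", "scenario": scenario})

    def test_disjoint_unions(self):
        samples = [self._design({(f"G{i}_{j}", "E0") for j in range(5)}) for i in range(3)]
        pairwise = combine_designs(samples, "pairwise_union")
        assert len(pairwise) == 3 and all(d.size == 10 for d in pairwise)
        assert all(d.provenance["scenario"] == "OTS2" for d in pairwise)
        full = combine_designs(samples, "full_union")
        assert len(full) == 1 and full[0].size == 15
        assert full[0].provenance["scenario"] == "OTS3"

    def test_identical_samples_union_is_idempotent(self):
        s = self._design({("G0", "E0"), ("G1", "E0")})
        assert combine_designs([s, s, s], "full_union")[0].cells == s.cells

    def test_overlapping_unions_smaller_than_size_sums(self, rng):
        k = _small_kernel(rng, n_g=6, q=3)
        samples = [random_design(k, 8, seed=s) for s in range(3)]
        full = combine_designs(samples, "full_union")[0]
        assert full.size < sum(s.size for s in samples)

    def test_mixed_kernel_provenance_rejected(self):
        a = self._design({("G0", "E0")})
        b = TrainingDesign(cells=frozenset({("G1", "E0")}),
                           provenance={"kernel": "GWT", "scenario": "OTS1"})
        with pytest.raises(ValueError, match="different kernels"):
            combine_designs([a, b], "full_union")

    def test_random_design_deterministic_and_exhaustive(self, rng):
        k = _small_kernel(rng)
        assert random_design(k, 3, seed=5).cells == random_design(k, 3, seed=5).cells
        assert random_design(k, 6, seed=1).cells == frozenset(k.cell_ids())

    def test_random_inclusion_uniform_over_seeds(self, rng):
        k = _small_kernel(rng, n_g=4, q=2)  # 8 cells
        n, n_seeds = 3, 200
        counts = {c: 0 for c in k.cell_ids()}
        for s in range(n_seeds):
            for c in random_design(k, n, seed=s).cells:
                counts[c] += 1
        p = n / 8
        band = 2.58 * np.sqrt(p * (1 - p) * n_seeds)  # 99% binomial band
        for c, cnt in counts.items():
            assert abs(cnt - p * n_seeds) <= band, (c, cnt)
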