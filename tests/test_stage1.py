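"""Trait scaling, stage-1 BLUEs (fixed and random blocks), H2, trait covariance."""

import numpy as np
import pandas as pd
import pytest

from otsgp.stage1 import (BlueTable, PlotRecords, estimate_heritability, fit_stage1_blues,
                          standardize_traits, trait_covariance, transform_ear_height)


class TestEarHeightTransform:
    @pytest.mark.parametrize("eh,expected", [(80, 0.0), (100, -20.0), (60, -20.0)])
    def test_distance_to_ideotype(self, eh, expected):
        assert transform_ear_height(eh) == expected

    def test_custom_ideotype(self):
        assert transform_ear_height(80, ideotype_cm=90) == -10.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            transform_ear_height(-5)

    def test_never_positive(self, rng):
        eh = rng.uniform(0, 200, 100)
        assert (transform_ear_height(eh) <= 0).all()


def _blue_table(values_by_trait):
    rows = []
    for trait, vals in values_by_trait.items():
        for i, v in enumerate(vals):
            rows.append({"genotype": f"G{i}", "env": "E1", "trait": trait, "value": v})
    return BlueTable(pd.DataFrame(rows))


class TestStandardize:
    def test_z_scores(self):
        out = standardize_traits(_blue_table({"GY": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(sorted(out.data["value"]), [-1, 0, 1])

    def test_idempotent_and_missing_preserved(self):
        b = _blue_table({"GY": [1.0, np.nan, 3.0, 5.0]})
        once = standardize_traits(b)
        twice = standardize_traits(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert once.data["value"].isna().sum() == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_traits(_blue_table({"GY": [2.0, 2.0, 2.0]}))


def _rcbd(genos, blocks, effects, block_shift=None, noise=None, env="E1"):
    rows = []
    rng = np.random.default_rng(0)
    for b in range(blocks):
        for i, g in enumerate(genos):
            y = effects[i] + (block_shift[b] if block_shift else 0.0)
            if noise:
                y += rng.normal(0, noise)
            rows.append({"genotype": g, "env": env, "block": f"B{b}", "y": y})
    return PlotRecords(pd.DataFrame(rows))


class TestFixedBlockBlues:
    def test_balanced_no_blocks_no_noise_equals_plot_mean(self):
        p = _rcbd(["G0", "G1", "G2"], 2, [1.0, 2.0, 3.0])
        b = fit_stage1_blues(p, design="blocks_fixed")
        for i in range(3):
            assert b.value(f"G{i}", "E1", "y") == pytest.approx(i + 1.0)

    def test_known_block_shifts_recovered_exactly(self):
        p = _rcbd(["G0", "G1", "G2", "G3"], 2, [1.0, 2.0, 3.0, 4.0], block_shift=[1.0, -1.0])
        b = fit_stage1_blues(p, design="blocks_fixed")
        for i in range(4):
            assert b.value(f"G{i}", "E1", "y") == pytest.approx(i + 1.0, abs=1e-10)

    def test_agrees_with_normal_equations_oracle(self, rng):
        # random unbalanced small designs: BLUE = LS-mean from explicit normal equations
        for _ in range(5):
            n_g, n_b = int(rng.integers(3, 8)), int(rng.integers(2, 4))
            rows = []
            for g in range(n_g):
                for b in range(n_b):
                    if rng.random() < 0.85 or b == 0:
                        rows.append({"genotype": f"G{g}", "env": "E1", "block": f"B{b}",
                                     "y": float(rng.normal())})
            p = PlotRecords(pd.DataFrame(rows))
            blues = fit_stage1_blues(p, design="blocks_fixed")
            df = p.data
            genos = sorted(df["genotype"].unique())
            blocks = sorted(df["block"].unique())
            X = np.zeros((len(df), len(genos) + len(blocks) - 1))
            for r, (_, row) in enumerate(df.iterrows()):
                X[r, genos.index(row["genotype"])] = 1.0
                if row["block"] != blocks[0]:
                    X[r, len(genos) + blocks.index(row["block"]) - 1] = 1.0
            beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
            block_mean = np.concatenate([[0.0], beta[len(genos):]]).mean()
            for i, g in enumerate(genos):
                assert blues.value(g, "E1", "y") == pytest.approx(
                    beta[i] + block_mean, abs=1e-8)


class TestRandomBlockBlues:
    def test_block_variance_recovered_in_augmented_design(self):
        rng = np.random.default_rng(3)
        n_blocks, s2b, s2e = 200, 4.0, 1.0
        checks = ["C1", "C2"]
        rows = []
        k = 0
        for b in range(n_blocks):
            be = rng.normal(0, np.sqrt(s2b))
            members = checks + [f"G{k}", f"G{k + 1}", f"G{k + 2}"]
            k += 3
            for g in members:
                rows.append({"genotype": g, "env": "E1", "block": f"B{b}",
                             "is_check": g in checks,
                             "y": (1.0 if g in checks else rng.normal()) + be
                             + rng.normal(0, np.sqrt(s2e))})
        p = PlotRecords(pd.DataFrame(rows))
        b = fit_stage1_blues(p, design="blocks_random")
        vc = b.fit_info[("E1", "y")]
        assert vc["sigma2_block"] == pytest.approx(s2b, abs=0.8)

    def test_profile_optimum_beats_grid(self):
        rng = np.random.default_rng(4)
        rows = []
        for b in range(40):
            be = rng.normal(0, 1.5)
            for g in range(3):
                rows.append({"genotype": f"G{b % 10}_{g}", "env": "E1", "block": f"B{b}",
                             "y": be + rng.normal()})
        p = PlotRecords(pd.DataFrame(rows))
        from otsgp.stage1 import _design, _reml_profile
        sub = p.data
        y, X, Zb, genos, _ = _design(sub, "y")
        pieces, nll = _reml_profile(y, X, Zb)
        fit = fit_stage1_blues(p, design="blocks_random")
        gamma_hat = fit.fit_info[("E1", "y")]["gamma"]
        best = nll(np.log(gamma_hat))
        grid = np.exp(rng.uniform(np.log(1e-4), np.log(1e4), 50))
        assert all(best <= nll(np.log(g)) + 1e-6 for g in grid)


class TestHeritability:
    def _two_way(self, sg, sge, se, g_n=60, e_n=3, r=2, seed=0):
        rng = np.random.default_rng(seed)
        gv = rng.normal(0, np.sqrt(sg), g_n)
        gev = rng.normal(0, np.sqrt(sge), (g_n, e_n))
        rows = []
        for gi in range(g_n):
            for ei in range(e_n):
                for b in range(r):
                    rows.append({"genotype": f"G{gi}", "env": f"E{ei}", "block": f"B{b}",
                                 "y": gv[gi] + gev[gi, ei] + rng.normal(0, np.sqrt(se))})
        return PlotRecords(pd.DataFrame(rows))

    def test_no_noise_no_gxe_gives_one(self):
        h2 = estimate_heritability(self._two_way(1.0, 0.0, 1e-12)).heritability
        assert h2["y"] == pytest.approx(1.0, abs=1e-6)

    def test_no_genetic_variance_gives_zero(self):
        h2 = estimate_heritability(self._two_way(0.0, 0.0, 1.0)).heritability
        assert h2["y"] < 0.15

    def test_recovery_at_true_060(self):
        # 300 genotypes, 3 envs, 2 reps; H2 = 1/(1 + 0.5/3 + 2/6) = 2/3 scaled
        sg, sge, se = 1.0, 0.5, 2.0
        true = sg / (sg + sge / 3 + se / 6)
        p = self._two_way(sg, sge, se, g_n=300, seed=42)
        h2 = estimate_heritability(p).heritability
        assert h2["y"] == pytest.approx(true, abs=0.1)


class TestTraitCovariance:
    def test_perfect_and_anti_correlation(self):
        rows = []
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            rows += [
                {"genotype": f"G{i}", "env": "E1", "trait": "GY", "value": v},
                {"genotype": f"G{i}", "env": "E1", "trait": "PH", "value": 5.0 - v},
                {"genotype": f"G{i}", "env": "E1", "trait": "EH", "value": v},
            ]
        ts = trait_covariance(BlueTable(pd.DataFrame(rows)))
        assert ts.correlation.loc["GY", "EH"] == pytest.approx(1.0)
        assert ts.correlation.loc["GY", "PH"] == pytest.approx(-1.0)
        sd2 = np.var([1, 2, 3, 4], ddof=1)
        assert ts.covariance.loc["GY", "PH"] == pytest.approx(-sd2)

    def test_too_few_pairs_rejected(self):
        rows = [{"genotype": "G0", "env": "E1", "trait": t, "value": 1.0}
                for t in ("GY", "PH")]
        with pytest.raises(ValueError, match="3 complete pairs"):
            trait_covariance(BlueTable(pd.DataFrame(rows)))
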