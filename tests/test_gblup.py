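"""Model term structures and the multi-kernel Gibbs sampler."""

import numpy as np
import pandas as pd
import pytest

from otsgp.gblup import (GibbsConfig, MODEL_TERMS, ModelSpec, build_model_terms,
                         fit_gblup, predict_cells)
from otsgp.stage1 import BlueTable


def _grm(rng, n):
    a = rng.standard_normal((n, 2 * n))
    return a @ a.T / (2 * n)


def _blues(genos, envs, values, trait="GY"):
    rows = [{"genotype": g, "env": e, "trait": trait, "value": v}
            for (g, e), v in zip([(g, e) for g in genos for e in envs], values)]
    return BlueTable(pd.DataFrame(rows))


class TestModelTerms:
    def test_model_families(self):
        assert MODEL_TERMS["M1"] == ("A", "D")
        assert set(MODEL_TERMS["M5"]) >= {"AW", "DW"}
        assert not set(MODEL_TERMS["M5"]) & {"AE", "DE"}
        assert set(MODEL_TERMS["M4"]) == {"A", "D", "W", "AE", "DE"}

    def test_hadamard_identity_oracle(self, rng):
        # [Z_G G Z_G'] o [Z_E Z_E'] with Z_G = I (x) 1_q, Z_E = 1_g (x) I_q == G (x) I_q
        n_g, q = 3, 2
        g = _grm(rng, n_g)
        z_g = np.kron(np.eye(n_g), np.ones((q, 1)))
        z_e = np.kron(np.ones((n_g, 1)), np.eye(q))
        hadamard = (z_g @ g @ z_g.T) * (z_e @ z_e.T)
        np.testing.assert_allclose(hadamard, np.kron(g, np.eye(q)), atol=1e-12)
        spec = ModelSpec(model="M2")
        terms = dict(build_model_terms(spec, g, np.eye(n_g), None,
                                       [f"E{i}" for i in range(q)]))
        np.testing.assert_allclose(terms["AE"].materialize(), hadamard, atol=1e-12)

    def test_main_effect_terms_are_kron_with_ones(self, rng):
        g = _grm(rng, 3)
        terms = dict(build_model_terms(ModelSpec(model="M1"), g, np.eye(3), None,
                                       ["E0", "E1"]))
        np.testing.assert_allclose(terms["A"].materialize(),
                                   np.kron(g, np.ones((2, 2))), atol=1e-12)

    def test_enviromic_terms_need_kernel(self, rng):
        with pytest.raises(ValueError, match="K_E"):
            build_model_terms(ModelSpec(model="M3"), _grm(rng, 3), np.eye(3), None,
                              ["E0", "E1"])

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="M1..M5"):
            ModelSpec(model="M9")


class TestSampler:
    def test_zero_variance_response_collapses(self, rng):
        g = _grm(rng, 8)
        genos = [f"G{i}" for i in range(8)]
        y = _blues(genos, ["E0"], np.zeros(8))
        spec = ModelSpec(model="M1")
        terms = build_model_terms(spec, g, np.eye(8), None, ["E0"])
        fit = fit_gblup(y, spec, terms, GibbsConfig(iterations=600, burn_in=100, seed=0))
        assert np.abs(fit.genetic_mean).max() < 0.1

    def test_fixed_variance_posterior_matches_ridge(self, rng):
        n = 30
        g = _grm(rng, n)
        genos = [f"G{i}" for i in range(n)]
        y_vals = rng.multivariate_normal(np.zeros(n), g + np.eye(n))
        y = _blues(genos, ["E0"], y_vals)
        spec = ModelSpec(model="M1")
        terms = build_model_terms(spec, g, np.eye(n) * 1e-12, None, ["E0"])
        fit = fit_gblup(y, spec, terms,
                        GibbsConfig(iterations=10_000, burn_in=1_000, thinning=1, seed=4,
                                    fix_variances={"A": 1.0, "D": 1e-12, "residual": 1.0}))
        v = g + np.eye(n)
        vi = np.linalg.inv(v)
        x = np.ones((n, 1))
        beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y_vals).item()
        u = g @ vi @ (y_vals - beta)
        idx = fit.cell_index()
        u_hat = np.array([fit.genetic_mean[idx[(g_, "E0")]] for g_ in genos])
        # per-cell agreement within MC error; the worst cell stays bounded too
        assert np.abs(u_hat - u).mean() < 0.02
        assert np.abs(u_hat - u).max() < 0.05

    def test_heritability_recovered_at_300_cells(self, rng):
        n = 300
        a = rng.standard_normal((n, 60))
        g = a @ a.T / 60  # structured kinship: identifiable A-vs-residual split
        genos = [f"G{i}" for i in range(n)]
        u = np.linalg.cholesky(g + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
        y = _blues(genos, ["E0"], u + rng.standard_normal(n))
        spec = ModelSpec(model="M1")
        terms = build_model_terms(spec, g, np.eye(n) * 1e-12, None, ["E0"])
        fit = fit_gblup(y, spec, terms,
                        GibbsConfig(iterations=10_000, burn_in=1_000, seed=8,
                                    fix_variances={"D": 1e-12}))
        va, ve = fit.variance_components["A"], fit.variance_components["residual"]
        assert va / (va + ve) == pytest.approx(0.5, abs=0.1)

    def test_seed_reproducibility_bit_identical(self, rng):
        g = _grm(rng, 10)
        genos = [f"G{i}" for i in range(10)]
        y = _blues(genos, ["E0", "E1"], rng.standard_normal(20))
        spec = ModelSpec(model="M2")
        terms = build_model_terms(spec, g, _grm(rng, 10), None, ["E0", "E1"])
        cfg = GibbsConfig(iterations=500, burn_in=100, seed=13)
        a = fit_gblup(y, spec, terms, cfg)
        b = fit_gblup(y, spec, terms, cfg)
        np.testing.assert_array_equal(a.genetic_mean, b.genetic_mean)
        assert a.variance_components == b.variance_components

    def test_m5_with_identity_enviromic_kernel_matches_m2(self, rng):
        """AW with K_E = I degenerates to AE; posterior means must agree within MC error."""
        n, q = 12, 3
        g_a, g_d = _grm(rng, n), _grm(rng, n)
        genos = [f"G{i}" for i in range(n)]
        envs = [f"E{i}" for i in range(q)]
        y = _blues(genos, envs, rng.standard_normal(n * q))
        m2 = ModelSpec(model="M2")
        m5 = ModelSpec(model="M5")
        t2 = build_model_terms(m2, g_a, g_d, None, envs)
        t5 = build_model_terms(m5, g_a, g_d, np.eye(q), envs)
        fixed = {"A": 0.5, "D": 0.2, "AE": 0.4, "DE": 0.1, "residual": 1.0}
        fixed5 = {"A": 0.5, "D": 0.2, "AW": 0.4, "DW": 0.1, "W": 1e-12, "residual": 1.0}
        f2 = fit_gblup(y, m2, t2, GibbsConfig(iterations=6_000, burn_in=1_000, seed=3,
                                              fix_variances=fixed))
        f5 = fit_gblup(y, m5, t5, GibbsConfig(iterations=6_000, burn_in=1_000, seed=3,
                                              fix_variances=fixed5))
        assert np.abs(f2.genetic_mean - f5.genetic_mean).max() < 0.05

    def test_missing_environment_rejected(self, rng):
        g = _grm(rng, 4)
        genos = [f"G{i}" for i in range(4)]
        y = _blues(genos, ["E0"], rng.standard_normal(4))
        spec = ModelSpec(model="M1")
        terms = build_model_terms(spec, g, np.eye(4), None, ["E0", "E1"])
        with pytest.raises(ValueError, match="no observed cells"):
            fit_gblup(y, spec, terms, GibbsConfig(iterations=200, burn_in=50, seed=0))


class TestPrediction:
    def _fit(self, rng, hide_genotype=None):
        n, q = 10, 2
        g = _grm(rng, n)
        g[0] = g[1]; g[:, 0] = g[:, 1]; g[0, 0] = g[1, 1]  # G0 duplicates G1
        genos = [f"G{i}" for i in range(n)]
        envs = ["E0", "E1"]
        u = np.linalg.cholesky(g + 1e-6 * np.eye(n)) @ rng.standard_normal(n)
        rows = []
        for i, ge in enumerate(genos):
            for e in envs:
                if ge != hide_genotype:
                    rows.append({"genotype": ge, "env": e, "trait": "GY", "value": u[i]})
        y = BlueTable(pd.DataFrame(rows))
        spec = ModelSpec(model="M1")
        terms = build_model_terms(spec, g, np.eye(n) * 1e-12, None, envs)
        fit = fit_gblup(y, spec, terms, GibbsConfig(iterations=3_000, burn_in=500, seed=7,
                                                    fix_variances={"D": 1e-12}))
        return fit, u, genos

    def test_observed_cells_track_noiseless_signal(self, rng):
        fit, u, genos = self._fit(rng)
        pred = predict_cells(fit, trait="GY")
        sub = pred[pred["env"] == "E0"].set_index("genotype").loc[genos]
        assert np.corrcoef(sub["predicted"], u)[0, 1] > 0.9

    def test_unobserved_genotype_still_predicted_everywhere(self, rng):
        fit, _, _ = self._fit(rng, hide_genotype="G5")
        pred = predict_cells(fit, trait="GY")
        assert len(pred[pred["genotype"] == "G5"]) == 2
        assert pred["predicted"].notna().all()

    def test_duplicate_genotypes_get_identical_predictions(self, rng):
        fit, _, _ = self._fit(rng, hide_genotype="G0")
        pred = predict_cells(fit, trait="GY").set_index(["genotype", "env"])
        for e in ("E0", "E1"):
            assert pred.loc[("G0", e), "genetic_value"] == pytest.approx(
                pred.loc[("G1", e), "genetic_value"], abs=1e-9)

    def test_unknown_cell_rejected(self, rng):
        fit, _, _ = self._fit(rng)
        with pytest.raises(KeyError):
            predict_cells(fit, cells=[("G99", "E0")])
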