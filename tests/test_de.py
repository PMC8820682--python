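"""Linear-model fitting, empirical-Bayes moderation, BH and DE calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hepamir as hm
from hepamir.de import (FitResult, MiRNALinearModel, adjust_bh, estimate_prior,
                        fit_models, make_contrast, moderate, trigamma_inverse)
from hepamir.io import ExpressionMatrix

from conftest import make_meta


def expr_from_array(arr, meta):
    arr = np.asarray(arr, dtype=float)
    vals = pd.DataFrame(arr, index=[f"miR-t{i}" for i in range(arr.shape[0])],
                        columns=meta["sample_id"])
    return ExpressionMatrix(vals, meta)


def two_group_design(meta):
    X = pd.get_dummies(meta["diet"], dtype=float)
    X.index = meta["sample_id"]
    return X


class TestFitModels:
    def test_two_constant_groups(self):
        meta = make_meta([f"S{i}" for i in range(6)], diets=["CHO"] * 3 + ["EtOH"] * 3)
        em = expr_from_array([[1, 1, 1, 3, 3, 3]], meta)
        fit = fit_models(em, two_group_design(meta), {"d": "EtOH - CHO"})
        assert fit.contrast_estimates.loc["miR-t0", "d"] == pytest.approx(2.0)
        assert fit.s2.loc["miR-t0"] == pytest.approx(0.0)

    def test_intercept_only_is_sample_mean(self, rng):
        meta = make_meta([f"S{i}" for i in range(5)])
        y = rng.normal(size=(3, 5))
        em = expr_from_array(y, meta)
        X = pd.DataFrame({"intercept": np.ones(5)}, index=meta["sample_id"])
        fit = fit_models(em, X, {"mu": "intercept"})
        assert np.allclose(fit.coefficients["intercept"], y.mean(axis=1))

    def test_matches_normal_equations_oracle(self, rng):
        meta = make_meta([f"S{i}" for i in range(6)], diets=["CHO"] * 3 + ["EtOH"] * 3,
                         times=[0, 6, 24, 0, 6, 24])
        y = rng.normal(size=(10, 6))
        em = expr_from_array(y, meta)
        X = pd.DataFrame({"a": [1, 1, 1, 0, 0, 0], "b": [0, 0, 0, 1, 1, 1],
                          "t": [0, 6, 24, 0, 6, 24]}, index=meta["sample_id"], dtype=float)
        fit = fit_models(em, X, {"d": "b - a"})
        Xn = X.to_numpy()
        for g in range(10):
            beta = np.linalg.solve(Xn.T @ Xn, Xn.T @ y[g])
            assert np.allclose(fit.coefficients.iloc[g], beta, atol=1e-10)

    def test_rank_deficient_design_names_aliased_column(self):
        meta = make_meta([f"S{i}" for i in range(4)], diets=["CHO", "CHO", "EtOH", "EtOH"])
        em = expr_from_array(np.ones((2, 4)), meta)
        X = two_group_design(meta)
        X["dup"] = X["CHO"] + X["EtOH"]
        with pytest.raises(ValueError, match="dup"):
            fit_models(em, X, {})

    def test_contrast_parser(self):
        cols = ["A", "B", "C"]
        assert np.allclose(make_contrast(cols, "A - B"), [1, -1, 0])
        assert np.allclose(make_contrast(cols, "0.5*A + 0.5*B - C"), [0.5, 0.5, -1])
        with pytest.raises(ValueError, match="nope"):
            make_contrast(cols, "A - nope")


class TestModeration:
    @staticmethod
    def _random_fit(rng, G=200, n=6):
        meta = make_meta([f"S{i}" for i in range(n)],
                         diets=["CHO"] * (n // 2) + ["EtOH"] * (n - n // 2))
        y = rng.normal(size=(G, n)) * rng.uniform(0.5, 2.0, size=(G, 1))
        em = expr_from_array(y, meta)
        X = pd.get_dummies(meta["diet"], dtype=float)
        X.index = meta["sample_id"]
        return fit_models(em, X, {"d": "EtOH - CHO"})

    def test_d0_zero_limit_equals_ordinary_t(self, rng):
        fit = self._random_fit(rng)
        _, t_mod, _, _ = moderate(fit, d0_override=0.0)
        se = fit.contrast_stdev_unscaled["d"] * np.sqrt(fit.s2)
        t_ord = fit.contrast_estimates["d"] / se
        assert np.allclose(t_mod["d"], t_ord, atol=1e-12)

    def test_equal_variances_are_fixed_point(self):
        G = 50
        fit = FitResult(
            coefficients=pd.DataFrame(np.ones((G, 1)), columns=["a"]),
            contrast_estimates=pd.DataFrame({"d": np.ones(G)}),
            contrast_stdev_unscaled=pd.DataFrame({"d": np.ones(G)}),
            s2=pd.Series(np.full(G, 0.7)),
            df_residual=4.0,
            ave_expr=pd.Series(np.zeros(G)),
        )
        prior, t, p, _ = moderate(fit)
        # all s2 equal -> no excess variability -> posterior equals the common value
        post = (prior.d0 * prior.s0_squared + 4.0 * 0.7) / (prior.d0 + 4.0) \
            if np.isfinite(prior.d0) else prior.s0_squared
        assert post == pytest.approx(0.7, rel=1e-6)

    def test_posterior_variance_between_s2_and_prior(self, rng):
        fit = self._random_fit(rng, G=300)
        prior, *_ = moderate(fit)
        from hepamir.de import posterior_variance
        post = posterior_variance(fit.s2.to_numpy(), fit.df_residual, prior)
        s2 = fit.s2.to_numpy()
        lo = np.minimum(s2, prior.s0_squared) - 1e-12
        hi = np.maximum(s2, prior.s0_squared) + 1e-12
        assert ((post >= lo) & (post <= hi)).all()

    def test_trigamma_inverse_inverts(self):
        from scipy.special import polygamma
        for y in (0.05, 0.5, 3.0, 40.0):
            assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-8)

    def test_prior_estimation_needs_two_variances(self):
        with pytest.raises(ValueError, match=">= 2"):
            estimate_prior(np.array([0.0, 0.0]), 4.0)


class TestAdjustBH:
    def test_closed_form_triplet(self):
        assert np.allclose(adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(adjust_bh(np.ones(5)), 1.0)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(100):
            p = rng.uniform(size=rng.integers(3, 40))
            want = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(adjust_bh(p) - want)) < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.2]))

    def test_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCallDe:
    @staticmethod
    def _results_from_tables(lfc, adj):
        idx = [f"m{i}" for i in range(len(lfc))]
        meta = make_meta(["S0", "S1", "S2", "S3"], diets=["CHO", "CHO", "EtOH", "EtOH"])
        em = expr_from_array(np.zeros((len(lfc), 4)), meta)
        X = pd.get_dummies(meta["diet"], dtype=float)
        X.index = meta["sample_id"]
        model = MiRNALinearModel(em, X, {"d": "EtOH - CHO"})
        res = model.fit()
        res.fit.contrast_estimates = pd.DataFrame({"d": lfc}, index=idx)
        res.adj_p = pd.DataFrame({"d": adj}, index=idx)
        return res

    def test_boundary_log2fc_included(self):
        res = self._results_from_tables([1.5, 3.0, -1.5], [0.04, 0.2, 0.01])
        calls = res.call(lfc_min=1.5, alpha=0.05)["d"]
        assert calls["up"] == ["m0"]          # exactly 1.5 with adj p 0.04 -> called
        assert calls["down"] == ["m2"]
        assert "m1" not in calls["up"]        # big fold change, p 0.2 -> not called

    def test_fc_only_switch(self):
        res = self._results_from_tables([2.0], [0.9])
        assert res.call(fc_only=True)["d"]["up"] == ["m0"]
        assert res.call()["d"]["up"] == []

    def test_threshold_monotone(self):
        res = self._results_from_tables([1.4, 1.6, 2.5, -2.0], [0.01] * 4)
        loose = res.call(lfc_min=1.5)["d"]
        tight = res.call(lfc_min=2.0)["d"]
        assert set(tight["up"]) <= set(loose["up"])
        assert set(tight["down"]) <= set(loose["down"])


class TestPlantedRecovery:
    def test_planted_effects_recovered_with_low_false_discovery(self):
        """|delta| = 2 plants at n = 3, phi = 0.1: recall >= 0.8 and FDR on
        planted nulls <= 0.1, averaged over 20 seeds."""
        recalls, fdrs = [], []
        design = hm.StudyDesign(times_h=(0, 72), treatments=("untreated",),
                                treatment_times_h=(0,), n_reps=3, panel_size=200)
        for seed in range(20):
            pat = {f"miR-de{i:02d}": hm.PlantedPattern({"EtOH": (1,)}, 2.0) for i in range(10)}
            pat.update({f"miR-dn{i:02d}": hm.PlantedPattern({"EtOH": (-1,)}, 2.0) for i in range(5)})
            cfg = hm.SyntheticConfig(planted_patterns=pat, n_pos_corr=0, n_neg_corr=0,
                                     dispersion_phi=0.1, seed=seed)
            cm, truth = hm.generate_counts(design, cfg)
            em = hm.log_cpm(cm, hm.tmm_factors(cm))
            X = hm.group_design(cm.samples, factors=("diet", "time_h"))
            res = hm.MiRNALinearModel(em, X, {"d": "EtOH_72 - EtOH_0"}).fit()
            calls = res.call(lfc_min=1.5, alpha=0.05)["d"]
            called = set(calls["up"]) | set(calls["down"])
            planted = set(pat) | {truth.reference_mirna}
            planted_hits = {m for m in called if m in set(pat)}
            recalls.append(len(planted_hits) / len(pat))
            false = called - planted
            fdrs.append(len(false) / max(len(called), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdrs) <= 0.1


def test_from_formula_builds_group_design(rng):
    meta = make_meta([f"S{i}" for i in range(6)], diets=["CHO"] * 3 + ["EtOH"] * 3)
    em = expr_from_array(rng.normal(size=(4, 6)), meta)
    model = MiRNALinearModel.from_formula("0 + C(diet)", em,
                                          {"d": "C(diet)[EtOH] - C(diet)[CHO]"})
    res = model.fit()
    want = (em.values.iloc[:, 3:].mean(axis=1) - em.values.iloc[:, :3].mean(axis=1))
    assert np.allclose(res.log2fc["d"], want, atol=1e-10)
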