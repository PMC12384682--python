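import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import kstest, norm

from wardtrig.glmm import (GlmmFit, ModelSpec, SeparationError, build_design,
                           fit_glmm, fit_model, lrt, odds_ratio)


def simulate_glmm(seed, G=30, m=25, beta=(-1.0, 0.7), sigma=0.8,
                  extra_cols=0):
    rng = np.random.default_rng(seed)
    n = G * m
    groups = np.repeat(np.arange(G), m)
    X = np.column_stack([np.ones(n)] +
                        [rng.normal(size=n) for _ in range(len(beta) - 1
                                                           + extra_cols)])
    b = rng.normal(0, sigma, G) if sigma > 0 else np.zeros(G)
    eta = X[:, :len(beta)] @ np.asarray(beta) + b[groups]
    y = (rng.random(n) < expit(eta)).astype(float)
    return y, X, groups


def dense_loglik(beta, sigma, y, X, groups, n_grid=8001):
    """Brute-force marginal loglik: trapezoid over b ∈ [−10σ, 10σ]."""
    bs = np.linspace(-10 * sigma, 10 * sigma, n_grid)
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        eta = X[sel] @ beta
        ll = (y[sel, None] * (eta[:, None] + bs)
              - np.logaddexp(0, eta[:, None] + bs)).sum(axis=0)
        total += np.log(np.trapezoid(np.exp(ll) * norm.pdf(bs, 0, sigma), bs))
    return total


class TestModelSpec:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec("motor", ("z_sound_sd:time_group",))
        ModelSpec("motor", ("time_group", "z_sound_sd",
                            "z_sound_sd:time_group"))

    def test_nesting_is_subset_of_terms(self):
        a = ModelSpec("motor", ("time_group",))
        b = ModelSpec("motor", ("time_group", "z_sound_sd"))
        assert a.is_nested_in(b) and not b.is_nested_in(a)
        assert not a.is_nested_in(ModelSpec("verbal", ("time_group",)))


class TestBuildDesign:
    df = pd.DataFrame({
        "motor": [0, 1, 0, 1], "patient_id": ["a", "a", "b", "b"],
        "time_group": [1, 2, 3, 2],
        "maj_room_group": ["living room", "hallway", "living room",
                          "dining room"],
        "z": [0.5, -1.0, 0.0, 2.0],
    })

    def test_reference_levels_and_names(self):
        y, X, names, groups = build_design(
            self.df, ModelSpec("motor", ("time_group", "maj_room_group",
                                         "z")))
        assert names == ["intercept", "time_group[2]", "time_group[3]",
                         "maj_room_group[dining room]",
                         "maj_room_group[hallway]", "z"]
        assert X[:, 0].tolist() == [1, 1, 1, 1]
        assert X[:, 1].tolist() == [0, 1, 0, 1]
        assert groups.tolist() == [0, 0, 1, 1]

    def test_interaction_columns_are_products(self):
        y, X, names, _ = build_design(
            self.df, ModelSpec("motor", ("time_group", "z",
                                         "z:time_group")))
        j = names.index("z:time_group[2]")
        assert np.allclose(X[:, j], X[:, names.index("z")]
                           * X[:, names.index("time_group[2]")])


class TestFitAgainstOracles:
    def test_marginal_loglik_matches_dense_integration(self):
        # tiny fixture (3 groups × 4 observations): the quadrature is
        # compared to brute-force integration at fixed parameter values,
        # so the check isolates the integral from the optimizer
        from wardtrig.glmm import _MarginalLoglik
        y, X, groups = simulate_glmm(1, G=3, m=4, sigma=1.2)
        f = _MarginalLoglik(y, X, groups)
        for beta, sigma in [((-1.0, 0.7), 1.2), ((0.3, -0.4), 0.5),
                            ((0.0, 0.0), 2.0)]:
            ll = -f(np.array([*beta, np.log(sigma)]))[0]
            oracle = dense_loglik(np.asarray(beta), sigma, y, X, groups)
            assert ll == pytest.approx(oracle, abs=1e-6)
        # and at the fitted optimum as well
        fit = fit_glmm(y, X, groups)
        sigma_hat = max(fit.sigma_b, 1e-3)
        ll_hat = -f(np.array([*fit.beta, np.log(sigma_hat)]))[0]
        oracle = dense_loglik(fit.beta, sigma_hat, y, X, groups)
        assert ll_hat == pytest.approx(oracle, abs=1e-6)

    def test_sigma_zero_data_matches_plain_logistic(self):
        # independence data whose σ_b MLE lands on the boundary: the GLMM
        # collapses onto the plain GLM logistic estimates
        import statsmodels.api as sm
        y, X, groups = simulate_glmm(4, G=25, m=40, sigma=0.0)
        fit = fit_glmm(y, X, groups)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.sigma_b == pytest.approx(0.0, abs=1e-3)
        assert np.abs(fit.beta - np.asarray(glm.params)).max() < 1e-4

    def test_fix_sigma_zero_is_exact_logistic(self):
        import statsmodels.api as sm
        y, X, groups = simulate_glmm(4, G=10, m=30, sigma=0.6)
        fit = fit_glmm(y, X, groups, fix_sigma=0.0)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.abs(fit.beta - np.asarray(glm.params)).max() < 1e-6

    def test_quadrature_order_converged(self):
        y, X, groups = simulate_glmm(5, G=20, m=20, sigma=1.0)
        f25 = fit_glmm(y, X, groups, n_quad=25)
        f51 = fit_glmm(y, X, groups, n_quad=51)
        assert np.abs(f25.beta - f51.beta).max() < 1e-5
        assert abs(f25.sigma_b - f51.sigma_b) < 1e-5

    def test_matches_lme4_glmer_reference(self):
        y, X, groups = simulate_glmm(6, G=25, m=25, sigma=0.9)
        fit = fit_glmm(y, X, groups)
        with tempfile.TemporaryDirectory() as td:
            pd.DataFrame({"y": y.astype(int), "x": X[:, 1], "g": groups}) \
                .to_csv(f"{td}/d.csv", index=False)
            r = subprocess.run(
                ["Rscript", "-e",
                 f'd<-read.csv("{td}/d.csv");'
                 'suppressMessages(library(lme4));'
                 'm<-glmer(y~x+(1|g),data=d,family=binomial,nAGQ=25);'
                 'cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m),'
                 '    sep="\\n")'],
                capture_output=True, text=True, timeout=300)
            assert r.returncode == 0, r.stderr
            ref = [float(v) for v in r.stdout.strip().split("\n")]
        assert np.abs(fit.beta - ref[:2]).max() < 5e-3
        assert abs(fit.sigma_b - ref[2]) < 5e-3
        assert abs(fit.loglik - ref[3]) < 1e-3

    def test_deterministic_given_data(self):
        y, X, groups = simulate_glmm(7, G=15, m=20, sigma=0.7)
        a, b = fit_glmm(y, X, groups), fit_glmm(y, X, groups)
        assert np.array_equal(a.beta, b.beta)
        assert a.loglik == b.loglik


class TestFitDiagnostics:
    def test_single_class_outcome_rejected(self):
        y, X, groups = simulate_glmm(8, G=5, m=10)
        with pytest.raises(SeparationError):
            fit_glmm(np.zeros_like(y), X, groups)

    def test_fewer_than_two_groups_rejected(self):
        y, X, groups = simulate_glmm(9, G=4, m=10)
        with pytest.raises(ValueError, match="2 groups"):
            fit_glmm(y, X, np.zeros_like(groups))

    def test_complete_separation_flagged_not_raised(self):
        rng = np.random.default_rng(10)
        n = 200
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = (x > 0).astype(float)           # perfectly separable
        groups = np.arange(n) % 10
        fit = fit_glmm(y, X, groups)
        assert not fit.converged
        assert "separation" in fit.message

    def test_wald_null_calibration_under_permutation(self):
        # permuting a predictor against a null outcome gives uniform p
        rng = np.random.default_rng(11)
        y, X, groups = simulate_glmm(11, G=15, m=12, beta=(-0.5, 0.0),
                                     sigma=0.6)
        pvals = []
        for _ in range(400):
            Xp = X.copy()
            Xp[:, 1] = rng.permutation(X[:, 1])
            pvals.append(fit_glmm(y, Xp, groups).pvalues[1])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestRecoveryProperty:
    def test_unbiased_over_replicates(self):
        # 50 replicates: mean estimate within 2 MC SEs of truth for every
        # fixed effect and the random-intercept SD
        truth_beta, truth_sigma = np.array([-0.8, 0.6]), 0.8
        est = []
        for s in range(50):
            y, X, groups = simulate_glmm(100 + s, G=40, m=20,
                                         beta=tuple(truth_beta),
                                         sigma=truth_sigma)
            f = fit_glmm(y, X, groups)
            est.append([*f.beta, f.sigma_b])
        est = np.asarray(est)
        mean, mcse = est.mean(0), est.std(0, ddof=1) / np.sqrt(len(est))
        truth = np.array([*truth_beta, truth_sigma])
        assert np.all(np.abs(mean - truth) <= 2 * mcse + 1e-12), (mean, mcse)


class TestLrt:
    def _fits(self, seed=12):
        y, X, groups = simulate_glmm(seed, G=20, m=20, beta=(-0.8, 0.9),
                                     sigma=0.7, extra_cols=1)
        nested = fit_glmm(y, X[:, :2], groups, term_names=["intercept", "x"],
                          row_index=np.arange(len(y)))
        full = fit_glmm(y, X, groups, term_names=["intercept", "x", "noise"],
                        row_index=np.arange(len(y)))
        return nested, full

    def test_identical_specs_give_p_one_and_drop(self):
        nested, _ = self._fits()
        res = lrt(nested, nested)
        assert res.delta_deviance == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == 1.0 and not res.keep

    def test_non_nested_rejected(self):
        nested, full = self._fits()
        with pytest.raises(ValueError, match="nested"):
            lrt(full, nested)

    def test_differing_rows_rejected(self):
        nested, full = self._fits()
        full.row_index = full.row_index[:-1]
        full.n_obs -= 1
        with pytest.raises(ValueError, match="rows"):
            lrt(nested, full)

    def test_planted_effect_detected_with_high_significance(self):
        y, X, groups = simulate_glmm(13, G=30, m=25, beta=(-1.0, 0.8),
                                     sigma=0.6)
        nested = fit_glmm(y, X[:, :1], groups, term_names=["intercept"],
                          row_index=np.arange(len(y)))
        full = fit_glmm(y, X, groups, term_names=["intercept", "x"],
                        row_index=np.arange(len(y)))
        res = lrt(nested, full)
        assert res.pvalue < 1e-3 and res.keep

    def test_pure_noise_addition_type_one_error(self):
        # adding a pure-noise column: LRT rejects ≈ α of the time
        keep = []
        for s in range(120):
            nested, full = self._fits(200 + s)
            keep.append(lrt(nested, full).keep)
        rate = np.mean(keep)
        assert 0.01 <= rate <= 0.11, rate


class TestOddsRatio:
    def _fit(self):
        return GlmmFit(spec=None, terms=["intercept", "x"],
                       beta=np.array([0.0, 0.68]),
                       se=np.array([0.1, 0.17]), sigma_b=0.5, loglik=-10.0,
                       n_obs=100, n_groups=10, n_quad=25, converged=True)

    def test_zero_beta_gives_unit_or(self):
        assert odds_ratio(self._fit(), "intercept")["or"] == 1.0

    def test_exponentiation(self):
        res = odds_ratio(self._fit(), "x")
        assert res["or"] == pytest.approx(np.exp(0.68), abs=1e-12)
        assert res["or"] == pytest.approx(1.974, abs=1e-3)

    def test_ci_is_monotone_transform(self):
        fit = self._fit()
        fit.beta = np.array([0.0, -0.61])
        fit.se = np.array([0.1, 0.2602])   # Wald CI ≈ (−1.12, −0.10)
        res = odds_ratio(fit, "x")
        lo, hi = res["ci"]
        assert lo == pytest.approx(np.exp(-1.12), rel=1e-2)
        assert hi == pytest.approx(np.exp(-0.10), rel=1e-2)

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            odds_ratio(self._fit(), "nope")


class TestFitModelOnFeatureTable:
    def test_rows_dropped_listwise_and_recorded(self, small_dataset):
        from wardtrig.features import build_feature_table
        feats, _, _ = build_feature_table(small_dataset, [21.0])
        spec = ModelSpec("agitation", ("time_group", "z_sound_sd"))
        fit = fit_model(feats, spec)
        ok = feats[feats["passed"]].dropna(subset=["z_sound_sd"])
        assert fit.n_obs == len(ok)
        assert np.array_equal(fit.row_index, ok.index.to_numpy())
        assert fit.converged
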