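"""Conditional/marginal likelihood, MLE machinery and Wald intervals."""

import math

import numpy as np
import pandas as pd
import pytest

import h2mix as hm
from h2mix.fit import FitConfig, FitResult, _pack


def make_small_panel(ref_fixed, ref_V, n_subjects=2, times=(1.0, 18.0, 36.0), seed=5):
    """Tiny panel with known random effects for oracle integrations."""
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(ref_V.matrix)
    rows = []
    for i in range(n_subjects):
        race = i % 2
        b = chol @ rng.standard_normal(2)
        theta = hm.compose_theta(ref_fixed, hm.SubjectEffects(*b), race)
        for t in times:
            mu = hm.h2_mean(theta, t)
            rows.append(
                (f"P{i}", race, t, max(mu + rng.standard_normal() * math.sqrt(ref_fixed.sigma2_eps), 0.0))
            )
    return pd.DataFrame(rows, columns=["subject", "race", "t", "rate"])


def brute_force_marginal(fixed, V, panel, n_grid=400, half_width=6.0):
    """Independent 2-D trapezoid integration of the random-effects integral."""
    total = 0.0
    s1, s2 = math.sqrt(V.v11), math.sqrt(V.v22)
    b1 = np.linspace(-half_width * s1, half_width * s1, n_grid)
    b2 = np.linspace(-half_width * s2, half_width * s2, n_grid)
    B1, B2 = np.meshgrid(b1, b2, indexing="ij")
    Vinv = np.linalg.inv(V.matrix)
    log_prior = (
        -np.log(2 * np.pi)
        - 0.5 * math.log(np.linalg.det(V.matrix))
        - 0.5
        * (Vinv[0, 0] * B1**2 + 2 * Vinv[0, 1] * B1 * B2 + Vinv[1, 1] * B2**2)
    )
    for (subj, race), g in panel.groupby(["subject", "race"]):
        t = g["t"].to_numpy()
        y = g["rate"].to_numpy()
        ll = np.zeros_like(B1)
        for tj, yj in zip(t, y):
            level = fixed.alpha[0] + race * fixed.alpha[1] + B1
            rate = fixed.alpha[3] + race * fixed.alpha[4] + B2
            mu = level / (
                1 + fixed.alpha[2] * np.arcsinh(np.exp(-rate * tj ** fixed.alpha[5]))
            )
            ll += -0.5 * np.log(2 * np.pi * fixed.sigma2_eps) - (yj - mu) ** 2 / (
                2 * fixed.sigma2_eps
            )
        integrand = np.exp(ll + log_prior)
        total += math.log(np.trapezoid(np.trapezoid(integrand, b2, axis=1), b1))
    return total


class TestConditionalLoglik:
    def test_point_on_curve_with_special_variance(self, ref_fixed):
        """A residual of zero with variance 1/(2*pi) has log-density zero."""
        fixed = hm.H2FixedEffects(alpha=ref_fixed.alpha, sigma2_eps=1.0 / (2 * np.pi))
        theta = hm.compose_theta(fixed, hm.SubjectEffects(0.0, 0.0), 0)
        obs = pd.DataFrame({"t": [10.0], "rate": [hm.h2_mean(theta, 10.0)]})
        assert hm.conditional_loglik(fixed, hm.SubjectEffects(0.0, 0.0), 0, obs) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_closed_form_residual_sum(self, ref_fixed):
        theta = hm.compose_theta(ref_fixed, hm.SubjectEffects(0.0, 0.0), 0)
        t = np.array([1.0, 5.0, 9.0, 20.0])
        resid = np.array([0.5, -1.0, 0.25, 2.0])
        obs = pd.DataFrame({"t": t, "rate": hm.h2_mean(theta, t) + resid})
        s2 = ref_fixed.sigma2_eps
        expected = -len(t) / 2 * math.log(2 * math.pi * s2) - np.sum(resid**2) / (2 * s2)
        got = hm.conditional_loglik(ref_fixed, hm.SubjectEffects(0.0, 0.0), 0, obs)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_independent_density_sum(self, ref_fixed):
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        effects = hm.SubjectEffects(0.1, -0.0005)
        theta = hm.compose_theta(ref_fixed, effects, 1)
        t = np.arange(1.0, 11.0)
        y = hm.h2_mean(theta, t) + rng.normal(size=10)
        obs = pd.DataFrame({"t": t, "rate": y})
        oracle = float(
            np.sum(norm.logpdf(y, hm.h2_mean(theta, t), math.sqrt(ref_fixed.sigma2_eps)))
        )
        assert hm.conditional_loglik(ref_fixed, effects, 1, obs) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_nonpositive_variance_rejected(self, ref_fixed):
        with pytest.raises(ValueError):
            hm.H2FixedEffects(alpha=ref_fixed.alpha, sigma2_eps=0.0)


class TestMarginalLoglik:
    def test_degenerate_prior_collapses_to_conditional(self, ref_fixed, ref_V):
        panel = make_small_panel(ref_fixed, ref_V)
        V0 = hm.RandomEffectsCov(v11=1e-12, v12=0.0, v22=1e-12)
        expected = sum(
            hm.conditional_loglik(ref_fixed, hm.SubjectEffects(0.0, 0.0), race, g)
            for (_, race), g in panel.groupby(["subject", "race"])
        )
        got = hm.marginal_loglik(ref_fixed, V0, panel)
        assert got == pytest.approx(expected, abs=1e-4)

    def test_matches_brute_force_integration(self, ref_fixed, ref_V):
        """Adaptive quadrature agrees with dense 2-D trapezoid integration.

        With only three observations per subject the integrand is markedly
        non-Gaussian, so the quadrature needs more nodes here than on
        full-length series to reach the oracle tolerance.
        """
        panel = make_small_panel(ref_fixed, ref_V, n_subjects=2)
        oracle = brute_force_marginal(ref_fixed, ref_V, panel)
        got = hm.marginal_loglik(ref_fixed, ref_V, panel, nodes=15)
        assert got == pytest.approx(oracle, rel=1e-5)
        # the default node count is within a small multiple of that tolerance
        assert hm.marginal_loglik(ref_fixed, ref_V, panel) == pytest.approx(
            oracle, rel=5e-5
        )

    def test_invariant_to_subject_order(self, ref_fixed, ref_V, default_panel):
        ll = hm.marginal_loglik(ref_fixed, ref_V, default_panel)
        reversed_panel = default_panel.iloc[::-1].reset_index(drop=True)
        assert hm.marginal_loglik(ref_fixed, ref_V, reversed_panel) == ll

    def test_quadrature_stability_9_to_15_nodes(self, ref_fixed, ref_V, default_panel):
        ll9 = hm.marginal_loglik(ref_fixed, ref_V, default_panel, nodes=9)
        ll15 = hm.marginal_loglik(ref_fixed, ref_V, default_panel, nodes=15)
        assert abs(ll15 - ll9) < 1e-4

    def test_singular_V_rejected(self, ref_fixed, default_panel):
        V = hm.RandomEffectsCov(v11=1.0, v12=1.0, v22=1.0)  # det = 0
        with pytest.raises(ValueError):
            hm.marginal_loglik(ref_fixed, V, default_panel)


class TestWaldCI:
    def test_reconstructs_printed_first_row(self):
        lower, upper = hm.wald_ci(13.1361, 0.3877, 24, 0.95)
        # the printed interval was computed from unrounded SAS internals, so
        # reconstruction from the rounded estimate/SE agrees to ~2e-4
        assert lower == pytest.approx(12.3360, abs=2e-4)
        assert upper == pytest.approx(13.9361, abs=3e-4)
        assert 13.1361 / 0.3877 == pytest.approx(33.89, abs=0.01)

    def test_reconstructs_printed_negative_row(self):
        lower, upper = hm.wald_ci(-0.2230, 0.01105, 24, 0.95)
        assert lower == pytest.approx(-0.2457, abs=2e-4)
        assert upper == pytest.approx(-0.2002, abs=2e-4)
        assert -0.2230 / 0.01105 == pytest.approx(-20.18, abs=0.01)

    def test_zero_se_gives_point_interval(self):
        assert hm.wald_ci(3.2, 0.0, 24, 0.95) == (3.2, 3.2)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            hm.wald_ci(1.0, -0.1, 24, 0.95)
        with pytest.raises(ValueError):
            hm.wald_ci(1.0, 0.1, 0, 0.95)
        with pytest.raises(ValueError):
            hm.wald_ci(1.0, 0.1, 24, 1.5)


class TestFitMLE:
    def test_identity_fit_recovers_noise_free_truth(self, ref_fixed, noise_free_panel):
        res = hm.fit_mle(
            noise_free_panel,
            config=FitConfig(include_random_effects=False, compute_ses=False),
        )
        assert res.converged
        for i, name in enumerate(
            ("level", "level_race", "shape", "rate", "rate_race", "power")
        ):
            assert res.estimate(name) == pytest.approx(ref_fixed.alpha[i], rel=1e-6)

    def test_likelihood_ascent_from_explicit_init(self, ref_fixed, ref_V, default_panel):
        init = (ref_fixed, ref_V)
        res = hm.fit_mle(default_panel, init=init, config=FitConfig(nodes=3))
        ll_init = hm.marginal_loglik(ref_fixed, ref_V, default_panel, nodes=3)
        assert res.converged
        assert res.loglik >= ll_init - 1e-6

    def test_estimate_invariant_to_row_shuffle_and_relabel(self, default_panel):
        cfg = FitConfig(nodes=3, compute_ses=False)
        res1 = hm.fit_mle(default_panel, config=cfg)
        shuffled = default_panel.sample(frac=1.0, random_state=9).reset_index(drop=True)
        relabel = {f"S{i + 1:02d}": f"Z{i + 1:02d}" for i in range(13)}
        shuffled["subject"] = shuffled["subject"].map(relabel)
        res2 = hm.fit_mle(shuffled, config=cfg)
        np.testing.assert_allclose(res1.estimates, res2.estimates, atol=1e-8)

    def test_single_time_point_per_subject_rejected(self):
        panel = pd.DataFrame(
            {"subject": ["A", "B"], "race": [0, 1], "t": [1.0, 1.0], "rate": [5.0, 3.0]}
        )
        with pytest.raises(ValueError, match="fewer than 3 distinct time"):
            hm.fit_mle(panel)

    def test_t_values_are_estimate_over_se(self, default_panel):
        res = hm.fit_mle(default_panel, config=FitConfig(nodes=3))
        ok = np.isfinite(res.ses) & (res.ses > 0)
        np.testing.assert_allclose(
            res.t_values[ok], res.estimates[ok] / res.ses[ok], rtol=1e-12
        )
        # Wald intervals are symmetric about the estimate
        mid = 0.5 * (res.ci_lower[ok] + res.ci_upper[ok])
        np.testing.assert_allclose(mid, res.estimates[ok], rtol=1e-9, atol=1e-9)

    def test_table_has_nlmixed_style_columns(self, default_panel):
        res = hm.fit_mle(default_panel, config=FitConfig(nodes=3))
        table = res.to_table()
        assert list(table.columns) == [
            "Parameter", "Estimate", "SE", "DF", "t-value", "P-value", "Alpha",
            "Lower", "Upper",
        ]
        assert (table["DF"] == 24).all()  # 26 series - 2 random effects


class TestPredictSubject:
    def _fit_result_at(self, fixed, V, n_series=1):
        """Synthetic converged FitResult at known parameters."""
        names = ["level", "level_race", "shape", "rate", "rate_race", "power",
                 "v11", "v12", "v22", "sigma2"]
        q = np.concatenate([fixed.alpha, [V.v11, V.v12, V.v22, fixed.sigma2_eps]])
        nan = np.full(len(q), np.nan)
        return FitResult(
            names=names, estimates=q, ses=nan, df=24, t_values=nan, p_values=nan,
            ci_lower=nan, ci_upper=nan, level=0.95, loglik=0.0, converged=True,
            message="synthetic", vcov=None, n_series=n_series, grad_norm=0.0,
            fixed=fixed, V=V, config=FitConfig(),
        )

    def test_population_subject_predicted_on_population_curve(self, ref_fixed, ref_V):
        t = np.arange(1.0, 37.0)
        theta = hm.compose_theta(ref_fixed, hm.SubjectEffects(0.0, 0.0), 0)
        panel = pd.DataFrame(
            {"subject": "A", "race": 0, "t": t, "rate": hm.h2_mean(theta, t)}
        )
        fit = self._fit_result_at(ref_fixed, ref_V)
        pred = hm.predict_subject(fit, panel, "A")
        np.testing.assert_allclose(pred["rate_pred"], hm.h2_mean(theta, t), atol=1e-3)
        effects = pred.attrs["effects"]
        assert abs(effects.b1) < 1e-3 and abs(effects.b2) < 1e-5

    def test_recovers_large_level_effect(self, ref_fixed, ref_V):
        rng = np.random.default_rng(11)
        b1_true = 0.45
        theta = hm.compose_theta(ref_fixed, hm.SubjectEffects(b1_true, 0.0), 0)
        t = np.arange(1.0, 37.0)
        tight = hm.H2FixedEffects(alpha=ref_fixed.alpha, sigma2_eps=1e-4)
        panel = pd.DataFrame(
            {
                "subject": "A",
                "race": 0,
                "t": t,
                "rate": hm.h2_mean(theta, t) + 0.01 * rng.standard_normal(len(t)),
            }
        )
        fit = self._fit_result_at(tight, ref_V)
        pred = hm.predict_subject(fit, panel, "A")
        assert pred.attrs["effects"].b1 == pytest.approx(b1_true, rel=0.10)

    def test_unknown_subject_raises(self, ref_fixed, ref_V, default_panel):
        fit = self._fit_result_at(ref_fixed, ref_V)
        with pytest.raises(KeyError):
            hm.predict_subject(fit, default_panel, "NOPE")

    def test_unconverged_fit_rejected(self, ref_fixed, ref_V, default_panel):
        fit = self._fit_result_at(ref_fixed, ref_V)
        fit.converged = False
        with pytest.raises(RuntimeError):
            hm.predict_subject(fit, default_panel, "S01", race=0)
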