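import numpy as np
import pytest

from qtraitsem.covstruct import CovStruct, vech
from qtraitsem.dwls import (
    FitOptions,
    fit_dwls,
    chisq_diff,
    model_chisq,
    sandwich_vtheta,
)
from qtraitsem.factor_models import build_model, implied_sigma
from qtraitsem.synthetic import build_v, preset, replicate_rng, simulate_covstruct

INDS = ["y1", "y2", "y3"]
TRUE_THETA = np.array([0.9, 0.8, 0.5, 0.35, 0.0, 0.4, 0.45, 0.5, 1.0])
# order for followup ['y3']: lambda[y2], lambda[y3], psi, b, d[y3], theta[y1..3], phi


def _exact_cs(spec, theta, se=0.02):
    sigma = implied_sigma(spec, theta)
    m = sigma.shape[0] * (sigma.shape[0] + 1) // 2
    V = np.eye(m) * se**2
    return CovStruct(spec.variable_names, sigma, V)


class TestFitDWLS:
    def test_perfect_fit_recovers_truth(self):
        spec = build_model(INDS, "T", "common_pathway")
        theta_star = np.array([0.9, 0.8, 0.5, 0.35, 0.4, 0.45, 0.5, 1.0])
        cs = _exact_cs(spec, theta_star)
        fit = fit_dwls(spec, cs, FitOptions(seed=1))
        assert fit.converged
        np.testing.assert_allclose(fit.theta_hat, theta_star, atol=1e-6)
        assert fit.fwls_min < 1e-10
        assert fit.chisq == pytest.approx(0.0, abs=1e-8)

    def test_perfect_fit_followup(self):
        spec = build_model(INDS, "T", "followup", ["y3"])
        cs = _exact_cs(spec, TRUE_THETA)
        fit = fit_dwls(spec, cs, FitOptions(seed=1))
        np.testing.assert_allclose(fit.theta_hat, TRUE_THETA, atol=1e-6)

    def test_grid_search_oracle_two_parameter_profile(self):
        """The DWLS minimum matches brute-force enumeration on a profiled toy.

        All parameters except lambda[y2] and b are pinned at the generating
        values; the engine's constrained fit must land within one grid step
        (1e-3) of the exhaustive-search minimizer of F_WLS.
        """
        spec = build_model(INDS, "T", "common_pathway")
        theta_star = np.array([0.9, 0.8, 0.5, 0.35, 0.4, 0.45, 0.5, 1.0])
        sigma = implied_sigma(spec, theta_star)
        rng = np.random.default_rng(2024)
        pert = rng.normal(scale=0.01, size=sigma.shape)
        S = sigma + (pert + pert.T) / 2
        m = 10
        cs = CovStruct(spec.variable_names, S, np.eye(m) * 4e-4)

        fixed = {
            p.name: theta_star[i]
            for i, p in enumerate(spec.free_parameters)
            if p.name not in ("lambda[y2]", "b")
        }
        fit = fit_dwls(spec, cs, FitOptions(seed=0, fixed=fixed))
        assert fit.converged

        s_obs = vech(S)
        i_lam = spec.param_index("lambda[y2]")
        i_b = spec.param_index("b")

        def fwls(lam2, b):
            th = theta_star.copy()
            th[i_lam], th[i_b] = lam2, b
            r = s_obs - vech(implied_sigma(spec, th))
            return r @ r  # identity weights times constant; argmin unchanged

        grid = np.arange(-0.05, 0.05 + 1e-9, 1e-3)
        best, best_f = None, np.inf
        for dl in grid:
            for db in grid:
                f = fwls(0.9 + dl, 0.35 + db)
                if f < best_f:
                    best_f, best = f, (0.9 + dl, 0.35 + db)
        assert fit["lambda[y2]"] == pytest.approx(best[0], abs=1.5e-3)
        assert fit["b"] == pytest.approx(best[1], abs=1.5e-3)

    def test_relabeling_invariance(self):
        sc = preset("null_k5")
        sc.seed = 5
        cs = simulate_covstruct(sc)
        inds = sc.indicator_names
        spec = build_model(inds, "T", "common_pathway")
        fit = fit_dwls(spec, cs, FitOptions(seed=1))
        swapped = [inds[0], inds[2], inds[1]] + inds[3:]
        spec_p = build_model(swapped, "T", "common_pathway")
        fit_p = fit_dwls(spec_p, cs, FitOptions(seed=1))
        assert fit_p.fwls_min == pytest.approx(fit.fwls_min, rel=1e-6, abs=1e-12)
        for name in ("lambda[y2]", "lambda[y3]", "b", "phi"):
            assert fit_p[name] == pytest.approx(fit[name], abs=1e-5)

    def test_standardized_solution_identification_invariant(self, noisy_null):
        sc, cs = noisy_null
        for topo in ("common_pathway",):
            a = fit_dwls(build_model(sc.indicator_names, "T", topo), cs, FitOptions(seed=1))
            b = fit_dwls(
                build_model(sc.indicator_names, "T", topo, identification="unit_variance"),
                cs,
                FitOptions(seed=1),
            )
            assert a.std_solution["rg_correlate_factor"] == pytest.approx(
                b.std_solution["rg_correlate_factor"], abs=1e-5
            )
            np.testing.assert_allclose(
                a.std_solution["loadings_std"], b.std_solution["loadings_std"], atol=1e-5
            )

    def test_parameter_recovery_improves_with_precision(self):
        """RMSE of theta_hat decreases monotonically as the SEs shrink."""
        sc = preset("null_k5")
        spec = build_model(sc.indicator_names, "T", "common_pathway")
        true = np.concatenate(
            [sc.loadings[1:], [sc.psi, sc.b_true], sc.indicator_residuals, [sc.phi]]
        )
        rmses = []
        for scale in (0.05, 0.02, 0.005):
            errs = []
            for rep in range(25):
                sc.se_scale = scale
                cs = simulate_covstruct(sc, rng=replicate_rng(100 + rep, rep))
                fit = fit_dwls(spec, cs, FitOptions(seed=rep))
                if fit.converged:
                    errs.append(np.mean((fit.theta_hat - true) ** 2))
            rmses.append(np.sqrt(np.mean(errs)))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_heywood_flagging(self):
        spec = build_model(INDS, "T", "common_pathway")
        # an observed matrix whose first indicator correlates beyond what a
        # positive residual variance allows
        S = np.array(
            [
                [0.50, 0.62, 0.55, 0.30],
                [0.62, 1.00, 0.70, 0.28],
                [0.55, 0.70, 1.00, 0.26],
                [0.30, 0.28, 0.26, 1.00],
            ]
        )
        cs = CovStruct(spec.variable_names, S, np.eye(10) * 1e-4)
        fit = fit_dwls(spec, cs, FitOptions(seed=1))
        assert fit.converged
        assert any(h.startswith("theta[") or h == "psi" for h in fit.heywood)


class TestSandwich:
    def test_scalar_identity(self):
        out = sandwich_vtheta(np.array([[1.0]]), np.array([2.0]), np.array([[2.0]]))
        assert out[0, 0] == pytest.approx(2.0)

    def test_collapses_when_weights_equal_v(self, rng):
        # with a diagonal V and gamma = diag(V), the sandwich reduces to
        # the efficient-WLS covariance (D' V^{-1} D)^{-1}
        D = rng.normal(size=(6, 2))
        v = rng.uniform(0.5, 2.0, size=6)
        V = np.diag(v)
        out = sandwich_vtheta(D, v, V)
        expected = np.linalg.inv(D.T @ np.linalg.inv(V) @ D)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_rank_deficient_jacobian_raises(self):
        D = np.ones((4, 2))  # two identical columns
        with pytest.raises(np.linalg.LinAlgError, match="not locally identified"):
            sandwich_vtheta(D, np.ones(4), np.eye(4))


class TestModelChisq:
    def test_saturated_model_zero(self):
        sc = preset("ad_like")
        sc.seed = 3
        cs = simulate_covstruct(sc)
        spec = build_model(sc.indicator_names, "T", "independent_pathways")
        fit = fit_dwls(spec, cs, FitOptions(seed=1))
        # K=3 independent pathways is just-identified: m = q = 10
        assert fit.df == 0
        assert fit.chisq == pytest.approx(0.0, abs=1e-6)
        assert fit.p_value == 1.0

    def test_exact_data_zero_statistic(self):
        spec = build_model(INDS, "T", "common_pathway")
        theta_star = np.array([0.9, 0.8, 0.5, 0.35, 0.4, 0.45, 0.5, 1.0])
        sigma = implied_sigma(spec, theta_star)
        sc = preset("ad_like")
        V = build_v(sc, sigma)
        cs = CovStruct(spec.variable_names, sigma, V)
        fit = fit_dwls(spec, cs, FitOptions(seed=1))
        assert fit.chisq < 1e-8

    def test_mean_tracks_df_under_null(self):
        """Mean of the residual-based statistic approximates its df when the
        fitted model is the generating model (chi-square mean identity)."""
        sc = preset("null_k5")
        spec = build_model(sc.indicator_names, "T", "common_pathway")
        stats = []
        for rep in range(120):
            cs = simulate_covstruct(sc, rng=replicate_rng(77, rep))
            fit = fit_dwls(spec, cs, FitOptions(seed=rep))
            if fit.converged:
                stats.append(fit.chisq)
        df = 9  # m - q = 21 - 12 for K = 5
        mc_se = np.sqrt(2 * df / len(stats))
        assert abs(np.mean(stats) - df) < 3 * mc_se


class TestChisqDiff:
    def _fits(self, seed=3):
        sc = preset("ad_like")
        sc.seed = seed
        cs = simulate_covstruct(sc)
        opts = FitOptions(seed=1)
        cp = fit_dwls(build_model(sc.indicator_names, "T", "common_pathway"), cs, opts)
        ip = fit_dwls(build_model(sc.indicator_names, "T", "independent_pathways"), cs, opts)
        return cp, ip

    def test_df_is_k_minus_one(self):
        cp, ip = self._fits()
        q, df, p = chisq_diff(ip, cp)
        assert df == 2  # K - 1 for K = 3
        assert q >= 0

    def test_arithmetic(self):
        cp, ip = self._fits()
        ip.chisq, ip.df = 10.0, 3
        cp.chisq, cp.df = 46.75, 5
        q, df, _ = chisq_diff(ip, cp)
        assert q == pytest.approx(36.75)
        assert df == 2

    def test_identical_fits_give_zero(self):
        cp, ip = self._fits()
        ip.chisq = cp.chisq
        ip.df = cp.df - 2
        q, df, p = chisq_diff(ip, cp)
        assert q == 0.0 and p == 1.0

    def test_non_nested_raises(self):
        cp, ip = self._fits()
        with pytest.raises(ValueError, match="not nested"):
            chisq_diff(cp, ip)  # reversed roles

    def test_followup_df_arithmetic_k7(self, g_population):
        sc, cs = g_population
        opts = FitOptions(seed=1)
        fu = fit_dwls(
            build_model(sc.indicator_names, "T", "followup", ["y6", "y7"]), cs, opts
        )
        ip = fit_dwls(
            build_model(sc.indicator_names, "T", "independent_pathways"), cs, opts
        )
        q, df, p = chisq_diff(ip, fu)
        assert df == 4  # K - 1 - |freed| = 7 - 1 - 2
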