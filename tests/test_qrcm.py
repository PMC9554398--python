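"""Tests of the integrated-loss (QRCM) estimator and its inference tools."""

import numpy as np
import pytest
from scipy import stats

import countqr as cq
from countqr.basis import legendre, minus_log1mp
from countqr.qrcm import (
    QRCMFit,
    _gauss_legendre_01,
    _uniform_distance,
    covariance_sandwich,
)

from conftest import lp_integrated_oracle, simple_line_model, simulate_line_dataset


def make_fit(theta_values, spec, names=None):
    """Assemble a QRCMFit around a given theta (for prediction/PIT tests)."""
    theta = cq.ThetaMatrix(theta_values, spec.mask)
    return QRCMFit(
        theta_hat=theta, spec=spec, integrated_loss_value=0.0,
        gradient_norm=0.0, converged=True, n_nodes=199,
        design=np.ones((1, spec.n_coef)), working_response=np.zeros(1),
        names=names or [],
    )


class TestModelSpec:
    def test_union_mask_and_counts(self):
        spec = cq.ModelSpec([
            [legendre(0), legendre(1), minus_log1mp()],
            [legendre(0)],
            [legendre(0), legendre(1)],
        ])
        assert spec.k == 3
        assert spec.n_free == 6
        assert spec.mask.tolist() == [
            [True, True, True], [True, False, False], [True, True, False]]

    def test_validation(self):
        with pytest.raises(ValueError, match="at least one basis"):
            cq.ModelSpec([[legendre(0)], []])
        with pytest.raises(ValueError, match="duplicate"):
            cq.ModelSpec([[legendre(0), legendre(0)]])

    def test_json_roundtrip(self):
        spec = cq.ModelSpec([[legendre(0), minus_log1mp()], [legendre(2)]],
                            names=("const", "x1"))
        again = cq.ModelSpec.from_json(spec.to_json())
        assert again == spec


class TestThetaAndCurves:
    def test_masked_entries_must_be_zero(self):
        spec = cq.ModelSpec([[legendre(0), legendre(1)], [legendre(0)]])
        bad = np.array([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="exactly 0"):
            cq.ThetaMatrix(bad, spec.mask)

    def test_constant_basis_coefficient_is_flat(self):
        spec = cq.ModelSpec([[legendre(0), legendre(1)], [legendre(0)]])
        theta = cq.ThetaMatrix(np.array([[1.0, 2.0], [-0.7, 0.0]]), spec.mask)
        for p in (0.1, 0.5, 0.9):
            assert cq.beta_curve(theta, spec, p)[1] == pytest.approx(-0.7)

    def test_linearity_in_theta(self):
        spec = cq.ModelSpec([[legendre(0), legendre(1), minus_log1mp()]])
        rng = np.random.default_rng(0)
        a = rng.normal(size=(1, 3))
        b = rng.normal(size=(1, 3))
        t1 = cq.ThetaMatrix(a, spec.mask)
        t2 = cq.ThetaMatrix(b, spec.mask)
        t12 = cq.ThetaMatrix(a + b, spec.mask)
        zero = cq.ThetaMatrix(np.zeros((1, 3)), spec.mask)
        p = 0.37
        np.testing.assert_allclose(
            cq.beta_curve(t12, spec, p),
            cq.beta_curve(t1, spec, p) + cq.beta_curve(t2, spec, p))
        assert cq.beta_curve(zero, spec, p)[0] == 0.0

    def test_eval_basis_tail_log(self):
        spec = cq.ModelSpec([[legendre(0), minus_log1mp()]])
        b = cq.eval_basis(spec, 0.5)
        assert b.tolist() == pytest.approx([1.0, np.log(2.0)])
        with pytest.raises(ValueError):
            cq.eval_basis(spec, 1.0)


class TestIntegratedLoss:
    def setup_method(self):
        rng = np.random.default_rng(7)
        n = 40
        x = rng.normal(size=n)
        self.ds = cq.Dataset(np.column_stack([np.ones(n), x]),
                             rng.poisson(6, n))
        self.spec = cq.ModelSpec([[legendre(0), legendre(1)], [legendre(0)]])
        vals = np.array([[5.0, 1.0], [0.3, 0.0]])
        self.theta = cq.ThetaMatrix(vals, self.spec.mask)

    def test_matches_pointwise_pinball_quadrature(self):
        """Quadrature value equals the weighted sum of independent pointwise
        pinball evaluations at the same nodes, to 1e-12."""
        nodes, w = _gauss_legendre_01(199)
        t = self.ds.response + 0.5
        manual = sum(
            wk * cq.pinball_objective(
                self.theta.values @ self.spec.basis_matrix(pk)[0], pk, t,
                self.ds.design).loss
            for pk, wk in zip(nodes, w))
        val = cq.integrated_loss(self.theta, self.ds, self.spec)
        assert val == pytest.approx(manual, abs=1e-12 * max(1, manual))

    def test_positive_homogeneity(self):
        a = 3.7
        scaled = cq.ThetaMatrix(a * self.theta.values, self.spec.mask)
        v1 = cq.integrated_loss(self.theta, self.ds, self.spec,
                                working_response=self.ds.response + 0.5)
        v2 = cq.integrated_loss(scaled, self.ds, self.spec,
                                working_response=a * (self.ds.response + 0.5))
        assert v2 == pytest.approx(a * v1, rel=1e-12)

    def test_node_refinement_stability(self):
        v199 = cq.integrated_loss(self.theta, self.ds, self.spec, n_nodes=199)
        v999 = cq.integrated_loss(self.theta, self.ds, self.spec, n_nodes=999)
        assert abs(v199 - v999) / v999 < 1e-4


class TestFit:
    def test_matches_integrated_lp_oracle(self):
        """The quasi-Newton optimum equals the exact LP optimum of the
        quadrature objective on a small instance."""
        ds, _, _ = simulate_line_dataset(40, seed=5)
        spec = simple_line_model().spec
        fit = cq.fit_qrcm(ds, spec)
        _, f_lp = lp_integrated_oracle(ds.design, ds.response + 0.5, spec)
        assert fit.integrated_loss_value == pytest.approx(f_lp, rel=1e-5)

    def test_no_coordinate_perturbation_improves(self, model2_fit, psych_data):
        base = model2_fit.integrated_loss_value
        mask = model2_fit.spec.mask
        vals = model2_fit.theta_hat.values
        rows, cols = np.where(mask)
        rng = np.random.default_rng(0)
        pick = rng.choice(len(rows), size=8, replace=False)
        for i in pick:
            for delta in (1e-4, -1e-4):
                pert = vals.copy()
                pert[rows[i], cols[i]] += delta
                loss = cq.integrated_loss(
                    cq.ThetaMatrix(pert, mask), psych_data.dataset,
                    model2_fit.spec)
                assert loss >= base - 1e-7 * (1 + base)

    def test_deterministic_given_data(self):
        ds, model, _ = simulate_line_dataset(150, seed=2)
        f1 = cq.fit_qrcm(ds, model.spec)
        f2 = cq.fit_qrcm(ds, model.spec)
        np.testing.assert_array_equal(f1.theta_hat.values, f2.theta_hat.values)

    def test_jittered_and_offset_responses_agree(self, psych_data, model2_fit):
        """Fitting to jittered responses Z = Y + U gives near-identical theta
        to fitting the offset Y + 0.5: averaged over jitter draws (which
        removes the single-realisation noise) every entry moves by well under
        one SE, and a single draw moves entries by a small fraction of an SE
        in the median."""
        ds = psych_data.dataset
        spec = psych_data.model.spec
        se = model2_fit.standard_errors().values[spec.mask]
        thetas = []
        for s in range(10):
            z = cq.jitter_sample(ds.response, np.random.default_rng(100 + s)).z
            thetas.append(cq.fit_qrcm(ds, spec, working_response=z).theta_hat.free)
        single = np.abs(thetas[0] - model2_fit.theta_hat.free) / se
        averaged = np.abs(np.mean(thetas, axis=0) - model2_fit.theta_hat.free) / se
        assert np.median(single) < 0.25
        assert np.max(averaged) < 0.6

    def test_free_parameter_budget_enforced(self):
        ds, _, _ = simulate_line_dataset(60, seed=0)
        small = cq.Dataset(ds.design[:25], ds.response[:25])
        rich = cq.ModelSpec([cq.poly_basis(12) + [minus_log1mp()],
                             cq.poly_basis(11)])  # 26 free parameters
        with pytest.raises(ValueError, match="below the sample size"):
            cq.fit_qrcm(small, rich)


class TestSaturatedLimit:
    def test_rich_basis_tracks_pointwise_jittering(self):
        """With a rich basis (Legendre 0..8 plus -log(1-p)) on a one-covariate
        model, the jointly fitted coefficient curves coincide with pointwise
        jittering estimates at interior deciles, once the jittering
        intercept is put back on the identity scale (+p undoes the linear
        working transform)."""
        ds, _, _ = simulate_line_dataset(2000, seed=17)
        rich = cq.ModelSpec([
            cq.poly_basis(8) + [minus_log1mp()],
            cq.poly_basis(8) + [minus_log1mp()],
        ])
        fit = cq.fit_qrcm(ds, rich)
        p_grid = np.round(np.arange(0.1, 0.91, 0.1), 2)
        jfit = cq.average_jittering_fit(ds, p_grid,
                                        cq.JitterConfig(m=8, seed=5))
        jitter_identity = jfit.beta_avg.copy()
        jitter_identity[:, 0] += p_grid
        assert np.max(np.abs(fit.beta_at(p_grid) - jitter_identity)) < 0.15

    def test_fitted_curves_are_smooth(self, model2_fit):
        """No jump between adjacent percentile-grid points exceeds a quarter
        of a curve's total variation: the parametric fit cannot concentrate
        its movement in one grid step (continuity of the basis)."""
        curves = model2_fit.beta_at(cq.percentile_grid())
        jumps = np.abs(np.diff(curves, axis=0))
        tv = jumps.sum(axis=0)
        moving = tv > 1e-8
        assert np.all(jumps[:, moving].max(axis=0) <= 0.25 * tv[moving])


class TestCovarianceAndWald:
    def test_psd_and_positive_diagonal(self, model2_fit):
        V = model2_fit.covariance
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.diag(V) >= 0)
        assert np.min(np.linalg.eigvalsh(V)) > -1e-10

    def test_root_n_se_scaling(self):
        """Doubling n shrinks the median SE by about sqrt(2)."""
        meds = {}
        for n in (400, 1600):
            ses = []
            for seed in range(4):
                ds, model, _ = simulate_line_dataset(n, seed=seed)
                fit = cq.fit_qrcm(ds, model.spec)
                covariance_sandwich(fit)
                ses.append(np.sqrt(np.diag(fit.covariance)))
            meds[n] = np.median(ses)
        ratio = meds[400] / meds[1600]
        assert 1.5 < ratio < 2.7  # expected 2 for a 4x sample-size increase

    def test_wald_df_and_monotone_pvalue(self, model2_fit):
        stat, df, pval = cq.wald_test_global(model2_fit, 2)
        assert df == 7  # flexible cohort curve: degrees 0..5 plus -log(1-p)
        assert 0.0 <= pval <= 1.0
        assert stats.chi2.sf(stat + 1.0, df) < pval

    def test_wald_size_under_null(self):
        """With the covariate absent from the generator, the 5% Wald test
        rejects at about its nominal rate."""
        rejections = 0
        n_sets = 100
        for seed in range(n_sets):
            ds, _, _ = simulate_line_dataset(300, seed=seed, slope=0.0)
            fit = cq.fit_qrcm(ds, simple_line_model().spec)
            covariance_sandwich(fit)
            _, _, pval = cq.wald_test_global(fit, 1)
            rejections += pval < 0.05
        rate = rejections / n_sets
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_sets)
        assert 0.05 - band <= rate <= 0.05 + band + 1e-12


class TestPredictionAndPit:
    def _flat_fit(self, value):
        spec = cq.ModelSpec([[legendre(0)]])
        return make_fit(np.array([[value]]), spec)

    def test_ceiling_rule(self):
        x = [1.0]
        assert cq.predict_quantile_count(self._flat_fit(3.2), x, 0.5) == 3
        assert cq.predict_quantile_count(self._flat_fit(0.4), x, 0.5) == 0
        assert cq.predict_quantile_count(self._flat_fit(-0.3), x, 0.5) == -1

    def test_pit_identity_quantile_function(self):
        # beta0(p) = p  <=>  theta = (0.5, 0.5) on Legendre degrees 0, 1
        spec = cq.ModelSpec([[legendre(0), legendre(1)]])
        fit = make_fit(np.array([[0.5, 0.5]]), spec)
        got = cq.pit(fit, [1.0], -0.2)  # y0 = -0.2 + 0.5 = 0.3
        assert got == pytest.approx(0.3, abs=1e-3)

    def test_pit_clamps_out_of_range(self):
        spec = cq.ModelSpec([[legendre(0), legendre(1)]])
        fit = make_fit(np.array([[10.0, 2.0]]), spec)
        assert cq.pit(fit, [1.0], 0) == pytest.approx(1e-4)
        assert cq.pit(fit, [1.0], 50) == pytest.approx(1 - 1e-4)

    def test_latent_pit_is_uniform_under_truth(self):
        """The PIT of the continuous latent working variable under the true
        model is Uniform(0, 1)."""
        from countqr.qrcm import _pit_working

        rng = np.random.default_rng(4)
        n = 10_000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        model = simple_line_model()
        p_lat = rng.uniform(size=n)
        y0 = model.quantile_working(X, p_lat)
        fit = make_fit(model.theta_true.values, model.spec)
        u = _pit_working(fit, X, y0)
        assert stats.kstest(u, "uniform").statistic < 0.02


class TestGof:
    def test_ks_of_midpoint_grid(self):
        n = 50
        u = (np.arange(1, n + 1) - 0.5) / n
        assert _uniform_distance(u, "KS") == pytest.approx(0.5 / n)

    def test_cvm_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        u = np.sort(rng.uniform(size=37))
        n = u.size
        direct = 1.0 / (12 * n) + np.sum(((2 * np.arange(1, n + 1) - 1) / (2 * n) - u) ** 2)
        assert _uniform_distance(u, "CvM") == pytest.approx(direct, rel=1e-12)

    def test_gof_deterministic_and_bounded(self):
        ds, model, _ = simulate_line_dataset(120, seed=9)
        fit = cq.fit_qrcm(ds, model.spec)
        g1 = cq.gof_test(fit, ds, statistic="KS", n_mc=50, seed=3)
        g2 = cq.gof_test(fit, ds, statistic="KS", n_mc=50, seed=3)
        assert g1.statistic == g2.statistic
        assert g1.mc_p_value == g2.mc_p_value
        assert 0.0 <= g1.mc_p_value <= 1.0

    def test_nmc_minimum(self):
        ds, model, _ = simulate_line_dataset(60, seed=1)
        fit = cq.fit_qrcm(ds, model.spec)
        with pytest.raises(ValueError, match="n_mc"):
            cq.gof_test(fit, ds, n_mc=10)
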