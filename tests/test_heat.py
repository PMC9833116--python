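"""Arrhenius thresholds and Gaussian multi-peak decomposition."""

import numpy as np
import pytest

from nociquant import heat, simulate
from nociquant.calcium import Trace

KELVIN = 273.15
GROUP_MEANS = np.array([33.9, 39.8, 44.4, 52.0])


def two_line_trace(threshold_C, sub=2.0, gain=5.0, noise=0.0, seed=0,
                   baseline=0.5, scale=1.0):
    """Noise-controlled piecewise-linear Arrhenius trace via the generator."""
    traces, _ = simulate.gen_heat_ramp_cohort(
        1, component_means_C=(threshold_C,), component_sds_C=(0.0,),
        sub_slope=sub, supra_gain=gain, baseline_sd=noise,
        baseline_mean=baseline, seed=seed,
    )
    tr = traces[0]
    if scale != 1.0:
        tr = Trace(cell_id=tr.cell_id, t=tr.t, ratio=tr.ratio * scale,
                   temp_C=tr.temp_C, windows=[])
    return tr


class TestArrheniusThreshold:
    @pytest.mark.parametrize("theta", [36.0, 44.4, 50.0])
    def test_noiseless_two_line_intersection_recovered(self, theta):
        est = heat.arrhenius_threshold(two_line_trace(theta))
        assert est.accepted
        assert abs(est.threshold_C - theta) < 0.05

    def test_scale_invariance_of_threshold(self):
        """Multiplying the ratio trace by a positive constant shifts the
        Arrhenius intercepts only; the intersection temperature is unchanged."""
        a = heat.arrhenius_threshold(two_line_trace(44.4, noise=0.004, seed=3))
        b = heat.arrhenius_threshold(two_line_trace(44.4, noise=0.004, seed=3, scale=7.5))
        assert a.threshold_C == pytest.approx(b.threshold_C, abs=1e-6)

    def test_breakpoint_search_matches_exhaustive_oracle(self):
        """On short traces the implementation must equal a literal
        re-enumeration of every admissible split."""
        rng = np.random.default_rng(5)
        x = np.linspace(3.27, 3.05, 55)
        y = np.where(x > 3.15, -2.0 * x, -10.0 * x + 8.0 * 3.15) + rng.normal(0, 0.05, 55)

        def oracle(x, y, min_seg=5):
            best = (np.inf, None)
            for i in range(min_seg, len(x) - min_seg + 1):
                sse = 0.0
                for xs, ys in ((x[:i], y[:i]), (x[i:], y[i:])):
                    coef, res, *_ = np.polyfit(xs, ys, 1, full=True)
                    sse += res[0] if len(res) else 0.0
                if sse < best[0]:
                    best = (sse, i)
            return best

        fit = heat._two_segment_search(x, y)
        sse_o, i_o = oracle(x, y)
        assert fit.break_index == i_o
        assert fit.sse_total == pytest.approx(sse_o, rel=1e-9)

    def test_reversed_ramp_rejected(self):
        tr = two_line_trace(44.0)
        rev = Trace(cell_id="r", t=tr.t, ratio=tr.ratio, temp_C=tr.temp_C[::-1].copy())
        with pytest.raises(ValueError):
            heat.arrhenius_threshold(rev)

    def test_missing_temperature_channel_rejected(self):
        tr = two_line_trace(44.0)
        with pytest.raises(ValueError):
            heat.accelerating_filter(Trace(cell_id="x", t=tr.t, ratio=tr.ratio))

    def test_cohort_recovery_median_below_one_degree(self):
        traces, truths = simulate.gen_heat_ramp_cohort(150, seed=2)
        df = heat.estimate_thresholds(traces)
        errs = [
            abs(e - t.true_threshold_C)
            for e, t, acc in zip(df.threshold_C, truths, df.accepted)
            if acc
        ]
        assert len(errs) > 100
        assert np.median(errs) < 1.0


class TestAcceleratingFilter:
    def test_straight_line_not_accelerating(self):
        """A single-slope (non-gated) heat response must not pass."""
        traces, _ = simulate.gen_heat_ramp_cohort(
            1, component_means_C=(54.5,), component_sds_C=(0.0,),
            sub_slope=3.0, supra_gain=5.0, baseline_sd=0.002, seed=4,
        )
        # threshold at the very end of the ramp: effectively one line
        assert not heat.accelerating_filter(traces[0])

    def test_flat_trace_not_accelerating(self):
        t = np.arange(150) * 2.0
        temp = np.concatenate([np.full(15, 32.0), np.linspace(32.2, 55, 135)])
        tr = Trace(cell_id="f", t=t, ratio=np.full(150, 0.5), temp_C=temp)
        assert not heat.accelerating_filter(tr)

    def test_generated_accelerating_cell_passes(self):
        assert heat.accelerating_filter(two_line_trace(44.0, noise=0.005, seed=6))


class TestMixture:
    def test_identical_thresholds_collapse_to_single_component(self):
        fit = heat.fit_threshold_mixture([44.0] * 25, seed=0)
        assert fit.K == 1 and fit.means[0] == 44.0 and fit.weights[0] == 1.0

    def test_four_component_recovery_at_group_means(self):
        rng = np.random.default_rng(1)
        th = rng.normal(GROUP_MEANS[rng.integers(0, 4, 400)], 1.5)
        fit = heat.fit_threshold_mixture(th, seed=0)
        assert fit.K == 4
        assert np.abs(np.sort(fit.means) - GROUP_MEANS).max() < 0.5

    def test_k_selection_on_clean_three_component_draw(self):
        rng = np.random.default_rng(3)
        means = np.array([34.0, 42.0, 50.0])
        th = rng.normal(means[rng.integers(0, 3, 300)], 1.2)
        fit = heat.fit_threshold_mixture(th, seed=0)
        assert fit.K == 3
        assert np.abs(np.sort(fit.means) - means).max() < 0.5

    def test_histogram_fit_agrees_with_em_cross_check(self):
        """Dual route: the histogram least-squares fit and a raw-data EM fit
        must agree on a well-separated mixture."""
        rng = np.random.default_rng(2)
        means = np.array([35.0, 45.0])
        th = rng.normal(means[rng.integers(0, 2, 500)], 1.0)
        ls = heat.fit_threshold_mixture(th, K_candidates=(2,), seed=0)
        em_mu, _, em_w = heat.em_mixture(th, 2, seed=0)
        np.testing.assert_allclose(ls.means, em_mu, atol=0.3)
        np.testing.assert_allclose(ls.weights, em_w, atol=0.05)

    def test_em_cross_check_against_sklearn(self):
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(4)
        means = np.array([36.0, 48.0])
        th = rng.normal(means[rng.integers(0, 2, 400)], 1.5)
        mu, sd, w = heat.em_mixture(th, 2, seed=0)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(th[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(mu, gm.means_.ravel()[order], atol=0.1)
        np.testing.assert_allclose(w, gm.weights_[order], atol=0.03)

    def test_weights_recovered_on_unequal_mixture(self):
        rng = np.random.default_rng(5)
        comp = rng.choice(2, size=600, p=[0.7, 0.3])
        th = rng.normal(np.array([36.0, 47.0])[comp], 1.2)
        fit = heat.fit_threshold_mixture(th, K_candidates=(2,), seed=0)
        np.testing.assert_allclose(fit.weights, [0.7, 0.3], atol=0.07)

    def test_shifting_upper_components_moves_fitted_means(self):
        """Lowering the two upper populations by 2 and 4 degC moves the
        corresponding fitted means by the same amounts."""
        shifted = GROUP_MEANS.copy()
        shifted[2] -= 2.0
        shifted[3] -= 4.0
        rng = np.random.default_rng(1)
        th = rng.normal(shifted[rng.integers(0, 4, 400)], 1.5)
        fit = heat.fit_threshold_mixture(th, K_candidates=(4,), seed=0)
        assert np.abs(np.sort(fit.means) - shifted).max() < 0.5


class TestCumulative:
    def test_single_cell_returns_its_threshold(self):
        assert heat.cumulative_threshold([43.2], "pooled-fit") == 43.2
        assert heat.cumulative_threshold([43.2], "weighted-mean") == 43.2

    def test_symmetric_two_component_weighted_mean_is_midpoint(self):
        rng = np.random.default_rng(6)
        th = np.concatenate([rng.normal(38, 1.0, 300), rng.normal(46, 1.0, 300)])
        fit = heat.fit_threshold_mixture(th, K_candidates=(2,), seed=0)
        wm = heat.cumulative_threshold(th, "weighted-mean", mixture=fit)
        assert abs(wm - 42.0) < 0.3

    def test_modes_agree_on_near_symmetric_mixture(self):
        rng = np.random.default_rng(7)
        th = np.concatenate([rng.normal(40, 1.5, 250), rng.normal(44, 1.5, 250)])
        fit = heat.fit_threshold_mixture(th, K_candidates=(2,), seed=0)
        a = heat.cumulative_threshold(th, "pooled-fit")
        b = heat.cumulative_threshold(th, "weighted-mean", mixture=fit)
        assert abs(a - b) < 1.0
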