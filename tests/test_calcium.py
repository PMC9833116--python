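"""Response calling, viability gating and responder pooling."""

import numpy as np
import pytest

from nociquant import calcium as ca
from nociquant import simulate


def flat_trace(n=200, dt=2.0, level=0.5, windows=None, noise=None, cell_id="c0"):
    t = np.arange(n) * dt
    r = np.full(n, level)
    if noise is not None:
        r = r + noise
    return ca.Trace(cell_id=cell_id, t=t, ratio=r, windows=windows or [])


def spike(t, onset, amplitude, tau=20.0):
    out = np.zeros_like(t)
    m = t >= onset
    out[m] = amplitude * np.exp(-(t[m] - onset) / tau)
    return out


WIN = ca.ApplicationWindow("drug", 100.0, 130.0)
KCL = ca.ApplicationWindow("KCl", 200.0, 230.0, is_depolarising=True)


class TestBaselineStats:
    def test_constant_baseline(self):
        tr = flat_trace(windows=[WIN, KCL], level=0.7)
        mu, sd = ca.baseline_stats(tr, WIN)
        assert mu == pytest.approx(0.7) and sd == pytest.approx(0.0, abs=1e-15)

    def test_sd_consistency_on_gaussian_noise(self):
        rng = np.random.default_rng(0)
        n = 10_000
        tr = flat_trace(n=n + 50, dt=2.0, noise=rng.normal(0, 0.05, n + 50),
                        windows=[ca.ApplicationWindow("w", 2 * n, 2 * n + 30,
                                                      is_depolarising=True)])
        _, sd = ca.baseline_stats(tr, tr.windows[0], baseline_s=2 * n)
        assert abs(sd - 0.05) / 0.05 < 0.03

    def test_truncated_baseline_raises(self):
        early = ca.ApplicationWindow("a", 60.0, 96.0)
        late = ca.ApplicationWindow("b", 100.0, 130.0, is_depolarising=True)
        tr = flat_trace(windows=[early, late])
        with pytest.raises(ca.BaselineError):
            ca.baseline_stats(tr, late)  # only 2 clean samples remain


class TestCallResponse:
    def make(self, amplitude, onset, sigma=0.01, seed=1):
        rng = np.random.default_rng(seed)
        t = np.arange(200) * 2.0
        r = 0.5 + rng.normal(0, sigma, 200) + spike(t, onset, amplitude)
        return ca.Trace(cell_id="c", t=t, ratio=r, windows=[WIN, KCL])

    def test_amplitude_exactly_three_sigma_is_not_a_response(self):
        """The 3-sigma rule is a strict inequality.

        All values are powers of two so the baseline mean (0.5), SD (2^-7)
        and the 3-sigma peak are float-exact and the boundary is hit exactly.
        """
        w = 2.0 ** -7
        t = np.arange(200) * 2.0
        r = np.full(200, 0.5)
        base_ix = np.flatnonzero((t >= 70) & (t < 100))  # 15 baseline samples
        r[base_ix[:-1]] = 0.5 + np.tile([w, -w], 7)      # mean 0.5, sd w exactly
        seg = r[base_ix]
        mu, sd = seg.mean(), seg.std(ddof=1)
        assert (mu, sd) == (0.5, w)
        i = np.searchsorted(t, 105.0)
        r[i] = mu + 3.0 * sd  # peak at exactly 3 sigma above baseline mean
        tr = ca.Trace(cell_id="c", t=t, ratio=r, windows=[WIN, KCL])
        call = ca.call_response(tr, WIN)
        assert call.amplitude == pytest.approx(3.0 * sd)
        assert not call.responded

    def test_clear_responder_called(self):
        tr = self.make(amplitude=0.1, onset=105.0)
        call = ca.call_response(tr, WIN)
        assert call.responded and call.onset_s == pytest.approx(106.0, abs=2.0)

    def test_transient_before_window_is_rejected(self):
        tr = self.make(amplitude=0.2, onset=20.0)  # decays before the window
        call = ca.call_response(tr, WIN)
        assert not call.responded

    def test_degenerate_flat_trace_flagged(self):
        tr = flat_trace(windows=[WIN, KCL])
        call = ca.call_response(tr, WIN)
        assert not call.responded and call.degenerate

    def test_amplitude_and_auc_invariant_to_constant_offset(self):
        tr = self.make(amplitude=0.1, onset=105.0)
        shifted = ca.Trace(cell_id="c", t=tr.t, ratio=tr.ratio + 3.3, windows=tr.windows)
        a, b = ca.call_response(tr, WIN), ca.call_response(shifted, WIN)
        assert a.amplitude == pytest.approx(b.amplitude)
        assert a.auc == pytest.approx(b.auc)


class TestCohort:
    def test_responder_sensitivity_above_99_percent(self):
        """Amplitude 10x baseline SD: nearly every planted response is called."""
        traces, truths = simulate.gen_calcium_traces(
            1000, baseline_sd=0.01, amplitude_mean=0.1, amplitude_sd=0.0, seed=4
        )
        calls = ca.call_all(traces).set_index(["cell_id", "window"])
        hits = total = 0
        for tt in truths:
            for w in tt.responded_windows:
                total += 1
                hits += bool(calls.loc[(tt.cell_id, w), "responded"])
        assert hits / total >= 0.99

    def test_all_dead_cohort_retains_nothing(self):
        traces, _ = simulate.gen_calcium_traces(
            30, class_mix={"dead": 1.0}, baseline_sd=0.0, seed=7
        )
        calls = ca.call_all(traces)
        assert ca.viability_filter(calls) == []

    def test_viability_gate_recovers_nondead_labels(self, mixed_calcium_cohort):
        traces, truths = mixed_calcium_cohort
        calls = ca.call_all(traces)
        retained = set(ca.viability_filter(calls))
        non_dead = {t.cell_id for t in truths if t.cell_class != "dead"}
        assert retained == non_dead
        assert retained <= {t.cell_id for t in truths}

    def test_pool_counts_identities(self, mixed_calcium_cohort):
        traces, _ = mixed_calcium_cohort
        calls = ca.call_all(traces)
        counts = ca.pool_counts(
            calls, cross=[("LPC 30uM", "capsaicin 500nM")]
        )
        viable = set(ca.viability_filter(calls))
        for label, (k, n) in counts["per_label"].items():
            assert 0 <= k <= n == len(viable)
        sub = calls[calls["cell_id"].isin(viable)]
        both = counts["cross"][("LPC 30uM", "capsaicin 500nM")]
        ra = set(sub[(sub.window == "LPC 30uM") & sub.responded].cell_id)
        rb = set(sub[(sub.window == "capsaicin 500nM") & sub.responded].cell_id)
        assert both == len(ra & rb)

    def test_false_positive_rate_stable_across_seeds(self):
        """3-sigma calls on pure-noise viable traces: the FP rate is a property
        of the rule (window length, dt, baseline length), not of the seed."""
        def rate(seed):
            traces, _ = simulate.gen_calcium_traces(
                2000, class_mix={"kcl_only": 1.0}, seed=seed
            )
            calls = ca.call_all(traces)
            sub = calls[~calls.is_depolarising]
            return sub.responded.mean()
        r1, r2 = rate(1), rate(2)
        assert abs(r1 - r2) < 0.02

    def test_round_trip_through_bundle_files(self, tmp_path, mixed_calcium_cohort):
        traces, truths = mixed_calcium_cohort
        ca.save_traces(traces[:5], tmp_path / "t.csv", tmp_path / "t.json",
                       truth=[t.as_dict() for t in truths[:5]])
        back, truth = ca.load_traces(tmp_path / "t.csv", tmp_path / "t.json")
        assert [tr.cell_id for tr in back] == [tr.cell_id for tr in traces[:5]]
        np.testing.assert_allclose(back[0].ratio, traces[0].ratio)
        assert back[0].windows == traces[0].windows
        assert truth[0]["cell_class"] == truths[0].cell_class
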