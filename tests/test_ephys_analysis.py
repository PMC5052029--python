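import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from glica.ephys_analysis import (
    TrialRecord,
    compare_groups,
    detect_spikelets,
    fisher_exact_2x2,
    predict_passive_peak,
    psp_metrics,
    ratios_vs_passive,
    responding_fraction_curve,
    train_halfwidth_series,
)
from glica.stim_waveforms import normalized_strength
from glica.trace import Trace

from conftest import pad_trace, rc_convolution


def triangle_trace(base_ms=4.0, amp=10.0, dt=5e-5, baseline=-85.0,
                   onset_s=0.01):
    """Symmetric triangular pulse of the given base width starting at onset."""
    n = int(0.05 / dt)
    v = np.full(n, baseline)
    half = int(base_ms / 2 * 1e-3 / dt)
    i0 = int(onset_s / dt)
    up = np.linspace(0, amp, half, endpoint=False)
    down = np.linspace(amp, 0, half, endpoint=False)
    v[i0:i0 + half] += up
    v[i0 + half:i0 + 2 * half] += down
    return Trace(values=v, dt=dt, units="mV")


class TestPspMetrics:
    def test_triangle_half_width(self):
        tr = triangle_trace(base_ms=4.0)
        m = psp_metrics(tr, stim_onset=0.01)
        assert m.half_width == pytest.approx(2.0, abs=0.01)
        assert m.amplitude == pytest.approx(10.0, abs=1e-6)

    def test_offset_invariance(self):
        tr = triangle_trace()
        shifted = Trace(values=tr.values + 10.0, dt=tr.dt)
        m1 = psp_metrics(tr, 0.01)
        m2 = psp_metrics(shifted, 0.01)
        assert m1.amplitude == pytest.approx(m2.amplitude)
        assert m1.half_width == pytest.approx(m2.half_width)

    def test_time_dilation_scales_half_width(self):
        tr = triangle_trace()
        dilated = Trace(values=tr.values, dt=tr.dt * 3.0)
        m1 = psp_metrics(tr, 0.01)
        m2 = psp_metrics(dilated, 0.03)
        assert m2.half_width == pytest.approx(3.0 * m1.half_width, rel=1e-6)

    def test_flat_trace_undefined(self):
        tr = Trace(values=np.full(1000, -85.0), dt=5e-5)
        m = psp_metrics(tr, stim_onset=0.01)
        assert not m.defined
        assert np.isnan(m.half_width)

    def test_passive_convolution_peak(self, quantal_epsc):
        # amplitude within 1% of the analytic convolution peak
        from glica.synthetic_data import CellParams, simulate_membrane
        inj = pad_trace(quantal_epsc, pre=0.01, post=0.02)
        inj = inj.copy(values=inj.values * 30.0)
        V, _ = simulate_membrane(CellParams(R_in=250.0, C_m=12.0), inj)
        m = psp_metrics(V, stim_onset=0.01)
        expected = rc_convolution(inj.values, inj.dt, 250.0, 12.0, -85.0)
        assert m.amplitude == pytest.approx(expected.max() + 85.0, rel=0.01)

    def test_hyperpolarizing_probe(self):
        tr = triangle_trace(amp=-6.0)
        m = psp_metrics(tr, 0.01)
        assert m.amplitude == pytest.approx(-6.0, abs=1e-6)
        assert m.half_width == pytest.approx(2.0, abs=0.01)

    def test_baseline_window_must_precede_onset(self):
        tr = triangle_trace()
        with pytest.raises(ValueError):
            psp_metrics(tr, stim_onset=0.0)


class TestRatiosVsPassive:
    def test_identical_traces(self):
        m = psp_metrics(triangle_trace(), 0.01)
        assert ratios_vs_passive(m, m) == (pytest.approx(1.0),
                                           pytest.approx(1.0))

    def test_half_width_ratio(self):
        a = psp_metrics(triangle_trace(base_ms=2.0), 0.01)
        p = psp_metrics(triangle_trace(base_ms=4.0), 0.01)
        hw_r, _ = ratios_vs_passive(a, p)
        assert hw_r == pytest.approx(0.5, abs=0.01)

    def test_undefined_passive_raises(self):
        a = psp_metrics(triangle_trace(), 0.01)
        flat = psp_metrics(Trace(values=np.full(1000, -85.0), dt=5e-5), 0.01)
        with pytest.raises(ValueError):
            ratios_vs_passive(a, flat)


class TestPredictPassivePeak:
    def test_zero_strength(self):
        s = normalized_strength(0, 250.0)
        assert predict_passive_peak(s, 0.5) == -85.0

    def test_linearity(self):
        s1 = normalized_strength(100, 250.0)
        s2 = normalized_strength(200, 250.0)
        d1 = predict_passive_peak(s1, 0.5) + 85.0
        d2 = predict_passive_peak(s2, 0.5) + 85.0
        assert d2 == pytest.approx(2.0 * d1)

    def test_matches_passive_simulation(self, quantal_epsc):
        from glica.synthetic_data import CellParams, simulate_membrane
        cell = CellParams(R_in=250.0, C_m=12.0)
        # unit response: peak depolarization of a 1-equivalent injection
        inj1 = pad_trace(quantal_epsc, pre=0.005, post=0.02)
        V1, _ = simulate_membrane(cell, inj1)
        unit = V1.values.max() + 85.0
        s = normalized_strength(60, 250.0)
        inj = inj1.copy(values=inj1.values * 60.0)
        V, _ = simulate_membrane(cell, inj)
        predicted = predict_passive_peak(s, unit)
        assert V.values.max() == pytest.approx(predicted, rel=0.02)


class TestTrainHalfwidthSeries:
    def make_train(self, widths_ms, isi_ms=10.0, dt=5e-5):
        n = int((len(widths_ms) * isi_ms + 10) * 1e-3 / dt)
        v = np.zeros(n)
        onsets = []
        for i, w in enumerate(widths_ms):
            t0 = 0.005 + i * isi_ms * 1e-3
            onsets.append(t0)
            half = int(w / 2 * 1e-3 / dt)
            i0 = int(t0 / dt) + 10
            v[i0:i0 + half] += np.linspace(0, 10, half, endpoint=False)
            v[i0 + half:i0 + 2 * half] += np.linspace(10, 0, half,
                                                      endpoint=False)
        return Trace(values=v, dt=dt, units="mV"), onsets

    def test_identical_shapes_zero_increase(self):
        tr, onsets = self.make_train([2.0] * 5)
        widths, pct = train_halfwidth_series(tr, onsets)
        assert pct == pytest.approx(0.0, abs=0.5)

    def test_hand_built_fifty_percent(self):
        tr, onsets = self.make_train([2.0, 2.0, 3.0])
        widths, pct = train_halfwidth_series(tr, onsets)
        assert widths[0] == pytest.approx(1.0, abs=0.05)  # triangle hw = w/2
        assert pct == pytest.approx(50.0, abs=3.0)

    def test_control_broadens_but_gA0_does_not(self):
        from glica.stim_waveforms import build_psp_train
        from glica.synthetic_data import default_cell, simulate_membrane
        stim = pad_trace(build_psp_train(n=10, rate=100.0, Q=35),
                         pre=0.02, post=0.05)
        onsets = [0.02 + i * 0.01 for i in range(10)]
        _, pct_ctrl = train_halfwidth_series(
            simulate_membrane(default_cell("control"), stim)[0], onsets)
        _, pct_noA = train_halfwidth_series(
            simulate_membrane(default_cell("4AP"), stim)[0], onsets)
        assert pct_ctrl > 0.0
        assert pct_noA <= 0.0

    def test_unsorted_onsets_raise(self):
        tr, onsets = self.make_train([2.0, 2.0])
        with pytest.raises(ValueError):
            train_halfwidth_series(tr, onsets[::-1])


class TestDetectSpikelets:
    def test_smooth_gaussian_no_events(self):
        dt = 5e-5
        t = np.arange(0, 0.5, dt)
        v = -85.0 + 30.0 * np.exp(-((t - 0.25) / 0.05) ** 2)
        assert detect_spikelets(Trace(values=v, dt=dt)) == []

    def test_fast_transient_one_event(self):
        dt = 5e-5
        t = np.arange(0, 0.2, dt)
        v = np.full(t.size, -85.0)
        onset_idx = 2000
        rise = 20  # 1 ms rise to +20 mV: dV/dt = 20 mV/ms = 4x threshold
        v[onset_idx:onset_idx + rise] += np.linspace(0, 20, rise,
                                                     endpoint=False)
        v[onset_idx + rise:onset_idx + 200] += 20 * np.exp(
            -np.arange(180) / 60)
        events = detect_spikelets(Trace(values=v, dt=dt),
                                  dvdt_threshold=5.0, min_amplitude=5.0)
        assert len(events) == 1
        t_ev, amp = events[0]
        assert abs(t_ev - onset_idx * dt) <= 2 * dt
        # amplitude relative to the threshold-crossing voltage
        assert amp == pytest.approx(20.0, abs=2.0)

    def test_sampling_rate_guard(self):
        with pytest.raises(ValueError):
            detect_spikelets(Trace(values=np.zeros(100), dt=1e-3))


class TestRespondingFractionCurve:
    def test_all_responders(self):
        trials = [TrialRecord(strength=s, peak_Vm=0.0, responded=True)
                  for s in np.linspace(0, 100, 50)]
        _, fracs, _ = responding_fraction_curve(trials,
                                                np.linspace(0, 100, 6))
        np.testing.assert_allclose(fracs, 1.0)

    def test_logistic_midpoint_recovery(self):
        rng = np.random.default_rng(0)
        m = 50.0
        strengths = rng.uniform(0, 100, 1000)
        prob = 1.0 / (1.0 + np.exp(-(strengths - m) / 5.0))
        trials = [TrialRecord(strength=s, peak_Vm=0.0,
                              responded=bool(rng.random() < p))
                  for s, p in zip(strengths, prob)]
        edges = np.linspace(0, 100, 11)
        _, _, half = responding_fraction_curve(trials, edges)
        assert half is not None
        assert abs(half - m) <= 10.0  # within one bin width

    def test_empty_bin_excluded(self):
        trials = [TrialRecord(strength=s, peak_Vm=0.0, responded=True)
                  for s in [5.0, 15.0, 35.0]]  # nothing in [20, 30)
        centers, fracs, _ = responding_fraction_curve(
            trials, np.array([0.0, 10.0, 20.0, 30.0, 40.0]))
        assert centers.size == 3
        assert 25.0 not in centers

    def test_never_crosses_half(self):
        trials = [TrialRecord(strength=s, peak_Vm=0.0, responded=False)
                  for s in np.linspace(0, 100, 30)]
        _, _, half = responding_fraction_curve(trials,
                                               np.linspace(0, 100, 6))
        assert half is None

    def test_monotone_on_monotone_data(self):
        rng = np.random.default_rng(1)
        strengths = rng.uniform(0, 100, 1000)
        trials = [TrialRecord(strength=s, peak_Vm=0.0,
                              responded=bool(rng.random() < s / 100.0))
                  for s in strengths]
        _, fracs, _ = responding_fraction_curve(trials,
                                                np.linspace(0, 100, 6))
        assert np.all(np.diff(fracs) >= -0.12)  # non-decreasing within noise


def fisher_enumeration_oracle(a, b, c, d):
    """Full hypergeometric enumeration with binomial coefficients."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1, exact=True)

    def prob(x):
        return comb(r1, x, exact=True) * comb(n - r1, c1 - x, exact=True) \
            / denom

    p_obs = prob(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestFisherExact:
    def test_reported_responder_counts_vs_enumeration(self):
        # responder tables: 9/40 vs 22/43
        odds, p = fisher_exact_2x2(9, 31, 22, 21)
        assert p == pytest.approx(fisher_enumeration_oracle(9, 31, 22, 21),
                                  abs=1e-12)
        assert p < 0.05

    def test_odds_ratio_value(self):
        odds, _ = fisher_exact_2x2(9, 31, 22, 21)
        assert odds == pytest.approx(189.0 / 682.0, rel=1e-12)

    def test_proportional_table(self):
        _, p = fisher_exact_2x2(5, 5, 10, 10)
        assert p == pytest.approx(1.0)

    def test_zero_margin(self):
        odds, p = fisher_exact_2x2(0, 0, 5, 5)
        assert np.isnan(odds)
        assert p == 1.0

    @given(a=st.integers(0, 12), b=st.integers(0, 12),
           c=st.integers(0, 12), d=st.integers(0, 12))
    @settings(max_examples=60, deadline=None)
    def test_row_and_column_swap_symmetry(self, a, b, c, d):
        _, p = fisher_exact_2x2(a, b, c, d)
        _, p_row = fisher_exact_2x2(c, d, a, b)
        _, p_col = fisher_exact_2x2(b, a, d, c)
        assert p == pytest.approx(p_row, abs=1e-12)
        assert p == pytest.approx(p_col, abs=1e-12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestCompareGroups:
    def test_paired_t_identical(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "paired_t")
        assert t == 0.0
        assert p == 1.0

    def test_wmw_exact_enumeration(self):
        # all 3 observations of x below all of y: most extreme of C(6,3)=20
        # orderings; two-sided exact p = 2/20
        _, p = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], "wmw")
        assert p == pytest.approx(2.0 / 20.0, abs=1e-12)

    def test_pearson_r2_linear(self):
        x = np.arange(10.0)
        r2, p = compare_groups(x, 3.0 * x + 1.0, "pearson_r2")
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0], "wmw")

    def test_unknown_test(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [3, 4], "anova")
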