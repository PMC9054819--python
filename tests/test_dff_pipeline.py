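import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import fiberquant as fq
from fiberquant.errors import ConfigError

from oracles import biexp_sse, eq1_corrected, ols_slope_intercept, random_search_biexp


def _biexp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


class TestFitBiexponential:
    def test_noise_free_recovery(self):
        t = np.linspace(0, 300, 3000)
        f = _biexp(t, 1.0, 10.0, 0.5, 100.0, 0.2)
        fit = fq.fit_biexponential(f, t)
        assert fit.sse < 1e-10
        # components are exchangeable; compare as sorted (tau, a) pairs
        got = sorted([(fit.tau1_s, fit.a1), (fit.tau2_s, fit.a2)])
        assert got[0][0] == pytest.approx(10.0, rel=1e-3)
        assert got[0][1] == pytest.approx(1.0, rel=1e-3)
        assert got[1][0] == pytest.approx(100.0, rel=1e-3)
        assert got[1][1] == pytest.approx(0.5, rel=1e-3)
        assert fit.c == pytest.approx(0.2, abs=1e-5)

    def test_constant_vector(self):
        t = np.linspace(0, 10, 50)
        fit = fq.fit_biexponential(np.full(50, 3.0), t)
        assert fit.c == pytest.approx(3.0)
        assert fit.a1 == pytest.approx(0.0, abs=1e-9)
        assert fit.a2 == pytest.approx(0.0, abs=1e-9)

    def test_noisy_beats_random_search_oracle(self, rng):
        t = np.linspace(0, 300, 2000)
        f = _biexp(t, 0.8, 30.0, 0.3, 200.0, 1.0) + rng.normal(0, 0.01, t.size)
        fit = fq.fit_biexponential(f, t)
        oracle_sse = random_search_biexp(t, f, n_draws=1000, seed=1)
        assert fit.sse <= oracle_sse

    def test_sse_not_worse_than_single_exponential(self, rng):
        # single-exponential truth: the biexponential fit must match or beat it
        t = np.linspace(0, 100, 1000)
        f = 0.5 * np.exp(-t / 20.0) + 1.0 + rng.normal(0, 0.005, t.size)
        fit = fq.fit_biexponential(f, t)
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(lambda t, a, tau, c: a * np.exp(-t / tau) + c, t, f, p0=[0.5, 20.0, 1.0])
        single_sse = float(np.sum((f - (popt[0] * np.exp(-t / popt[1]) + popt[2])) ** 2))
        assert fit.sse <= single_sse * (1 + 1e-6)

    def test_fitted_curve_monotone_nonincreasing(self):
        t = np.linspace(0, 300, 1500)
        f = _biexp(t, 0.4, 50.0, 0.2, 500.0, 1.0)
        fit = fq.fit_biexponential(f, t)
        assert fit.a1 >= 0 and fit.a2 >= 0
        curve = fit.curve(t)
        assert np.all(np.diff(curve) <= 1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ConfigError):
            fq.fit_biexponential(np.ones(4), np.arange(4.0))

    def test_sse_matches_reported_curve(self, rng):
        t = np.linspace(0, 60, 600)
        f = _biexp(t, 0.3, 10.0, 0.1, 50.0, 0.9) + rng.normal(0, 0.002, t.size)
        fit = fq.fit_biexponential(f, t)
        assert fit.sse == pytest.approx(biexp_sse(t, f, (fit.a1, fit.tau1_s, fit.a2, fit.tau2_s, fit.c)), rel=1e-9)


class TestScaleReference:
    def test_identity(self):
        x = np.linspace(2, 1, 100)
        ref = fq.scale_reference(x, x)
        assert ref.slope == pytest.approx(1.0)
        assert ref.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine(self):
        x = np.linspace(2, 1, 100)
        y = 2.0 * x + 5.0
        ref = fq.scale_reference(x, y)
        assert ref.slope == pytest.approx(2.0)
        assert ref.intercept == pytest.approx(5.0)
        np.testing.assert_allclose(ref.scaled, y)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(2.0, 0.3, 500)
        y = 1.7 * x + 0.4 + rng.normal(0, 0.1, 500)
        ref = fq.scale_reference(x, y)
        slope, intercept = ols_slope_intercept(x, y)
        assert ref.slope == pytest.approx(slope, rel=1e-12)
        assert ref.intercept == pytest.approx(intercept, rel=1e-12)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ConfigError):
            fq.scale_reference(np.ones(10), np.arange(10.0))


class TestComputeDff:
    def test_equal_inputs_zero(self):
        s = fq.ScaledReference(slope=1.0, intercept=0.0, scaled=np.full(10, 2.0))
        trace = fq.compute_dff(np.full(10, 2.0), s)
        np.testing.assert_array_equal(trace.dff, np.zeros(10))

    def test_five_percent_offset(self):
        scaled = np.linspace(2, 1, 50)
        s = fq.ScaledReference(slope=1.0, intercept=0.0, scaled=scaled)
        trace = fq.compute_dff(1.05 * scaled, s)
        np.testing.assert_allclose(trace.dff, 0.05)

    def test_nonpositive_scaled_reports_index(self):
        scaled = np.array([1.0, 1.0, -0.5, 1.0])
        s = fq.ScaledReference(slope=1.0, intercept=0.0, scaled=scaled)
        with pytest.raises(ConfigError, match="index 2"):
            fq.compute_dff(np.ones(4), s)

    def test_noise_free_session_peak_equals_injected_amplitude(self, clean_session):
        session, truth = clean_session
        trace = fq.process_session(fq.deinterleave(session))
        assert truth.event_times_s.size > 0
        # peak height above the trace's own baseline (median): the OLS
        # scaling absorbs a constant share of the transient mass, which the
        # baseline-relative readout removes
        peak = trace.dff.max() - np.median(trace.dff)
        assert peak == pytest.approx(0.05, rel=0.01)


class TestBaselineCorrect:
    def _spec(self, hc, test, window=(0.0, 10.0)):
        hc = np.asarray(hc, dtype=float)
        return fq.BaselineSpec(hc=hc, hc_time_s=np.linspace(*window, len(hc)), test=test, hc_window=window)

    def test_zero_mean_zero_min_unchanged(self):
        spec = self._spec(np.zeros(100), np.array([0.0, 0.3, 0.1]))
        out = fq.baseline_correct(spec)
        assert out.baseline_offset == 0.0
        np.testing.assert_array_equal(out.dff, [0.0, 0.3, 0.1])

    def test_forced_example(self):
        spec = self._spec(np.ones(100), np.array([-0.5, 0.2]))
        out = fq.baseline_correct(spec)
        np.testing.assert_allclose(out.dff, [1.0, 1.7])
        assert out.dff.min() == pytest.approx(1.0)  # lands exactly on mean(hc)

    def test_matches_printed_formula_oracle(self, rng):
        for _ in range(50):
            hc = rng.normal(0.1, 0.5, 200)
            test = rng.normal(-0.2, 0.8, 300)
            spec = self._spec(hc, test)
            out = fq.baseline_correct(spec)
            np.testing.assert_allclose(out.dff, eq1_corrected(hc.mean(), test), atol=1e-12)

    def test_min_lands_on_hc_mean_when_below(self, rng):
        for _ in range(50):
            hc = rng.normal(0.5, 0.2, 100)
            test = rng.normal(0.0, 0.3, 200)
            spec = self._spec(hc, test)
            if test.min() <= hc.mean():
                out = fq.baseline_correct(spec)
                assert out.dff.min() == pytest.approx(hc.mean(), abs=1e-12)

    def test_empty_window_errors(self):
        spec = fq.BaselineSpec(
            hc=np.ones(10), hc_time_s=np.linspace(0, 1, 10), test=np.ones(5), hc_window=(60.0, 240.0)
        )
        with pytest.raises(ConfigError):
            fq.baseline_correct(spec)

    @given(
        test=hnp.arrays(
            np.float64,
            st.integers(2, 50),
            elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False),
        ),
        hc_mean=st.floats(-5, 5, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_pure_shift_property(self, test, hc_mean):
        spec = fq.BaselineSpec(
            hc=np.full(10, hc_mean), hc_time_s=np.linspace(0, 1, 10), test=test, hc_window=(0.0, 1.0)
        )
        out = fq.baseline_correct(spec)
        shift = out.dff - test
        np.testing.assert_allclose(shift, shift[0], atol=1e-9)
        assert np.var(out.dff) == pytest.approx(np.var(test), abs=1e-9)


class TestProcessSession:
    def test_provenance_recorded(self, channel_pair):
        trace = fq.process_session(channel_pair)
        assert trace.provenance["reference"] == "fit"
        assert "bleach_fit" in trace.provenance

    def test_unknown_reference_mode(self, channel_pair):
        with pytest.raises(ConfigError):
            fq.process_session(channel_pair, reference="airPLS")

    def test_raw_mode_runs(self, channel_pair):
        trace = fq.process_session(channel_pair, reference="raw")
        assert np.isfinite(trace.dff).all()
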