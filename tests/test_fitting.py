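"""Reconvolution fitting, tau_AvInt, QC and the repetition-rate rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flimkit as fk
from flimkit.errors import AxisMismatchError, ConfigError, UndefinedResultError

from conftest import emg_expected_counts, hist_from_photons


class TestIntensityWeightedLifetime:
    @pytest.mark.parametrize(
        "amps, taus, expected",
        [
            ((1.0,), (4.0,), 4.0),  # single-component identity
            ((0.5, 0.5), (1.0, 3.0), 2.5),  # sum(a tau^2)/sum(a tau) = 5/2
            ((1.0, 0.0), (2.0, 7.0), 2.0),  # zero-amplitude component ignored
        ],
    )
    def test_known_values(self, amps, taus, expected):
        model = fk.FitModel(np.array(amps), np.array(taus))
        assert fk.intensity_weighted_lifetime(model) == pytest.approx(expected)

    def test_all_zero_amplitudes_undefined(self):
        model = fk.FitModel(np.array([0.0, 0.0]), np.array([1.0, 3.0]))
        with pytest.raises(UndefinedResultError):
            fk.intensity_weighted_lifetime(model)

    @given(
        amps=st.lists(st.floats(0.01, 10), min_size=2, max_size=3),
        taus=st.lists(st.floats(0.1, 20), min_size=3, max_size=3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_component_lifetimes(self, amps, taus):
        n = len(amps)
        model = fk.FitModel(np.array(amps), np.array(taus[:n]))
        tau = fk.intensity_weighted_lifetime(model)
        assert min(taus[:n]) - 1e-9 <= tau <= max(taus[:n]) + 1e-9


class TestRecommendRepetition:
    @pytest.mark.parametrize(
        "lifetime, t_repeat, rate",
        [(5.0, 50.0, 20.0), (1.0, 10.0, 100.0), (2.5, 25.0, 40.0)],
    )
    def test_ten_times_rule(self, lifetime, t_repeat, rate):
        assert fk.recommend_repetition(lifetime) == pytest.approx((t_repeat, rate))

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ConfigError):
            fk.recommend_repetition(0.0)


class TestQualityControl:
    def test_exclusion_threshold_is_strict_less_than(self):
        def hist(total):
            counts = np.zeros(100, dtype=int)
            counts[10] = total
            t = (np.arange(100) + 0.5) * 0.5
            return fk.DecayHistogram(t, counts, 50.0)

        assert not fk.qc_filter(hist(9_999))
        assert fk.qc_filter(hist(10_000))
        assert not fk.qc_filter(hist(0))

    def test_component_count_photon_advisory(self):
        assert fk.advisory_min_photons(1) == 100
        assert fk.advisory_min_photons(2) == 10_000
        assert fk.advisory_min_photons(3) == 1_000_000
        with pytest.raises(ConfigError):
            fk.advisory_min_photons(4)

    @pytest.mark.parametrize(
        "period, expected",
        [(50.0, (0.2, 45.0)), (25.0, (0.2, 25.0)), (12.5, (0.2, 12.5))],
    )
    def test_fit_range_per_rate(self, period, expected):
        assert fk.default_fit_range(period) == pytest.approx(expected)


class TestReconvolve:
    def test_delta_irf_gives_pure_exponential_tail(self, acq20):
        """With a one-bin IRF the post-peak bin ratios are exactly
        exp(-dt/tau)."""
        values = np.zeros(acq20.n_bins)
        values[40] = 1.0  # delta at 2.025 ns
        irf = fk.InstrumentResponse(acq20.time_axis(), values, acq20.period_ns)
        model = fk.FitModel(np.array([1.0]), np.array([2.0]))
        out = fk.reconvolve(model, irf, acq20.period_ns)
        tail = out[60:400]  # beyond that the FFT noise floor dominates
        np.testing.assert_allclose(
            tail[1:] / tail[:-1], math.exp(-0.05 / 2.0), rtol=1e-6
        )

    def test_matches_emg_quadrature_oracle(self):
        """Against independent quadrature of the exponentially-modified-
        Gaussian bin integrals (well-resolved 400 ps IRF)."""
        acq = fk.AcquisitionConfig(irf_fwhm_ps=400.0)
        irf = acq.irf()
        model = fk.FitModel(np.array([1.0]), np.array([3.0]))
        out = fk.reconvolve(model, irf, acq.period_ns)
        out = out / out.sum()
        exact = emg_expected_counts([1.0], [3.0], acq)
        sel = exact > exact.max() * 1e-2
        np.testing.assert_allclose(out[sel], exact[sel], rtol=5e-3)

    def test_integer_shift_is_circular_translation(self, acq20, irf20):
        base = fk.FitModel(np.array([1.0]), np.array([3.0]))
        shifted = fk.FitModel(np.array([1.0]), np.array([3.0]), shift_ns=0.25)
        out0 = fk.reconvolve(base, irf20, acq20.period_ns)
        out5 = fk.reconvolve(shifted, irf20, acq20.period_ns)
        np.testing.assert_allclose(out5, np.roll(out0, 5), rtol=1e-6, atol=1e-9)

    def test_axis_mismatch_rejected(self, irf20):
        model = fk.FitModel(np.array([1.0]), np.array([3.0]))
        with pytest.raises(AxisMismatchError):
            fk.reconvolve(model, irf20, 25.0)


class TestFitDecay:
    def test_noise_free_parameters_recovered(self, acq20, irf20):
        """On an expected-count histogram the generating parameters come
        back to at least 4 significant figures."""
        truth = fk.FitModel(
            np.array([1200.0, 400.0]), np.array([2.0, 6.0]), offset=3.0, shift_ns=0.1
        )
        expected = fk.reconvolve(truth, irf20, acq20.period_ns)
        h = fk.DecayHistogram(acq20.time_axis(), expected, acq20.period_ns)
        res = fk.fit_decay(h, irf20, n=2)
        np.testing.assert_allclose(res.model.amplitudes, truth.amplitudes, rtol=1e-4)
        np.testing.assert_allclose(res.model.lifetimes_ns, truth.lifetimes_ns, rtol=1e-4)
        assert res.model.offset == pytest.approx(3.0, rel=1e-3)
        assert res.model.shift_ns == pytest.approx(0.1, abs=1e-4)

    def test_mono_recovery_within_two_percent(self, acq20, irf20):
        from flimkit.probes import constant_probe

        probe = constant_probe("m", 4.0)
        h = hist_from_photons(probe, probe.windows[0], acq20, 100_000, seed=11)
        res = fk.fit_decay(h, irf20, n=1)
        assert res.tau_av_int_ns == pytest.approx(4.0, rel=0.02)
        assert res.converged and not res.outlier

    def test_lifetimes_sorted_ascending(self, acq20, irf20):
        truth = fk.FitModel(np.array([500.0, 1500.0]), np.array([6.0, 2.0]))
        expected = fk.reconvolve(truth.sorted(), irf20, acq20.period_ns)
        h = fk.DecayHistogram(acq20.time_axis(), expected, acq20.period_ns)
        res = fk.fit_decay(h, irf20, n=2)
        assert res.model.lifetimes_ns[0] < res.model.lifetimes_ns[1]

    def test_combined_windows_fit_between_component_lifetimes(self, acq20, irf20):
        """Pooling equal-photon 3 ns and 5 ns windows yields a mean
        lifetime strictly between 3 and 5 ns."""
        from flimkit.probes import ProbeModel, WindowDecay

        w1, w2 = fk.SpectralWindow(500, 600), fk.SpectralWindow(600, 700)
        probe = ProbeModel(
            "two", (w1, w2),
            (WindowDecay((1.0,), (3.0,)), WindowDecay((1.0,), (5.0,))),
            (1.0, 1.0), 700.0,
        )
        h1 = hist_from_photons(probe, w1, acq20, 50_000, seed=12)
        h2 = hist_from_photons(probe, w2, acq20, 50_000, seed=13)
        combined = fk.combine_histograms([h1, h2])
        res = fk.fit_decay(combined, irf20, n=2)
        assert 3.0 < res.tau_av_int_ns < 5.0

    def test_qc_gate_and_override(self, acq20, irf20):
        counts = np.zeros(acq20.n_bins, dtype=int)
        counts[100:200] = 5  # 500 photons, below QC
        h = fk.DecayHistogram(acq20.time_axis(), counts, acq20.period_ns)
        with pytest.raises(ConfigError):
            fk.fit_decay(h, irf20, n=1)
        res = fk.fit_decay(h, irf20, n=1, allow_qc_fail=True)
        assert res is not None

    def test_pathological_data_flagged_not_raised(self, acq20, irf20):
        counts = np.full(acq20.n_bins, 50, dtype=int)  # flat, no decay
        h = fk.DecayHistogram(acq20.time_axis(), counts, acq20.period_ns)
        res = fk.fit_decay(h, irf20, n=1)
        assert res.outlier or not res.converged

    def test_component_count_validated(self, acq20, irf20):
        counts = np.full(acq20.n_bins, 50, dtype=int)
        h = fk.DecayHistogram(acq20.time_axis(), counts, acq20.period_ns)
        with pytest.raises(ConfigError):
            fk.fit_decay(h, irf20, n=4)
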