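"""Phasor transform, calibration, semicircle geometry and maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flimkit as fk
from flimkit.errors import (
    CalibrationError,
    EmptySelectionError,
    UndefinedResultError,
)
from flimkit.probes import constant_probe

from conftest import hist_from_photons


def wrapped_mono_hist(tau, acq, scale=1.0):
    """Noise-free binned wrapped monoexponential (no IRF)."""
    t = acq.time_axis()
    dens = np.exp(-t / tau) / (1.0 - math.exp(-acq.period_ns / tau))
    return fk.DecayHistogram(t, scale * dens, acq.period_ns)


class TestPhasorTransform:
    def test_delta_in_first_bin_is_near_origin_phase(self, acq20):
        counts = np.zeros(acq20.n_bins)
        counts[0] = 100.0
        h = fk.DecayHistogram(acq20.time_axis(), counts, acq20.period_ns)
        p = fk.phasor_transform(h)
        assert p.g == pytest.approx(1.0, abs=1e-4)
        assert p.s == pytest.approx(0.0, abs=1e-2)

    def test_uniform_counts_map_to_origin(self, acq20):
        h = fk.DecayHistogram(
            acq20.time_axis(), np.full(acq20.n_bins, 7.0), acq20.period_ns
        )
        p = fk.phasor_transform(h)
        assert abs(p.g) < 1e-9 and abs(p.s) < 1e-9

    def test_closed_form_at_omega_tau_one(self, acq20):
        """g = 1/(1+(wt)^2), s = wt/(1+(wt)^2) -> (0.5, 0.5) at wt = 1."""
        tau = acq20.period_ns / (2.0 * math.pi)
        p = fk.phasor_transform(wrapped_mono_hist(tau, acq20))
        assert p.g == pytest.approx(0.5, abs=1e-3)
        assert p.s == pytest.approx(0.5, abs=1e-3)

    def test_zero_counts_undefined(self, acq20):
        h = fk.DecayHistogram(
            acq20.time_axis(), np.zeros(acq20.n_bins), acq20.period_ns
        )
        with pytest.raises(UndefinedResultError):
            fk.phasor_transform(h)


class TestCalibration:
    def test_identity_reference(self, acq20):
        p = fk.PhasorPoint(0.3, 0.4, omega=0.1)
        out = fk.calibrate(p, fk.PhasorPoint(1.0, 0.0))
        assert (out.g, out.s) == pytest.approx((0.3, 0.4))

    def test_irf_calibrates_to_unity(self, acq20, irf20):
        ref = fk.irf_phasor(irf20)
        out = fk.calibrate(ref, ref)
        assert (out.g, out.s) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_zero_modulus_reference_rejected(self):
        with pytest.raises(CalibrationError):
            fk.calibrate(fk.PhasorPoint(0.5, 0.5), fk.PhasorPoint(0.0, 0.0))

    def test_monoexponential_lands_on_semicircle(self, acq20, irf20):
        probe = constant_probe("m", 4.0)
        h = hist_from_photons(probe, probe.windows[0], acq20, 200_000, seed=31)
        p = fk.calibrate(fk.phasor_transform(h), fk.irf_phasor(irf20))
        assert abs(fk.semicircle_distance(p)) < 1e-2


class TestSemicircle:
    def test_on_circle_point(self):
        assert fk.semicircle_distance(fk.PhasorPoint(0.5, 0.5)) == pytest.approx(0.0)

    def test_interior_point_negative(self):
        assert fk.semicircle_distance(fk.PhasorPoint(0.5, 0.25)) == pytest.approx(-0.25)

    def test_mixtures_strictly_inside(self, acq20):
        h1 = wrapped_mono_hist(1.5, acq20, scale=1000)
        h2 = wrapped_mono_hist(6.0, acq20, scale=1000)
        mix = fk.DecayHistogram(
            acq20.time_axis(), h1.counts + h2.counts, acq20.period_ns
        )
        assert fk.semicircle_distance(fk.phasor_transform(mix)) < -1e-3


class TestPhasorLifetimes:
    def test_closed_form_at_omega_tau_one(self):
        omega = 0.5
        tau_phi, tau_m = fk.phasor_lifetimes(fk.PhasorPoint(0.5, 0.5, omega=omega))
        assert tau_phi == pytest.approx(1.0 / omega)
        assert tau_m == pytest.approx(1.0 / omega)

    def test_zero_lifetime_point(self):
        tau_phi, tau_m = fk.phasor_lifetimes(fk.PhasorPoint(1.0, 0.0, omega=0.5))
        assert tau_phi == 0.0 and tau_m == 0.0

    @given(frac=st.floats(0.05, 0.95))
    @settings(max_examples=50, derandomize=True)
    def test_interior_mixture_phase_below_modulation(self, frac):
        """tau_phi < tau_m anywhere strictly inside the semicircle
        (two-component mixtures scanned over mixing fraction)."""
        omega = 1.0

        def on_circle(tau):
            wt = omega * tau
            return np.array([1, wt]) / (1 + wt * wt)

        p = frac * on_circle(1.0) + (1 - frac) * on_circle(6.0)
        tau_phi, tau_m = fk.phasor_lifetimes(
            fk.PhasorPoint(p[0], p[1], omega=omega)
        )
        assert tau_phi < tau_m

    def test_modulus_above_one_undefined(self):
        with pytest.raises(UndefinedResultError):
            fk.phasor_lifetimes(fk.PhasorPoint(1.0, 0.5, omega=0.5))


class TestLinearity:
    def test_mixture_lies_on_chord(self, acq20):
        """Photon-weighted mixtures of two decays stay on the segment
        joining their phasors (noise-free, < 1e-6)."""
        h1 = wrapped_mono_hist(1.5, acq20, scale=1e6)
        h2 = wrapped_mono_hist(6.0, acq20, scale=1e6)
        p1, p2 = fk.phasor_transform(h1), fk.phasor_transform(h2)
        a = np.array([p1.g, p1.s])
        b = np.array([p2.g, p2.s])
        u = (b - a) / np.linalg.norm(b - a)
        normal = np.array([-u[1], u[0]])
        for frac in np.linspace(0, 1, 21):
            mix = fk.DecayHistogram(
                acq20.time_axis(),
                frac * h1.counts + (1 - frac) * h2.counts,
                acq20.period_ns,
            )
            p = fk.phasor_transform(mix)
            deviation = abs(np.dot(np.array([p.g, p.s]) - a, normal))
            assert deviation < 1e-6

    def test_discretization_error_shrinks_with_bin_width(self):
        """Phasor of a binned exponential approaches the continuous
        closed form as bins shrink."""
        tau, rate = 3.0, 20.0

        def error(bin_width):
            acq = fk.AcquisitionConfig(rep_rate_mhz=rate, bin_width_ns=bin_width)
            p = fk.phasor_transform(wrapped_mono_hist(tau, acq))
            wt = p.omega * tau
            return math.hypot(p.g - 1 / (1 + wt**2), p.s - wt / (1 + wt**2))

        assert error(0.05) < 0.7 * error(0.1)


@pytest.fixture(scope="module")
def mono_image():
    acq = fk.AcquisitionConfig(seed=2)
    probe = constant_probe("m", 4.0)
    labels = np.ones((12, 12), dtype=np.int8)
    pm = fk.PhaseMap(labels, {1: probe}, photons_per_pixel=2500)
    return fk.simulate_flim_image(pm, acq, seed=41), acq


class TestPhasorMap:
    def test_homogeneous_cloud_matches_pooled_decay(self, mono_image):
        img, acq = mono_image
        channel = next(iter(img.channels))
        pmap = fk.phasor_map(img, channel, smooth=None)
        pooled = fk.phasor_transform(fk.pool_whole_image(img, channel))
        centroid = pmap.cloud_centroid()
        assert centroid.g == pytest.approx(pooled.g, abs=5e-3)
        assert centroid.s == pytest.approx(pooled.s, abs=5e-3)

    def test_smoothing_reduces_spread_keeps_centroid(self, mono_image):
        img, acq = mono_image
        channel = next(iter(img.channels))
        raw = fk.phasor_map(img, channel, smooth=None)
        smoothed = fk.phasor_map(img, channel, smooth="median")
        spread = lambda m: np.nanstd(m.g) + np.nanstd(m.s)  # noqa: E731
        assert spread(smoothed) < spread(raw)
        # median filtering is slightly nonlinear on sparse per-bin
        # counts, so the centroid is only approximately preserved
        assert smoothed.cloud_centroid().g == pytest.approx(
            raw.cloud_centroid().g, abs=0.05
        )

    def test_roi_average_recovers_mono_lifetime(self, mono_image):
        img, acq = mono_image
        channel = next(iter(img.channels))
        pmap = fk.phasor_map(img, channel, irf=acq.irf(), smooth=None)
        c = pmap.cloud_centroid()
        tau = fk.roi_average_lifetime(pmap, fk.PhasorROI(c.g, c.s, 0.05))
        assert tau == pytest.approx(4.0, rel=0.02)

    def test_empty_roi_rejected(self, mono_image):
        img, acq = mono_image
        pmap = fk.phasor_map(img, next(iter(img.channels)), smooth=None)
        with pytest.raises(EmptySelectionError):
            fk.roi_average_lifetime(pmap, fk.PhasorROI(-5.0, -5.0, 0.01))

    def test_two_phase_image_separates_into_two_clouds(self):
        """Lo and Ld pixels form distinct phasor clouds (centroid gap
        larger than the within-cloud spread) and the Lo cloud reads out
        the longer lifetime."""
        acq = fk.AcquisitionConfig(seed=3)
        pm = fk.two_phase_disk(shape=(20, 20), photons_per_pixel=3000)
        img = fk.simulate_flim_image(pm, acq, seed=42)
        pmap = fk.phasor_map(img, "500-600nm", irf=acq.irf(), smooth=None)
        ld, lo = pm.labels == 1, pm.labels == 2
        gap = math.hypot(
            np.nanmean(pmap.g[lo]) - np.nanmean(pmap.g[ld]),
            np.nanmean(pmap.s[lo]) - np.nanmean(pmap.s[ld]),
        )
        spread = max(
            np.nanstd(pmap.g[ld]) + np.nanstd(pmap.s[ld]),
            np.nanstd(pmap.g[lo]) + np.nanstd(pmap.s[lo]),
        )
        assert gap > 3.0 * spread
        tau_ld = fk.roi_average_lifetime(
            pmap, fk.PhasorROI(np.nanmean(pmap.g[ld]), np.nanmean(pmap.s[ld]), 0.05)
        )
        tau_lo = fk.roi_average_lifetime(
            pmap, fk.PhasorROI(np.nanmean(pmap.g[lo]), np.nanmean(pmap.s[lo]), 0.05)
        )
        assert tau_lo > tau_ld
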