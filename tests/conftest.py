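"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import erfc

import flimkit as fk
from flimkit.probes import ProbeModel, WindowDecay
from flimkit.simulate import _bin_times, sample_photons


@pytest.fixture(scope="session")
def acq20() -> fk.AcquisitionConfig:
    """Default acquisition: 20 MHz, 0.05 ns bins, 120 ps IRF at 2 ns."""
    return fk.AcquisitionConfig(seed=1)


@pytest.fixture(scope="session")
def irf20(acq20) -> fk.InstrumentResponse:
    return acq20.irf()


@pytest.fixture(scope="session")
def biexp5_probe() -> ProbeModel:
    """Single-window biexponential with tau_AvInt exactly 5 ns."""
    w = fk.SpectralWindow(500.0, 700.0)
    return ProbeModel("biexp5", (w,), (WindowDecay((0.7, 0.3), (2.0, 7.0)),), (1.0,), 500.0)


def hist_from_photons(
    probe: ProbeModel,
    window: fk.SpectralWindow,
    acq: fk.AcquisitionConfig,
    n_photons: int,
    seed: int,
) -> fk.DecayHistogram:
    """Exact-N unbiased simulation helper (no per-pulse artifacts)."""
    rng = np.random.default_rng(seed)
    times = sample_photons(probe, window, acq, n_photons, rng)
    return fk.DecayHistogram(
        acq.time_axis(), _bin_times(times, acq), acq.period_ns, window=window
    )


def emg_expected_counts(
    amplitudes,
    lifetimes_ns,
    acq: fk.AcquisitionConfig,
    n_photons: float = 1.0,
    wraps: int = 40,
    fine: int = 32,
) -> np.ndarray:
    """Independent oracle for expected TCSPC bin contents.

    Bin integrals of the continuous Gaussian-IRF-convolved wrapped
    multi-exponential, via the closed-form exponentially-modified
    Gaussian summed over excitation periods and midpoint quadrature on
    a ``fine``-times-refined grid.  Shares no code with ``reconvolve``.
    """
    T, n = acq.period_ns, acq.n_bins
    mu, sig = acq.irf_center_ns, acq.irf_sigma_ns
    edges = np.linspace(0.0, T, n * fine + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    dens = np.zeros_like(mid)
    for a, tau in zip(amplitudes, lifetimes_ns):
        for k in range(-2, wraps):
            x = mid + k * T
            # a is the pre-exponential amplitude: a*tau times the
            # unit-area exponentially-modified Gaussian
            dens += (
                0.5
                * a
                * np.exp(0.5 * (sig / tau) ** 2 - (x - mu) / tau)
                * erfc((sig / tau - (x - mu) / sig) / np.sqrt(2.0))
            )
    per_bin = dens.reshape(n, fine).mean(axis=1)
    return per_bin * n_photons / per_bin.sum()
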