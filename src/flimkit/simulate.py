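"""Synthetic TCSPC decay, spectral-series and FLIM-image generation.

The generator draws photon arrival times as

    t = t_IRF + t_decay  (mod T),

with t_IRF Gaussian (the instrument response), t_decay exponential with
a component lifetime picked by its steady-state photon share, and T the
repetition period.  Taking the result modulo T produces the wraparound
of incomplete decays into later excitation periods.  Two detector
artifacts are modeled per pulse: classical pile-up (dead time spanning
the full period, so only the earliest photon of a pulse is recorded)
and the single-photon filter that discards pulses in which more than
one photon arrived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .histogram import (
    FWHM_TO_SIGMA,
    DecayHistogram,
    SpectralWindow,
    gaussian_irf,
    time_axis,
)
from .imaging import FLIMImage
from .probes import ProbeModel

__all__ = [
    "AcquisitionConfig",
    "ground_truth_decay",
    "simulate_decay",
    "simulate_spectral_series",
    "PhaseMap",
    "two_phase_disk",
    "simulate_flim_image",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings of a simulated TCSPC measurement.

    The repetition period is 1000/rate ns and must be an integer number
    of time bins.  ``mean_photons_per_pulse`` is the detected count rate
    mu (the instrument guideline is to stay at or below 0.5).
    """

    rep_rate_mhz: float = 20.0
    bin_width_ns: float = 0.05
    irf_center_ns: float = 2.0
    irf_fwhm_ps: float = 120.0
    mean_photons_per_pulse: float = 0.1
    pileup: bool = False
    single_photon_filter: bool = False
    efficiency: float | Mapping[float, float] = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rep_rate_mhz <= 0:
            raise ConfigError("repetition rate must be positive")
        if self.mean_photons_per_pulse <= 0:
            raise ConfigError("mean photons per pulse must be positive")
        if self.bin_width_ns <= 0:
            raise ConfigError("bin width must be positive")
        ratio = self.period_ns / self.bin_width_ns
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"period {self.period_ns} ns is not an integer number of "
                f"{self.bin_width_ns} ns bins"
            )
        effs = (
            self.efficiency.values()
            if isinstance(self.efficiency, Mapping)
            else [self.efficiency]
        )
        if any(not 0 < e <= 1 for e in effs):
            raise ConfigError("detector efficiency factors must lie in (0, 1]")

    @property
    def period_ns(self) -> float:
        return 1000.0 / self.rep_rate_mhz

    @property
    def n_bins(self) -> int:
        return int(round(self.period_ns / self.bin_width_ns))

    @property
    def irf_sigma_ns(self) -> float:
        return self.irf_fwhm_ps * 1e-3 * FWHM_TO_SIGMA

    def efficiency_for(self, window: SpectralWindow) -> float:
        if isinstance(self.efficiency, Mapping):
            return float(self.efficiency.get(window.center_nm, 1.0))
        return float(self.efficiency)

    def time_axis(self) -> np.ndarray:
        return time_axis(self.n_bins, self.bin_width_ns)

    def irf(self):
        return gaussian_irf(
            self.n_bins, self.bin_width_ns, self.irf_center_ns, self.irf_fwhm_ps
        )


def ground_truth_decay(
    probe: ProbeModel,
    window: SpectralWindow,
    t: np.ndarray | float,
    period_ns: float,
) -> np.ndarray | float:
    """Wraparound-summed decay density on [0, period).

    Summing the multi-exponential over all previous excitation periods
    gives, per component, the geometric-series closed form
    a * exp(-t/tau) / (1 - exp(-T/tau)) (unnormalized density).
    """
    decay = probe.decay_for(window)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr >= period_ns):
        raise ConfigError("t must satisfy 0 <= t < period")
    out = np.zeros_like(t_arr)
    for a, tau in zip(decay.amplitudes, decay.lifetimes_ns):
        out = out + a * np.exp(-t_arr / tau) / (1.0 - math.exp(-period_ns / tau))
    return out if out.shape else float(out)


def _draw_arrival_times(
    photon_fractions: np.ndarray,
    lifetimes_ns: np.ndarray,
    n: int,
    acq: AcquisitionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Arrival times (mod period) of ``n`` photons: IRF jitter plus an
    exponential delay from a component drawn by photon share."""
    comp = rng.choice(photon_fractions.size, size=n, p=photon_fractions)
    delay = rng.exponential(lifetimes_ns[comp])
    jitter = rng.normal(acq.irf_center_ns, acq.irf_sigma_ns, size=n)
    return np.mod(delay + jitter, acq.period_ns)


def _bin_times(times: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    idx = np.floor(times / acq.bin_width_ns).astype(np.int64)
    np.clip(idx, 0, acq.n_bins - 1, out=idx)
    return np.bincount(idx, minlength=acq.n_bins).astype(np.int64)


def _resolve_rng(
    acq: AcquisitionConfig, rng: np.random.Generator | int | None
) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = acq.seed
    return np.random.default_rng(rng)


def sample_photons(
    probe: ProbeModel,
    window: SpectralWindow,
    acq: AcquisitionConfig,
    n_photons: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw exactly ``n_photons`` unbiased arrival times (no per-pulse
    artifacts): the IRF-convolved wrapped decay distribution."""
    decay = probe.decay_for(window)
    return _draw_arrival_times(
        decay.photon_fractions, np.asarray(decay.lifetimes_ns), n_photons, acq, rng
    )


def simulate_decay(
    probe: ProbeModel,
    window: SpectralWindow,
    acq: AcquisitionConfig,
    n_pulses: int,
    rng: np.random.Generator | int | None = None,
) -> DecayHistogram:
    """Pulse-train TCSPC simulation of one spectral window.

    Per pulse the number of arriving photons is Poisson with mean
    mu * efficiency.  With ``single_photon_filter`` only pulses carrying
    exactly one photon are retained (the high-speed counter rejects
    multi-photon pulses); otherwise with ``pileup`` only the earliest
    photon of each pulse is recorded (full-period dead time).
    """
    if n_pulses < 1:
        raise ConfigError("n_pulses must be >= 1")
    rng = _resolve_rng(acq, rng)
    decay = probe.decay_for(window)
    mu_eff = acq.mean_photons_per_pulse * acq.efficiency_for(window)
    per_pulse = rng.poisson(mu_eff, size=n_pulses)
    total = int(per_pulse.sum())
    times = _draw_arrival_times(
        decay.photon_fractions, np.asarray(decay.lifetimes_ns), total, acq, rng
    )
    if acq.single_photon_filter:
        keep_pulse = per_pulse == 1
        times = times[np.repeat(keep_pulse, per_pulse)]
    elif acq.pileup and total:
        pulse_ids = np.repeat(np.arange(n_pulses), per_pulse)
        order = np.lexsort((times, pulse_ids))
        first = np.ones(order.size, dtype=bool)
        first[1:] = pulse_ids[order][1:] != pulse_ids[order][:-1]
        times = times[order][first]
    counts = _bin_times(times, acq)
    return DecayHistogram(
        acq.time_axis(),
        counts,
        acq.period_ns,
        window=window,
        provenance={
            "simulator": "pulse_train",
            "n_pulses": n_pulses,
            "mu": acq.mean_photons_per_pulse,
            "pileup": acq.pileup,
            "single_photon_filter": acq.single_photon_filter,
            "probe": probe.name,
            "seed": acq.seed,
        },
    )


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by largest remainder: exact
    conservation of the grand total."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    base = np.floor(exact).astype(np.int64)
    short = total - int(base.sum())
    if short:
        base[np.argsort(exact - base)[::-1][:short]] += 1
    return base


def simulate_spectral_series(
    probe: ProbeModel,
    acq: AcquisitionConfig,
    total_photons: int,
    rng: np.random.Generator | int | None = None,
) -> list[DecayHistogram]:
    """One histogram per probe window; the grand photon total is split
    across windows by emission-spectrum brightness x detector efficiency
    (largest-remainder apportionment, so the totals sum exactly)."""
    if total_photons < 0:
        raise ConfigError("total_photons must be non-negative")
    rng = _resolve_rng(acq, rng)
    weights = np.array(
        [b * acq.efficiency_for(w) for w, b in zip(probe.windows, probe.brightness)]
    )
    counts = _apportion(weights, total_photons)
    out = []
    for window, n in zip(probe.windows, counts):
        times = sample_photons(probe, window, acq, int(n), rng)
        out.append(
            DecayHistogram(
                acq.time_axis(),
                _bin_times(times, acq),
                acq.period_ns,
                window=window,
                provenance={"simulator": "spectral_series", "probe": probe.name,
                            "seed": acq.seed},
            )
        )
    return out


@dataclass
class PhaseMap:
    """Label image of a phase-separated vesicle field.

    Labels: 0 = background, 1 = liquid-disordered (Ld), 2 = liquid-ordered
    (Lo).  ``probes`` maps each non-zero label to its ProbeModel.
    """

    labels: np.ndarray
    probes: Mapping[int, ProbeModel]
    photons_per_pixel: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConfigError("label image must be 2-D")
        present = set(np.unique(self.labels).tolist())
        if not present <= {0, 1, 2}:
            raise ConfigError(f"labels restricted to {{0,1,2}}, got {sorted(present)}")
        if self.photons_per_pixel <= 0:
            raise ConfigError("photons per pixel must be positive")
        missing = [l for l in sorted(present - {0}) if l not in self.probes]
        if missing:
            raise ConfigError(f"no probe model for labels {missing}")


def two_phase_disk(
    shape: tuple[int, int] = (32, 32),
    radius: float | None = None,
    probes: Mapping[int, ProbeModel] | None = None,
    photons_per_pixel: float = 500.0,
) -> PhaseMap:
    """A disk-shaped vesicle cross-section: upper half Ld (1), lower half
    Lo (2), background 0 — the simplest phase-separated geometry."""
    from .probes import get_probe

    ny, nx = shape
    radius = radius if radius is not None else 0.4 * min(shape)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    labels = np.zeros(shape, dtype=np.int8)
    labels[inside & (yy <= cy)] = 1
    labels[inside & (yy > cy)] = 2
    probes = probes or {1: get_probe("flipper_ld"), 2: get_probe("flipper_lo")}
    return PhaseMap(labels, probes, photons_per_pixel)


DEFAULT_CHANNELS: tuple[tuple[float, float], ...] = ((500.0, 600.0), (600.0, 700.0))


def _channel_label(span: tuple[float, float]) -> str:
    return f"{span[0]:g}-{span[1]:g}nm"


def simulate_flim_image(
    phase_map: PhaseMap,
    acq: AcquisitionConfig,
    channels: Sequence[tuple[float, float]] = DEFAULT_CHANNELS,
    seed: int | None = None,
    dark_counts_per_pixel: float = 0.0,
) -> FLIMImage:
    """Per-pixel decay histograms in wide emission channels (default
    green 500-600 nm and red 600-700 nm).

    Each (pixel, channel) uses an independent substream seeded by
    (seed, y, x, channel index), so results are bit-identical for a
    given seed regardless of evaluation order.  A pixel's expected
    photon count is photons_per_pixel scaled by the fraction of the
    probe's brightness falling in the channel; background pixels
    receive only Poisson dark counts (default 0).
    """
    if seed is None:
        seed = acq.seed if acq.seed is not None else 0
    ny, nx = phase_map.labels.shape
    n_bins = acq.n_bins
    t = acq.time_axis()
    mixtures: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    fractions: dict[tuple[int, int], float] = {}
    for label, probe in phase_map.probes.items():
        total_b = sum(probe.brightness)
        for ci, (lo, hi) in enumerate(channels):
            mixtures[(label, ci)] = probe.channel_mixture(lo, hi)
            fractions[(label, ci)] = probe.channel_brightness(lo, hi) / total_b
    data = {
        _channel_label(span): np.zeros((ny, nx, n_bins), dtype=np.uint32)
        for span in channels
    }
    for y in range(ny):
        for x in range(nx):
            label = int(phase_map.labels[y, x])
            for ci, span in enumerate(channels):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), y, x, ci])
                )
                if label == 0:
                    if dark_counts_per_pixel > 0:
                        n = rng.poisson(dark_counts_per_pixel)
                        if n:
                            times = rng.uniform(0, acq.period_ns, size=n)
                            data[_channel_label(span)][y, x] = _bin_times(times, acq)
                    continue
                mean = phase_map.photons_per_pixel * fractions[(label, ci)]
                n = rng.poisson(mean)
                if not n:
                    continue
                probs, taus = mixtures[(label, ci)]
                times = _draw_arrival_times(probs, taus, n, acq, rng)
                data[_channel_label(span)][y, x] = _bin_times(times, acq)
    return FLIMImage(
        channels=data,
        time_ns=t,
        period_ns=acq.period_ns,
        channel_spans={_channel_label(span): span for span in channels},
        meta={
            "seed": int(seed),
            "photons_per_pixel": phase_map.photons_per_pixel,
            "rep_rate_mhz": acq.rep_rate_mhz,
            "labels": phase_map.labels.copy(),
        },
    )
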