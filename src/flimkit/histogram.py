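"""Core TCSPC containers: spectral windows, decay histograms and IRFs.

A TCSPC (time-correlated single photon counting) measurement is a
histogram of photon arrival times relative to the excitation pulse,
binned on a uniform grid covering one repetition period.  Emission is
split into spectral windows (by default a 20 nm ladder tiling
500-700 nm), and each window carries its own decay histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import AxisMismatchError, ConfigError

__all__ = [
    "SpectralWindow",
    "default_window_ladder",
    "DecayHistogram",
    "InstrumentResponse",
    "gaussian_irf",
    "combine_histograms",
    "time_axis",
]


@dataclass(frozen=True, order=True)
class SpectralWindow:
    """Half-open emission window [lower_nm, upper_nm) labeled by its center."""

    lower_nm: float
    upper_nm: float

    def __post_init__(self) -> None:
        if not self.upper_nm > self.lower_nm:
            raise ConfigError(
                f"window upper edge {self.upper_nm} must exceed lower edge {self.lower_nm}"
            )

    @property
    def center_nm(self) -> float:
        return 0.5 * (self.lower_nm + self.upper_nm)

    @property
    def width_nm(self) -> float:
        return self.upper_nm - self.lower_nm

    def contains(self, wavelength_nm: float) -> bool:
        return self.lower_nm <= wavelength_nm < self.upper_nm

    @property
    def label(self) -> str:
        return f"{self.center_nm:g}nm"


def default_window_ladder(
    lower_nm: float = 500.0, upper_nm: float = 700.0, step_nm: float = 20.0
) -> tuple[SpectralWindow, ...]:
    """The default detection ladder: 20 nm windows tiling 500-700 nm."""
    edges = np.arange(lower_nm, upper_nm + 0.5 * step_nm, step_nm)
    return tuple(
        SpectralWindow(float(lo), float(hi)) for lo, hi in zip(edges[:-1], edges[1:])
    )


def time_axis(n_bins: int, bin_width_ns: float) -> np.ndarray:
    """Bin centers for a uniform grid of left-closed bins starting at t=0."""
    return (np.arange(n_bins) + 0.5) * bin_width_ns


def _check_uniform(time_ns: np.ndarray) -> float:
    if time_ns.ndim != 1 or time_ns.size < 2:
        raise ConfigError("time axis must be 1-D with at least two bins")
    dt = np.diff(time_ns)
    width = float(dt[0])
    if not np.allclose(dt, width, rtol=1e-6, atol=1e-9):
        raise ConfigError("time bins must be uniform")
    return width


@dataclass
class DecayHistogram:
    """Photon counts per time bin for one spectral window / ROI.

    ``time_ns`` holds bin centers; bins are left-closed with the time
    origin at pulse emission.  ``counts`` are non-negative (integers for
    measured/simulated data; floats are allowed so that noise-free
    expected-count curves can flow through the same fitting path).
    """

    time_ns: np.ndarray
    counts: np.ndarray
    period_ns: float
    window: SpectralWindow | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.time_ns.shape:
            raise AxisMismatchError("counts and time axis must have the same length")
        if np.any(self.counts < 0):
            raise ConfigError("counts must be non-negative")
        _check_uniform(self.time_ns)
        if self.time_ns[-1] >= self.period_ns:
            raise ConfigError(
                f"max bin center {self.time_ns[-1]:.4f} ns must lie below the "
                f"repetition period {self.period_ns:.4f} ns"
            )

    @property
    def bin_width_ns(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])

    @property
    def n_bins(self) -> int:
        return int(self.time_ns.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def same_axis(self, other: "DecayHistogram | InstrumentResponse") -> bool:
        return (
            self.time_ns.shape == other.time_ns.shape
            and np.allclose(self.time_ns, other.time_ns)
            and math.isclose(self.period_ns, getattr(other, "period_ns", self.period_ns))
        )

    def copy(self) -> "DecayHistogram":
        return replace(
            self,
            time_ns=self.time_ns.copy(),
            counts=self.counts.copy(),
            provenance=dict(self.provenance),
        )


@dataclass
class InstrumentResponse:
    """IRF histogram on the same time axis as the decays, unit sum."""

    time_ns: np.ndarray
    values: np.ndarray
    period_ns: float

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.time_ns.shape:
            raise AxisMismatchError("IRF values and time axis must have the same length")
        if np.any(self.values < 0):
            raise ConfigError("IRF values must be non-negative")
        total = self.values.sum()
        if total <= 0:
            raise ConfigError("IRF must contain signal")
        self.values = self.values / total
        _check_uniform(self.time_ns)


FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def gaussian_irf(
    n_bins: int,
    bin_width_ns: float,
    center_ns: float = 2.0,
    fwhm_ps: float = 120.0,
) -> InstrumentResponse:
    """Gaussian IRF evaluated at bin centers (default FWHM 120 ps).

    The center sits at 2 ns by default so decays retain a pre-pulse
    baseline region, which fitting uses to initialize the offset.
    """
    from scipy.special import ndtr

    t = time_axis(n_bins, bin_width_ns)
    sigma = fwhm_ps * 1e-3 * FWHM_TO_SIGMA
    edges = np.arange(n_bins + 1) * bin_width_ns
    # bin-integrated profile (what a measured IRF histogram records)
    values = np.diff(ndtr((edges - center_ns) / sigma))
    return InstrumentResponse(t, values, period_ns=n_bins * bin_width_ns)


def combine_histograms(hists: Sequence[DecayHistogram]) -> DecayHistogram:
    """Bin-wise sum of decays recorded in different windows.

    Pooling detection windows widens the effective emission window; the
    combined histogram's window label becomes the union span.
    """
    if not hists:
        raise ConfigError("need at least one histogram to combine")
    first = hists[0]
    counts = np.zeros_like(np.asarray(first.counts, dtype=float))
    lowers, uppers = [], []
    for h in hists:
        if not first.same_axis(h):
            raise AxisMismatchError("histograms must share time axis and period")
        counts = counts + h.counts
        if h.window is not None:
            lowers.append(h.window.lower_nm)
            uppers.append(h.window.upper_nm)
    window = SpectralWindow(min(lowers), max(uppers)) if lowers else None
    if np.all(counts == np.round(counts)):
        counts = counts.astype(np.int64)
    return DecayHistogram(
        first.time_ns.copy(),
        counts,
        first.period_ns,
        window=window,
        provenance={"combined_from": [h.provenance for h in hists]},
    )
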