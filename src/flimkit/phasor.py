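"""Fit-free phasor analysis of decays and FLIM images.

A decay histogram c(t) maps to the first-harmonic Fourier coordinates

    g = sum c(t) cos(n w0 t) / sum c(t),
    s = sum c(t) sin(n w0 t) / sum c(t),        w0 = 2 pi / T.

Monoexponential decays lie on the universal semicircle (radius 0.5
centered at (0.5, 0)); mixtures lie inside it, on the chord joining
their components (the transform is linear in photon weight).  Dividing
by the IRF's phasor calibrates out the instrument delay and width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    CalibrationError,
    ConfigError,
    EmptySelectionError,
    UndefinedResultError,
)
from .histogram import DecayHistogram, InstrumentResponse
from .imaging import FLIMImage

__all__ = [
    "PhasorPoint",
    "PhasorROI",
    "PhasorMap",
    "phasor_transform",
    "irf_phasor",
    "calibrate",
    "semicircle_distance",
    "phasor_lifetimes",
    "phasor_map",
    "roi_average_lifetime",
]


@dataclass(frozen=True)
class PhasorPoint:
    """(g, s) coordinates of one decay at a given harmonic."""

    g: float
    s: float
    harmonic: int = 1
    omega: float = 0.0  # rad/ns
    photons: float = 0.0

    @property
    def modulus(self) -> float:
        return math.hypot(self.g, self.s)

    @property
    def phase(self) -> float:
        return math.atan2(self.s, self.g)


@dataclass(frozen=True)
class PhasorROI:
    """Circular selection in phasor (g, s) units (default radius 0.05)."""

    center_g: float
    center_s: float
    radius: float = 0.05

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigError("ROI radius must be positive")

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        return (g - self.center_g) ** 2 + (s - self.center_s) ** 2 <= self.radius**2


def _fourier_gs(
    counts: np.ndarray, time_ns: np.ndarray, period_ns: float, harmonic: int
) -> tuple[float, float, float]:
    total = float(np.sum(counts))
    if total <= 0:
        raise UndefinedResultError("phasor transform undefined for zero counts")
    omega = harmonic * 2.0 * math.pi / period_ns
    g = float(np.sum(counts * np.cos(omega * time_ns)) / total)
    s = float(np.sum(counts * np.sin(omega * time_ns)) / total)
    return g, s, omega


def phasor_transform(hist: DecayHistogram, harmonic: int = 1) -> PhasorPoint:
    """Phasor coordinates of one decay (discrete Fourier sums evaluated
    at bin centers)."""
    if harmonic < 1:
        raise ConfigError("harmonic must be >= 1")
    g, s, omega = _fourier_gs(
        np.asarray(hist.counts, dtype=float), hist.time_ns, hist.period_ns, harmonic
    )
    return PhasorPoint(g, s, harmonic, omega, photons=hist.total)


def irf_phasor(
    irf: InstrumentResponse, period_ns: float | None = None, harmonic: int = 1
) -> PhasorPoint:
    """Phasor of the IRF itself, the calibration reference."""
    period = period_ns if period_ns is not None else irf.period_ns
    g, s, omega = _fourier_gs(irf.values, irf.time_ns, period, harmonic)
    return PhasorPoint(g, s, harmonic, omega, photons=1.0)


def calibrate(sample: PhasorPoint, irf_point: PhasorPoint) -> PhasorPoint:
    """Divide out the IRF contribution (complex division), so that a
    monoexponential sample lands on the universal semicircle."""
    if irf_point.modulus <= 0:
        raise CalibrationError("cannot calibrate with a zero-modulus IRF phasor")
    z = complex(sample.g, sample.s) / complex(irf_point.g, irf_point.s)
    return PhasorPoint(z.real, z.imag, sample.harmonic, sample.omega, sample.photons)


def semicircle_distance(p: PhasorPoint) -> float:
    """Signed distance to the universal semicircle (negative inside)."""
    return math.hypot(p.g - 0.5, p.s) - 0.5


def phasor_lifetimes(p: PhasorPoint) -> tuple[float, float]:
    """Phase and modulation lifetimes (ns) of a calibrated point:

        tau_phi = tan(phase)/omega,   tau_m = sqrt(1/(g^2+s^2) - 1)/omega.

    They coincide for monoexponential decays and split (tau_phi <
    tau_m) for mixtures.
    """
    if p.omega <= 0:
        raise ConfigError("phasor point lacks an angular frequency")
    if p.g <= 0:
        raise UndefinedResultError("phase lifetime undefined for g <= 0")
    tau_phi = (p.s / p.g) / p.omega
    m2 = p.g**2 + p.s**2
    if m2 <= 0 or m2 > 1.0 + 1e-9:
        raise UndefinedResultError(
            f"modulation lifetime undefined for modulus^2 = {m2:.6f}"
        )
    tau_m = math.sqrt(max(1.0 / m2 - 1.0, 0.0)) / p.omega
    return tau_phi, tau_m


@dataclass
class PhasorMap:
    """Per-pixel phasor coordinates of one image channel; empty pixels
    are NaN and excluded downstream."""

    g: np.ndarray
    s: np.ndarray
    counts: np.ndarray
    harmonic: int
    omega: float
    channel: str = ""
    smoothed: bool = False

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.g) & np.isfinite(self.s)

    def cloud_centroid(self, weight_by_photons: bool = True) -> PhasorPoint:
        """Photon-weighted centroid of all valid pixels."""
        m = self.valid
        if not m.any():
            raise EmptySelectionError("phasor map has no valid pixels")
        w = self.counts[m] if weight_by_photons else np.ones(m.sum())
        return PhasorPoint(
            float(np.average(self.g[m], weights=w)),
            float(np.average(self.s[m], weights=w)),
            self.harmonic,
            self.omega,
            photons=float(self.counts[m].sum()),
        )


def phasor_map(
    img: FLIMImage,
    channel: str,
    harmonic: int = 1,
    smooth: str | None = "median",
    irf: InstrumentResponse | None = None,
) -> PhasorMap:
    """Per-pixel phasor transform of one channel.

    ``smooth="median"`` applies a 3x3 spatial median filter to every
    time bin before the transform (a denoising step that tightens the
    photon clouds; the transform itself is untouched).  If an IRF is
    given, every pixel is calibrated by its phasor.
    """
    stack = img.channel(channel).astype(float)
    if smooth == "median":
        stack = ndimage.median_filter(stack, size=(3, 3, 1))
    elif smooth is not None:
        raise ConfigError(f"unknown smoothing {smooth!r}")
    counts = stack.sum(axis=-1)
    omega = harmonic * 2.0 * math.pi / img.period_ns
    cos_w = np.cos(omega * img.time_ns)
    sin_w = np.sin(omega * img.time_ns)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = stack @ cos_w / counts
        s = stack @ sin_w / counts
    g[counts <= 0] = np.nan
    s[counts <= 0] = np.nan
    if irf is not None:
        ref = irf_phasor(irf, img.period_ns, harmonic)
        if ref.modulus <= 0:
            raise CalibrationError("cannot calibrate with a zero-modulus IRF phasor")
        z = (g + 1j * s) / complex(ref.g, ref.s)
        g, s = z.real, z.imag
    return PhasorMap(
        g=g, s=s, counts=counts, harmonic=harmonic, omega=omega,
        channel=channel, smoothed=smooth is not None,
    )


def roi_average_lifetime(pmap: PhasorMap, roi: PhasorROI) -> float:
    """Photon-weighted mean phase lifetime of the pixels whose phasor
    falls inside the circular selection."""
    m = pmap.valid & (pmap.counts > 0)
    m[m] = roi.contains(pmap.g[m], pmap.s[m]) & (pmap.g[m] > 0)
    if not m.any():
        raise EmptySelectionError("no pixels inside the phasor ROI")
    tau_phi = (pmap.s[m] / pmap.g[m]) / pmap.omega
    return float(np.average(tau_phi, weights=pmap.counts[m]))
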