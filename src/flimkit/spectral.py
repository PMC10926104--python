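"""Spectrally resolved lifetime profiles, normalized spectra and GP.

A spectral lifetime profile collects the intensity-weighted mean
lifetime and the summed intensity of each emission window.  The
generalized polarization

    GP = (I_B - I_R) / (I_B + I_R)

contrasts the intensity at a blue-shifted wavelength (where the
ordered-phase spectrum peaks) against a red-shifted one; it ranges from
+1 (all signal blue) to -1 (all signal red), with large red shifts of
the emission producing low GP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, EmptyProfileError, UndefinedResultError
from .fitting import FitResult, fit_decay, qc_filter
from .histogram import DecayHistogram, InstrumentResponse, SpectralWindow

__all__ = [
    "SpectralLifetimeProfile",
    "spectral_profile",
    "aggregate_profiles",
    "normalized_spectrum",
    "spline_spectrum",
    "GPConfig",
    "GP_WAVELENGTHS",
    "gp",
    "gp_from_profile",
    "delta_tau",
]


@dataclass
class SpectralLifetimeProfile:
    """Per-window tau_AvInt (with optional replicate dispersion) and
    summed intensity for one condition."""

    windows: tuple[SpectralWindow, ...]
    tau_av_int_ns: np.ndarray
    intensities: np.ndarray
    tau_sd_ns: np.ndarray | None = None
    condition: str = ""
    fits: tuple[FitResult, ...] | None = None

    def __post_init__(self) -> None:
        self.tau_av_int_ns = np.asarray(self.tau_av_int_ns, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not (len(self.windows) == self.tau_av_int_ns.size == self.intensities.size):
            raise ConfigError("windows, lifetimes and intensities must align")
        centers = [w.center_nm for w in self.windows]
        if sorted(centers) != centers or len(set(centers)) != len(centers):
            raise ConfigError("windows must be strictly ordered by center")
        if np.any(self.intensities < 0):
            raise ConfigError("intensities must be non-negative")

    @property
    def centers_nm(self) -> np.ndarray:
        return np.array([w.center_nm for w in self.windows])

    def window_index_at(self, wavelength_nm: float) -> int:
        for i, w in enumerate(self.windows):
            if w.contains(wavelength_nm):
                return i
        raise ConfigError(
            f"no window of profile {self.condition!r} contains {wavelength_nm} nm"
        )

    def tau_at(self, wavelength_nm: float) -> float:
        return float(self.tau_av_int_ns[self.window_index_at(wavelength_nm)])

    def intensity_at(self, wavelength_nm: float) -> float:
        return float(self.intensities[self.window_index_at(wavelength_nm)])


def spectral_profile(
    hists: Sequence[DecayHistogram],
    irf: InstrumentResponse,
    n: int = 2,
    condition: str = "",
    **fit_kwargs,
) -> SpectralLifetimeProfile:
    """Fit every window's decay and assemble the lifetime profile.

    Windows failing the 10^4-photon QC are dropped with a warning
    (mirroring exclusion of unreliable decays); if all fail, an
    EmptyProfileError is raised.
    """
    kept: list[tuple[SpectralWindow, FitResult, float]] = []
    for h in hists:
        if h.window is None:
            raise ConfigError("every histogram needs a spectral window label")
        if not qc_filter(h):
            warnings.warn(
                f"window {h.window.label} excluded by QC "
                f"({h.total:.0f} photons)",
                stacklevel=2,
            )
            continue
        res = fit_decay(h, irf, n=n, **fit_kwargs)
        kept.append((h.window, res, h.total))
    if not kept:
        raise EmptyProfileError("all spectral windows failed quality control")
    kept.sort(key=lambda item: item[0].center_nm)
    windows, fits, totals = zip(*kept)
    return SpectralLifetimeProfile(
        windows=tuple(windows),
        tau_av_int_ns=np.array([f.tau_av_int_ns for f in fits]),
        intensities=np.array(totals),
        condition=condition,
        fits=tuple(fits),
    )


def aggregate_profiles(
    profiles: Sequence[SpectralLifetimeProfile], condition: str = ""
) -> SpectralLifetimeProfile:
    """Median lifetime across replicates per window, with the standard
    deviation as dispersion band; intensities are summed."""
    if not profiles:
        raise ConfigError("need at least one replicate profile")
    windows = profiles[0].windows
    if any(p.windows != windows for p in profiles):
        raise ConfigError("replicates must share the window ladder")
    taus = np.vstack([p.tau_av_int_ns for p in profiles])
    return SpectralLifetimeProfile(
        windows=windows,
        tau_av_int_ns=np.median(taus, axis=0),
        intensities=np.sum([p.intensities for p in profiles], axis=0),
        tau_sd_ns=np.std(taus, axis=0, ddof=1) if len(profiles) > 1 else None,
        condition=condition or profiles[0].condition,
    )


def normalized_spectrum(profile: SpectralLifetimeProfile) -> np.ndarray:
    """Per-window summed intensity divided by its maximum (range (0, 1],
    maximum exactly 1)."""
    peak = profile.intensities.max() if profile.intensities.size else 0.0
    if peak <= 0:
        raise UndefinedResultError("cannot normalize an all-zero spectrum")
    return profile.intensities / peak


def spline_spectrum(
    profile: SpectralLifetimeProfile, grid_nm: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline interpolation of the normalized spectrum on a dense
    wavelength grid — for display only; quantitative GP and delta-tau
    always use the raw window intensities."""
    from scipy.interpolate import CubicSpline

    centers = profile.centers_nm
    values = normalized_spectrum(profile)
    if grid_nm is None:
        grid_nm = np.linspace(centers[0], centers[-1], 201)
    return grid_nm, CubicSpline(centers, values)(grid_nm)


#: Probe-specific blue/red GP wavelength pairs (lambda_Lo, lambda_Ld) in nm.
GP_WAVELENGTHS: dict[str, tuple[float, float]] = {
    "nr12s": (550.0, 670.0),
    "nr12a": (590.0, 670.0),
    "flipper": (570.0, 650.0),
}


@dataclass(frozen=True)
class GPConfig:
    """Blue-shifted (ordered-phase, lambda_Lo) and red-shifted
    (disordered-phase, lambda_Ld) wavelengths used for GP."""

    lambda_lo_nm: float
    lambda_ld_nm: float

    def __post_init__(self) -> None:
        if not self.lambda_lo_nm < self.lambda_ld_nm:
            raise ConfigError("lambda_Lo must be blue of (less than) lambda_Ld")

    @classmethod
    def for_probe(cls, name: str) -> "GPConfig":
        key = name.lower().split("_")[0]
        try:
            return cls(*GP_WAVELENGTHS[key])
        except KeyError:
            raise ConfigError(
                f"no GP wavelength pair for probe {name!r}; "
                f"known: {sorted(GP_WAVELENGTHS)}"
            ) from None


def gp(i_blue: float, i_red: float) -> float:
    """Generalized polarization (I_B - I_R)/(I_B + I_R) in [-1, +1]."""
    if i_blue < 0 or i_red < 0:
        raise ConfigError("intensities must be non-negative")
    total = i_blue + i_red
    if total <= 0:
        raise UndefinedResultError("GP undefined for two zero intensities")
    return (i_blue - i_red) / total


def gp_from_profile(profile: SpectralLifetimeProfile, cfg: GPConfig) -> float:
    """GP of the summed intensities of the windows containing the
    configured blue and red wavelengths (containment lookup, since the
    window ladder is coarser than single wavelengths)."""
    return gp(
        profile.intensity_at(cfg.lambda_lo_nm),
        profile.intensity_at(cfg.lambda_ld_nm),
    )


def delta_tau(
    profile_a: SpectralLifetimeProfile,
    profile_b: SpectralLifetimeProfile,
    wavelength_nm: float,
) -> float:
    """Signed lifetime contrast tau_A(lambda) - tau_B(lambda)."""
    return profile_a.tau_at(wavelength_nm) - profile_b.tau_at(wavelength_nm)
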