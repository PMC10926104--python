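"""Probe models: per-window multi-exponential decays with solvent relaxation.

Solvatochromic membrane probes emit later photons at longer wavelengths:
while the solvation shell relaxes around the excited-state dipole, the
emission spectrum red-shifts, so red detection windows collect photons
with longer mean delay.  Here that mechanism is emulated
phenomenologically at the window level: the intensity-weighted mean
lifetime follows a saturating curve of the window center,

    tau_mean(lam) = tau_max - (tau_max - tau_min) * exp(-(lam - 500)/lam_scale),

clipped flat above a probe-specific plateau wavelength.  Each window's
biexponential amplitude fractions are solved so the window's
intensity-weighted mean lifetime equals that target exactly.

The bundled presets (Flipper-like, NR12S/NR12A-like, AF488-like control,
each with liquid-ordered/liquid-disordered variants) are simulator
ground truth chosen to reproduce the qualitative photophysics — they are
not measurements of the real dyes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, MissingWindowError
from .histogram import SpectralWindow, default_window_ladder

__all__ = [
    "WindowDecay",
    "ProbeModel",
    "saturating_lifetime",
    "relaxation_probe",
    "constant_probe",
    "PROBE_PRESETS",
    "get_probe",
]


@dataclass(frozen=True)
class WindowDecay:
    """Multi-exponential decay parameters for one spectral window.

    ``amplitudes`` are pre-exponential fractions a_i >= 0 summing to 1;
    ``lifetimes_ns`` are the component lifetimes tau_i > 0.
    """

    amplitudes: tuple[float, ...]
    lifetimes_ns: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        tau = np.asarray(self.lifetimes_ns, dtype=float)
        if a.shape != tau.shape or a.size == 0:
            raise ConfigError("amplitudes and lifetimes must align and be non-empty")
        if np.any(a < 0) or not math.isclose(a.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ConfigError("amplitude fractions must be non-negative and sum to 1")
        if np.any(tau <= 0):
            raise ConfigError("lifetimes must be strictly positive")

    @property
    def tau_av_int(self) -> float:
        """Intensity-weighted mean lifetime sum(a tau^2)/sum(a tau)."""
        a = np.asarray(self.amplitudes)
        tau = np.asarray(self.lifetimes_ns)
        return float(np.sum(a * tau**2) / np.sum(a * tau))

    @property
    def photon_fractions(self) -> np.ndarray:
        """Probability that a detected photon comes from each component
        (steady-state intensity share a_i tau_i)."""
        w = np.asarray(self.amplitudes) * np.asarray(self.lifetimes_ns)
        return w / w.sum()


@dataclass(frozen=True)
class ProbeModel:
    """A probe's per-window decays, emission-spectrum weights and plateau."""

    name: str
    windows: tuple[SpectralWindow, ...]
    decays: tuple[WindowDecay, ...]
    brightness: tuple[float, ...]
    lambda_plateau_nm: float

    def __post_init__(self) -> None:
        if not (len(self.windows) == len(self.decays) == len(self.brightness)):
            raise ConfigError("windows, decays and brightness must align")
        if any(b < 0 for b in self.brightness) or sum(self.brightness) <= 0:
            raise ConfigError("brightness weights must be non-negative with positive sum")
        centers = [w.center_nm for w in self.windows]
        if sorted(centers) != centers:
            raise ConfigError("windows must be ordered by center wavelength")
        self._check_monotone_plateau()

    def _check_monotone_plateau(self, tol: float = 1e-6) -> None:
        taus = [d.tau_av_int for d in self.decays]
        for w0, w1, t0, t1 in zip(self.windows, self.windows[1:], taus, taus[1:]):
            if w1.center_nm <= self.lambda_plateau_nm and t1 < t0 - tol:
                raise ConfigError(
                    f"{self.name}: mean lifetime decreases before the plateau "
                    f"({w0.label}: {t0:.3f} ns -> {w1.label}: {t1:.3f} ns)"
                )
            if w0.center_nm >= self.lambda_plateau_nm and abs(t1 - t0) > 1e-3:
                raise ConfigError(
                    f"{self.name}: mean lifetime not flat beyond the plateau"
                )

    def _index(self, window: SpectralWindow) -> int:
        try:
            return self.windows.index(window)
        except ValueError:
            raise MissingWindowError(
                f"window {window.label} is not defined for probe {self.name!r}"
            ) from None

    def decay_for(self, window: SpectralWindow) -> WindowDecay:
        return self.decays[self._index(window)]

    def brightness_for(self, window: SpectralWindow) -> float:
        return self.brightness[self._index(window)]

    def tau_av_int(self, window: SpectralWindow) -> float:
        """Ground-truth intensity-weighted mean lifetime of one window."""
        return self.decay_for(window).tau_av_int

    def window_at(self, wavelength_nm: float) -> SpectralWindow:
        for w in self.windows:
            if w.contains(wavelength_nm):
                return w
        raise MissingWindowError(
            f"no window of probe {self.name!r} contains {wavelength_nm} nm"
        )

    def channel_mixture(
        self, lower_nm: float, upper_nm: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (photon fractions, lifetimes) of all windows whose
        center falls in [lower_nm, upper_nm).

        Pooling windows into a wide channel mixes their decays with
        brightness weights; the returned fractions are per-photon
        component probabilities.
        """
        probs: list[float] = []
        taus: list[float] = []
        for w, d, b in zip(self.windows, self.decays, self.brightness):
            if lower_nm <= w.center_nm < upper_nm and b > 0:
                for p, tau in zip(d.photon_fractions, d.lifetimes_ns):
                    probs.append(b * float(p))
                    taus.append(tau)
        if not probs:
            raise MissingWindowError(
                f"probe {self.name!r} has no windows in [{lower_nm}, {upper_nm}) nm"
            )
        p = np.asarray(probs)
        return p / p.sum(), np.asarray(taus)

    def channel_tau_av_int(self, lower_nm: float, upper_nm: float) -> float:
        """Ground-truth tau_AvInt of the pooled decay of a wide channel.

        For a mixture with photon shares p_k the intensity-weighted mean
        is the photon-share-weighted mean of the component lifetimes.
        """
        p, tau = self.channel_mixture(lower_nm, upper_nm)
        return float(np.sum(p * tau))

    def channel_brightness(self, lower_nm: float, upper_nm: float) -> float:
        return sum(
            b
            for w, b in zip(self.windows, self.brightness)
            if lower_nm <= w.center_nm < upper_nm
        )


def saturating_lifetime(
    wavelength_nm: float,
    tau_min_ns: float,
    tau_max_ns: float,
    lam_scale_nm: float,
    lam_plateau_nm: float,
) -> float:
    """Target mean lifetime at a wavelength: saturating rise, flat plateau."""
    lam = min(wavelength_nm, lam_plateau_nm)
    return tau_max_ns - (tau_max_ns - tau_min_ns) * math.exp(
        -(lam - 500.0) / lam_scale_nm
    )


def _amplitude_for_mean(mean_ns: float, tau1: float, tau2: float) -> float:
    """Amplitude fraction a1 of a biexponential (tau1 < tau2) whose
    intensity-weighted mean lifetime equals ``mean_ns``."""
    if not tau1 < mean_ns < tau2:
        raise ConfigError(
            f"target mean {mean_ns:.3f} ns not bracketed by components "
            f"({tau1}, {tau2}) ns"
        )
    ratio = (tau2 * (tau2 - mean_ns)) / (tau1 * (mean_ns - tau1))  # a1/a2
    return ratio / (1.0 + ratio)


def relaxation_probe(
    name: str,
    tau_components_ns: tuple[float, float],
    tau_min_ns: float,
    anchor: tuple[float, float],
    lam_scale_nm: float,
    lam_plateau_nm: float,
    emission_peak_nm: float,
    emission_sigma_nm: float = 45.0,
    windows: tuple[SpectralWindow, ...] | None = None,
) -> ProbeModel:
    """Build a biexponential probe whose window mean lifetimes follow the
    solvent-relaxation curve, anchored exactly at ``anchor=(lam, tau)``.

    The anchor pins the curve so that the window containing ``lam`` has
    tau_AvInt exactly ``tau`` (used to encode known phase contrasts).
    """
    windows = windows or default_window_ladder()
    lam_a, tau_a = anchor
    q = math.exp(-(lam_a - 500.0) / lam_scale_nm)
    tau_max = (tau_a - tau_min_ns * q) / (1.0 - q)
    tau1, tau2 = sorted(tau_components_ns)
    decays = []
    brightness = []
    for w in windows:
        m = saturating_lifetime(w.center_nm, tau_min_ns, tau_max, lam_scale_nm, lam_plateau_nm)
        a1 = _amplitude_for_mean(m, tau1, tau2)
        decays.append(WindowDecay((a1, 1.0 - a1), (tau1, tau2)))
        brightness.append(
            math.exp(-0.5 * ((w.center_nm - emission_peak_nm) / emission_sigma_nm) ** 2)
        )
    return ProbeModel(name, tuple(windows), tuple(decays), tuple(brightness), lam_plateau_nm)


def constant_probe(
    name: str,
    tau_ns: float,
    emission_peak_nm: float = 520.0,
    emission_sigma_nm: float = 35.0,
    windows: tuple[SpectralWindow, ...] | None = None,
) -> ProbeModel:
    """Monoexponential control with the same lifetime in every window
    (AF488-like: no solvent-relaxation wavelength dependence)."""
    windows = windows or default_window_ladder()
    decays = tuple(WindowDecay((1.0,), (tau_ns,)) for _ in windows)
    brightness = tuple(
        math.exp(-0.5 * ((w.center_nm - emission_peak_nm) / emission_sigma_nm) ** 2)
        for w in windows
    )
    return ProbeModel(name, tuple(windows), decays, brightness, windows[0].center_nm)


def _build_presets() -> dict[str, ProbeModel]:
    return {
        # Flipper-like: lifetime probe, small spectral shift, early plateau.
        # Lo/Ld anchored at 570 nm to 5.6/4.0 ns (simulated two-phase
        # vesicle contrast of 1.6 ns).
        "flipper_ld": relaxation_probe(
            "flipper_ld", (2.0, 6.0), tau_min_ns=3.6, anchor=(570.0, 4.0),
            lam_scale_nm=40.0, lam_plateau_nm=600.0,
            emission_peak_nm=605.0, emission_sigma_nm=50.0,
        ),
        "flipper_lo": relaxation_probe(
            "flipper_lo", (3.0, 7.5), tau_min_ns=5.1, anchor=(570.0, 5.6),
            lam_scale_nm=40.0, lam_plateau_nm=600.0,
            emission_peak_nm=590.0, emission_sigma_nm=50.0,
        ),
        # NR12S-like: solvatochromic, large spectral shift, plateau 650 nm,
        # Lo-Ld lifetime gap larger below 600 nm (better green resolution).
        "nr12s_ld": relaxation_probe(
            "nr12s_ld", (0.8, 6.0), tau_min_ns=1.3, anchor=(650.0, 4.33),
            lam_scale_nm=60.0, lam_plateau_nm=650.0,
            emission_peak_nm=630.0, emission_sigma_nm=45.0,
        ),
        "nr12s_lo": relaxation_probe(
            "nr12s_lo", (1.5, 7.0), tau_min_ns=3.3, anchor=(650.0, 5.32),
            lam_scale_nm=60.0, lam_plateau_nm=650.0,
            emission_peak_nm=560.0, emission_sigma_nm=45.0,
        ),
        # Constant-lifetime control (no wavelength dependence).
        "af488": constant_probe("af488", 4.1),
    }


PROBE_PRESETS: dict[str, ProbeModel] = _build_presets()


def get_probe(name: str) -> ProbeModel:
    try:
        return PROBE_PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown probe preset {name!r}; available: {sorted(PROBE_PRESETS)}"
        ) from None
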