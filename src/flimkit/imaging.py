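"""FLIM image container and pooling strategies.

Pixel-wise multi-exponential fitting is rarely feasible at realistic
photon budgets, so analysis runs on pooled histograms: either the whole
image or mask-selected regions (e.g. the Lo and Ld phases of a
vesicle).  A fast per-pixel phasor phase-lifetime map is provided for
display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import AxisMismatchError, ConfigError, EmptySelectionError
from .histogram import DecayHistogram, SpectralWindow

__all__ = [
    "FLIMImage",
    "ROIMask",
    "pool_whole_image",
    "pool_roi",
    "lifetime_display_map",
]

#: Minimum photons per pixel for a display-grade lifetime estimate
#: (the reliability floor for monoexponential analysis).
DISPLAY_MIN_PHOTONS = 100


@dataclass
class FLIMImage:
    """Per-pixel decay histograms, one dense (ny, nx, n_bins) stack per
    emission channel, all sharing a single time axis and period."""

    channels: dict[str, np.ndarray]
    time_ns: np.ndarray
    period_ns: float
    channel_spans: dict[str, tuple[float, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 3 or arr.shape[-1] != self.time_ns.size:
                raise AxisMismatchError(
                    f"channel {name!r} must be (ny, nx, n_bins={self.time_ns.size})"
                )
            shapes.add(arr.shape[:2])
            self.channels[name] = arr
        if len(shapes) > 1:
            raise AxisMismatchError("all channels must share the image shape")

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ConfigError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def window_for(self, name: str) -> SpectralWindow | None:
        span = self.channel_spans.get(name)
        return SpectralWindow(*span) if span else None

    def counts(self, name: str) -> np.ndarray:
        """Total photons per pixel in one channel."""
        return self.channel(name).sum(axis=-1)


@dataclass
class ROIMask:
    """Binary pixel mask with a phase/region label."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ConfigError("mask must be 2-D")


def _as_mask(img: FLIMImage, mask: "ROIMask | np.ndarray") -> tuple[np.ndarray, str]:
    label = mask.label if isinstance(mask, ROIMask) else ""
    arr = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if arr.shape != img.shape:
        raise AxisMismatchError(
            f"mask shape {arr.shape} does not match image shape {img.shape}"
        )
    return arr, label


def pool_roi(
    img: FLIMImage, mask: "ROIMask | np.ndarray", channel: str
) -> DecayHistogram:
    """Bin-wise sum of the decays of mask-selected pixels."""
    arr, label = _as_mask(img, mask)
    if not arr.any():
        raise EmptySelectionError("ROI mask selects no pixels")
    counts = img.channel(channel)[arr].sum(axis=0, dtype=np.int64)
    return DecayHistogram(
        img.time_ns.copy(),
        counts,
        img.period_ns,
        window=img.window_for(channel),
        provenance={
            "pooling": "roi",
            "roi_label": label,
            "n_pixels": int(arr.sum()),
            "channel": channel,
            "seed": img.meta.get("seed"),
        },
    )


def pool_whole_image(img: FLIMImage, channel: str) -> DecayHistogram:
    """Bin-wise sum of all pixel decays (whole-image analysis mode)."""
    ny, nx = img.shape
    hist = pool_roi(img, np.ones((ny, nx), dtype=bool), channel)
    hist.provenance["pooling"] = "whole_image"
    return hist


def lifetime_display_map(
    img: FLIMImage,
    channel: str,
    irf=None,
    harmonic: int = 1,
    min_photons: int = DISPLAY_MIN_PHOTONS,
) -> np.ndarray:
    """Fast per-pixel lifetime estimate for display (phasor phase
    lifetime, no fitting).

    Pixels with fewer than ``min_photons`` photons (or a non-physical
    phasor position) are NaN.  If an IRF is supplied its phasor is
    divided out first, removing the instrument delay.
    """
    from .phasor import irf_phasor

    stack = img.channel(channel).astype(float)
    counts = stack.sum(axis=-1)
    omega = harmonic * 2.0 * np.pi / img.period_ns
    cos_w = np.cos(omega * img.time_ns)
    sin_w = np.sin(omega * img.time_ns)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = stack @ cos_w / counts
        s = stack @ sin_w / counts
    if irf is not None:
        ref = irf_phasor(irf, img.period_ns, harmonic)
        z = (g + 1j * s) / complex(ref.g, ref.s)
        g, s = z.real, z.imag
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (s / g) / omega
    tau[(counts < min_photons) | ~(g > 0) | ~(s >= 0)] = np.nan
    return tau
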