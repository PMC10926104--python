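"""Plain-text and TIFF on-disk formats.

Decay histograms are stored as two-column TSV (``time_ns``, ``counts``)
with a JSON sidecar (same stem, ``.json``) recording the spectral
window, repetition period, photon total and provenance.  FLIM images
are multi-page TIFF stacks, one page per time bin and one file per
channel, plus a JSON sidecar with the time axis and channel spans.
These formats are deliberately simple so third parties can convert
from vendor files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .histogram import DecayHistogram, SpectralWindow
from .imaging import FLIMImage

__all__ = [
    "write_histogram",
    "read_histogram",
    "write_flim_image",
    "read_flim_tiff",
    "write_mask",
    "read_mask",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_histogram(hist: DecayHistogram, path: str | Path) -> Path:
    """Write TSV (time_ns, counts) plus a JSON sidecar; returns the TSV path."""
    path = Path(path)
    df = pd.DataFrame({"time_ns": hist.time_ns, "counts": hist.counts})
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "window_nm": [hist.window.lower_nm, hist.window.upper_nm]
        if hist.window
        else None,
        "period_ns": hist.period_ns,
        "total_photons": hist.total,
        "provenance": _jsonable(hist.provenance),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_histogram(path: str | Path, period_ns: float | None = None) -> DecayHistogram:
    """Read a TSV decay histogram, validating against its JSON sidecar.

    Without a sidecar, defaults apply with a warning and ``period_ns``
    becomes required.  A sidecar photon total that disagrees with the
    recomputed total is a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    for col in ("time_ns", "counts"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    counts = df["counts"].to_numpy()
    if np.any(counts < 0):
        bad = int(np.argmax(counts < 0))
        raise FormatError(f"{path}: negative count at data line {bad + 1}")

    sidecar_file = _sidecar_path(path)
    window = None
    provenance: dict = {}
    if sidecar_file.exists():
        try:
            sidecar = json.loads(sidecar_file.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{sidecar_file}: invalid JSON ({exc})") from exc
        if sidecar.get("window_nm"):
            window = SpectralWindow(*sidecar["window_nm"])
        period_ns = sidecar.get("period_ns", period_ns)
        provenance = sidecar.get("provenance", {}) or {}
        expected = sidecar.get("total_photons")
        if expected is not None and not np.isclose(expected, counts.sum()):
            raise FormatError(
                f"{path}: sidecar total {expected} != recomputed {counts.sum()}"
            )
    else:
        warnings.warn(f"{path}: no sidecar found, applying defaults", stacklevel=2)
        if period_ns is None:
            raise FormatError(
                f"{path}: period_ns required when no sidecar is present"
            )
    if period_ns is None:
        raise FormatError(f"{sidecar_file}: sidecar lacks period_ns")
    return DecayHistogram(
        df["time_ns"].to_numpy(),
        counts,
        float(period_ns),
        window=window,
        provenance=provenance,
    )


def write_flim_image(img: FLIMImage, out_dir: str | Path, stem: str = "flim") -> Path:
    """One multi-page TIFF per channel (page = time bin) plus a shared
    JSON sidecar; returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, arr in img.channels.items():
        safe = name.replace("/", "_")
        tiff_path = out_dir / f"{stem}_{safe}.tif"
        tifffile.imwrite(tiff_path, np.moveaxis(arr, -1, 0))
        files[name] = tiff_path.name
    sidecar = {
        "bin_width_ns": float(img.time_ns[1] - img.time_ns[0]),
        "period_ns": img.period_ns,
        "n_bins": int(img.time_ns.size),
        "channels": files,
        "channel_spans": _jsonable(img.channel_spans),
        "meta": _jsonable({k: v for k, v in img.meta.items() if k != "labels"}),
    }
    sidecar_path = out_dir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    if "labels" in img.meta:
        write_mask(np.asarray(img.meta["labels"]), out_dir / f"{stem}_labels.tif")
    return sidecar_path


def read_flim_tiff(sidecar_path: str | Path) -> FLIMImage:
    """Rebuild a FLIMImage from the sidecar written by write_flim_image."""
    sidecar_path = Path(sidecar_path)
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{sidecar_path}: invalid JSON ({exc})") from exc
    for key in ("bin_width_ns", "period_ns", "n_bins", "channels"):
        if key not in sidecar:
            raise FormatError(f"{sidecar_path}: missing key {key!r}")
    n_bins = int(sidecar["n_bins"])
    dt = float(sidecar["bin_width_ns"])
    if abs(n_bins * dt - sidecar["period_ns"]) > 1e-6:
        raise FormatError(
            f"{sidecar_path}: n_bins x bin width != period "
            f"({n_bins} x {dt} != {sidecar['period_ns']})"
        )
    channels = {}
    for name, fname in sidecar["channels"].items():
        arr = tifffile.imread(sidecar_path.parent / fname)
        if arr.ndim != 3 or arr.shape[0] != n_bins:
            raise FormatError(
                f"{fname}: expected {n_bins} pages (one per time bin), "
                f"got shape {arr.shape}"
            )
        channels[name] = np.moveaxis(arr, 0, -1)
    time_ns = (np.arange(n_bins) + 0.5) * dt
    spans = {k: tuple(v) for k, v in sidecar.get("channel_spans", {}).items()}
    return FLIMImage(
        channels=channels,
        time_ns=time_ns,
        period_ns=float(sidecar["period_ns"]),
        channel_spans=spans,
        meta=sidecar.get("meta", {}),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))
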