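"""Data model and I/O for CEUS cineloops and region-of-interest masks.

A cineloop is the dynamic recording of a microbubble bolus transiting
tissue: a stack of 2-D intensity frames with per-frame timestamps.  The
pipeline operates on linearized echo-power intensities; vendor exports that
are log-compressed can be flagged in ``meta`` and delinearized with
:func:`delinearize`.

Two on-disk representations are supported:

* a portable single-file container (NumPy ``.npz``: named arrays ``frames``,
  ``times``, ``pixel_spacing`` plus a JSON-encoded ``meta`` entry) — lossless
  round-trip, no imaging dependencies;
* basic multi-frame DICOM (read-only) via :mod:`pydicom`, using
  ``NumberOfFrames`` together with ``FrameTime``/``FrameTimeVector`` or
  ``CineRate`` to synthesize timestamps.

ROI masks are stored as 0/255 PNG images or ``.npy`` boolean arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
from PIL import Image

from .errors import ValidationError

__all__ = [
    "Cineloop",
    "RoiMask",
    "read_cineloop",
    "write_cineloop",
    "read_mask",
    "write_mask",
    "delinearize",
]


@dataclass
class Cineloop:
    """A CEUS recording: ``frames`` indexed (time, row, column).

    Parameters
    ----------
    frames
        3-D stack of non-negative linear intensities, shape (T, H, W).
    times
        Seconds since recording start, one per frame, strictly increasing.
    pixel_spacing
        Optional (row, column) spacing in mm per pixel.
    meta
        Free-form acquisition metadata (probe, MI, agent dose, provenance).
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be 3-D (time, row, column); got ndim={self.frames.ndim}"
            )
        if self.n_frames < 2:
            raise ValidationError("a cineloop needs at least 2 frames")
        if self.times.shape != (self.n_frames,):
            raise ValidationError(
                f"times has shape {self.times.shape}, expected ({self.n_frames},)"
            )
        if self.times[0] < 0:
            raise ValidationError("times[0] must be >= 0")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValidationError(
                f"times must be strictly increasing; first violation at index {bad}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("frame intensities must be finite")
        if np.any(self.frames < 0):
            raise ValidationError("frame intensities must be >= 0")

    # -- convenience -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return float(self.times[-1] - self.times[0])

    def copy(self) -> "Cineloop":
        return Cineloop(
            frames=self.frames.copy(),
            times=self.times.copy(),
            pixel_spacing=self.pixel_spacing,
            meta=json.loads(json.dumps(self.meta)),
        )


@dataclass
class RoiMask:
    """Boolean region-of-interest mask congruent with one cineloop frame."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValidationError(f"mask must be 2-D; got ndim={self.mask.ndim}")
        if self.n_pixels < 1:
            raise ValidationError("empty ROI: mask has no true pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def check_congruent(self, loop: Cineloop) -> None:
        """Reject a mask that does not match the cineloop frame geometry."""
        if self.shape != loop.frame_shape:
            raise ValidationError(
                f"mask shape {self.shape} does not match frame shape {loop.frame_shape}"
            )


def delinearize(loop: Cineloop, k: float = 10.0) -> Cineloop:
    """Undo log compression: I -> 10**(I/k).

    Applied only when ``meta['log_compressed']`` is truthy; the result is
    marked linear.  ``k`` is the compression scale in intensity units per
    decade (vendor dependent, default 10).
    """
    if not loop.meta.get("log_compressed", False):
        return loop
    out = loop.copy()
    out.frames = np.power(10.0, out.frames / float(k))
    out.meta["log_compressed"] = False
    out.meta["delinearized_k"] = float(k)
    return out


# ---------------------------------------------------------------------------
# container format
# ---------------------------------------------------------------------------

def write_cineloop(loop: Cineloop, path: str | Path) -> Path:
    """Write ``loop`` to the portable container (.npz), losslessly.

    Arrays are stored uncompressed at full float64 precision; ``meta`` is
    embedded as JSON so nested keys survive the round-trip.
    """
    path = Path(path)
    spacing = (
        np.asarray(loop.pixel_spacing, dtype=np.float64)
        if loop.pixel_spacing is not None
        else np.asarray([np.nan, np.nan])
    )
    try:
        with open(path, "wb") as fh:
            np.savez(
                fh,
                frames=loop.frames,
                times=loop.times,
                pixel_spacing=spacing,
                meta=np.str_(json.dumps(loop.meta)),
            )
    except OSError:
        path.unlink(missing_ok=True)
        raise
    return path


def _read_container(path: Path) -> Cineloop:
    with np.load(path, allow_pickle=False) as z:
        frames = z["frames"]
        times = z["times"]
        spacing = z["pixel_spacing"]
        meta = json.loads(str(z["meta"]))
    pixel_spacing = None if np.any(np.isnan(spacing)) else (float(spacing[0]), float(spacing[1]))
    return Cineloop(frames=frames, times=times, pixel_spacing=pixel_spacing, meta=meta)


# ---------------------------------------------------------------------------
# DICOM (basic multi-frame layout only)
# ---------------------------------------------------------------------------

def _read_dicom(path: Path) -> Cineloop:
    import pydicom

    ds = pydicom.dcmread(path)
    n = int(getattr(ds, "NumberOfFrames", 1))
    if n < 2:
        raise ValidationError("DICOM object is not multi-frame (NumberOfFrames < 2)")
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim == 4:  # colour frames -> luminance
        arr = arr.mean(axis=-1)
    if arr.ndim != 3:
        raise ValidationError(f"unsupported DICOM pixel data ndim={arr.ndim}")

    times = _dicom_frame_times(ds, n)
    meta: dict[str, Any] = {"source": str(path), "format": "dicom"}
    for tag in ("Manufacturer", "ManufacturerModelName", "MechanicalIndex"):
        if hasattr(ds, tag):
            meta[tag] = str(getattr(ds, tag))
    spacing = None
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return Cineloop(frames=arr, times=times, pixel_spacing=spacing, meta=meta)


def _dicom_frame_times(ds, n: int) -> np.ndarray:
    """Per-frame seconds from FrameTimeVector, FrameTime or CineRate."""
    ftv = getattr(ds, "FrameTimeVector", None)
    if ftv is not None and len(ftv) == n:
        return np.cumsum(np.asarray(ftv, dtype=np.float64)) / 1000.0 - float(ftv[0]) / 1000.0
    ft = getattr(ds, "FrameTime", None)  # ms between frames
    if ft is not None and float(ft) > 0:
        return np.arange(n, dtype=np.float64) * float(ft) / 1000.0
    rate = getattr(ds, "CineRate", None)  # frames per second
    if rate is not None and float(rate) > 0:
        return np.arange(n, dtype=np.float64) / float(rate)
    raise ValidationError(
        "DICOM object carries no frame-time information "
        "(FrameTimeVector / FrameTime / CineRate all absent)"
    )


def read_cineloop(path: str | Path, format: str = "container") -> Cineloop:
    """Read a cineloop from disk.

    Parameters
    ----------
    path
        Input file.
    format
        ``"container"`` for the portable .npz archive, ``"dicom"`` for a
        basic multi-frame DICOM object.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "container":
        return _read_container(path)
    if format == "dicom":
        return _read_dicom(path)
    raise ValidationError(f"unknown cineloop format {format!r}")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path, loop: Cineloop | None = None) -> RoiMask:
    """Read an ROI mask from a PNG (nonzero -> true) or ``.npy`` array file.

    If ``loop`` is given, the mask is checked against its frame geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path, allow_pickle=False)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim != 2:
        raise ValidationError(f"mask file must hold a single 2-D plane; got ndim={arr.ndim}")
    if not np.any(arr):
        raise ValidationError("empty ROI: mask file contains no nonzero pixels")
    m = RoiMask(arr != 0)
    if loop is not None:
        m.check_congruent(loop)
    return m


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    """Write a mask as 0/255 PNG or as ``.npy`` depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, mask.mask)
    else:
        Image.fromarray((mask.mask.astype(np.uint8)) * 255, mode="L").save(path)
    return path


def elliptical_mask(
    shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    semi_axes: tuple[float, float] | None = None,
) -> RoiMask:
    """Elliptical ROI — the conventional stand-in for a traced prostate
    boundary on the sagittal plane.  Defaults fill ~60% of the frame."""
    h, w = shape
    cr, cc = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    ar, ac = semi_axes if semi_axes is not None else (0.35 * h, 0.42 * w)
    rr, cc_grid = np.mgrid[0:h, 0:w]
    inside = ((rr - cr) / ar) ** 2 + ((cc_grid - cc) / ac) ** 2 <= 1.0
    return RoiMask(inside)
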