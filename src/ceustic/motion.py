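"""Rigid motion compensation for CEUS cineloops.

Transrectal acquisition leaves mostly small in-plane translations, so each
frame is registered to a reference frame by exhaustive normalized
cross-correlation over integer shifts within ``±max_shift``, with optional
subpixel refinement by a local quadratic fit of the correlation surface.
Correlation is computed on a temporally smoothed log-intensity copy of the
loop to damp speckle and bolus-phase intensity swings (NCC itself is
invariant to affine intensity changes between frames).

Ties at the correlation peak are broken toward the smaller displacement
norm, then lexicographically (row, then column), so estimates are fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cineloop import Cineloop
from .errors import EstimationError, ValidationError

__all__ = ["MotionTrace", "estimate_motion", "apply_motion", "correct_motion"]


@dataclass
class MotionTrace:
    """Per-frame (row, col) displacement relative to the reference frame."""

    shifts: np.ndarray       # (n_frames, 2) float
    reference_index: int

    def __post_init__(self) -> None:
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=np.float64))
        if self.shifts.shape[1] != 2:
            raise ValidationError("shifts must be an (n_frames, 2) array")
        ref = self.shifts[self.reference_index]
        if not np.allclose(ref, 0.0, atol=1e-9):
            raise ValidationError("shift at the reference frame must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]

    @property
    def max_abs_shift(self) -> float:
        return float(np.abs(self.shifts).max())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"frame": np.arange(self.n_frames), "dr": self.shifts[:, 0], "dc": self.shifts[:, 1]}
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, reference_index: int | None = None) -> "MotionTrace":
        df = pd.read_csv(path)
        shifts = df[["dr", "dc"]].to_numpy()
        if reference_index is None:
            zero = np.flatnonzero(np.all(np.abs(shifts) < 1e-12, axis=1))
            reference_index = int(zero[0]) if zero.size else 0
        return cls(shifts=shifts, reference_index=reference_index)


def _smoothed_log_stack(frames: np.ndarray, window: int) -> np.ndarray:
    """log1p intensities, then a centered temporal moving average."""
    log = np.log1p(frames)
    if window <= 1:
        return log
    kernel = np.ones(window) / window
    # truncated edges: normalize by the actual number of frames in the window
    num = ndimage.convolve1d(log, kernel, axis=0, mode="constant", cval=0.0)
    den = ndimage.convolve1d(np.ones(frames.shape[0]), kernel, mode="constant", cval=0.0)
    return num / den[:, None, None]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally shaped patches (nan if degenerate)."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def _overlap_slices(shape: tuple[int, int], dr: int, dc: int):
    """Slices pairing ref[r, c] with mov[r + dr, c + dc]: a moving frame
    whose content sits at displacement (dr, dc) scores highest there."""
    h, w = shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    ref_sl = (slice(r0, r1), slice(c0, c1))
    mov_sl = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
    return ref_sl, mov_sl


def _quadratic_peak_offset(cm1: float, c0: float, cp1: float) -> float:
    """Vertex offset of the parabola through three equally spaced samples."""
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:  # not a maximum; keep the integer peak
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_motion(
    loop: Cineloop,
    reference_index: int | None = None,
    max_shift: int = 5,
    subpixel: bool = True,
    temporal_window: int = 3,
) -> MotionTrace:
    """Estimate per-frame rigid translation against a reference frame.

    For every frame the integer shift maximizing the normalized
    cross-correlation with the reference is searched exhaustively within
    ``±max_shift`` pixels per axis; with ``subpixel=True`` the peak is
    refined by a separable quadratic fit.  A frame's shift is the
    displacement of its content relative to the reference, i.e. applying
    the negated shift re-aligns the frame.

    Raises
    ------
    EstimationError
        If the reference frame has zero intensity variance.
    """
    if reference_index is None:
        reference_index = int(np.argmax(loop.frames.mean(axis=(1, 2))))
    if not 0 <= reference_index < loop.n_frames:
        raise ValidationError(f"reference_index {reference_index} out of range")
    if max_shift < 1:
        raise ValidationError("max_shift must be >= 1")

    stack = _smoothed_log_stack(loop.frames, temporal_window)
    # the reference stays unsmoothed: temporal averaging would blend in
    # neighbours at other displacements and bias the correlation peak
    ref = np.log1p(loop.frames[reference_index])
    if np.ptp(ref) == 0:
        raise EstimationError("degenerate reference: frame has zero intensity variance")

    offsets = range(-max_shift, max_shift + 1)
    shifts = np.zeros((loop.n_frames, 2))
    for i in range(loop.n_frames):
        if i == reference_index:
            continue
        mov = stack[i]
        size = 2 * max_shift + 1
        surf = np.full((size, size), -np.inf)
        for a, dr in enumerate(offsets):
            for b, dc in enumerate(offsets):
                ref_sl, mov_sl = _overlap_slices(ref.shape, dr, dc)
                c = _ncc(ref[ref_sl], mov[mov_sl])
                if not np.isnan(c):
                    surf[a, b] = c
        best = np.max(surf)
        if not np.isfinite(best):  # flat moving frame: no information
            shifts[i] = (0.0, 0.0)
            continue
        cand = np.argwhere(surf >= best - 1e-12)
        disp = cand - max_shift
        norms = np.einsum("ij,ij->i", disp, disp)
        order = np.lexsort((disp[:, 1], disp[:, 0], norms))
        a, b = cand[order[0]]
        dr, dc = float(a - max_shift), float(b - max_shift)
        if subpixel:
            if 0 < a < size - 1 and np.all(np.isfinite(surf[a - 1 : a + 2, b])):
                dr += _quadratic_peak_offset(surf[a - 1, b], surf[a, b], surf[a + 1, b])
            if 0 < b < size - 1 and np.all(np.isfinite(surf[a, b - 1 : b + 2])):
                dc += _quadratic_peak_offset(surf[a, b - 1], surf[a, b], surf[a, b + 1])
        shifts[i] = (dr, dc)
    return MotionTrace(shifts=shifts, reference_index=reference_index)


def apply_motion(loop: Cineloop, trace: MotionTrace, order: int = 1) -> Cineloop:
    """Resample every frame by the inverse of its estimated shift.

    Out-of-field pixels are filled with edge values and the fact is flagged
    in ``meta``; timestamps are untouched.  ``order`` is the spline
    interpolation order (0 = nearest neighbour, 1 = bilinear default);
    integer shifts are exact for either.
    """
    if trace.n_frames != loop.n_frames:
        raise ValidationError(
            f"trace has {trace.n_frames} frames but loop has {loop.n_frames}"
        )
    out = loop.copy()
    for i in range(loop.n_frames):
        if np.any(trace.shifts[i] != 0):
            out.frames[i] = ndimage.shift(
                loop.frames[i], -trace.shifts[i], order=order, mode="nearest"
            )
    np.clip(out.frames, 0.0, None, out=out.frames)
    out.meta["motion_corrected"] = True
    out.meta["motion_reference_index"] = int(trace.reference_index)
    out.meta["motion_max_abs_shift_px"] = trace.max_abs_shift
    out.meta["motion_edge_fill"] = "nearest"
    return out


def correct_motion(
    loop: Cineloop,
    reference_index: int | None = None,
    max_shift: int = 5,
    subpixel: bool = True,
) -> tuple[Cineloop, MotionTrace]:
    """Estimate and apply in one step (the pipeline's step 1)."""
    trace = estimate_motion(loop, reference_index, max_shift, subpixel=subpixel)
    return apply_motion(loop, trace), trace
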