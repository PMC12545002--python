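"""Pixel-wise time-intensity-curve analysis and wash-in parametric mapping.

For every pixel inside the prostate ROI the intensity trace is smoothed
with a centered moving average, its landmarks are detected (baseline level,
enhancement start, peak), and the headline perfusion parameter — the
*mean gradient to peak*, the average TIC slope over the wash-in phase —
is computed as the endpoint-difference quotient

    (y_peak - y(t_start)) / (t_peak - t_start)      [intensity / s]

which equals the time-average of the instantaneous wash-in slope.  The
per-pixel values form a parametric map that is colour-coded from cool
(slow perfusion) to hot (rapid perfusion) for display.

Landmark conventions (all configurable via :class:`TicConfig`):

* baseline — mean of the smoothed trace over the first max(3, 5% of frames)
  frames (the pre-arrival window);
* peak — global maximum of the smoothed trace, earliest frame on ties;
  a maximum on the final frame means washout was not observed and the pixel
  is flagged ``censored_peak``;
* enhancement start — first upward crossing of
  baseline + threshold_frac * (y_peak - baseline), linearly interpolated
  between samples;
* pixels whose peak-above-baseline falls below ``noise_floor`` are flagged
  ``no_enhancement`` and excluded from the map.

The whole computation is deterministic and linear in n_pixels x n_frames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cineloop import Cineloop, RoiMask
from .errors import ValidationError

__all__ = [
    "TicConfig",
    "TICurve",
    "ParametricMap",
    "QUALITY_OK",
    "QUALITY_NO_ENHANCEMENT",
    "QUALITY_CENSORED_PEAK",
    "QUALITY_DEGENERATE",
    "QUALITY_OUTSIDE",
    "moving_average",
    "detect_landmarks",
    "extract_tic",
    "mean_gradient_to_peak",
    "compute_map",
    "colorize",
    "render_map",
]

log = logging.getLogger(__name__)

QUALITY_OK = 0
QUALITY_NO_ENHANCEMENT = 1
QUALITY_CENSORED_PEAK = 2
QUALITY_DEGENERATE = 3
QUALITY_OUTSIDE = 255

QUALITY_NAMES = {
    QUALITY_OK: "ok",
    QUALITY_NO_ENHANCEMENT: "no_enhancement",
    QUALITY_CENSORED_PEAK: "censored_peak",
    QUALITY_DEGENERATE: "degenerate_interval",
    QUALITY_OUTSIDE: "outside_roi",
}

PARAMETERS = ("mean_gradient_to_peak", "peak_enhancement", "time_to_peak")


@dataclass(frozen=True)
class TicConfig:
    """Tunables of the TIC analysis.

    smooth_window : odd moving-average width in frames (1 = no smoothing).
    threshold_frac : enhancement-start threshold as a fraction of
        peak-above-baseline — relative, so robust across gain settings.
    noise_floor : minimum peak-above-baseline (absolute intensity units)
        for a pixel to count as enhancing.
    gradient_from : lower endpoint of the wash-in quotient —
        ``start_intensity`` (the threshold-crossing value, literal reading
        of "start of enhancement to peak") or ``baseline``.
    """

    smooth_window: int = 5
    threshold_frac: float = 0.05
    noise_floor: float = 1e-6
    gradient_from: str = "start_intensity"

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValidationError("smooth_window must be odd and >= 1")
        if not 0 < self.threshold_frac < 1:
            raise ValidationError("threshold_frac must be in (0, 1)")
        if self.noise_floor < 0:
            raise ValidationError("noise_floor must be >= 0")
        if self.gradient_from not in ("start_intensity", "baseline"):
            raise ValidationError("gradient_from must be 'start_intensity' or 'baseline'")


@dataclass
class TICurve:
    """One pixel's (or region's) smoothed intensity-vs-time trace with
    landmarks."""

    t: np.ndarray
    y: np.ndarray            # smoothed trace
    baseline: float
    t_start: float
    t_peak: float
    y_peak: float
    y_start: float
    quality: int = QUALITY_OK

    @property
    def quality_name(self) -> str:
        return QUALITY_NAMES[self.quality]


@dataclass
class ParametricMap:
    """Per-pixel perfusion parameter restricted to the ROI.

    ``values`` is finite exactly where the mask is true and quality is ok;
    everywhere else it holds NaN.  ``quality`` records why a pixel was
    excluded.
    """

    values: np.ndarray
    parameter_name: str
    mask: RoiMask
    quality: np.ndarray
    config: TicConfig = field(default_factory=TicConfig)

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape or self.quality.shape != self.mask.shape:
            raise ValidationError("values, quality and mask must share one shape")

    def ok_values(self) -> np.ndarray:
        """The finite in-mask parameter values, flattened."""
        return self.values[(self.quality == QUALITY_OK) & self.mask.mask]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(
            path,
            values=self.values,
            quality=self.quality,
            mask=self.mask.mask,
            parameter_name=np.str_(self.parameter_name),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ParametricMap":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                values=z["values"],
                parameter_name=str(z["parameter_name"]),
                mask=RoiMask(z["mask"]),
                quality=z["quality"],
            )


# ---------------------------------------------------------------------------
# smoothing and landmarks
# ---------------------------------------------------------------------------

def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with truncated edges.

    At the edges the window is shortened to the frames actually available,
    so a constant trace stays exactly constant.
    """
    if window <= 1:
        return np.asarray(y, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    t_len = y.shape[0]
    h = window // 2
    cs = np.concatenate([np.zeros((1,) + y.shape[1:]), np.cumsum(y, axis=0)], axis=0)
    idx = np.arange(t_len)
    lo = np.clip(idx - h, 0, t_len)
    hi = np.clip(idx + h + 1, 0, t_len)
    counts = (hi - lo).astype(np.float64)
    out = (cs[hi] - cs[lo]) / counts.reshape((t_len,) + (1,) * (y.ndim - 1))
    return out


def _baseline_window(n_frames: int) -> int:
    return max(3, math.ceil(0.05 * n_frames))


def _landmarks_stack(
    y_raw: np.ndarray, t: np.ndarray, config: TicConfig
) -> dict[str, np.ndarray]:
    """Vectorized landmark detection on a (T, N) stack of raw traces."""
    t_len, n = y_raw.shape
    if t_len < 4:
        raise ValidationError("need at least 4 samples per trace")
    y = moving_average(y_raw, config.smooth_window)
    nb = _baseline_window(t_len)
    baseline = y[:nb].mean(axis=0)

    ip = np.argmax(y, axis=0)                     # earliest global max
    y_peak = y[ip, np.arange(n)]
    enh = y_peak - baseline

    quality = np.zeros(n, dtype=np.uint8)
    quality[ip == t_len - 1] = QUALITY_CENSORED_PEAK
    quality[enh < config.noise_floor] = QUALITY_NO_ENHANCEMENT

    y_thr = baseline + config.threshold_frac * enh
    before_peak = np.arange(t_len)[:, None] <= ip[None, :]
    crossed = (y >= y_thr[None, :]) & before_peak
    j = np.argmax(crossed, axis=0)                # first crossing index

    t_start = np.full(n, t[0], dtype=np.float64)
    y_start = y[0].copy()
    pos = j > 0
    jm = j[pos] - 1
    cols = np.flatnonzero(pos)
    y_lo = y[jm, cols]
    y_hi = y[j[pos], cols]
    frac = (y_thr[pos] - y_lo) / (y_hi - y_lo)
    t_start[pos] = t[jm] + frac * (t[j[pos]] - t[jm])
    y_start[pos] = y_thr[pos]

    t_peak = t[ip]
    degenerate = (t_peak - t_start <= 0) & (quality == QUALITY_OK)
    quality[degenerate] = QUALITY_DEGENERATE

    return {
        "smoothed": y,
        "baseline": baseline,
        "t_start": t_start,
        "t_peak": t_peak,
        "y_peak": y_peak,
        "y_start": y_start,
        "quality": quality,
    }


def detect_landmarks(
    y: np.ndarray,
    t: np.ndarray,
    threshold_frac: float = 0.05,
    smooth_window: int = 5,
    noise_floor: float = 1e-6,
) -> TICurve:
    """Detect (baseline, t_start, t_peak, y_peak) on a single raw trace."""
    y = np.asarray(y, dtype=np.float64).ravel()
    t = np.asarray(t, dtype=np.float64).ravel()
    if y.shape != t.shape:
        raise ValidationError("y and t must have equal length")
    cfg = TicConfig(
        smooth_window=smooth_window, threshold_frac=threshold_frac, noise_floor=noise_floor
    )
    lm = _landmarks_stack(y[:, None], t, cfg)
    return TICurve(
        t=t,
        y=lm["smoothed"][:, 0],
        baseline=float(lm["baseline"][0]),
        t_start=float(lm["t_start"][0]),
        t_peak=float(lm["t_peak"][0]),
        y_peak=float(lm["y_peak"][0]),
        y_start=float(lm["y_start"][0]),
        quality=int(lm["quality"][0]),
    )


def extract_tic(
    loop: Cineloop, row: int, col: int, smooth_window: int = 5, config: TicConfig | None = None
) -> TICurve:
    """TIC of one pixel: smoothed trace plus detected landmarks."""
    h, w = loop.frame_shape
    if not (0 <= row < h and 0 <= col < w):
        raise ValidationError(f"pixel ({row}, {col}) outside frame bounds {h}x{w}")
    cfg = config if config is not None else TicConfig(smooth_window=smooth_window)
    if config is None and smooth_window != cfg.smooth_window:
        cfg = replace(cfg, smooth_window=smooth_window)
    return detect_landmarks(
        loop.frames[:, row, col],
        loop.times,
        threshold_frac=cfg.threshold_frac,
        smooth_window=cfg.smooth_window,
        noise_floor=cfg.noise_floor,
    )


def mean_gradient_to_peak(curve: TICurve, gradient_from: str = "start_intensity") -> float:
    """Average wash-in slope of a TIC, intensity per second.

    The mean of the instantaneous gradient over [t_start, t_peak] telescopes
    to the endpoint difference divided by the interval length; the lower
    endpoint is the threshold-crossing intensity (default) or the baseline.
    """
    if curve.quality == QUALITY_NO_ENHANCEMENT:
        raise ValidationError("pixel shows no enhancement; gradient undefined")
    dt = curve.t_peak - curve.t_start
    if dt <= 0:
        raise ValidationError("degenerate wash-in interval (t_peak == t_start)")
    lower = curve.y_start if gradient_from == "start_intensity" else curve.baseline
    return (curve.y_peak - lower) / dt


# ---------------------------------------------------------------------------
# map computation
# ---------------------------------------------------------------------------

def compute_map(
    loop: Cineloop,
    mask: RoiMask,
    parameter: str = "mean_gradient_to_peak",
    config: TicConfig | None = None,
) -> ParametricMap:
    """Apply the TIC analysis to every in-mask pixel of a (motion-corrected)
    cineloop and return the parametric map.

    Pixels flagged ``no_enhancement``, ``censored_peak`` or with a degenerate
    wash-in interval carry NaN in ``values``; the ``quality`` grid says why.
    """
    if parameter not in PARAMETERS:
        raise ValidationError(f"unknown parameter {parameter!r}; choose from {PARAMETERS}")
    mask.check_congruent(loop)
    if mask.n_pixels == 0:
        raise ValidationError("empty ROI")
    cfg = config if config is not None else TicConfig()
    if not loop.meta.get("motion_corrected", False):
        log.info("compute_map: input loop not flagged motion_corrected")

    h, w = loop.frame_shape
    flat = loop.frames.reshape(loop.n_frames, h * w)
    idx = np.flatnonzero(mask.mask.ravel())
    lm = _landmarks_stack(flat[:, idx], loop.times, cfg)

    ok = lm["quality"] == QUALITY_OK
    vals = np.full(idx.size, np.nan)
    if parameter == "mean_gradient_to_peak":
        lower = lm["y_start"] if cfg.gradient_from == "start_intensity" else lm["baseline"]
        dt = lm["t_peak"] - lm["t_start"]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[ok] = (lm["y_peak"][ok] - lower[ok]) / dt[ok]
    elif parameter == "peak_enhancement":
        vals[ok] = (lm["y_peak"] - lm["baseline"])[ok]
    else:  # time_to_peak
        vals[ok] = (lm["t_peak"] - lm["t_start"])[ok]

    values = np.full((h, w), np.nan)
    values.ravel()[idx] = vals
    quality = np.full((h, w), QUALITY_OUTSIDE, dtype=np.uint8)
    quality.ravel()[idx] = lm["quality"]
    return ParametricMap(
        values=values, parameter_name=parameter, mask=mask, quality=quality, config=cfg
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def colorize(
    pmap: ParametricMap,
    colormap: str = "jet",
    normalization: tuple[float, float] = (0.0, 100.0),
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """8-bit RGB rendering of a parametric map.

    In-mask ok pixels are coloured by min-max (or percentile) normalization
    of the values; everything else shows the grayscale reference frame if
    given, else black.  Returns an (H, W, 3) uint8 array.
    """
    import matplotlib

    vals = pmap.ok_values()
    h, w = pmap.values.shape
    if reference is not None:
        ref = np.asarray(reference, dtype=np.float64)
        rng = np.ptp(ref)
        gray = ((ref - ref.min()) / rng * 255.0).astype(np.uint8) if rng > 0 else np.zeros_like(ref, dtype=np.uint8)
        rgb = np.repeat(gray[:, :, None], 3, axis=2)
    else:
        rgb = np.zeros((h, w, 3), dtype=np.uint8)
    if vals.size == 0:
        log.warning("colorize: no ok-quality pixels to render")
        return rgb
    vmin, vmax = np.percentile(vals, normalization)
    if vmax <= vmin:
        log.warning("colorize: constant map; rendering a single colour")
        vmax = vmin + 1.0
    cmap = matplotlib.colormaps[colormap]
    sel = (pmap.quality == QUALITY_OK) & pmap.mask.mask
    norm = np.clip((pmap.values[sel] - vmin) / (vmax - vmin), 0.0, 1.0)
    rgb[sel] = (np.asarray(cmap(norm))[:, :3] * 255).astype(np.uint8)
    return rgb


def render_map(
    pmap: ParametricMap,
    colormap: str = "jet",
    out: str | Path | None = None,
    reference: np.ndarray | None = None,
    normalization: tuple[float, float] = (0.0, 100.0),
    dpi: int = 150,
):
    """Render the map with an embedded colour bar and save it as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.cm import ScalarMappable
    from matplotlib.colors import Normalize

    rgb = colorize(pmap, colormap, normalization, reference)
    vals = pmap.ok_values()
    vmin, vmax = (np.percentile(vals, normalization) if vals.size else (0.0, 1.0))
    if vmax <= vmin:
        vmax = vmin + 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(rgb)
    ax.set_axis_off()
    sm = ScalarMappable(norm=Normalize(vmin=vmin, vmax=vmax), cmap=colormap)
    cbar = fig.colorbar(sm, ax=ax, fraction=0.046, pad=0.04)
    cbar.set_label(f"{pmap.parameter_name} [intensity/s]"
                   if pmap.parameter_name == "mean_gradient_to_peak"
                   else pmap.parameter_name)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=dpi)
        plt.close(fig)
        return Path(out)
    return fig
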