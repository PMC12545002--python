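"""Synthetic CEUS cineloops and reader-ratings tables with known ground truth.

The simulator emulates a transrectal CEUS bolus study: every pixel follows a
gamma-variate indicator-dilution curve (baseline, wash-in, peak, washout over
>= 120 s), modulated by a static speckle-texture gain, multiplicative frame
noise, and an optional smooth rigid drift.  Lesions are laid out in one of
four spatial archetypes of perfusion discreteness:

* type 1 — a single focal contiguous hyper-perfused disc;
* type 2 — one dominant disc plus a few small satellite foci;
* type 3 — several distinct non-contiguous discs with scattered foci;
* type 4 — numerous small foci scattered diffusely across the gland.

Lesion kinetics default to twice the background peak enhancement over half
the background wash-in interval (a four-fold wash-in gradient), a contrast
chosen for realism, not fitted to any cohort.

Everything is deterministic given the spec's ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .cineloop import Cineloop, RoiMask, elliptical_mask
from .errors import ValidationError
from .readerstats import RatingsTable

__all__ = [
    "BolusModel",
    "LesionComponent",
    "PhantomSpec",
    "GroundTruth",
    "gamma_variate",
    "make_phantom",
    "make_ratings",
    "analytic_start_time",
    "analytic_mean_gradient",
]


@dataclass(frozen=True)
class BolusModel:
    """Gamma-variate bolus-transit kinetics for one tissue compartment.

    The curve is ``baseline`` for t <= t0 and

        baseline + ymax * u**alpha * exp(alpha * (1 - u)),  u = (t - t0)/(tpk - t0)

    afterwards: it peaks at exactly ``baseline + ymax`` at ``t = tpk`` and
    decays smoothly (washout).  ``alpha`` controls how abruptly enhancement
    starts; 1.5 is a typical first-pass bolus shape.
    """

    t0: float = 10.0
    tpk: float = 40.0
    ymax: float = 20.0
    alpha: float = 1.5
    baseline: float = 5.0

    def __post_init__(self) -> None:
        if not (self.tpk > self.t0 >= 0):
            raise ValidationError(f"need tpk > t0 >= 0; got t0={self.t0}, tpk={self.tpk}")
        if self.ymax <= 0 or self.alpha <= 0 or self.baseline < 0:
            raise ValidationError("need ymax > 0, alpha > 0, baseline >= 0")

    @property
    def wash_in_duration(self) -> float:
        return self.tpk - self.t0

    @property
    def mean_gradient(self) -> float:
        """Analytic mean wash-in slope, ymax / (tpk - t0), intensity/s."""
        return self.ymax / self.wash_in_duration


def gamma_variate(t, model: BolusModel):
    """Evaluate the bolus curve at time(s) ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=np.float64)
    u = (t - model.t0) / model.wash_in_duration
    u = np.clip(u, 0.0, None)
    with np.errstate(over="ignore"):
        y = model.baseline + model.ymax * np.power(u, model.alpha) * np.exp(
            model.alpha * (1.0 - u)
        )
    return y if y.ndim else float(y)


def analytic_start_time(model: BolusModel, threshold_frac: float) -> float:
    """Closed-form enhancement-start time: the instant the noiseless curve
    crosses ``baseline + threshold_frac * ymax`` on the way up (root-bracketed
    on the exact curve)."""
    if not 0 < threshold_frac < 1:
        raise ValidationError("threshold_frac must be in (0, 1)")
    target = model.baseline + threshold_frac * model.ymax

    def f(t: float) -> float:
        return gamma_variate(t, model) - target

    return float(optimize.brentq(f, model.t0 + 1e-12, model.tpk, xtol=1e-12))


def analytic_mean_gradient(model: BolusModel, threshold_frac: float) -> float:
    """Closed-form endpoint-quotient wash-in slope:
    (peak - crossing intensity) / (tpk - start time)."""
    ts = analytic_start_time(model, threshold_frac)
    y_start = model.baseline + threshold_frac * model.ymax
    return (model.baseline + model.ymax - y_start) / (model.tpk - ts)


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionComponent:
    """One hyper-perfused disc: centroid (row, col), radius in px, kinetics."""

    center: tuple[float, float]
    radius: float
    model: BolusModel


_DEFAULT_BACKGROUND = BolusModel(t0=10.0, tpk=40.0, ymax=20.0, alpha=1.5, baseline=5.0)
# lesion: double peak enhancement, half wash-in interval -> 4x gradient
_DEFAULT_LESION = BolusModel(t0=10.0, tpk=25.0, ymax=40.0, alpha=1.5, baseline=5.0)

# Base layouts on the 128x128 reference grid (scaled to other shapes);
# (row, col, radius) per component, first entry is the dominant one.
_LAYOUTS: dict[int, list[tuple[float, float, float]]] = {
    1: [(58, 64, 14)],
    2: [(58, 60, 13), (80, 90, 3), (45, 95, 3), (75, 30, 3)],
    3: [(50, 40, 7), (80, 64, 7), (48, 88, 7), (75, 95, 2.5), (70, 30, 2.5)],
    4: [
        (40, 40, 3), (38, 70, 3), (45, 95, 3), (60, 25, 3), (62, 55, 3),
        (60, 85, 3), (64, 105, 3), (82, 40, 3), (85, 70, 3), (80, 95, 3),
    ],
}


@dataclass
class PhantomSpec:
    """Everything needed to synthesize one cineloop deterministically."""

    shape: tuple[int, int] = (128, 128)
    n_frames: int = 240
    frame_interval: float = 0.5
    roi: RoiMask | None = None
    lesion_type: int | None = None  # 1..4 or None for homogeneous gland
    lesion_components: list[LesionComponent] | None = None
    background: BolusModel = field(default_factory=lambda: _DEFAULT_BACKGROUND)
    noise_sigma: float = 0.0
    motion_amplitude: float = 0.0
    texture_sigma: float = 0.05
    jitter: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.frame_interval <= 0:
            raise ValidationError("need n_frames >= 2 and frame_interval > 0")
        if self.noise_sigma < 0 or self.motion_amplitude < 0 or self.texture_sigma < 0:
            raise ValidationError("noise_sigma, motion_amplitude, texture_sigma must be >= 0")
        if self.lesion_type is not None and self.lesion_type not in (1, 2, 3, 4):
            raise ValidationError("lesion_type must be in {1,2,3,4} or None")
        if self.roi is None:
            h, w = self.shape
            self.roi = elliptical_mask(
                self.shape, semi_axes=(0.3125 * h, 0.40625 * w)
            )  # (40, 52) on the 128x128 reference grid


@dataclass
class GroundTruth:
    """Per-pixel analytic truth carried alongside a synthesized cineloop."""

    gradient_map: np.ndarray  # gain * ymax/(tpk-t0) per pixel, intensity/s
    label_image: np.ndarray   # 0 = background, k >= 1 = lesion component id
    lesion_type: int | None
    components: list[LesionComponent]
    background: BolusModel
    shifts: np.ndarray        # (n_frames, 2) applied rigid drift (row, col) px
    gain: np.ndarray          # static texture field


def _layout_components(spec: PhantomSpec, rng: np.random.Generator) -> list[LesionComponent]:
    if spec.lesion_components is not None:
        return list(spec.lesion_components)
    if spec.lesion_type is None:
        return []
    h, w = spec.shape
    sr, sc = h / 128.0, w / 128.0
    comps = []
    for (r, c, rad) in _LAYOUTS[spec.lesion_type]:
        jr, jc = rng.uniform(-spec.jitter, spec.jitter, size=2)
        comps.append(
            LesionComponent(
                center=(r * sr + jr, c * sc + jc),
                radius=rad * min(sr, sc),
                model=_DEFAULT_LESION,
            )
        )
    return comps


def _check_inside_roi(comps: Sequence[LesionComponent], roi: RoiMask) -> None:
    h, w = roi.shape
    for i, comp in enumerate(comps, start=1):
        r0, c0 = comp.center
        for dr, dc in ((comp.radius, 0), (-comp.radius, 0), (0, comp.radius), (0, -comp.radius)):
            rr = int(round(min(max(r0 + dr, 0), h - 1)))
            cc = int(round(min(max(c0 + dc, 0), w - 1)))
            if not roi.mask[rr, cc]:
                raise ValidationError(f"lesion component {i} extends outside the ROI")


def make_phantom(spec: PhantomSpec) -> tuple[Cineloop, RoiMask, GroundTruth]:
    """Synthesize a cineloop, its ROI mask, and the analytic ground truth.

    The noiseless trace of every pixel is exactly its component's (or the
    background's) bolus curve times the pixel's static texture gain; speckle
    is multiplicative Gaussian ``I*(1 + sigma*eps)`` clipped at 0; motion is a
    smooth sinusoidal rigid translation bounded by ``motion_amplitude``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    roi = spec.roi
    assert roi is not None

    comps = _layout_components(spec, rng)
    _check_inside_roi(comps, roi)

    # component label image (later components paint over earlier ones)
    rr, cc = np.mgrid[0:h, 0:w]
    label = np.zeros((h, w), dtype=np.int32)
    for k, comp in enumerate(comps, start=1):
        r0, c0 = comp.center
        label[(rr - r0) ** 2 + (cc - c0) ** 2 <= comp.radius**2] = k

    # per-label curves sampled on the frame grid
    times = np.arange(spec.n_frames, dtype=np.float64) * spec.frame_interval
    models = [spec.background] + [c.model for c in comps]
    curves = np.stack([gamma_variate(times, m) for m in models])  # (K+1, T)
    frames = curves[label]                      # (H, W, T)
    frames = np.ascontiguousarray(np.moveaxis(frames, -1, 0))  # (T, H, W)

    # static speckle texture (tissue property: moves with the tissue);
    # band-limited like real speckle, whose grain size follows the PSF —
    # white noise would decorrelate under subpixel resampling
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
    field /= field.std()
    gain = np.clip(1.0 + spec.texture_sigma * field, 0.1, None)
    frames *= gain[None, :, :]

    # rigid sinusoidal drift
    shifts = np.zeros((spec.n_frames, 2))
    if spec.motion_amplitude > 0:
        phases = rng.uniform(0, 2 * math.pi, size=2)
        tt = times / times[-1]
        shifts[:, 0] = spec.motion_amplitude * np.sin(2 * math.pi * 1.5 * tt + phases[0])
        shifts[:, 1] = spec.motion_amplitude * np.sin(2 * math.pi * 1.0 * tt + phases[1])
        for i in range(spec.n_frames):
            frames[i] = ndimage.shift(frames[i], shifts[i], order=1, mode="nearest")

    # multiplicative speckle noise
    if spec.noise_sigma > 0:
        frames = frames * (1.0 + spec.noise_sigma * rng.standard_normal(frames.shape))
        np.clip(frames, 0.0, None, out=frames)

    ymax_map = np.full((h, w), spec.background.mean_gradient)
    for k, comp in enumerate(comps, start=1):
        ymax_map[label == k] = comp.model.mean_gradient
    gt = GroundTruth(
        gradient_map=gain * ymax_map,
        label_image=label,
        lesion_type=spec.lesion_type,
        components=comps,
        background=spec.background,
        shifts=shifts,
        gain=gain,
    )
    meta = {
        "simulator": "ceustic.synth",
        "seed": spec.seed,
        "lesion_type": spec.lesion_type,
        "noise_sigma": spec.noise_sigma,
        "motion_amplitude": spec.motion_amplitude,
        "duration_s": float(times[-1]),
    }
    loop = Cineloop(frames=frames, times=times, meta=meta)
    return loop, roi, gt


# ---------------------------------------------------------------------------
# reader-ratings simulator
# ---------------------------------------------------------------------------

def make_ratings(
    n_cases: int,
    n_raters: int,
    prevalence: float,
    sens: float | Sequence[float],
    spec: float | Sequence[float],
    seed: int,
    session_label: str = "",
) -> RatingsTable:
    """Simulate a complete cases x raters binary reading session.

    Ground truth is Bernoulli(prevalence); conditionally on truth each
    rater calls malignant with probability ``sens`` (truth malignant) or
    ``1 - spec`` (truth benign), independently across raters and cases.
    ``sens``/``spec`` may be scalars or per-rater sequences.
    """
    if n_cases < 1 or n_raters < 1:
        raise ValidationError("need n_cases >= 1 and n_raters >= 1")
    sens_arr = np.broadcast_to(np.asarray(sens, dtype=float), (n_raters,))
    spec_arr = np.broadcast_to(np.asarray(spec, dtype=float), (n_raters,))
    for name, arr in (("prevalence", np.asarray([prevalence])), ("sens", sens_arr), ("spec", spec_arr)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = (rng.random(n_cases) < prevalence).astype(np.int8)
    p_call = np.where(truth[:, None] == 1, sens_arr[None, :], 1.0 - spec_arr[None, :])
    ratings = (rng.random((n_cases, n_raters)) < p_call).astype(np.int8)
    return RatingsTable(
        case_ids=[f"case_{i:04d}" for i in range(n_cases)],
        truth=truth,
        ratings=ratings,
        session_label=session_label,
    )


def lesion_with(
    spec: PhantomSpec, *, lesion: BolusModel | None = None, background: BolusModel | None = None
) -> PhantomSpec:
    """Convenience: swap kinetics on a spec without rebuilding layouts."""
    out = replace(spec)
    if background is not None:
        out.background = background
    if lesion is not None and spec.lesion_type is not None:
        out.lesion_components = [
            replace(c, model=lesion) for c in _layout_components(spec, np.random.default_rng(spec.seed))
        ]
    return out
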