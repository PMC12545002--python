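"""Reproducible validation experiments on the synthetic simulator.

Each function runs one self-contained study — parameter recovery on
phantoms, motion-trace recovery, discreteness-grade recovery, Monte-Carlo
reader simulations, null calibration of the tests — and returns plain
numbers.  They power the acceptance checks and are handy for sensitivity
analyses when tuning the pipeline.
"""

from __future__ import annotations

import numpy as np

from .discreteness import grade_map
from .motion import estimate_motion
from .readerstats import TrendTable, cochran_armitage, diagnostic_metrics, mcnemar
from .synth import PhantomSpec, analytic_mean_gradient, make_phantom, make_ratings
from .ticmap import QUALITY_OK, compute_map

__all__ = [
    "gradient_recovery_errors",
    "motion_recovery_errors",
    "discreteness_recovery",
    "pooled_auc_simulation",
    "null_calibration",
]


def gradient_recovery_errors(
    noise_sigma: float,
    seed: int,
    threshold_frac: float = 0.05,
    lesion_type: int | None = 1,
) -> dict[str, float]:
    """Pixel-wise relative error of the wash-in gradient map against the
    closed-form oracle on a motionless phantom (240 frames at 0.5 s,
    128 x 128)."""
    spec = PhantomSpec(lesion_type=lesion_type, noise_sigma=noise_sigma,
                       texture_sigma=0.0, seed=seed)
    loop, roi, gt = make_phantom(spec)
    pmap = compute_map(loop, roi)
    sel = (pmap.quality == QUALITY_OK) & roi.mask
    grads = {0: analytic_mean_gradient(gt.background, threshold_frac)}
    for k, comp in enumerate(gt.components, start=1):
        grads[k] = analytic_mean_gradient(comp.model, threshold_frac)
    oracle = np.vectorize(grads.get)(gt.label_image)
    rel = np.abs(pmap.values[sel] - oracle[sel]) / oracle[sel]
    return {
        "max_rel_err": float(rel.max()),
        "mean_rel_err": float(rel.mean()),
        "median_rel_err": float(np.median(rel)),
        "n_pixels": int(sel.sum()),
    }


def motion_recovery_errors(seed: int, n_frames: int = 120) -> dict[str, float]:
    """Shift-recovery errors: exactness on injected integer shifts and the
    max error on a 3 px sinusoidal subpixel drift."""
    # integer shifts on a repeated textured frame
    spec = PhantomSpec(shape=(64, 64), n_frames=20, noise_sigma=0.0,
                       texture_sigma=0.1, lesion_type=1, seed=seed)
    loop, _, _ = make_phantom(spec)
    ref = loop.frames[10]
    frames = np.stack([ref] + [np.roll(ref, (2, -3), axis=(0, 1))] * 5)
    from .cineloop import Cineloop
    still = Cineloop(frames=frames, times=np.arange(6.0))
    tr = estimate_motion(still, reference_index=0, max_shift=5, subpixel=False)
    integer_err = float(np.abs(tr.shifts[1:] - np.array([2.0, -3.0])).max())

    # sinusoidal subpixel drift (relative shift can reach 2x the amplitude)
    spec = PhantomSpec(noise_sigma=0.05, texture_sigma=0.1, lesion_type=1,
                       seed=seed, motion_amplitude=3.0, n_frames=n_frames)
    loop, _, gt = make_phantom(spec)
    tr = estimate_motion(loop, max_shift=8, subpixel=True)
    rel_truth = gt.shifts - gt.shifts[tr.reference_index]
    subpixel_err = float(np.abs(tr.shifts - rel_truth).max())
    return {"integer_max_err_px": integer_err, "subpixel_max_err_px": subpixel_err,
            "n_frames": n_frames}


def discreteness_recovery(
    n_seeds: int = 50,
    noise_sigma: float = 0.1,
    seed0: int = 0,
    threshold_method: str = "otsu",
) -> dict[int, float]:
    """Fraction of seeded phantoms per archetype assigned their true grade."""
    rates: dict[int, float] = {}
    for lesion_type in (1, 2, 3, 4):
        hits = 0
        for s in range(n_seeds):
            spec = PhantomSpec(lesion_type=lesion_type, noise_sigma=noise_sigma,
                               seed=seed0 + s)
            loop, roi, _ = make_phantom(spec)
            pmap = compute_map(loop, roi)
            result = grade_map(pmap, threshold_method=threshold_method)
            hits += int(result.grade == lesion_type)
        rates[lesion_type] = hits / n_seeds
    return rates


def pooled_auc_simulation(
    sens: float, spec: float, n_cases: int = 620, n_raters: int = 4,
    prevalence: float = 11 / 62, seed: int = 0,
) -> float:
    """Pooled single-operating-point AUC of a simulated reading session."""
    tab = make_ratings(n_cases, n_raters, prevalence, sens, spec, seed=seed)
    calls, truth = tab.pooled_calls()
    return diagnostic_metrics(calls, truth).auc.value


def null_calibration(n_tables: int = 2000, seed: int = 0) -> dict[str, float]:
    """Empirical type-I error of McNemar and Cochran-Armitage at alpha=5%
    under their nulls (independent binary pairs; no grade-outcome trend)."""
    rej_mc = rej_ca = n_ca = 0
    for i in range(n_tables):
        rng = np.random.default_rng(seed + i)
        x = rng.integers(0, 2, 100)
        y = rng.integers(0, 2, 100)
        if mcnemar(x, y, method="asymptotic").p < 0.05:
            rej_mc += 1
        grades = rng.integers(1, 5, 200)
        truth = rng.integers(0, 2, 200)
        counts = np.zeros((2, 4), dtype=int)
        for g, t in zip(grades, truth):
            counts[t, g - 1] += 1
        res = cochran_armitage(TrendTable(counts))
        if not res.degenerate:
            n_ca += 1
            rej_ca += int(res.p < 0.05)
    return {"mcnemar_rate": rej_mc / n_tables, "cochran_armitage_rate": rej_ca / max(n_ca, 1)}
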