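# ceustic

Pixel-wise time-intensity-curve (TIC) parametric imaging for
contrast-enhanced ultrasound (CEUS), with the multi-reader statistics needed
to evaluate it as a diagnostic adjunct.

## The problem

Transrectal CEUS records the transit of a microbubble bolus through the
prostate as a cineloop — a stack of intensity frames over ≥ 120 s.
Conventional quantitative CEUS analyses a single hand-placed region of
interest, which is subjective and blind to the spatial heterogeneity that
distinguishes the chaotic neovasculature of carcinoma from the organised
perfusion of benign tissue.  `ceustic` instead analyses **every pixel** of
the gland:

1. **Motion correction** — each frame is registered to a reference frame by
   normalized cross-correlation over rigid translations (subpixel refined),
   so a pixel tracks one anatomical location.
2. **Pixel-wise TICs** — each in-ROI pixel's intensity trace *y(t)* is
   smoothed and its landmarks detected: baseline, enhancement start
   *t*<sub>start</sub> (first crossing of
   baseline + θ·(y<sub>peak</sub> − baseline), θ = 0.05 by default), and
   peak (*t*<sub>peak</sub>, *y*<sub>peak</sub>).
3. **Mean gradient to peak** — the headline perfusion parameter, the average
   wash-in slope

   &nbsp;&nbsp;&nbsp;&nbsp;*g* = (*y*<sub>peak</sub> − *y*(*t*<sub>start</sub>)) / (*t*<sub>peak</sub> − *t*<sub>start</sub>)&nbsp;&nbsp;[intensity/s],

   rendered as a colour-coded parametric map (cool = slow, hot = rapid
   perfusion).
4. **Discreteness grading** — the hot (hyper-perfused) regions are
   segmented and the spatial pattern is graded on an ordinal four-tier
   scale, from Type 1 (a single focal hot area) to Type 4 (numerous foci
   scattered across the gland), via an explicit, auditable decision rule on
   connected-component features.
5. **Reader-study statistics** — ICC(A,1)/(A,k) (two-way random effects,
   absolute agreement), Fleiss' and Cohen's kappa, McNemar's paired test,
   the Cochran-Armitage trend test, operating-point metrics with exact
   Clopper-Pearson intervals, Youden's J, and Mann-Whitney AUC with DeLong
   variance and paired-AUC comparison.  For binary calls the AUC reduces
   exactly to (Se + Sp)/2.

A seeded simulator (`ceustic.synth`) generates bolus-transit phantoms with
gamma-variate kinetics, speckle texture and noise, rigid drift, and all four
spatial archetypes — so the whole pipeline is testable with known ground
truth and no data download.

## Worked example

`examples/01_simulate_and_map.py` synthesizes a phantom with one
hyper-perfused lesion (4× the background wash-in gradient) and recovers it:

```text
cineloop: 240 frames of (128, 128), 120 s of contrast transit, ROI 6532 px
mean wash-in gradient: lesion 2.69, background 0.69 intensity/s
lesion/background ratio 3.90 (simulated kinetics: x4)
median relative error vs analytic ground truth: 8.0%
colour-coded map written to parametric_map.png (cool = slow perfusion, hot = rapid)
```

The recovered lesion/background contrast (3.90) matches the simulated 4×
kinetic ratio; the per-pixel error reflects the 5% speckle noise.
`examples/03_discreteness_grading.py` grades all four archetypes:

```text
simulated type 1: graded 1 (1 hot components, dominant fraction 1.00, dispersion 0.00)
simulated type 2: graded 2 (4 hot components, dominant fraction 0.86, dispersion 0.53)
simulated type 3: graded 3 (5 hot components, dominant fraction 0.31, dispersion 0.48)
simulated type 4: graded 4 (10 hot components, dominant fraction 0.10, dispersion 0.47)
```

and `examples/04_reader_study.py` simulates a paired crossover reading of 62
cases by four readers, unassisted (Se 0.20 / Sp 0.65) versus map-assisted
(Se 0.94 / Sp 0.79):

```text
unassisted: pooled AUC 0.407 (95% CI 0.346-0.467), Se 0.11, Sp 0.70, ICC 0.018
assisted  : pooled AUC 0.903 (95% CI 0.877-0.930), Se 1.00, Sp 0.81, ICC 0.346
McNemar on correctness, assisted vs not: b=0 c=54 p=2.00e-13
```

There is also a thin CLI: `ceustic simulate | motion | ticmap | classify |
reader-stats | run` (see `ceustic run --help` for the end-to-end pipeline,
which writes the map, its PNG rendering, the grade report and a manifest).

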