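# Methods

## Model

The pseudophakic eye is a two-surface thin-lens system: an effective corneal
power Z (D) at the corneal vertex and a thin IOL at the effective lens
position ELP (mm), in aqueous of index 1.336 (the literal 1336 numerator
with distances in mm). The IOL power that focuses a distant object on the
retina is

    P = 1336/(AL - ELP) - 1336/(1336/Z - ELP),

with ELP = a0 + a1·ACD + a2·AL (Haigis; ULIB ZCB00 constants by default).
A nonzero target refraction is handled by adding its corneal-plane vergence
to Z; with a plano target this reduces bit-exactly to the formula above.
Refractions move between spectacle and corneal planes through
REFc = 1000·REFs/(1000 - REFs·VD), VD = 12 mm.

Predicted refraction for a given implanted power is the closed-form
inversion: the vergence the cornea must deliver is A = 1336/(AL - ELP) - P;
the corneal power delivering it is z_req = 1336/(1336/A + ELP); the
predicted refraction is z_req - Z back-transformed to the spectacle plane.
The forward/inverse pair round-trips to below 1e-9 D across the clinical
grid (AL 22–34 mm, ELP 4–7.5 mm, Z 28–48 D, targets -3 to +1 D).

Three corneal powers define the formula variants:

* **haigis** — keratometric power (n - 1)·1000/r with n = 1.3315 (Haigis
  convention, configurable). Biased on post-ablation corneas; kept as the
  baseline comparator.
* **haigis-l** — Z = -5.6125·r + 82.2603 - 0.35. The regression corrects
  the radius and index errors on post-myopic-laser corneas; the -0.35 D
  offset compensates residual lens-position error and is kept inside the
  corneal power, as specified, not applied to the final refraction.
* **modified-haigis-l** — Z' = Z - REFc(0.583·SA8 - 2.3488). The expected
  prediction error is subtracted at the *corneal* plane (not from the
  predicted refraction at the spectacle plane); the two differ by the
  nonlinearity of the vertex transform and the corneal-plane form is the
  one implemented. Prediction error is defined as observed postoperative
  spherical equivalent minus predicted, so a positive expected error
  (hyperopic surprise) lowers Z' and raises the computed power.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| a0, a1, a2 | -1.302, 0.210, 0.251 | —, /mm, /mm | ELP regression (ZCB00, ULIB) |
| vertex distance | 12.0 | mm | spectacle↔corneal transform |
| keratometric index | 1.3315 | — | baseline Haigis corneal power only |
| PE slope, intercept | 0.583, -2.3488 | D/µm, D | SA error model (training-cohort fit) |
| residual SD | 0.45 | D | generator noise after the SA trend |

IOL power is treated as continuous throughout evaluation (the quantity of
interest is the error of the actually implanted power); a 0.5 D rounding
step exists only as a CLI display option.

## Calibration

Recalibration computes the Haigis-L prediction error per eye via the full
prediction pipeline and fits ordinary least squares of PE on SA8
(scipy.stats.linregress; cross-checked in tests against a direct
normal-equations solve). Pearson screening of all candidate predictors (AL,
ACD, r, Q and eccentricity at 6/8 mm, SA6, SA8) uses two-sided t p-values
on n-2 df; degenerate predictors are flagged per row rather than aborting
the screen. Only the single-predictor SA8 model is fitted — multivariable
or regularized alternatives are out of scope. Training/test splitting is
the caller's responsibility.

## Synthetic cohorts

The generator emulates the published training cohort: each biometric
variable is an independent Gaussian with the published mean/SD, truncated
to the published range by rejection resampling (clipping would create
boundary atoms). Per eye, the implanted power is the continuous Haigis-L
power for the target refraction (plano by default — per-case surgical
targets were not published); the true prediction error is the SA regression
plus N(0, 0.45) noise; and the observed outcome is the Haigis-L predicted
refraction plus that error. Each variable draws from its own substream of
the root seed, so adding a variable never perturbs the others, and
identical (params, seed) give bit-identical cohorts.

What the generator does *not* emulate: correlations between biometric
variables (only marginals are published), device measurement noise, real
targets other than plano, and any non-Gaussian or nonlinear error
structure. Passing tests therefore demonstrate internal consistency of the
method and faithful recovery of a known generative truth — not clinical
accuracy on real eyes.

## Simulation sizes and numerical choices

The recovery experiment uses 200 replicates of n = 80 eyes (the training-
cohort size), with SA8 untruncated so closed-form Gaussian expectations
apply to the replicate means; it runs in a few seconds. The published
summaries are mutually consistent under this model: the SA-trend SD is
0.583·0.87 ≈ 0.507 and sqrt(0.68² - 0.45²) ≈ 0.510.

Quantiles interpolate linearly between order statistics (type 7); SDs are
n-1 sample SDs; the %-within thresholds are inclusive at the boundary
(neither convention is fixed by the source material, so the common ones are
used). Vergence denominators within 1e-9 of zero raise a singular-vergence
error instead of returning huge powers; a lens plane at or beyond the
retina raises a geometry error. Sample SD of a singleton is reported as
NaN, not an exception.

One knowingly preserved inconsistency: the published regression line does
not pass through the published means (0.583·3.69 - 2.3488 = -0.198, while
the reported Haigis-L mean error is -0.05; an OLS line must pass through
the means, so those three numbers cannot all be exact). The package uses
the published coefficients verbatim and does not arbitrate; consequently
the Haigis-L mean error is not a simulation target, and the simulated
Haigis-L MAE sits slightly above the reported 0.55 D.

## Limitations

Thin-lens optics only: no thick-lens or ray-tracing model, no toric or
astigmatic vergence. Comparator formulas with unpublished internals
(Barrett True-K, Shammas-PL) are out of scope. The error model is a single
linear term in SA8 fitted on post-myopic-ablation eyes; it has no validity
for virgin or post-hyperopic-ablation corneas.
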