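# haigisl

Intraocular-lens (IOL) power calculation for eyes that previously underwent
myopic laser refractive surgery (LASIK/PRK), for ophthalmic biometry
researchers and formula developers.

After myopic ablation the cornea becomes oblate: standard keratometry
overestimates corneal power, so standard IOL formulas underestimate the
implant and leave patients hyperopic. The Haigis-L approach replaces the
keratometric power with a regression on the measured anterior radius r (mm):

    Z = -5.6125 r + 82.2603 - 0.35      (effective corneal power, D)

and feeds it to the Haigis thin-lens formula with effective lens position
ELP = a0 + a1·ACD + a2·AL (ULIB ZCB00 constants a0 = -1.302, a1 = 0.210,
a2 = 0.251):

    P = 1336/(AL - ELP) - 1336/(1336/Z - ELP)

This package additionally implements a *modified* Haigis-L formula: the
residual prediction error of Haigis-L correlates strongly with the
anterior-corneal spherical aberration over the 8.0 mm zone (SA8, µm), a
proxy for the ablation magnitude. The expected error

    PE = 0.583 · SA8 - 2.3488           (D, spectacle plane)

is moved to the corneal plane with the vertex transform
REFc = 1000·REFs/(1000 - REFs·VD), VD = 12 mm, and subtracted from Z:

    Z' = Z - REFc(PE)

The package provides the vergence optics, the three formula variants,
prediction-error metrics (ME, MAE, medians, IQR, %-within bands),
recalibration of the error regression from a cohort, and a synthetic-cohort
generator matching the published training-set biometry, so the whole
pipeline is testable without patient data.

## Worked example

```sh
python examples/calc_one_eye.py
```

```
Eye: AL 28.43 mm, ACD 3.62 mm, r 8.79 mm, SA8 3.69 um
formula               corneal power Z  IOL power (plano)
haigis                        37.71 D            14.84 D
haigis-l                      32.58 D            22.37 D
modified-haigis-l             32.77 D            22.09 D
```

For this training-cohort mean eye the raw keratometric power (37.71 D)
is far too high for a post-ablation cornea and would select a 14.84 D
implant — about 7.5 D too weak, a large hyperopic surprise. Haigis-L
corrects the corneal power down to 32.58 D (implant 22.37 D); at
SA8 = 3.69 µm the error model expects a small myopic surprise (-0.20 D),
so the modified formula raises Z' slightly and trims the implant to
22.09 D.

The same numbers are available from the shell:

```sh
haigisl calc --al 28.43 --acd 3.62 --r 8.79 --sa8 3.69 --formula modified-haigis-l
```

Other entry points: `haigisl simulate` writes a synthetic cohort CSV,
`haigisl calibrate` refits the error regression on a cohort,
`haigisl evaluate` prints the formula-comparison error report. The
`examples/` scripts show the same capabilities from Python.

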