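# discsignal

Quantitative T2-weighted MRI profiling of intervertebral discs.

Visual gradings of disc degeneration (e.g. Pfirrmann) are too coarse to
detect early, sub-clinical changes such as the nucleus dehydration seen in
athletes under high repetitive axial load.  `discsignal` implements a
data-driven alternative: from a sagittal T2-weighted volume and a
multi-label segmentation (one label per disc T1-T2 … L5-S1, one for
cerebrospinal fluid), it extracts CSF-normalized signal means over
anterior–posterior disc subregions and compares groups per disc level with
a mixed model.  It is aimed at researchers running case–control spine
studies (here: elite climbers vs matched controls) on segmentations
produced by tools such as TotalSpineSeg; the package also ships a synthetic
spine-phantom generator so the entire analysis can be developed and
validated without patient data.

## Method

Per subject and disc:

1. **Midsagittal selection** — a disc spanning E sagittal slices
   contributes its 3 (E odd) or 4 (E even) central slices.
2. **CSF normalization** — every voxel is divided by the mean raw signal
   over the CSF mask of the same image, removing scanner scaling:
   after normalization CSF ≡ 1 and disc values are dimensionless.
3. **AP subregioning** — in each selected slice, disc voxels are projected
   onto the disc's anterior–posterior axis (per-slice principal axis by
   default) and split into equal-width bins: coarse (5, anterior = 1 …
   posterior = 5) and fine (25, nested in the coarse bins).  Bins 2–4
   cover the nucleus pulposus, bins 1 and 5 the annulus fibrosus.
4. **Statistics** — mean and SD of normalized signal per bin and for the
   whole selected region; group profiles as median (IQR) across subjects
   per fine bin.

Group comparison uses the Gaussian linear mixed model

```
mean_signal ~ group + disc + group:disc + (1 | subject)
```

fitted by REML (statsmodels), whose random subject intercept plus iid
residual induces a compound-symmetry within-subject covariance.  Least
squares means per (group, disc), the control − climber difference, 95%
confidence limits and p-values are produced per disc level ("sliced"
comparisons), either for whole-disc means or per coarse subregion (one
model per subregion).  Degrees of freedom use a Satterthwaite
approximation computed from the REML profile likelihood (see
`docs/methods.md`); it matches `lmerTest`/`emmeans` to four decimals in
the test suite.

## Worked example

```
discsignal simulate --out demo/cohort --seed 7 --n 15 15
discsignal extract  --manifest demo/cohort/manifest.csv --out demo/profiles
discsignal stats    --tables demo/profiles --out demo/stats
```

The simulated cohort injects the default group-effect template — a
climber signal loss concentrated in nucleus bins 2–4 of the six
thoracolumbar discs T10-T11 … L3-L4.  The `stats` step prints

```
6/17 whole-disc contrasts significant at alpha=0.05
```

and `demo/stats/contrasts_whole_disc.csv` contains, around the
thoracolumbar junction (seed 7):

```
   disc  lsmean_climbers  lsmean_controls  difference  ci_low  ci_high       p_value
 T9-T10           0.3305           0.3331      0.0025 -0.0183   0.0234  8.1e-01
T10-T11           0.2677           0.3341      0.0665  0.0456   0.0873  3.7e-07
T11-T12           0.2307           0.3334      0.1027  0.0818   0.1235  5.1e-11
 T12-L1           0.2646           0.3419      0.0772  0.0564   0.0980  2.2e-08
  L1-L2           0.2473           0.3394      0.0921  0.0712   0.1129  5.8e-10
  L4-L5           0.3428           0.3416     -0.0012 -0.0220   0.0197  9.1e-01
```

Positive differences mean controls > climbers.  The six significant discs
are exactly the six that received an injected effect; the per-subregion
table localizes all 18 significant cells to bins 2–4 of those discs, e.g.
at L1-L2 the estimated differences 0.1225, 0.1344, 0.1251 (bins 2–4)
recover the injected 0.12, 0.13, 0.12.  `demo/profiles/group_profiles_25.csv`
holds the median (IQR) AP profiles behind the
`discsignal report` profile plot, and forest-plot PNGs are written next to
the contrast tables.

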