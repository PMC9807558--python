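# Methods

This note documents the models implemented in `pedci`, the assumptions they
make, the defaults they ship with, and what the synthetic test bed does and
does not establish.

## Tissue model

The classifier rests on three OCT signatures of sub-RPE material:

* **serous fluid** — hyporeflective and uniform;
* **neovascular tissue** — mid-reflective with high local heterogeneity:
  hyporeflective vascular pockets embedded in a hyperreflective matrix;
* **fibrous scar** — uniformly hyperreflective (collagen).

Raw intensity alone cannot separate neovascular from fibrous tissue (their
intensity distributions overlap), which is why the cascade scores each pixel
by intensity *penalized by local heterogeneity*.

## Pre-processing

**Normalization.** Each scan is min–max normalized to [0, 1] per image.
Scanner exports vary in brightness and bit depth; per-image normalization
makes the downstream thresholds comparable across scans. A constant image
maps to all zeros.

**Shadow compensation.** Overlying vessels and fluid attenuate the OCT beam
and darken everything beneath them. The compensation divides each pixel at
depth z by twice the residual signal energy below it in its own A-scan,
`2·Σ_{z'≥z} I(z')^e + ε`, with contrast exponent `e` (default 2) and
`ε = 1e-8`. Because the factor depends only on the column at and below the
pixel, two columns identical below a depth receive identical compensated
values there, whatever sits above — that is the shadow-removal property. Two
caveats are inherent to this family of methods and documented rather than
hidden:

* a pure multiplicative attenuation `s` of a whole column is rescaled by
  `s^(1-e)`; `e = 1` cancels it exactly, `e = 2` over-corrects while boosting
  contrast (the default follows the contrast-enhancing convention);
* the factor diverges near the bottom of the scan as the residual energy
  vanishes. Renormalization therefore clips at the 99.5th percentile before
  the linear rescale to [0, 1], so a thin band of blown-up bottom pixels
  cannot compress the retina's dynamic range.

Compensation reweights intensities by depth, so the gate thresholds below
must be tuned on compensated images if compensation is enabled. The phantom
experiments run on normalization alone: phantoms carry no shadows by default,
and this keeps their intensities on the scale the thresholds refer to.

## The scarring-likelihood cascade

On the PED's padded bounding box:

| stage | definition | role |
| --- | --- | --- |
| I1 | AVG(I0, 7) | local mean |
| I2 | STD(I0, 7) | local sample SD (n−1) |
| I3 | I2 / (I1 + ε) | local coefficient of variation |
| I4 | I0 − I3 | intensity penalized by heterogeneity |
| I5 | AVG(I4, 11) | aggregation |
| I6 | AVG(I0, 9) | serous-gate statistic |
| I7 | 0 if I6 < G_T1, else clip(I5, 0, 1) | scarring likelihood |

Numerical choices:

* **Borders.** All filters mirror-reflect (edge pixel not repeated). The
  region is the mask's bounding box extended by `pad` on all sides, filled
  with true image content where available and mirror reflection where the
  image ends. Default `pad = 8` = 5 (half-width of the 11×11 stage) + 3 (the
  7×7 context that stage's input consumes), so every in-mask value of I5 is
  computed from real neighborhood content rather than from the reflection of
  an already-filtered stage; `pad` remains an argument with the hard floor 5.
* **ε in I3.** The division I2/I1 is undefined on all-zero windows. Such
  windows belong to serous regions that the gate sets to 0 anyway; ε = 1e-8
  only keeps intermediates finite and shifts nothing else materially.
* **Clipping.** I4 = I0 − I3 can be negative and I5 can leave [0, 1]; the
  likelihood is defined as clip(I5, 0, 1). A consequence worth knowing: a
  strongly heterogeneous region can clip to *exactly* 0 and be labeled
  serous even though the gate did not fire. This is a property of the method
  itself — heterogeneity so high that it swamps brightness is treated as
  non-scar — and it bounds how much texture contrast the neovascular class
  tolerates (see phantom section).
* **Gate tie.** I6 exactly equal to G_T1 takes the non-serous branch.
* **Standard deviation.** Sample (n−1) convention; the std filter is
  computed from window moments after centering the grid on its global mean,
  which keeps the m2 − m1² cancellation error far below the 1e-10 oracle
  tolerance used in the tests.

## Classification and indices

* serous: I7 = 0; neovascular: 0 < I7 < G_T2; fibrous: I7 ≥ G_T2. The tie at
  G_T2 is fibrous by default (`tie_break="neovascular"` flips it).
* PEDCI-S/N/F are pixel-count fractions of the mask; they sum to 1 exactly
  as rationals. Areas in mm² are count × axial scale × transverse scale.
* The size gate measures the mask's bounding box (not polygon extremes)
  against the 100 µm minimum in both directions, with ≥ as inclusion.
* Cohort summaries report absolute areas over present-only eyes (a component
  is "present" when its count is positive, with no minimum blob size) and
  indices over all eyes, mean ± sample SD plus median/range.

**Thresholds.** `G_T1 = 0.25` and `G_T2 = 0.6` are configuration defaults.
G_T2 = 0.6 mirrors the boundary between the documented likelihood bands
(low-intermediate vs high). G_T1 has no published value; 0.25 sits between
the serous level and the neovascular band on normalized scans and should be
re-tuned for other scanners, export pipelines, or when shadow compensation
is enabled. `sweep_thresholds` exists for exactly that tuning loop: it
evaluates a (G_T1, G_T2) grid against phantom ground truth and reports the
error-minimizing row, leaving the choice to the user.

## Baselines

Both baselines see only the processed image, never the likelihood map, so
comparisons are between genuinely different methods.

* **Multi-Otsu**: two thresholds maximizing between-class variance of the
  in-mask histogram (256 bins by default), classes mapped by ascending
  intensity. The search runs in extended precision with cancellation-free
  segment sums because realistic mixtures produce threshold pairs whose
  objectives tie to ~1e-16 — including *exact* rational ties, where the
  returned pair is one of several equally optimal answers.
* **K-means** (k = 3) on (intensity, 7×7 local SD), k-means++ seeded
  initialization, plain Lloyd iterations with the inertia trajectory
  recorded (it is non-increasing by construction and tested), empty-cluster
  restarts (≤ 5), clusters relabeled by ascending mean intensity.

## Agreement statistics

Grades are 0–100 scores per image × grader × timepoint × category, with
absent tissue ungraded (missing); missing rows are dropped listwise per
category.

* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measurement — from the ANOVA mean squares:
  `ICC = (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`.
  Absolute agreement is the right model when graders should be
  interchangeable. Variance components are truncated at 0 for reporting; a
  negative ICC is reported as computed, with a warning; zero total variance
  reports ICC 1 with a warning.
* **Repeatability**: per grader, measurements = the two timepoints.
  **Reproducibility**: measurements = graders, each grader's timepoints
  averaged first (`average_timepoints=False` uses timepoint 1 only — the
  design is not uniquely determined by convention, so both are available).
* **Bland–Altman** limits are mean difference ± 2 × sample SD — exactly 2,
  not 1.96.

## The synthetic phantom

The generator emulates what the classifier keys on: a parabolic-dome PED
under a bright RPE line and mid-intensity retina band, over a choroid-like
background (0.35), with per-compartment textures:

| compartment | mean | target local CV (7×7) | texture |
| --- | --- | --- | --- |
| serous | 0.05 | 0.10 | gamma speckle |
| neovascular | 0.55 | 0.50 | dark pockets + gamma speckle |
| fibrous | 0.85 | 0.05 | gamma speckle |

* **Speckle** is multiplicative gamma noise with shape 1/CV² (mean 1) — the
  standard controllable-CV surrogate for OCT speckle.
* **Neovascular pockets** are radius-1 dark disks on a jittered 3×3 grid
  (stratified sampling; expected coverage = `pocket_fraction`, default 5/9).
  Stratification rather than pure Poisson placement is deliberate: Poisson
  clumping makes the local CV swing so widely that the cascade's aggregated
  score dips below zero over whole patches, which misrepresents tissue-scale
  heterogeneity as compartment-scale structure. The matrix/pocket contrast is
  solved from the *realized* coverage so the compartment mean equals its
  level exactly and the combined variance hits the CV target (realized CV is
  within a few percent of target; the tests allow 20%).
* **Determinism.** A fixed seed reproduces the image bit-for-bit; different
  seeds change speckle but not the truth labels. With all speckle CVs set to
  0 the phantom is fully deterministic: pockets sit at cell centers, and the
  pipeline then classifies compartment interiors (≥ 6 px from boundaries)
  essentially perfectly (100% serous/fibrous, ≥ 99% neovascular).
* **Shadows** multiply whole columns by an attenuation factor.
* **Margins.** At CV 0.5 the neovascular expectation of I5 is only
  `0.55 − 0.5 = 0.05`, so a few percent of speckled neovascular pixels clip
  to 0 even away from boundaries; together with boundary mixing this puts
  default-phantom recovery at ≈ 0.91 accuracy and ≤ 0.06 per-index error
  (seed 0). The constructed endpoint phantoms (`endpoint_phantom_result`)
  use milder neovascular contrast (CV 0.3) precisely so their premises — no
  clipped zeros, no fibrous-band pixel — hold with margin, and those premises
  are *verified at run time* on the computed likelihood map.

**What phantom results do not show.** The phantom has no point-spread
function, no depth-dependent sensitivity roll-off, no drusen, no real
speckle statistics, and compartments with crisp vertical boundaries. Passing
recovery tests demonstrates the pipeline implements its definition and
separates the modeled signatures; it does not validate clinical accuracy on
patient scans, which the grading-agreement machinery exists to assess.

## Problem sizes

The default phantom is a 240×360 canvas with a 300×110 px dome
(≈ 22,000 PED pixels), chosen so compartment-boundary pixels — the known
error source — are a small fraction of the mask while the whole suite and
the acceptance script run in seconds. Smaller domes behave identically up to
a larger boundary share.

## Known limitations

* G_T1/G_T2 are scanner- and pipeline-dependent; defaults are calibrated to
  the normalized phantom scale, not to any particular device.
* The cascade subtracts a dimensionless CV from an intensity (I4 = I0 − I3);
  the two are on different scales, and the method inherits whatever balance
  that implies. It is implemented literally.
* Energy-based shadow compensation over-corrects pure attenuations at the
  default exponent and is unreliable in the bottom rows of a scan.
* Rasterization uses pixel-center inclusion with boundary ties inside; other
  tools (e.g. ImageJ's fill) may differ by a boundary pixel ring.
* The ImageJ ROI codec reads/writes integer-coordinate polygon ROIs only.
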