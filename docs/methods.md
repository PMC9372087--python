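# Methods

This note documents the models, conventions and numerical choices behind
`contoureval`, in the order the pipeline applies them.

## Data model and coordinate conventions

Volumes are 3D scalar lattices indexed `(x, y, z)` with anisotropic
spacing in mm; the physical position of voxel `(i, j, k)` is
`origin + index·spacing` (voxel-center convention, 0-based). Dose is in
cGy throughout. Structures are binary masks sharing one grid; a
structure set tags its provenance (`manual` or `auto`). File IO covers
NIfTI and NRRD through SimpleITK; direction matrices other than identity
are not supported. When dose and mask lattices differ, dose is
resampled trilinearly onto the mask grid (never the reverse, so
structure boundaries are preserved exactly); voxels outside the source
extent are filled with 0 and a warning is issued. Masks use
nearest-neighbour resampling and stay binary.

## Geometric metrics

DSC and JC are voxel-count ratios and therefore exact. Surface
distances need two conventions, both chosen to make an exhaustive
all-pairs oracle bit-comparable:

* **Surface** — a foreground voxel with at least one background
  6-neighbour; the volume border counts as background. Surface points
  are voxel centers in physical mm, so a 5 mm slice spacing contributes
  5 mm steps, not 1.
* **Percentile Hausdorff** — for each direction, the p-th percentile
  (numpy linear interpolation between order statistics) of the
  distribution of nearest-surface distances; the symmetric value is the
  larger of the two directed values, and p = 100 reproduces the classic
  HD. 95%HD is the robust variant reported for segmentation quality.

Distances are computed with a KD-tree over surface points; tests check
exact equality against a brute-force all-pairs oracle. Comparing two
empty masks raises rather than returning a conventional value, and
whole masks are always compared — no cropping of superior/inferior
borders.

## Dose–volume histogram and indices

The cumulative DVH is exact at its edges: `cum(d) = 100 · fraction of
structure voxels with dose ≥ d`, with 1 cGy default bin width — fine
enough that interpolation error is far below 1 cGy at a ~5000 cGy
prescription. `D_x%` / `D_x cc` is read off the curve as the largest
dose at which the cumulative volume still reaches the request (linear
interpolation); `V_d` interpolates the curve at `d`, with percent-of-
prescription specs resolved through the plan. `D_mean` and `D_max` are
computed on raw voxel doses, not the binned curve; `D_max` is the
literal maximum, kept separate from `D_0.03cc`. Binary in/out voxel
membership is used — no partial-volume weighting — matching the binary
mask model.

The paired evaluation computes, for each structure, its index of record
(CTV: D_mean and V_100; spinal cord: D_max; kidneys, bladder, femoral
heads, pelvic bone, rectum: D_mean) plus every constrained quantity,
for both contour sets against the *same* dose grid. The plan is never
re-optimized for auto contours; this transmit-into-original-plan
protocol is enforced structurally (the dose grid is an input computed
from the manual set only).

Default plan: 5040 cGy in 28 fractions (1.8 Gy/fraction), the upper end
of the 45–50.4 Gy prescription range conventional for definitive pelvic
EBRT. The constraint set covers the target (D_99% > prescription,
D_max < 110%) and the standard OAR limits (cord D_max < 4000 cGy,
kidney D_mean < 1200 cGy, bladder/rectum D_50% < prescription and
D_0.03cc < 110%, femoral head D_15% < 3000 cGy and D_mean < 2000 cGy,
pelvic bone D_mean < 3000 cGy). Small intestine is not modelled or
evaluated.

## Statistics

* **Wilcoxon paired signed-rank** — zero differences dropped, tied
  absolute differences mid-ranked. Exact null enumeration when ≤ 25
  tie-free nonzero pairs, otherwise the normal approximation with
  continuity correction (the signed Z reported in summary tables always
  comes from the corrected normal form). α = 0.05 two-sided. Fewer than
  5 nonzero differences is an error at the API level; the pipeline
  records such cells as not-testable instead of failing.
* **Bland–Altman** — bias = mean(auto − manual), limits of agreement
  bias ± 1.96·SD (sample SD, n−1). The agreement P is a two-sided
  one-sample t-test of zero mean difference, gated by a Shapiro–Wilk
  normality pre-check at α = 0.05: clearly non-normal differences are
  reported but marked not-applicable, since the parametric P is then
  meaningless. Zero-variance differences yield zero-width limits and a
  flagged degenerate P.
* **Spearman** — Pearson correlation of mid-ranks with the t
  approximation for P (scipy). |r| ≥ 0.8 is labelled strong. The dose
  difference entering the correlation is the magnitude |auto − manual|:
  a better contour should produce a *smaller* difference whatever its
  sign, which is why DSC/JC correlate negatively and 95%HD positively
  with Δ.
* No multiple-testing correction — results are reported per structure,
  as is conventional for this evaluation design; treat borderline P
  values accordingly.

## Synthetic phantom cohort

Each case is generated deterministically from a per-case seed derived
from the master seed (`SeedSequence`). The default grid is 64×64×24 at
2×2×5 mm — desk scale, but preserving the strongly anisotropic z
resolution of planning CT. Nine structures are placed as parametric
solids with per-case jitter of positions (±2 mm SD) and sizes (±5%):
an irregular union-of-ellipsoids CTV, ellipsoidal kidneys and bladder,
tubular rectum and spinal cord, spherical femoral heads, and an
elliptical-annulus pelvic bone whose *inner surface hugs the CTV* a few
mm out — as the sacrum and iliac wings do — which places it on the
steep dose gradient. Manual structures are made disjoint by carving in
a fixed priority order. The image assigns one intensity per structure
plus Gaussian noise; it exists for the segmenter, and makes no claim of
CT texture or HU calibration.

### Contour-error model

Auto contours are derived from manual ones by independent per-structure
draws: a rigid Gaussian shift, a signed uniform margin
(dilation/erosion) drawn as Gaussian around an optional systematic bias
(automated contours tend to systematically over- or under-estimate
specific structures), smooth random boundary displacement (thresholded
smoothed noise added to the signed distance field), and optional
deletion of the outermost superior/inferior slice. A draw that
annihilates a structure is retried with halved magnitudes and a
warning. A zero spec returns identical masks, which makes the
end-to-end identity checks exact.

The default profile was calibrated once and frozen. Measured over a
30-case cohort it gives mean DSC ≈ 0.92–0.95 (kidneys, bladder), 0.89
(femoral heads), 0.78 (CTV), 0.69 (pelvic bone), with the pelvic bone
also carrying the largest 95%HD (≈ 8.5 mm) — the fidelity ordering
reported for deep-learning pelvic segmentation. The pelvic-bone error
budget is deliberately morph-dominated: a uniform margin error moves
its mean dose monotonically (the inner surface sits on the dose
gradient), producing the strong positive correlation between its 95%HD
and its mean-dose change that the evaluation should detect. For a
uniform margin `m`, ΔD_mean ≈ (m/V)·∮(D(s) − D̄)dA over the structure
surface — near zero for structures whose boundary dose matches their
mean, which is why only the bone shows a strong correlation while the
high-fidelity organs show dose differences indistinguishable from
noise.

### Dose surrogate

Dose = `1.01 × prescription` over the CTV expanded by a 1 mm margin,
Gaussian falloff `exp(−d²/2σ²)` with σ = 13 mm outside, times smooth
multiplicative noise (0.3% SD, clipped at ±3 SD). By construction the
manual CTV is fully covered (V_100 = 100%, D_99 > prescription,
D_max < 110%) and all OAR constraints hold for the default geometry —
verified by voxel counting in the tests, not assumed. The 1 mm margin
makes target coverage realistically sensitive to contour error: the
default auto-CTV loses ~5–8 points of V_100. This is a geometric
surrogate, not beam physics; only the pipeline's comparative behaviour
is claimed, not absolute clinical dosimetry.

## Segmenter

A 2D per-slice encoder–decoder in pure numpy: input projection
(3×3 conv + BN + ReLU), three encoders (2×2 max-pool, then
3×3 conv + BN + ReLU with doubling width), three decoders (3×3
transposed conv stride 2, skip concatenation with the same-level
encoder output, 3×3 conv + BN + ReLU), and a 1×1 output projection;
volumes are segmented slice-by-slice by argmax and restacked. Training
uses Adam on softmax cross-entropy with **median-frequency class
weighting** — without it, organs occupying < 0.6% of pixels are never
learned at this scale. Augmentation: lateral mirroring that also swaps
the left/right structure labels (a mirrored left kidney *is* a right
kidney), and an optional random crop; cropping is off by default
because it removes the absolute lateral position that distinguishes
paired L/R organs at a 64×64 field of view (measured held-out five-organ
DSC 0.83 with crops vs 0.98 without). After training, batch-norm
running statistics are re-estimated on full-size un-augmented slices,
removing the train/inference statistics mismatch that augmented crops
introduce.

Channel widths (16, 32, 64 by default, smaller in tests), epochs and
learning rate are declared defaults chosen for phantom convergence on
one CPU core; nothing is claimed about any clinical training regime.
Everything is a pure function of the seed, so training and inference
are bit-reproducible; checkpoints are npz weight archives with a JSON
sidecar.

## Problem sizes and determinism

Default analyses use 30-case cohorts on the 64×64×24 grid and
20–100-slice training sets; these sizes keep the full pipeline in the
minutes range on a single core while leaving the statistics usable
(n = 30 pairs per structure). Every stochastic quantity — anatomy
jitter, contour errors, dose noise, weight init, augmentation — derives
from explicit integer seeds, and rerunning any entry point with the
same seed reproduces outputs bit for bit (CSV files included).

## What passing tests do and do not show

The synthetic cohort demonstrates that the *measurement machinery* is
correct (metrics equal independent oracles; statistics are calibrated;
the pipeline detects planted fidelity orderings and distance–dose
correlations). It does not validate any segmentation model clinically:
the phantoms lack real CT texture, deformable anatomy, inter-observer
ambiguity, and the error anatomy of real networks. Known limitations:
no DICOM-RT parsing (NIfTI/NRRD only), no plan (re-)optimization or
beam modelling, no EQD2/BED conversion, no proportional-bias
(regression) Bland–Altman, no confidence intervals on the limits of
agreement, and no small-intestine model.
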