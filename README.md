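# contoureval

Geometric **and** dosimetric evaluation of auto-segmented radiotherapy
planning structures, with a synthetic pelvic phantom generator and a
small encoder–decoder segmenter so the whole workflow runs end-to-end
without clinical data.

## The problem

Automatic delineation of the clinical target volume (CTV) and organs at
risk (OARs) is increasingly used in external-beam radiotherapy planning,
but a contour that *looks* right is not automatically *dosimetrically*
safe. This package implements the standard three-section evaluation used
to vet an auto-segmentation model against reference (manual) contours:

1. **Geometry** — per-structure overlap and surface distance:

   - Dice similarity coefficient `DSC = 2|A∩B| / (|A|+|B|)`
   - Jaccard coefficient `JC = |A∩B| / |A∪B|`
   - Hausdorff distance `HD = max(h(A,B), h(B,A))` with
     `h(A,B) = max_{b∈B} min_{a∈A} ‖a−b‖` over surface points in
     physical mm, and the robust **95%HD** that replaces each directed
     maximum by the 95th percentile of the directed distance
     distribution.

2. **Dosimetry on the fixed plan** — the plan is computed once from the
   manual contours and *frozen*; auto contours are swapped into that
   fixed dose grid and the dose–volume indices of record are recomputed
   (CTV: D_mean and V_100; spinal cord: D_max; parallel organs: D_mean;
   plus the constraint set D_99%, D_50%, D_30%, D_15%, D_0.03cc).
   Re-planning on auto contours would hide coverage errors; transmitting
   them into the original plan exposes them.

3. **Statistics** — paired Wilcoxon signed-rank tests (significant dose
   shift?), Bland–Altman bias and 95% limits of agreement (dose
   consistency?), and Spearman correlations between the geometric
   metrics and the per-case dose differences |Δ| (does geometric error
   predict dosimetric error?).

Because clinical cohorts are private, the package ships a first-class
synthetic-data module: desk-scale pelvic phantoms (64×64×24 voxels at
2×2×5 mm) with nine named structures, a calibrated per-structure
contour-error model whose fidelity profile mirrors what is reported for
deep-learning pelvic segmentation (kidneys/bladder/femoral heads DSC
≈ 0.88–0.95, CTV ≈ 0.78, pelvic bone ≈ 0.65), and a CTV-conformal dose
surrogate at a 5040 cGy prescription that satisfies every planning
constraint for the manual contours by construction.

## Worked example

```python
import contoureval as ce

cases  = ce.generate_cohort(n=12, seed=42)   # phantoms + manual/auto contours + dose
report = ce.evaluate_cohort(cases)           # geometry + dosimetry + statistics
print(report.summary_markdown())
```

prints (abridged):

```
| structure   | DSC           | JC            | 95%HD (mm)  |
| Bladder     | 0.933 ± 0.043 | 0.877 ± 0.074 | 1.90 ± 0.64 |
| CTV         | 0.785 ± 0.054 | 0.649 ± 0.073 | 6.01 ± 0.82 |
| Kidney L    | 0.937 ± 0.052 | 0.885 ± 0.087 | 1.67 ± 0.78 |
| Pelvic Bone | 0.657 ± 0.178 | 0.513 ± 0.193 | 8.50 ± 3.38 |

| structure   | metric | manual          | auto            | Z     | P        |
| CTV         | V100%  | 100.00 ± 0.00   | 92.10 ± 4.76    | -3.02 | 0.000488 |
| Pelvic Bone | Dmean  | 2438.06 ± 138.64| 2227.25 ± 232.00| -2.55 | 0.00684  |
| Kidney L    | Dmean  | 54.00 ± 19.10   | 53.39 ± 16.62   | -0.04 | 0.966    |
```

Reading it: the high-fidelity organs (kidneys, bladder, femoral heads)
show no significant dose differences, while the CTV — although its
DSC of 0.785 looks respectable — loses ~8 percentage points of
prescription-dose coverage (V_100 drops from 100% to 92%) when the auto
contour is evaluated against the original plan. That dissociation
between geometric and dosimetric acceptability is exactly what the
pipeline is built to expose. `report.save(outdir)` writes the full CSV
bundle (per-case geometry, paired dose–volume indices, Wilcoxon /
Bland–Altman summary, correlation table and heatmap matrix, run
metadata, and this summary).

The `examples/` directory has one short script per capability
(geometric metrics, DVH indices, cohort evaluation, segmenter
training), and a thin CLI mirrors the pipeline:

```bash
contoureval generate-cohort -n 30 --seed 1 -o cohort/
contoureval evaluate --cohort-dir cohort/ -o results/
contoureval train-segmenter -o model.npz
```

## The segmenter

A compact pure-numpy 2D encoder–decoder (three encoders, three
decoders, 3×3 convolutions, batch norm, ReLU, max-pooling, transposed
convolutions, level-wise skip concatenation, pixel-wise softmax
cross-entropy, Adam) trains on labelled phantom slices in minutes on a
CPU, so the segment→evaluate workflow can be exercised end to end. It
is deliberately minimal infrastructure for the evaluation pipeline, not
a clinical-accuracy model.

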