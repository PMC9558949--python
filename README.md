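# perinet

Axillary lymph-node status (ALNS) is among the strongest prognostic factors
in breast cancer, yet it is established by invasive surgery (sentinel-node
biopsy or axillary dissection).  `perinet` implements a non-invasive image
analysis pipeline that predicts the dichotomized node status (LN+ vs LN−)
from the primary tumor's dynamic contrast-enhanced MRI (DCE-MRI), with a
specific scientific focus: **how much peritumoral parenchyma should the
classifier see?**  Evidence suggests the tissue around and between lesions
carries information about lymphatic spread that is invisible to the eye;
the package makes that question experimentally testable.

It is aimed at medical-imaging and radiomics researchers who have, per
patient, a 4D DCE series (one pre-contrast volume `t_0`, post-contrast
volumes `t_1 … t_{N_p−1}`), a binary lesion segmentation, and a clinical
metadata table.

## Method

1. **Subtractive series.** `s_i = t_i − t_0` isolates contrast enhancement.
   Four canonical timepoints are kept per patient regardless of `N_p`: the
   first, second, mid-course and last subtractive volumes, preserving
   wash-in and wash-out kinetics. They form a 4-channel input.
2. **Six tumor-bounding options**, ordered by how much healthy tissue they
   include:
   | option | rule | samples/patient | input size |
   |--------|------|-----------------|------------|
   | SFB  | fixed 160×160×80 box at the tumor centroid | 1 | 160×160×80×4 |
   | SVB  | smallest cube around all lesions           | 1 | 64×64×64×4 |
   | SIB  | SVB after isotropic voxel resampling       | 1 | 64×64×64×4 |
   | SLVB | one SVB-style cube per lesion              | #lesions | 64×64×64×4 |
   | SLIB | SLVB after isotropic resampling            | #lesions | 64×64×64×4 |
   | 2DS  | lesion-bearing 2D slices of the SVB cube   | #slices | 64×64×4 |
3. **Three reduction CNNs** (strided convolutions only, two fully connected
   layers, softmax over {LN+, LN−}): `SFB-NET` (3 blocks, 5³ kernels,
   stride 4), `VB-NET` (5 blocks, 4³ kernels, stride 2, padding 1 except
   the last block — 64³ collapses to 1³), and `2DS-NET` (the 2D twin of
   VB-NET).  Networks are built on a small numpy engine in `perinet.nn`.
4. **Patient-wise rotating 10-fold cross-validation**: fold *i* tests,
   fold *i−1* validates, the rest train; training sets are balanced by
   replicating minority-class (LN+) samples and augmented with random
   in-plane flips and 90/180/270° rotations.  Per-sample predictions are
   aggregated per patient by majority vote; reported metrics are ACC, SENS,
   SPE (percent), the rank-statistic AUC and Cohen's κ = (p_o−p_e)/(1−p_e).
5. **Clinical statistics.** Categorical clinical/histological covariates are
   compared between LN+ and LN− with a two-sided Wilcoxon rank-sum test on
   ordinally encoded categories (midranks, tie correction, continuity
   correction), plus an exact permutation variant for small samples.
6. **Synthetic phantoms.** A built-in generator produces DCE phantom cohorts
   (variable acquisition counts, anisotropic voxels, curve type I/II/III
   kinetics, unifocal/multifocal/multicentric layouts, 27:128 class
   imbalance) with a label-correlated texture planted in the peritumoral
   rim — so the entire pipeline is testable without clinical data.

## Worked example

```python
from perinet import PhantomConfig, TrainConfig, generate_cohort, run_cross_validation

# 40-patient phantom cohort with a strong planted peritumoral signal
cohort, metadata = generate_cohort(
    PhantomConfig(n_patients=40, grid_shape=(32, 32, 32),
                  lesion_radius_mm=(2.5, 5.0), delta=0.5, seed=7)
)
config = TrainConfig(max_epochs=1, batch_size=8, learning_rate=1e-3,
                     width_scale=0.25, seed=7)
report, plan = run_cross_validation(cohort, "svb", config, k=5, seed=7)
print({k: round(v, 2) for k, v in report.pooled.items()})
```

prints

```
{'tp': 6, 'fp': 6, 'tn': 27, 'fn': 1, 'acc': 82.5, 'sens': 85.71,
 'spe': 81.82, 'precision': 0.5, 'kappa': 0.53, 'auc': 0.8}
```

Six of the seven LN+ phantoms are recovered (sensitivity 85.7%, patient-level
AUC 0.80) at the cost of 6 false positives among 33 LN− patients: even at
this very reduced scale (tiny cohort, one training epoch, quarter-width
network) the smallest-cube (SVB) pipeline picks up the planted peritumoral
texture well above chance.

The same pipeline is available from the shell:

```bash
perinet simulate --n-patients 40 --seed 7 --out cohort/
perinet extract  --option svb --input cohort/metadata.csv --out samples/
perinet evaluate --option svb --input cohort/metadata.csv --out run/ --folds 5
perinet stats    --manifest cohort/metadata.csv --out table.csv
```

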