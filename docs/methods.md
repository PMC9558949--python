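# Methods

## Problem and data model

The package predicts dichotomized axillary lymph-node status (LN+ = at
least one metastatic node at surgical pathology, LN− otherwise) from the
primary breast tumor's DCE-MRI.  A patient is a `DCESeries`: an ordered
list of `N_p ≥ 5` co-registered 3D acquisitions (index 0 pre-contrast),
voxel spacing in mm (row, column, between-slice), a binary lesion mask on
the same grid, and the label.  The two breasts of a bilateral case are
treated as independent lesion-level subjects; the fold builder accepts a
grouping map so both stay in one cross-validation fold.

Subtractive volumes `s_i = t_i − t_0` isolate enhancement.  Negative
values are kept: the later per-sample min–max normalization maps the
sample minimum to 0, and clipping beforehand would discard wash-out
contrast.  Because `N_p` varies across patients, four canonical
subtractives are selected: `s_1`, `s_2`, the mid-course volume `s_m` with
`m = floor(median([3, n−1]))` (ties resolve to the earlier timepoint,
which carries the richer wash-in information), and the last `s_n`.  Fewer
than four subtractives is an error rather than a channel-duplication
fallback.

## Bounding options

All options act identically on the four channels and produce values in
[0, 1] (min–max over the channels jointly, so the wash-in/wash-out
ordering between timepoints survives; a constant sample maps to zeros).

* **SFB** — a fixed 160×160×80 crop centered on the rounded voxel centroid
  of the union mask, zero-padded at grid borders, fed to its network at
  native size.  A tumor larger than the box warns but does not fail.
* **SVB** — the smallest cube containing the union mask: side = the
  largest per-axis bounding-box extent; the cube is anchored so the mask
  is always fully inside, with any odd padding voxel on the high side.
  Out-of-grid regions are zero-padded rather than shifting the cube,
  which would move the tumor off-center.
* **SIB** — isotropic resampling first (target spacing = the minimum of
  the three spacings: pure upsampling, no information discarded; trilinear
  for intensities, nearest-neighbor for the mask so it stays binary; new
  axis length = round(old × spacing/target)), then the SVB rule.  On an
  already isotropic grid SIB ≡ SVB.
* **SLVB / SLIB** — the SVB/SIB rule applied per lesion.  Lesions are
  26-connected components of the mask, labeled in decreasing voxel-count
  order.  Inter-lesion parenchyma is thereby excluded — that is the
  scientific point of these options.
* **2DS** — the SVB cube is cut along the axis with the coarsest spacing
  (ties break toward the last axis, the conventional slice direction), so
  each kept plane lies in the finest-resolution projection; only
  lesion-bearing slices are kept.  Normalization happens per slice after
  the resize, treating each slice as an independent sample.

Cubes and slices are resized to 64×64×64 / 64×64 by channel-wise linear
interpolation.

## Networks

Three reduction CNNs, one per input geometry, all ending in two fully
connected layers (hidden width 128) and a softmax over the two classes;
rectified-linear activations after every convolution and the first dense
layer; no pooling, normalization layers or dropout:

| net | blocks | kernel | stride | padding | channels |
|-----|--------|--------|--------|---------|----------|
| SFB-NET | 3 | 5³ | 4 | 2 | 4→16→32→64 |
| VB-NET  | 5 | 4³ | 2 | 1,1,1,1,0 | 4→16→32→64→128→256 |
| 2DS-NET | 5 | 4² | 2 | 1,1,1,1,0 | as VB-NET |

The kernel/stride/padding scheme fixes the reduction geometry (VB-NET
collapses 64³ to 1³; SFB-NET reduces 160×160×80 to 3×3×2 with padding 2,
chosen so three stride-4 blocks leave a usable spatial extent); channel
widths double per block, the standard convention for reduction networks.
`build(name, width_scale=…)` scales the channel progression for
reduced-scale experiments without touching the geometry.  Networks accept
exactly their canonical input shape and reject every other shape.

The engine (`perinet.nn`) is a compact numpy implementation: convolutions
are decomposed over kernel offsets (one unit-stride slice per offset after
splitting the padded input by stride phase, then one small matmul), which
keeps temporaries output-sized; gradients were verified against finite
differences and a brute-force convolution.  The first convolution skips
the input gradient, which is never needed.  Everything runs in float32.

## Training protocol

Rotating patient-wise 10-fold cross-validation: iteration *i* uses fold
*i* as test and fold *(i−1) mod 10* as validation, so every patient is
exactly once a test and once a validation subject, and a patient's
samples never straddle training and evaluation.  Folds are
label-stratified: within each class, patients are shuffled by seed and
dealt round-robin, remainders landing in the earliest folds.

Full-scale defaults (`TrainConfig`): cross-entropy loss, Adam with
learning rate 1e−6 and weight decay 1e−4, up to 500 epochs, batch 16
(3D) / 32 (2D), minority-replication balancing (duplicates random LN+
samples until class counts match; the majority class is never touched),
and augmentation applied to all training samples — independently with
probability 0.5 each, a vertical flip, a horizontal flip, and one of
90/180/270° rotations, acting on the two in-plane axes identically across
channels.  The checkpoint with the best validation loss is kept: the
rotating validation fold exists precisely to select it, and no separate
early-stopping rule is assumed.  A grid search helper evaluates
configurations by mean validation loss (ties → smaller learning rate,
then smaller batch).

## Evaluation

Patient-level hard calls are majority votes over the patient's sample
predictions; an exact tie resolves to LN− (the prior class; the rule is a
configurable argument).  Patient-level scores for ROC and
precision–recall curves are the mean positive-class probability over the
patient's samples.  ACC/SENS/SPE are percentages with LN+ positive; AUC
uses the midrank Mann–Whitney formulation (verified against all-pairs
concordance); Cohen's κ uses the confusion-table marginals for chance
agreement.  Degenerate denominators return NaN, never a silent 0.
Reports carry per-fold metrics, their mean (the headline), and the pooled
confusion matrix in which each patient appears exactly once.

## Clinical covariate statistics

Each categorical covariate has a fixed clinically ordered category list
(grading 1<2<3, signal curve I<II<III, molecular class Luminal A <
Luminal B < HER2 < TN, …).  Categories are encoded 1..g and the LN+/LN−
groups compared with the two-sided rank-sum test in normal approximation:
midranks, tie-corrected variance, 0.5 continuity correction.  Applied to
the embedded contingency tables of the 155-lesion clinical cohort (27
LN+/128 LN−) this reproduces the reported p-values to four decimals for
menopause (0.0233), grading (0.0011), molecular class (0.0013), hormone
therapy (0.0733), signal curve (0.2819) and histotype (0.7351).  The
familiarity and margins variables do not reproduce under any
row-order encoding we consider plausible; their original encodings are
unknown, and they are reported by the package without a reproduction
claim.  `exact_rank_sum_p` enumerates all group assignments for small N —
the asymptotic p can differ from the exact one by ~0.1 on tiny tables, so
small-sample users should prefer the exact path.

## Phantom generator

`generate_cohort` emulates the statistical structure the method assumes,
not breast anatomy or MR physics: a smooth random parenchyma background
(Gaussian-filtered noise), ellipsoidal mass-like lesions with physical
radii 3–7 mm squashed by the anisotropic default spacing 0.7×0.7×2.4 mm,
5–8 acquisitions per patient, and per-lesion enhancement following curve
type I (progressive, `τ^0.8`), II (plateau, `1−e^{−5τ}`) or III
(wash-out, peak at τ=0.25) with curve-type frequencies taken per class
from the clinical cohort.  Layout mix is 70% unifocal / 20% multifocal
(nearby foci) / 10% multicentric (2–3 distant foci); placements are
rejection-sampled so components never touch and component labeling always
recovers the planted lesion count.  Class ratio defaults to 27:128 over
155 patients.

The label signal is planted where the scientific hypothesis puts it: LN+
patients get a high-frequency texture of amplitude `delta` (relative to
the lesion enhancement amplitude) in a 2-voxel dilation rim around each
lesion and, for multi-lesion LN+ patients, along the straight tracks
between lesion centroids.  With `delta = 0` the images carry no label
information.  Clinical covariates are sampled per class from the cohort
frequencies, independently per patient — real covariates are correlated
with each other, which the phantom does not model.  Other deliberate
non-goals: no motion, no coil or bias fields, no intensity
non-stationarity, no segmentation error.  Passing the phantom experiments
therefore shows the pipeline recovers a planted peritumoral signal under
its own assumptions; it does not certify clinical performance.

`planted_signal_check` scores each patient by the standard deviation of
the mean subtractive channel inside the rim — a one-line oracle whose AUC
upper-bounds what a trained network should approach.

## Reduced-scale experiment sizes

The class-recovery experiment (also run by `scripts/acceptance.py`) uses
the generator defaults — 155 patients, 48³ grids, strong rim signal
`delta = 0.5`, noise 0.02 — with a reduced training configuration chosen
once for this problem size: quarter-width VB-NET, one epoch, batch 8,
learning rate 1e−3 (inside the full-scale grid-search ranges, batch
∈ (8, 64), lr ∈ (1e−7, 1e−3)).  Under these conditions the SVB and SIB
pipelines reach patient-level AUC ≈ 1.0 on the planted cohort while the
null cohort stays at chance; the whole experiment runs in about ten
minutes on one CPU.  Unit and property tests use smaller cohorts (10–40
patients, 24³–32³ grids) and width-scale 0.125 networks.

## Numerical choices and degenerate inputs

* Crops are half-open intervals on 0-based (row, column, slice) indices;
  bounding-cube anchoring guarantees mask containment with the odd
  padding voxel on the high side.
* Constant samples normalize to all-zeros; empty masks, single-class
  training sets, empty prediction lists, non-finite losses and
  sub-minimum acquisition counts raise errors rather than degrade.
* All randomness (fold shuffles, balancing draws, augmentation, weight
  init, phantom generation) flows through explicit integer seeds;
  repeated runs are bit-reproducible.
* Weight decay is coupled (added to the gradient), matching the common
  Adam implementation.
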