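# Methods

`rgdfusion` implements an information-fusion classifier (RGD) for
benign/malignant lung-nodule classification on CT sub-volumes.  Three feature
families are combined per nodule — 3D texture radiomics, five convolutional
backbones, and a GCN fusion over the backbone features — and five fusion
heads are ensembled with accuracy-proportional weights.  This note records
the model, the defaults and why, the numerical choices, and what the
synthetic phantoms do and do not establish.

## Cohort preparation

Labels derive from 1–5 radiologist malignancy ratings: a nodule with mean
rating ≤ 2.75 is benign, ≥ 3.125 malignant, and anything in between is
*uncertain* and excluded.  Both boundary values are claimed by two rules in
the source convention; we resolve the overlap by giving 2.75 to benign and
3.125 to malignant, matching the order in which the rules are stated.
Inclusion additionally requires at least three raters.

Volumes are standardised to the network input in four steps: slice spacing
resampled to 1 mm along z (linear interpolation), a 56×56×8 crop around the
nodule centre (zero-padded at borders), in-plane upsampling to 128×128
(cubic), and intensity normalisation.  When the input is in Hounsfield
units, it is first clipped to the standard lung window [−1000, 400] HU; the
result is min–max scaled to [0, 1].  A constant volume maps to all-zeros
(avoids division by zero); the degeneracy test uses a relative tolerance of
1e-9 because cubic interpolation leaves machine-epsilon ripple on constant
fields.  In-plane pixel spacing is not resampled before the crop (the source
procedure leaves this open; we crop in native pixels).

Cross-validation folds are patient-disjoint: patients are shuffled by seed,
sorted largest-first, and greedily assigned to the smallest fold, which
keeps per-fold nodule counts within the spread the patient grouping allows.

## Radiomics vector FR

FR is the concatenation of three descriptors, computed by default on the
128×128×8 volume fed to the CNNs (the alternative — the raw 56×56×8 crop —
is available by preprocessing choice; descriptor code accepts any volume).

**Volume LBP** (defaults L=1, P=4, R=1): for each interior voxel a
(3P+2)-bit pattern of thresholded differences B(g − g_centre), B(x)=1 iff
x ≥ 0, over: the centre pixel of the slice L below; the P circular
neighbours at radius R in the slices L below, at, and L above; the centre
pixel of the slice L above — in that bit order.  The histogram over all
2^(3P+2) = 16384 patterns is L1-normalised.  No uniform-pattern reduction is
applied: the pattern number itself is the descriptor, and P=4 keeps the full
histogram tractable.  P=4/R=1 neighbours fall on exact grid offsets; other
settings use bilinear interpolation, standard circular-LBP practice.

**3D HOG**: per-voxel gradients by the [−1, 0, 1] mask along each axis
(edge-replicated at borders), described by two angles — the unsigned
in-plane azimuth atan2(Gy, Gx) mod π and the elevation
atan2(Gz, √(Gx²+Gy²)) — and binned per cell with magnitude-weighted hard
assignment.  Defaults: 32×32×4 cells (4×4×2 cells on the standard volume),
8 azimuth bins over [0, π), 4 elevation bins over [−π/2, π/2], one global
L2-normalisation block, final L2 normalisation.  Cell/bin geometry is not
prescribed by the source method; these values give a compact 1024-dim
descriptor and are recorded in the run config.  An all-constant volume
yields the zero descriptor (a zero vector is never normalised).

**3D GLCM**: intensities are quantised to 32 equal-width levels of [0, 1];
for each of the 13 unique directions of the 26-neighbourhood (opposite
directions merged) co-occurrence counts are accumulated symmetrically (both
orders), at distances 1, 2, 4, 8 for the four purely in-plane directions and
1, 2, 3, 4 for the nine directions with a z component.  That enumeration
yields 52 (direction, distance) matrices — the source text mentions
"fifty" without saying which two would be dropped, so all 52 are kept — and
each contributes energy Σp², entropy −Σ p log p (natural log, 0·log 0 := 0),
contrast Σ(i−j)²p and homogeneity Σ p/(1+|i−j|): 208 features in a fixed,
named (direction, distance, statistic) order.  A displacement exceeding the
volume extent produces an all-zero feature block with a warning.

## Backbones

Five families — AlexNet, VGG13, ResNet34, Attention56 (attention-masked
residual), GoogLeNet (inception) — are provided at two scales.  `tiny`, the
desk-scale default, keeps each family's defining motif (plain stack with
dense layers / deep 3×3 stacks / residual skips / mask-modulated residual
trunk t·(1+σ(mask)) / parallel 1×1-3×3-5×5 branches) at small widths;
`full` widens and deepens each.  The networks are built on a small numpy
reverse-mode autodiff engine inside the package (`rgdfusion.nn`):
convolutions are im2col gathers plus matmuls, so 1 CPU suffices at tiny
scale.

The 8-slice depth is absorbed by a 3D convolution in the first block
(kernel and stride 8×8×8 spanning the full depth), after which feature maps
are planar; every family ends in a learned linear projection to a common
`feature_dim` so the GCN sees dimension-aligned node features, plus a
linear-sigmoid classifier.  The feature vector F_i is the post-ReLU output
of that projection — the last representation before the classification
output.

Training uses the focal loss below with Adam; reference defaults are
lr 1e-4, weight decay 1e-4 (added to the gradient), at most 100 epochs.
The phantom preset uses lr 1e-3 for 8 epochs, sized to the much easier
synthetic task; this is a schedule choice recorded in the config, not a
change to the reference recipe.

## Divergence graph and GCN fusion

For a trained fold, `similarity(i, j)` is the fraction of training samples
on which backbones i and j emit the same hard prediction; the default
adjacency is the *divergence* A_ij = 1 − similarity(i, j) with zero
diagonal (similarity of a model with itself is 1, so the diagonal is 0
before self-loops are added).  Ablation variants: `as` (similarity
weights), `a1` (all-ones complete graph), `a0` (all-zeros, i.e. self-loops
only).  The adjacency is computed once per training fold from training-set
predictions and reused for every sample; only the node features H⁽⁰⁾ vary
per sample — nothing per-sample is defined for the graph topology.

Propagation follows S = D̃^(−1/2)(A+I)D̃^(−1/2) with D̃ the degree matrix of
A+I; an all-zero adjacency therefore propagates as the identity.  Two
layers with ReLU after each produce H⁽²⁾, and FG concatenates the five node
rows.  Layer widths default to 256→256→128 (full scale) and 32→64→32
(phantom preset); the source gives no widths, so these are package
defaults.  The GCN has no standalone objective: its weights are trained
jointly with the fusion heads.

## Focal loss, fusion heads, ensemble

Focal loss (natural-log convention, probabilities clamped to
[1e-7, 1−1e-7]):

    L = −α (1−y′)^γ log y′        if y = 1
    L = −(1−α) y′^γ log(1−y′)     if y = 0

with α = 0.25, γ = 2 by default; batch loss is the mean.  At γ=0, α=0.5 it
reduces to half the binary cross-entropy.

Each backbone i owns a fusion head: a linear-sigmoid classifier over
[F_i | FR | FG].  The FR block is z-scored with training-fold statistics
(constant columns pass through as zeros).  The five heads and the shared
GCN weights are optimised jointly with focal loss while the backbone trunks
stay frozen; a separate per-network fine-tune is not meaningful here
because FG is shared by all heads, which forces shared GCN weights.

Ensemble weights are accuracy-proportional, W_i = Acc_i / Σ_j Acc_j, with
Acc_i measured on a held-out validation split (10% of the training fold's
patients, stratified by class, patient-disjoint) rather than on training
data, where near-saturated accuracies would make the weights
uninformative.  The final probability is P = Σ W_i P_i, thresholded at 0.5.

## Evaluation

Accuracy, sensitivity, specificity, precision and F1 come from confusion
counts with malignant as the positive class; undefined ratios are reported
as NaN with a warning.  AUC uses the pairwise-ranking estimator
Σ_neg Σ_pos B(f(t₀) < f(t₁)) / (|D⁰||D¹|); the default `strict` tie mode
implements the indicator literally (ties score 0), `half` gives the
Mann–Whitney 0.5 credit.  Fold aggregation is the unweighted mean across
folds (matching how the published mean row relates to its per-fold values)
with the population standard deviation.

The package carries the published 10-fold LIDC-IDRI results of the
full-scale RGD model as data (`rgdfusion.published`) for arithmetic
consistency checks.  One printed value — fold 5's precision, 82.31% — is
irreconcilable with its own row: the confusion counts implied by the row's
accuracy/sensitivity/specificity (TP=24, FN=5, TN=46, FP=2 of n=77) give
precision 92.31% and reproduce the printed F1 0.8727 exactly, while 82.31%
would give 0.8253.  We treat it as a digit transposition; the printed
column mean (92.46%) is reproducible only from the printed values, i.e. the
transposition propagated into the mean.  Both facts are asserted by tests.

## Synthetic phantoms

The phantom generator supplies labelled 56×56×8 crops so the full pipeline
trains and evaluates without a CT archive.  Benign nodules are smooth
Gaussian-blurred ellipsoids (blur σ = 2 voxels); malignant nodules are
wobbled ellipsoids with 8 radial spicules (mostly in-plane, as spiculation
presents on axial slices) and a band-limited internal texture of amplitude
0.4 of the intensity range, emulating the margin and heterogeneity cues
that distinguish the classes on CT.  Both receive additive Gaussian noise
(σ = 0.02) and one nodule per synthetic patient, which makes
patient-disjoint folds trivial.  The default cohort is 100 nodules per
class.

What the phantoms do **not** emulate: CT acquisition physics (beam
hardening, reconstruction kernels, dose noise structure), anatomical
context (vessels, pleura, juxta-pleural attachment), size distributions,
inter-rater label noise, or class imbalance.  Phantom results therefore
validate the pipeline's mechanics and the qualitative ordering of its
components (fusion should not degrade on a task where every component can
succeed) — they say nothing about clinical performance, and the published
LIDC-IDRI numbers are not reproducible at this scale.

## Problem sizes and determinism

Desk-scale runs use the tiny backbones (feature_dim 32), 100 phantoms per
class, 5 folds, 8 backbone epochs and 30 head epochs; one full CV run takes
a few minutes on one CPU.  One master seed fans out to every stochastic
component (cohort generation, fold shuffling, weight initialisation,
minibatch order) through a sha256-based derivation, so a config plus seed
reproduces ensemble probabilities bit-for-bit.  Patient disjointness of
every fold is re-checked at run time and violations are hard failures.

## Known limitations

* Backbone trunks are not updated during head fine-tuning (frozen-trunk
  fusion only).
* The LBP histogram is dense (16384 bins for P=4); most bins are empty on
  smooth volumes, and heads see the z-scored dense block.
* The `full` backbone scale is provided but not exercised by the test
  suite, which is sized for one CPU.
* `auc strict` (the literal indicator) is the reporting default; with
  heavily tied scores it underestimates the Mann–Whitney AUC.
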