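# Methods

This note documents the models, conventions and design choices behind
`svxresp`, in the order the pipeline runs them, together with what the
synthetic phantom does and does not establish.

## Problem setting

At suspected glioblastoma recurrence, enhancing tissue is a mixture of
vital progressing tumor (TP) and treatment-related change (PsP), often
within one lesion. The unit of analysis is the *supervoxel*: a spatially
connected, multimodally homogeneous group of ~200 voxels inside the
baseline contrast-enhancing tumor (CET). Each supervoxel receives a ground
truth label from follow-up imaging and a predicted TP probability from its
baseline radiomics profile.

## Synthetic phantom cohort

The generator emulates the imaging bundle of one exam on a single
co-registered grid (default 64³ voxels at 1 mm³; anisotropic spacings are
supported throughout): a spherical brain with concentric WM/GM/CSF shells
and a tumor with necrotic core, enhancing rim (CET, ~5000 voxels at the
default 12 mm radius and 4 mm rim) and edema margin.

**Response geography.** A Gaussian random field smoothed at
`blob_scale_mm` (4 mm) is thresholded inside the CET at the quantile
matching `tp_fraction` (0.5), yielding contiguous interdigitated TP/PsP
territories rather than salt-and-pepper voxels — the mixed-response
geography the pipeline is meant to resolve.

**Channels.** Each channel is a per-class mean plateau plus a spatially
correlated zero-mean texture field (1.5 mm correlation length, SD equal to
the configured class SD) plus white Gaussian scan noise. Keeping the class
means as sharp plateaus (instead of smoothing them) makes the per-class
marginal means match the configuration exactly, which the tests verify
with cluster-robust standard errors. Defaults (chosen once, to reproduce
the *direction* and plausible magnitude of published TP/PsP contrasts, not
any specific printed value):

| channel | TP mean (SD) | PsP mean (SD) | background | noise SD |
|---|---|---|---|---|
| PET TBR (unitless) | 2.8 (0.45) | 1.9 (0.45) | WM 1.0, GM 1.3 | 0.10 |
| CBV (arb.) | 3.0 (0.70) | 2.0 (0.70) | WM 1.0, GM 2.0 | 0.20 |
| T1c (arb.) | 2.6 (0.55) | 2.3 (0.55) | brain ≈ 0 | 0.12 |

TBR and CBV separate strongly, T1c only weakly — both classes enhance,
which is precisely why the problem is hard on conventional MRI. Raw PET
uptake is emitted as `TBR × 100` arbitrary units so the normalization
module has real work to do.

**Follow-up.** The follow-up T1c reuses the baseline enhancement field
(anatomy persists between scans): TP territory is multiplied by 1.6 and
additionally grown 2 mm outward *beyond the baseline CET*, PsP territory
is multiplied by 0.7, and fresh scan noise is added. Growth never
overwrites PsP territory inside the baseline CET, because labels are
defined on the baseline CET and must remain consistent with the planted
truth. Repeat inclusion (3 of 30 patients with a second case by default)
exercises the grouped cross-validation.

**What the phantom does not model:** MR physics (no k-space, bias fields,
Rician magnitude statistics by default — a Gaussian approximation is used),
anatomy beyond concentric shells, registration error between baseline and
follow-up, segmentation error of the input masks, and scanner effects.
Passing tests therefore demonstrate correctness of the computational
pipeline and learnability under the stated noise model, not clinical
performance; the headline AUC on the phantom (~0.98) is an upper bound set
by the planted effect sizes, not a clinical estimate.

## CBV with leakage correction

ΔR2\*(t) = −(1/TE)·ln(S(t)/S₀), with S₀ the mean pre-bolus signal; voxels
with non-positive S₀ or signal are flagged and excluded rather than
raising. The leakage model fits each voxel curve against the mean curve
R(t) of reference tissue (brain minus CET/necrosis/edema, ≥100 voxels) as
K1·R(t) − K2·∫₀ᵗR, solved voxel-wise by 2×2 normal equations; corrected
CBV = ∫ΔR2\* + K2·∬R. The correction is exact for data generated by the
model and recovers K1/K2/CBV to sub-percent median error at 1% peak noise.
Trapezoidal integration throughout; the synthetic bolus is a gamma-variate
(t₀ = 12 s, α = 3, β = 1.5). CBV is left in arbitrary units (an optional
WM-normalized variant exists); the classifier is scale-free and the GLCM
discretization is per-supervoxel, so global CBV scaling is immaterial.

## PET normalization

TBR = uptake / mean(uptake over WM ∖ (CET ∪ necrosis ∪ edema)), the
arithmetic-mean convention of FET quantification, with a 100-voxel floor
on the reference region. Whole-brain WM is the default reference; a
contralateral-only restriction can be passed as the WM mask itself.

## Response labeling

Baseline and follow-up T1c are z-normalized to nonenhancing brain
(arbitrary T1w units are not comparable across scans), then
TP ⇔ (FU − BL)/BL > 0.10. The 10% threshold is the package's explicit,
reproducible surrogate for an expert's mRANO judgement of "further
progressive" versus "stable or decreasing" enhancement; it recovers
≥ 99.9% of the planted truth on the default phantom and its effect is
monotone (higher thresholds never produce more TP). Voxels with
non-positive baseline intensity are filled by iterative 26-neighborhood
majority (PsP if isolated). Enhancement appearing outside the baseline CET
is deliberately ignored: labels live on the baseline CET. "Decreasing" and
"stable" enhancement are pooled into a single PsP class, matching the
binary classifier. Externally drawn label maps are accepted verbatim after
validation.

## Supervoxels

Masked SLIC (scikit-image) on the three channels z-scored over CET voxels
per case (they live on incommensurate scales), compactness 0.1 (favoring
intensity homogeneity), spatial distances in mm via the voxel spacing,
n_segments = |CET|/200. scikit-image's own connectivity enforcement sizes
its minimum segment against the full image rather than the mask and
collapses masked partitions, so it is disabled; instead each label keeps
its largest 26-connected component and orphan fragments are merged into
the adjacent supervoxel with the nearest centroid. Ids are canonicalized
to ascending (z, y, x) centroid order, making the id volume a pure
function of the inputs. A CET smaller than the target size becomes a
single supervoxel with a warning. Majority voting resolves exact ties to
TP — conservative toward not missing progression — and reports the
majority fraction.

## Radiomics

18 first-order features (energy, total energy, entropy, minimum, P10,
P90, maximum, mean, median, IQR, range, MAD, robust MAD, RMS, skewness,
kurtosis, variance, uniformity; population moment conventions,
entropy/uniformity on the discretized histogram) and 24 GLCM features
(autocorrelation, joint average, cluster prominence/shade/tendency,
contrast, correlation, difference average/entropy/variance, joint
energy/entropy, IMC1/2, ID(N), IDM(N), inverse variance, maximum
probability, sum average/entropy, sum of squares, MCC) per channel, 126
per supervoxel.

Conventions: fixed-bin-count discretization with 32 bins per supervoxel
per channel (supervoxels are small and channel ranges differ; fixed bin
count makes features invariant to affine intensity shifts);
co-occurrences only between voxel pairs both inside the supervoxel,
distance 1, 13 unique 3D directions, symmetric, per-direction matrices
normalized to sum 1 and features averaged over directions with at least
one pair; the gray-level universe (Ng) is the set of levels present in the
supervoxel. Degenerate cases: correlation and MCC are 1 for a single gray
level; supervoxels that are constant on some channel, or have no valid
co-occurrence pair, are excluded from the feature table with a logged
reason rather than imputed. PET features are computed on TBR, CBV on the
(corrected) CBV map, and T1c on the brain-z-scored volume by default
(`t1c_mode="raw"` disables). The whole feature roster is verified, value
by value, against a naive double-loop oracle.

## Classifier and evaluation

Random Forest: 100 trees, entropy criterion, bootstrap resampling, √p
feature subsampling, fixed seed. Patients are assigned to ten folds by
greedy largest-first balancing of supervoxel counts (deterministic given
the seed); every supervoxel of a patient shares its fold, and the CV loop
programmatically asserts the absence of patient overlap between train and
test. Out-of-fold TP probabilities (fraction of trees) are pooled;
"macro AUC" is the unweighted mean of the two one-vs-rest AUCs (identical
to the plain AUC for a binary problem with complementary scores — this
reading of a class-imbalance-aware AUC is configurable); thresholded
metrics use the pre-defined 0.5 cutoff. Feature importances are
impurity-based, from a final forest fitted on all data (fold-model
averages behave equivalently; the single refit keeps the importance table
tied to one reproducible model), and sum to 1. The permutation null
shuffles labels *within* patients, preserving each patient's class mix
while destroying the feature-label link; grouped CV on it must score at
chance, which doubles as an empirical leakage check. Mann-Whitney U uses
midranks with tie and continuity corrected normal approximation
(two-sided), with significance stars at 0.05/0.01/0.001.

## Pipeline and I/O

All volumes are NIfTI-1 (written uncompressed so artifact hashes are
byte-reproducible); tables are CSV; configs and manifests are JSON. Every
stage persists its outputs with SHA-256 hashes in a run manifest; a rerun
skips stages whose inputs and recorded outputs verify, and a full rerun
with the same config and seed reproduces identical hashes. Volumes of one
case must share shape and spacing exactly — nothing is resampled silently.

## Problem sizes

Defaults were sized for a desk-scale study that still exercises every code
path: 30 patients (33 cases) on 64³ grids with ~25 supervoxels per case
(~840 total), 100-voxel curve sets for perfusion recovery, 50 reduced
(32³) cases for the partition/majority oracles, and 5 permutation seeds
for the null. All knobs scale up through the configuration dataclasses.

## Known limitations

Single-voxel-distance GLCM only (no GLRLM/GLSZM, wavelets or shape
features); no dynamic PET; no deconvolution-based perfusion (CBF/MTT); no
registration or segmentation — inputs must arrive co-registered with
masks; supervoxels are classified independently, ignoring neighborhood
context; the automatic labeling rule is a simplification of expert mRANO
assessment and is validated only against the phantom's planted truth.
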