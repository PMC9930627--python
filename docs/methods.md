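# Methods

## The analysis problem

The pipeline analyzes condition-by-run fMRI β-estimate patterns from a
4 × 2 factorial design: four person-concepts ordered by social distance
from the participant (PresentSelf = 0, PastSelf = 1, Mother = 2,
Queen = 3) crossed with the emotive valence of the trait descriptions
used to probe them.  Eight ROIs are analyzed — five default-network
regions (dmPFC, vmPFC, PCC, left/right IPL) and three semantic-network
regions (left/right ATL, left IFG).  With 8 conditions and 8 scanning
runs each subject contributes 64 β vectors per ROI: one pattern per
condition per run, the denoising trade-off that prefers few clean
examples over many noisy per-trial estimates.

Two complementary MVPA families are implemented: supervised decoding
(linear SVM classification) and representational similarity analysis
(correlation structure of the patterns), plus the group statistics both
require.

## Decoding

All classification uses a soft-margin linear SVM with cost C = 1 (the
conventional toolbox default for this kind of analysis).  Features are
not scaled by default; train-fold z-scoring is available behind
`ClassifierSettings(scaling="train_fold_zscore")`.  Multiclass problems
are decided by explicit one-vs-one voting over the 6 pairwise
classifiers, with vote ties broken deterministically toward the earliest
class in the scheme's declared class order.

**Cross-validation** is leave-one-run-out: with R runs there are R folds,
each training on R−1 runs and testing on the held-out run, so no example
ever appears on both sides of a split; the reported accuracy is the mean
of fold accuracies, and confusion counts are pooled over folds.

**Cross-classification** trains on one condition partition and tests on a
disjoint partition (e.g. 4-way person classification trained on all 32
positive-valence examples, tested on the 32 negative-valence examples).
Both directions are always run and their accuracies averaged, so the
result is invariant to which partition is nominally "train".

The seven standard schemes are: (1) self vs other, (2) PresentSelf vs
PastSelf, (3) Mother vs Queen, (4) 4-way person, (5) self/other trained
on the near pair (PresentSelf vs Mother) and tested on the far pair
(PastSelf vs Queen), (6) near/far trained within the self domain and
tested within the other domain, (7) 4-way across valence.  Chance is
1/2 for binary schemes and 1/4 for 4-way schemes.

**Combinatorial-ROI decoding** concatenates voxel dimensions of ROI
pairs (all ROIs must have — or be seeded-subsampled to — equal voxel
counts, so combined patterns are exactly matched in dimensionality).
`delta[r, c]` is the joint accuracy of (r + c) minus r's single-ROI
baseline; the column mean is a region's *contribution* ("giver"), the
row mean its *benefit* ("taker").  The DN-vs-SN contrast is a two-tailed
signed-rank test on subject-level network means.  Because a linear
kernel is invariant to feature order, the joint accuracy of an unordered
pair is computed once and reused for both orientations.

## Searchlight

A sphere of fixed physical radius (10 mm by default; membership is
center-to-center distance in millimeters, voxel size × index) is
centered on every in-mask voxel; its in-mask pattern is decoded with the
same engine and the accuracy assigned to the centroid.  Out-of-mask
voxels never enter a sphere; spheres with fewer than 2 voxels are
computed but flagged.

Group inference is a voxel-wise one-sample *t* test against chance with
familywise error controlled by the max-statistic sign-flip permutation
test: under the null, each subject's deviation from chance is symmetric,
so random sign flips generate the joint null of the maximum *t* over
voxels; the FWE threshold is its 95th percentile.  This permutation
scheme replaces parametric random-field correction by design: it is
distribution-free, exact under exchangeability, and well matched to
desk-scale synthetic grids (which are simulated pre-aligned, so no
normalization or smoothing of accuracy maps is applied; smoothing is a
documented no-op here rather than an emulated step).  Voxels with zero
between-subject variance have no defined *t*; they are flagged and
excluded from the max statistic.

ROI definition from a *t* map follows the localizer ladder: threshold at
p < 0.001 (then 0.005, then 0.01 if empty; the caller supplies the df
that converts p to a critical *t*), find the local maxima of the
suprathreshold set (strictly greater than all 26-connected in-mask
neighbors; plateau ties broken by smallest linear index), take the one
nearest the landmark in millimeters, and return the 10 mm sphere around
it.  An empty ladder result raises an explicit error, never a silent
empty mask.

## Representational similarity analysis

First-order similarity is the Pearson correlation between run-averaged
condition patterns (similarity r and distance 1−r are two views of the
same matrix; clustering and model comparison use the distance view).
Per-run matrices with Fisher-z averaging are available behind
`run_average=False`; run-averaging is the default because run handling
is a free design choice here, and averaged patterns match the decoding
stage's denoising philosophy.  The 8 × 8 condition level and the 4 × 4
person level (valence variants averaged, or a single valence selected)
are both supported; all second-order statistics use only the
m(m−1)/2 lower-triangular entries.

Second-order comparisons use Kendall's τ-a — (concordant − discordant) /
(n(n−1)/2), with *no* tie correction, the standard conservative choice
for comparing RDMs that may contain ties — and Spearman's ρ (Pearson on
midranks).  Note a consequence of the τ-a definition: the τ-a of a tied
vector with itself is below 1 (tied pairs count zero), so "identical
matrices correlate perfectly" holds exactly for ρ and only up to the tie
share for τ-a.  Group-level tests on coefficients are one-tailed
signed-rank tests against zero, Bonferroni-corrected over ROIs;
model-vs-model contrasts are two-tailed signed-rank tests on per-subject
coefficient differences.

The **noise ceiling** brackets the best correlation any true model could
achieve: the upper bound is the mean correlation of each subject's
matrix with the group mean including that subject; the lower bound is
the leave-one-subject-out version.

**Model RDMs** (4 × 4, person level): *binary* — 0 within the self pair
and within the other pair, 1 between; *graded* — |position difference|
on the equidistant social-distance spectrum; *behavioral* —
(100 − rating)/100 from each subject's pairwise similarity ratings (a
linear transform of the 0–100 scale; only the scale itself is fixed by
the design).  Degenerate (constant) models are flagged and excluded
from comparisons.

**Hierarchical clustering** is agglomerative with average linkage
(UPGMA) by default — the linkage is a free choice here and is exposed as
a parameter — on 1−r (conditions) or 1−τ/ρ (regions) distances, with
merge bookkeeping exported as a merge table and Newick text.

The **membership × valence ANOVA** computes, per subject and valence
context, the mean rank correlation between ROI pairs within the same
network and between networks, then runs a 2 × 2 repeated-measures ANOVA.
Two aggregations are emitted: pair-weighted (every ROI pair equal) and
network-balanced (each network's within mean weighted equally), since
the pooling level is a free choice.

## Group statistics

* One-sample *t* vs chance (df = n−1); zero-variance inputs are flagged
  with p ∈ {0, 1} by sign convention rather than raising.
* Wilcoxon signed-rank: zeros dropped (Wilcoxon's convention), midranks
  for ties, statistic W⁺.  Exact p by full enumeration of the 2ⁿ sign
  assignments for n ≤ 12; above that, normal approximation with
  continuity correction and the tie-adjusted variance.
* Bonferroni: α/m (0.05/8 = 0.00625 for eight ROIs).
* 2 × 2 repeated-measures ANOVA: explicit within-subject SS
  decomposition, each effect tested against its subject × effect
  interaction, ηp² = SS_effect/(SS_effect + SS_error).
* Univariate contrasts: per subject/ROI/condition mean β over voxels and
  runs, paired two-tailed t tests for all condition pairs, Bonferroni
  over ROIs.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream claim is checked.

**Latent geometry.**  The 8 condition means live in a 6-dimensional
latent space with three orthogonal axes, assigned deterministically:
self/other (±d_self_other/2 by domain), near/far (±d_distance/2; Present
Self and Mother are the near members of their domains, so the distance
code is *shared* across domains — which is exactly what makes
cross-classification schemes 5 and 6 decodable), and valence
(±d_valence/2).  Defaults: d_self_other = 2.0, d_distance = 1.0,
d_valence = 0.3 (arbitrary GLM units).  These encode the qualitative
claims the analyses recover: the bipartite self/other split dominates,
social distance is nested within it (for PresentSelf the latent distance
ordering is PastSelf < Mother < Queen), and identity coding is largely
valence-invariant.  Setting every separation to zero defines the null
geometry used for chance calibration.

**Voxel embedding and noise.**  Each ROI embeds the latent means through
a random matrix with orthonormal columns (norm-preserving, so
information content is governed by the ROI's `info_scale` alone), then
adds run-level Gaussian noise (SD 0.3, shared by all conditions within a
run — a run-specific baseline shift) and voxel-level Gaussian noise
(SD 0.6, independent per β).  Gaussianity is the minimal assumption
matching GLM β sampling behavior; no BOLD time series, HRF convolution
or GLM fitting is simulated — generation starts at the β level.
Default ROIs have 80 voxels each (equal counts by construction, as the
combinatorial analysis requires); DN regions get info_scale 1.0 and SN
regions 0.45, planting the DN > SN information asymmetry.  These SNR
defaults were chosen so the default cohort lands in the qualitative
accuracy range the design targets (binary self/other decoding in the
0.8s for DN, within-domain pairs in the 0.6s, everything above chance
and DN > SN throughout).

**Subjects.**  24 subjects × 8 runs by default.  Each subject perturbs
the condition means with Gaussian jitter (SD = 10% of d_self_other
unless overridden — hence zero in the null geometry), giving shared
structure with individual idiosyncrasy so noise-ceiling bounds are
nondegenerate.  All randomness descends from one seed through spawned
`SeedSequence` streams: identical spec ⇒ bit-identical cohort.

**Behavioral ratings.**  Pairwise person-similarity ratings (0–100,
Gaussian around configurable pair means, clipped).  The default means
encode the reported qualitative pattern — Mother rated closer to
PresentSelf than PastSelf is, Queen distant from everyone familiar —
which is deliberately *not* the bipartite neural geometry, reproducing
the dissociation in which the behavioral model trails the binary and
graded models on neural data.  Per-subject distributions are a
qualitative reconstruction (no per-subject behavioral data exist to
emulate) and fully configurable.

**Volumes.**  4-D β grids (condition-major feature order, 0-based voxel
indices, physical coordinates = index × voxel size) with optional
planted informative spheres; inside a sphere each in-mask voxel gets its
own random latent loading, outside is pure noise, and planted signal
never leaks outside the mask.  Truth centers are recorded for recovery
tests.

**What the generator does not emulate** — and hence what passing tests
do and do not show: spatial autocorrelation and anatomy, physiological
and motion artifacts, HRF/temporal structure, inter-subject anatomical
misalignment, and non-Gaussian noise.  Green tests certify that the
*analysis machinery* is correct and calibrated (engines recover planted
structure; null inputs yield chance-level and FWE-controlled outputs);
they are not evidence about real brains.

## Problem sizes and numerical choices

Test-suite and calibration runs use these sizes, chosen as sensible
desk-scale defaults: 200 signal-free datasets for chance calibration
(Monte-Carlo SE ≈ 0.5 accuracy points for the binary scheme); the full
24-subject cohort for planted-structure recovery; 100 replicate null
map-sets (12³ grid, 12 subjects, 300 permutations) for FWE calibration,
with per-subject accuracy maps simulated directly at the map level —
the exchangeable null the permutation test operates on — since the test's
calibration is a property of the group stage, and the searchlight engine
itself is separately validated by planted-sphere recovery and by the
invariant that a sphere's searchlight value equals ROI decoding on the
same voxels.

Other numerical conventions: sphere membership uses a 1e-9 tolerance on
the radius comparison; Fisher-z averaging clips |r| at 1−1e-6;
rank-correlation of a constant vector is NaN (flagged undefined) rather
than an exception; degenerate statistics are flagged, never silently
dropped, so batch runs over many ROIs and simulations complete.

## Known limitations

* Cross-classification accuracies use two directional "folds"; their
  variance structure differs from cross-validation folds, so per-fold
  spread should not be compared across the two engine types.
* τ-a significance via signed-rank across subjects (not via the τ
  sampling distribution) follows standard RSA practice but assumes
  subject-level exchangeability.
* The 2 × 2 ANOVA has no sphericity issue (one df per effect), but the
  implementation is limited to the 2 × 2 within-subject case.
* The ROI-definition ladder converts p-levels with a caller-supplied df;
  it does not model search-volume corrections for the localizer map.
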