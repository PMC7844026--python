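# Methods

This note documents the models and procedures implemented in `tricomp`,
the defaults they ship with, and the design choices made where the
procedure was genuinely open.

## Compartment eigenvector

For one chromosome, the input is a normalized, symmetric contact matrix
on a fixed bin grid (100 kb by default).  Bins whose row sums to exactly
zero are masked as unassignable and stay missing ("NA") through every
downstream stage.  Asymmetric inputs are symmetrized by `(M + Mᵀ)/2`;
deviations beyond float noise additionally warn.

The pipeline is: observed/expected detrending → Pearson correlation of
columns → eigendecomposition → orientation → scaling.

*Observed/expected.*  Each entry is divided by the mean contact at its
genomic distance (the mean of its diagonal).  This step is on by default
(`oe=False` is available for matrices detrended upstream).  It is
necessary, not cosmetic: on matrices that retain a power-law decay
(exponent ≈ 1), column correlations are dominated by genomic proximity
and the leading eigenvector degenerates into a smooth positional
gradient — on simulated matrices the planted-label accuracy collapses
from ~1.0 to ~0.6 without it, independent of sequencing depth.  Dividing
out the distance expectation is what makes the correlation structure
reflect compartment identity.

*Orientation.*  Eigenvector sign is arbitrary, so the vector is flipped
if its Pearson correlation with an active-chromatin track (H3K4me1
and/or ATAC signal binned as mean peak score) is negative; with two
tracks the mean of the two correlations decides.  A correlation of
exactly zero keeps the orientation and warns.  Orientation is
idempotent.

*Eigenvector choice.*  Rank 1 by default.  An `"auto"` mode picks, among
ranks 1–3, the eigenvector with the largest |correlation| with the
activity track — a reproducible criterion standing in for visual
inspection of eigenvector profiles.

*Scaling.*  Division by the per-chromosome maximum |value| maps
coefficients onto [−1, +1], the scale on which all thresholds are
defined.  Max-abs scaling is the simplest monotone map achieving that
range; any monotone alternative would shift thresholds consistently.

*Sparse chromosomes.*  If fewer than `min_unmasked_fraction` (default
0.5) of bins are usable, the chromosome is emitted all-missing rather
than risking an unstable eigenvector.

## Three-state mixture segmentation

Eigenvector coefficients pooled genome-wide per sample are fit with a
k-component 1-D Gaussian mixture by EM.

* Initialization is deterministic given the data: means at the
  1/(k+1)…k/(k+1) quantiles, equal weights, pooled sd.  Degenerate fits
  (vanishing weight or variance) restart with jittered means up to five
  times; only the jitter consumes the seed.
* Convergence: relative log-likelihood change < 1e-8, max 1000
  iterations.
* BIC = p·ln(n) − 2·lnL with p = 3k − 1 free parameters (k−1 weights,
  k means, k sds), minimized; ties break toward smaller k.  The scan
  covers k = 1…10 by default.  An independent implementation
  (scikit-learn's `GaussianMixture`) is used in the test suite as a
  cross-check oracle for both the optimum and the BIC convention.

With k = 3 the components, sorted by mean, are the inactive,
intermediate and active modes.  The call thresholds are the intersection
points of adjacent *weighted* densities — weighted because that is the
mixture's own classification boundary: IV2 solves
π₁N(x;μ₁,σ₁) = π₂N(x;μ₂,σ₂) on (μ₁, μ₂), IV1 the analogous equation for
the upper pair.  Taking logs turns each into a quadratic solved in
closed form; the root strictly inside the open interval between the two
means is kept.  If no root lies there (heavily overlapping components),
the sd-weighted midpoint (σ₂μ₁ + σ₁μ₂)/(σ₁ + σ₂) is used with a warning.
Per-replicate thresholds are averaged (arithmetic mean) into consensus
thresholds.

Calls follow `A: EV > IV1; I: IV2 ≤ EV ≤ IV1; B: EV < IV2; NA:
missing`.  Boundary values belong to I: the published ranges are closed
on both sides, so ties must go somewhere, and the middle class is the
only assignment that keeps both outer classes strict.  Reference
thresholds of +0.43/−0.63 reported for the original twelve-replicate
B-cell panel are reproducible only with the controlled-access data and
are treated as reference constants, not targets.

## Compartment interaction score

For label L on one chromosome, `cscore(L) = intra / total`, where
`intra` sums contacts over bin pairs both labeled L and `total` over
pairs with at least one bin labeled L.  Each unordered pair is counted
once (upper triangle), the diagonal once, and NA bins are excluded
entirely; this pins the conservation identity Σ_L intra(L) + cross-label
contacts = total chromosomal contacts, which the tests assert exactly.

The phrase "compartments sharing the same segmentation were merged" is
ambiguous between pooling all same-label bins and merging only adjacent
ones, so both are implemented: `label` mode (default) pools per label;
`segment` mode scores each maximal run of same-label bins, counting its
contacts to all same-label bins as intra.  The I compartment's lower
C-score relative to A and B is an emergent consequence of the affinity
structure, not an assertion; it is tested on default simulations at
chromosome sizes (≥ ~600 bins) where the expectation-level ordering
concentrates.

The I compartment can be split by eigenvector sign into IA (EV ≥ 0) and
IB (EV < 0) to verify that low self-interaction is not an artifact of
averaging over the sign boundary.

## Chromatin-state enrichment

States live on a 200-bp grid with an 11-state alphabet (active promoter
and strong enhancer 1 are merged on load).  Seven states are A-related
(merged promoter/enhancer, weak promoter, strong enhancer 2, weak
enhancer, transcription transition/elongation, weak transcription), two
I-related (poised promoter, polycomb-repressed), two B-related
(heterochromatin-repressed, heterochromatin-low-signal).

Per replicate and compartment group, the enrichment is
`freq(state | group) / freq(state | genome)` in covered base pairs;
intervals crossing bin boundaries are split exactly.  The score is the
median across replicates, standardized by columns (states) then rows
(groups).  After the second pass rows are exactly zero-mean/unit-sd
(population sd); columns are only approximately so — an inherent
property of sequential two-way standardization, documented rather than
iterated to convergence.

## Log-ratio comparison maps

`G_σ ∗ log₂((A + ε)/(B + ε))` with pseudocount ε = 1 contact and
Gaussian σ = 1.0 bins, applied separably along both axes (50-kb maps by
default).  Log base and pseudocount are conventions, configurable in
`CompareConfig`.  Bins masked in either matrix are filled with the
nearest usable value (Euclidean distance transform) before smoothing.

## Differentiation dynamics

Labels carry the activity order A > I > B.  A step is activation if the
label moves up (B→I, B→A, I→A), inactivation if down, stable otherwise —
the nine ordered pairs split 3/3/3 and the classifier is antisymmetric.
Bins NA at any state of a path are excluded from that path's
denominators and their count reported.  Reversibility summaries report
(i) the fraction of path-complete bins whose final label equals the
initial one and (ii) among bins activated at the intermediate state, the
fraction inactivating again at the final state.  `transiently_activated`
selects bins active exclusively at the intermediate state (activation
then inactivation), the region class used for fold-change analyses of
chromatin-state groups between time points.

Label-based dynamics and ΔEV-based gain (ΔEV ≥ +0.4, the convention of
the subtype analysis) are distinct read-outs; both are available and
labeled distinctly.

## Differential compartments

Regions with any missing value among the compared samples are removed
first.  Per region a two-sample t-test compares case and control
eigenvector coefficients — Welch by default, since group sizes of 2–7
make the equal-variance assumption untenable (Student variant behind a
flag).  p-values are BH-FDR adjusted across tested regions; a region is
significant when adjusted p < α (0.05) and |Δmean EV| > 0.4.  The
"fold change" wording of the original criterion is implemented as the
absolute eigenvector difference, matching the explicit phrasing
"absolute difference in the eigenvalue > 0.4".  Regions with zero
variance in both groups and equal means get p = 1.

Entity-specific versus shared changes are a set partition
(A∖B, A∩B, B∖A) with counts obeying inclusion–exclusion exactly.  The
four case–control designs of a two-disease study are configuration
presets over this one engine, not separate code paths.

Subtype analysis is two-step: within each subtype, keep regions whose
eigenvector range (max − min across samples; the natural extension of
"difference" to more than two samples) is strictly below 0.4, reporting
the retention fraction; then call regions whose between-subtype mean
difference is ≥ 0.4, the gaining subtype given by the sign.

Monte-Carlo enrichment draws `|regions|` bins uniformly *without*
replacement from the assignable bins per repetition (10,000 by default)
and computes one-tailed empirical p = (1 + #{null ≥ observed})/(n_perm
+ 1), so the smallest achievable p is 1/(n_perm + 1) and p-values are
bit-reproducible given the seed.  Sampling without replacement from the
assignable universe matches the tested universe.  The same machinery
scores flagged-gene overlap enrichment, with genes annotated to bins by
coordinate overlap.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions every pipeline-level claim is evaluated under.

*Labels.*  Alternating segments of geometric length (mean 8 bins ≈
800 kb, echoing blocky compartment structure without modeling TADs),
label drawn per segment from proportions (0.35, 0.33, 0.32) for A/I/B —
the roughly even three-way split seen in per-subpopulation eigenvector
distributions.  Note that with ~n/8 segments per chromosome the realized
fractions of a single draw fluctuate at the segment level, not the bin
level.

*Contact matrices.*  `expected(i,j) = depth · |i−j|^(−α) ·
affinity(Lᵢ, Lⱼ)`, Poisson-sampled on the upper triangle and mirrored.
Defaults: decay α = 1.0 (the physical exponent), depth 100 expected
contacts at distance 1, lognormal whole-matrix jitter sd 0.1 per
replicate.  Affinity: A–A = B–B = 1.0, A–B = 0.2, I–I = 0.6, I–A = I–B
= 0.5 — like-with-like contact for the outer compartments, strong A/B
avoidance, and promiscuous intermediate contact.  The I row is
deliberately *not* dominated by I–I, which is what makes the low I
C-score an emergent prediction the tests can falsify.

*Tracks.*  Activity is Gaussian per label (means 10/4/1 for A/I/B, sd
2) — an H3K4me1/ATAC-like orientation signal.  Chromatin states are
geometric runs of 200-bp windows (mean 10 windows) drawn from
label-conditioned distributions concentrating active states in A bins,
poised/polycomb in I bins, heterochromatin in B bins.

*Cohorts.*  The default design mirrors the study layout: 3 replicates ×
4 normal B-cell states, 7 CLL (5 mCLL + 2 uCLL), 5 MCL (2 cMCL +
3 nnMCL).  Each bin gets one eigenvector *mode* per label, drawn once
per cohort from N(0.70, 0.12)/N(−0.08, 0.18)/N(−0.85, 0.10) for A/I/B
and clipped to [−1, 1]; a sample's value is its label's mode plus
replicate noise (sd 0.05).  Because modes are shared across samples,
unperturbed regions are exactly null between groups.

Planted effects: 30% dynamic bins switch label at the second state
(activation share 0.6, honored up to label headroom — a chromosome that
happens to draw many A segments cannot activate them, so the realized
share, recorded in the truth table, can sit below the design value);
75% of dynamic bins revert at the memory-like state and 30% at the
plasma-like state.  Disease effects shift the eigenvector mode by ±0.8
(direction chosen by headroom) and re-label to the nearest mode — this
plants a controlled ΔEV rather than inheriting the variance of two
independent label modes.  Entity-specific, shared and subtype-specific
region sets are disjoint from each other and from dynamic bins, and are
never also planted missing; random per-sample missingness (rate 0.01)
exercises the missing-value removal path.  The truth object records
every planted fact: per-state and per-subtype label maps, dynamic bins
with patterns, activated/reverted sets, region sets with directions and
realized deltas, eigen modes and patches.

Everything is a pure function of (config, design, seed).

*What the generator does not emulate* — and hence what green tests do
not certify about real data: TAD/loop structure and insulation,
karyotype abnormalities and copy-number effects on coverage,
chromosome-specific biases (planted region sets are uniform across
chromosomes, so chromosome-enrichment tests on them are calibration
checks, not power demonstrations), mapping artifacts, and the empirical
eigenvector distribution of any particular cell type.  Published
genome-wide percentages from the original cohorts (28.1% dynamic, 61.5%
activation share, 72.7%/82.9% memory-state reversal, 348/82 differential
regions, +0.43/−0.63 thresholds, 91.3%/87.1% homogenization retention)
depend on controlled-access data and are reference constants; the
pipeline reproduces their *bookkeeping* (set arithmetic, thresholds,
taxonomies) exactly and their magnitudes only as far as the planted
study conditions imply.

## Problem sizes and numerical choices

Tests and the acceptance script run on 250–1100-bin genomes (25–110 Mb
at 100 kb), 12-replicate threshold panels, 5-vs-5 differential cohorts,
100 null cohorts for the type-I-error check and 10,000 Monte-Carlo
repetitions — sizes chosen so the whole suite completes in about a
minute while keeping every statistical check at the sample sizes the
study design uses (including the smallest group, n = 2).

Degenerate-input behavior is pinned throughout: zero-variance
correlation columns are masked with a warning; EM restarts on collapse
and errors after five attempts; identical mixture components fall back
to their common mean; empty groups, empty gene tables, undersized
sample groups and out-of-range eigenvectors raise informative errors.
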