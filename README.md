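# tricomp

Three-state (A/I/B) chromatin-compartment analysis for Hi-C data.

Genomes segregate at the megabase scale into an active (A) and an
inactive (B) compartment, classically read off the sign of the first
eigenvector of the per-chromosome Hi-C correlation matrix.  Between the
two extremes sits a third, *intermediate* (I) compartment: a band of
eigenvector values enriched in poised-promoter and polycomb-repressed
chromatin, with weaker self-interaction than either A or B.  `tricomp`
implements the full analysis around this three-state view for studies of
cell differentiation and disease cohorts — typified by B-cell maturation
(naive → germinal-center → memory/plasma cells) and mature B-cell
neoplasms (CLL, MCL) with their clinico-biological subtypes.

## What it computes

* **Compartment eigenvector** — per chromosome, the normalized contact
  matrix is observed/expected-detrended, transformed into a Pearson
  correlation matrix, and decomposed; the leading eigenvector is
  oriented by active-chromatin signal (H3K4me1/ATAC) and scaled to
  [−1, +1].
* **Three-state segmentation** — eigenvector coefficients pooled per
  sample are modeled as a k-component Gaussian mixture fit by EM; BIC
  (p = 3k − 1, minimized) selects k.  With k = 3, the intersection
  points of adjacent weighted component densities define the call
  thresholds IV1 (A/I) and IV2 (I/B):
  `A: EV > IV1;  I: IV2 ≤ EV ≤ IV1;  B: EV < IV2`.  Replicate-level
  thresholds are averaged into a consensus before calling.
* **Compartment interaction score (C-score)** — intra-compartment
  contacts over all chromosomal contacts involving the compartment; the
  I compartment scores below A and B, its defining structural property.
* **Chromatin-state enrichment** — 11-state (200-bp) segmentations
  summarized per compartment group as genome-corrected frequencies,
  median across replicates, column- then row-standardized.
* **Differentiation dynamics** — transitions along a cell-state path
  classified by the activity order A > I > B into activation /
  inactivation / stable, with reversibility summaries (how much of the
  genome returns to its initial compartment) and state-group fold
  changes.
* **Differential compartments** — per 100-kb region, Welch t-tests of
  eigenvector coefficients between groups with Benjamini–Hochberg FDR;
  significant when adjusted p < 0.05 and |ΔEV| > 0.4.  Entity-specific
  vs shared changes by set partition; subtype-specific regions by
  within-subtype homogenization (range < 0.4) plus between-subtype mean
  difference ≥ 0.4; one-tailed Monte-Carlo tests for chromosome- and
  gene-level enrichment (p floor 1/(n_perm + 1)).
* **Synthetic cohorts** — a block-model Hi-C simulator (power-law decay
  × compartment-affinity, Poisson counts) plus cohort generator with
  planted dynamics, disease and subtype effects and exhaustive truth
  tables, so the whole pipeline is testable without controlled-access
  data.

## Worked example

```python
import numpy as np
from tricomp import eigencomp, segmentation, scores, synthetic_data as sd

cfg = sd.SimulationConfig(chromosome_sizes={"chr1": 40_000_000})
labels = sd.simulate_labels(cfg, seed=1)
activity, states = sd.simulate_tracks(labels, cfg, seed=2)
cm = sd.simulate_contact_matrix(labels, cfg, "chr1", seed=3)

ev = eigencomp.compartment_eigenvector(cm, activity, sample_id="rep1")
values = ev.values[np.isfinite(ev.values)]
table, k = segmentation.bic_scan(values, range(1, 7), seed=0)
model = segmentation.fit_gaussian_mixture(values, k=3, seed=0)
thresholds = segmentation.mixture_intersections(model)
calls = segmentation.call_compartments(ev, thresholds)
cscores = scores.compartment_score(cm, calls)

print(f"BIC selects k = {k}")
print(f"component means: {np.round(model.means, 3)}")
print(f"thresholds: IV1 = {thresholds.iv1:+.3f}, IV2 = {thresholds.iv2:+.3f}")
print(f"label accuracy vs planted truth: {(calls.labels == labels).mean():.3f}")
print(cscores.round(3).to_string(index=False))
```

Output:

```
BIC selects k = 3
component means: [-0.768  0.001  0.663]
thresholds: IV1 = +0.318, IV2 = -0.357
label accuracy vs planted truth: 1.000
chromosome label  intra_contacts  total_contacts  cscore
      chr1     A         98875.0        125394.0   0.789
      chr1     I         23216.0         55276.0   0.420
      chr1     B         73245.0         97834.0   0.749
```

The mixture finds the three eigenvector modes, the density
intersections become the A/I and I/B thresholds, every bin recovers its
planted label, and the intermediate compartment's C-score (0.42) sits
well below A (0.79) and B (0.75) — the signature of a compartment that
interacts promiscuously instead of with itself.

A command-line interface mirrors the library
(`tricomp eigen | segment | cscore | compare-maps | dynamics | diff |
enrich-chrom | simulate`); run `tricomp --help` for details.

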