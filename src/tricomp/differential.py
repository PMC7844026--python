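"""Differential compartment statistics between sample groups.

Per 100-kb region, a Welch two-sample t-test compares eigenvector
coefficients between a case and a control group; p-values are adjusted
by Benjamini-Hochberg FDR and a region is significant when the adjusted
p falls below ``alpha`` and the absolute group-mean difference exceeds
``delta_min`` (default 0.4 on the [-1, 1] eigenvector scale).  Regions
with any missing value among the compared samples are removed before
testing.

Subtype-specific regions use a two-step rule: within-subtype
homogenization (retain regions whose within-subtype eigenvector range is
below ``homog_max``) followed by a between-subtype mean-difference
threshold.  Chromosome- and gene-level enrichment of region sets is
assessed by one-tailed Monte-Carlo resampling of equally sized random
bin sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hic_io import BinGrid

__all__ = [
    "EVMatrix",
    "AnalysisConfig",
    "SpecificityPartition",
    "differential_compartments",
    "specificity_partition",
    "subtype_regions",
    "chromosome_enrichment_mc",
    "region_gene_enrichment_mc",
]


@dataclass
class EVMatrix:
    """Regions x samples matrix of eigenvector coefficients.

    ``values`` has one row per grid bin (region) and one column per
    sample; NaN marks regions unassigned in a sample.  ``sample_groups``
    maps sample name to its group label (cell state, disease or subtype).
    """

    grid: BinGrid
    values: pd.DataFrame
    sample_groups: Mapping[str, str]

    def __post_init__(self):
        if self.values.shape[0] != self.grid.n_bins:
            raise ValueError("EV matrix rows must match grid bins")
        missing = set(self.values.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns
                if self.sample_groups[s] == group]


@dataclass
class AnalysisConfig:
    """Thresholds and Monte-Carlo settings for differential analyses."""

    alpha: float = 0.05            # BH-adjusted p cutoff
    delta_min: float = 0.4         # minimum |mean EV difference|
    homog_max: float = 0.4         # within-subtype EV range cutoff (strict <)
    subtype_min_delta: float = 0.4  # between-subtype mean difference (>=)
    n_perm: int = 10_000
    seed: int = 0
    equal_var: bool = False        # Welch by default

    def __post_init__(self):
        for name in ("alpha", "delta_min", "homog_max", "subtype_min_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def differential_compartments(evm: EVMatrix, case_group: str,
                              control_group: str,
                              cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Case-vs-control t-test per region with BH-FDR adjustment.

    Returns one row per tested region (regions with any missing value
    among the compared samples are dropped) with columns: region,
    bin_index, mean_case, mean_control, delta, t_statistic, p_value,
    p_adjusted, significant, direction.
    """
    cfg = cfg or AnalysisConfig()
    case_cols = evm.samples_of(case_group)
    ctrl_cols = evm.samples_of(control_group)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each group needs at least 2 samples "
                         f"(case={len(case_cols)}, control={len(ctrl_cols)})")
    sub = evm.values[case_cols + ctrl_cols]
    complete = sub.notna().all(axis=1).to_numpy()
    case = evm.values.loc[complete, case_cols].to_numpy(float)
    ctrl = evm.values.loc[complete, ctrl_cols].to_numpy(float)
    idx = np.flatnonzero(complete)
    if idx.size == 0:
        raise ValueError("no regions without missing values")
    import warnings as _warnings
    with np.errstate(divide="ignore", invalid="ignore"), \
            _warnings.catch_warnings():
        # near-constant null rows trigger scipy's precision-loss warning
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(case, ctrl, axis=1,
                               equal_var=cfg.equal_var)
    delta = case.mean(axis=1) - ctrl.mean(axis=1)
    # degenerate rows: zero variance in both groups
    degen = ~np.isfinite(p)
    p = np.where(degen & (delta == 0), 1.0, p)
    p = np.where(degen & (delta != 0), 0.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(np.isfinite(t), t, np.where(delta == 0, 0.0,
                                                 np.sign(delta) * np.inf))
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    significant = (p_adj < cfg.alpha) & (np.abs(delta) > cfg.delta_min)
    ids = evm.values.index.to_numpy()[idx]
    return pd.DataFrame({
        "region": ids,
        "bin_index": idx,
        "mean_case": case.mean(axis=1),
        "mean_control": ctrl.mean(axis=1),
        "delta": delta,
        "t_statistic": t,
        "p_value": p,
        "p_adjusted": p_adj,
        "significant": significant,
        "direction": np.where(delta > 0, "activation", "inactivation"),
    })


@dataclass
class SpecificityPartition:
    common: np.ndarray
    a_specific: np.ndarray
    b_specific: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {"common": self.common.size,
                "a_specific": self.a_specific.size,
                "b_specific": self.b_specific.size}


def specificity_partition(set_a, set_b) -> SpecificityPartition:
    """Split two region sets into shared and set-specific parts.

    ``a_specific = A \\ B``, ``b_specific = B \\ A``, ``common = A & B``;
    the three parts tile A | B exactly.
    """
    a = np.asarray(sorted(set(np.asarray(list(set_a)).tolist())))
    b = np.asarray(sorted(set(np.asarray(list(set_b)).tolist())))
    common = np.intersect1d(a, b)
    return SpecificityPartition(
        common=common,
        a_specific=np.setdiff1d(a, b),
        b_specific=np.setdiff1d(b, a))


def subtype_regions(evm: EVMatrix, subtype1: str, subtype2: str,
                    cfg: AnalysisConfig | None = None
                    ) -> tuple[pd.DataFrame, float]:
    """Subtype-distinct regions within one disease.

    Step 1 (homogenization): drop regions with any missing value, then
    retain regions whose within-subtype eigenvector range (max - min) is
    strictly below ``homog_max`` in *both* subtypes; the retention
    fraction is returned alongside the result.  Step 2: a retained
    region is significant when the absolute difference of subtype means
    is at least ``subtype_min_delta``; its direction names the subtype
    gaining activity.
    """
    cfg = cfg or AnalysisConfig()
    cols1 = evm.samples_of(subtype1)
    cols2 = evm.samples_of(subtype2)
    if not cols1 or not cols2:
        raise ValueError("both subtypes need at least one sample")
    sub = evm.values[cols1 + cols2]
    complete = sub.notna().all(axis=1).to_numpy()
    idx = np.flatnonzero(complete)
    v1 = evm.values.loc[complete, cols1].to_numpy(float)
    v2 = evm.values.loc[complete, cols2].to_numpy(float)
    range1 = v1.max(axis=1) - v1.min(axis=1)
    range2 = v2.max(axis=1) - v2.min(axis=1)
    homogeneous = (range1 < cfg.homog_max) & (range2 < cfg.homog_max)
    retention = float(homogeneous.mean()) if idx.size else float("nan")
    idx = idx[homogeneous]
    m1 = v1[homogeneous].mean(axis=1)
    m2 = v2[homogeneous].mean(axis=1)
    delta = m1 - m2
    significant = np.abs(delta) >= cfg.subtype_min_delta
    out = pd.DataFrame({
        "region": evm.values.index.to_numpy()[idx],
        "bin_index": idx,
        f"mean_{subtype1}": m1,
        f"mean_{subtype2}": m2,
        "delta": delta,
        "significant": significant,
        "direction": np.where(delta >= 0, f"{subtype1}_gain",
                              f"{subtype2}_gain"),
    })
    return out, retention


# ---------------------------------------------------------------------------
# Monte-Carlo enrichment
# ---------------------------------------------------------------------------

def _empirical_p(null_ge_obs: np.ndarray, n_perm: int) -> np.ndarray:
    """One-tailed Monte-Carlo p with the +1 correction; the floor is
    ``1 / (n_perm + 1)``."""
    return (1.0 + null_ge_obs) / (n_perm + 1.0)


def chromosome_enrichment_mc(regions, grid: BinGrid,
                             cfg: AnalysisConfig | None = None,
                             assignable: np.ndarray | None = None
                             ) -> pd.DataFrame:
    """Per-chromosome enrichment of a region set by Monte-Carlo resampling.

    Each repetition draws ``|regions|`` bins uniformly without
    replacement from the assignable bins and tallies counts per
    chromosome; ``p = (1 + #{count >= observed}) / (n_perm + 1)``.
    ``assignable`` restricts the sampling universe (default: all bins).
    """
    cfg = cfg or AnalysisConfig()
    regions = np.asarray(list(regions), dtype=int)
    if regions.size < 1:
        raise ValueError("need at least one region")
    if assignable is None:
        assignable = np.ones(grid.n_bins, bool)
    pool = np.flatnonzero(assignable)
    if regions.size > pool.size:
        raise ValueError("more regions than assignable bins")
    chroms = list(grid.chromosomes)
    chrom_idx = {c: i for i, c in enumerate(chroms)}
    bin_chrom = np.array([chrom_idx[c] for c in grid.bin_chromosomes()])
    observed = np.bincount(bin_chrom[regions], minlength=len(chroms))
    rng = np.random.default_rng(cfg.seed)
    ge = np.zeros(len(chroms), dtype=int)
    exp_sum = np.zeros(len(chroms))
    for _ in range(cfg.n_perm):
        draw = rng.choice(pool, size=regions.size, replace=False)
        counts = np.bincount(bin_chrom[draw], minlength=len(chroms))
        ge += counts >= observed
        exp_sum += counts
    return pd.DataFrame({
        "chromosome": chroms,
        "observed": observed,
        "expected_mean": exp_sum / cfg.n_perm,
        "p_value": _empirical_p(ge, cfg.n_perm),
    })


def region_gene_enrichment_mc(regions, genes: pd.DataFrame,
                              flagged_genes, grid: BinGrid,
                              cfg: AnalysisConfig | None = None,
                              assignable: np.ndarray | None = None
                              ) -> dict[str, float]:
    """Enrichment of flagged genes within a region set, Monte-Carlo.

    ``genes`` needs columns (chromosome, start, end, gene_id); a gene
    overlaps the region set if any of its bins is in the set.  The null
    redraws an equally sized random bin set per repetition and counts
    flagged genes overlapping it.
    """
    cfg = cfg or AnalysisConfig()
    if genes.empty:
        raise ValueError("empty gene table")
    regions = np.asarray(list(regions), dtype=int)
    flagged = set(flagged_genes)
    res = grid.resolution
    # flagged-gene -> set of overlapped bins
    gene_bins: list[np.ndarray] = []
    for _, row in genes.iterrows():
        if row["gene_id"] not in flagged:
            continue
        off = grid.offset_of(row["chromosome"])
        first = int(row["start"]) // res
        last = (int(row["end"]) - 1) // res
        gene_bins.append(np.arange(off + first, off + last + 1))
    n_bins = grid.n_bins
    # bin -> flagged gene incidence matrix (genes are few; boolean rows)
    hit = np.zeros((len(gene_bins), n_bins), dtype=bool)
    for gi, bins_ in enumerate(gene_bins):
        hit[gi, bins_] = True
    in_set = np.zeros(n_bins, dtype=bool)
    in_set[regions] = True
    observed = int((hit @ in_set > 0).sum()) if len(gene_bins) else 0
    if assignable is None:
        assignable = np.ones(n_bins, bool)
    pool = np.flatnonzero(assignable)
    if regions.size > pool.size:
        raise ValueError("more regions than assignable bins")
    rng = np.random.default_rng(cfg.seed)
    ge = 0
    for _ in range(cfg.n_perm):
        draw = rng.choice(pool, size=regions.size, replace=False)
        sel = np.zeros(n_bins, dtype=bool)
        sel[draw] = True
        count = int((hit @ sel > 0).sum()) if len(gene_bins) else 0
        ge += count >= observed
    return {"observed": float(observed),
            "p_value": float(_empirical_p(np.array(ge), cfg.n_perm)),
            "n_flagged": float(len(gene_bins))}
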