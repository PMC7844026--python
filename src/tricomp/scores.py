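"""Compartment behavior metrics.

* C-score (compartment interaction score): intra-compartment contacts
  over total chromosomal contacts involving the compartment.  The
  intermediate compartment interacts promiscuously with both active and
  inactive chromatin, so its C-score sits below both the A and B scores.
* IA/IB split of the intermediate compartment by eigenvector sign.
* Chromatin-state enrichment matrices for compartment groups
  (genome-frequency-corrected state frequencies, median across
  replicates, column- then row-standardized).
* Smoothed log-ratio contact maps for comparing two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .eigencomp import EigenTrack
from .hic_io import BinGrid, ContactMatrix, StateSegmentation
from .segmentation import CompartmentCall

__all__ = [
    "CompareConfig",
    "compartment_score",
    "split_intermediate",
    "corrected_state_frequencies",
    "state_enrichment",
    "log_ratio_map",
]


@dataclass
class CompareConfig:
    """Parameters for condition-vs-condition contact-map comparison."""

    log_base: float = 2.0
    pseudocount: float = 1.0
    sigma: float = 1.0          # Gaussian smoothing sd, in bins
    map_resolution: int = 50_000

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# C-score
# ---------------------------------------------------------------------------

def _upper(values: np.ndarray) -> np.ndarray:
    """Upper triangle including the diagonal: each unordered bin pair
    (and each diagonal entry) counted exactly once."""
    return np.triu(values)


def compartment_score(cm: ContactMatrix, calls: CompartmentCall,
                      mode: str = "label") -> pd.DataFrame:
    """Intra-compartment contact fraction per label (or per segment).

    ``label`` mode: for each label L on the chromosome, ``intra`` sums
    contacts over bin pairs both labeled L and ``total`` over pairs with
    at least one bin labeled L; ``cscore = intra / total``.  Pairs are
    counted once (upper triangle, diagonal included); bins labeled NA are
    excluded entirely.

    ``segment`` mode: maximal runs of adjacent same-label bins become
    segments; for each segment, ``intra`` sums contacts between its bins
    and all same-label (non-NA) bins, ``total`` all contacts involving
    its bins and any non-NA bin.

    Returns a frame with columns (chromosome, label[, segment_id, start,
    end], intra_contacts, total_contacts, cscore).
    """
    if calls.grid.n_bins != cm.n_bins:
        raise ValueError("calls and matrix must share the grid")
    labels = calls.labels
    chrom = cm.chromosome
    valid = labels != "NA"
    W = _upper(cm.values)
    rows = []
    if mode == "label":
        for lab in _present_labels(labels):
            m = labels == lab
            o = valid & ~m
            intra = float(W[np.ix_(m, m)].sum())
            cross = float(W[np.ix_(m, o)].sum() + W[np.ix_(o, m)].sum())
            total = intra + cross
            if total == 0:
                continue
            rows.append((chrom, lab, intra, total, intra / total))
        return pd.DataFrame(rows, columns=[
            "chromosome", "label", "intra_contacts", "total_contacts",
            "cscore"])
    elif mode == "segment":
        res = cm.grid.resolution
        for seg_id, (i0, i1, lab) in enumerate(_segments(labels)):
            if lab == "NA":
                continue
            m = np.zeros(labels.shape[0], bool)
            m[i0:i1] = True
            same = (labels == lab) & ~m
            other = valid & ~m & ~same
            within = float(W[np.ix_(m, m)].sum())
            to_same = float(W[np.ix_(m, same)].sum()
                            + W[np.ix_(same, m)].sum())
            to_other = float(W[np.ix_(m, other)].sum()
                             + W[np.ix_(other, m)].sum())
            intra = within + to_same
            total = within + to_same + to_other
            if total == 0:
                continue
            rows.append((chrom, lab, seg_id, i0 * res, i1 * res,
                         intra, total, intra / total))
        return pd.DataFrame(rows, columns=[
            "chromosome", "label", "segment_id", "start", "end",
            "intra_contacts", "total_contacts", "cscore"])
    raise ValueError(f"unknown mode {mode!r}")


def _present_labels(labels: np.ndarray) -> list[str]:
    order = ["A", "IA", "I", "IB", "B"]
    present = set(np.unique(labels)) - {"NA"}
    return [l for l in order if l in present]


def _segments(labels: np.ndarray):
    """Yield (start_bin, end_bin, label) for maximal same-label runs."""
    n = labels.shape[0]
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        yield i, j, labels[i]
        i = j


def split_intermediate(calls: CompartmentCall, ev: EigenTrack) -> CompartmentCall:
    """Split I bins by eigenvector sign: IA for ev >= 0, IB for ev < 0."""
    if ev.grid.n_bins != calls.grid.n_bins:
        raise ValueError("calls and eigenvector must share the grid")
    labels = calls.labels.copy()
    is_i = labels == "I"
    labels[is_i & (ev.values >= 0)] = "IA"
    labels[is_i & (ev.values < 0)] = "IB"
    return CompartmentCall(grid=calls.grid, labels=labels,
                           thresholds=calls.thresholds,
                           sample_id=calls.sample_id)


# ---------------------------------------------------------------------------
# chromatin-state enrichment
# ---------------------------------------------------------------------------

def state_bp_by_bin(seg: StateSegmentation, grid: BinGrid) -> pd.DataFrame:
    """Base pairs of each chromatin state within each grid bin.

    Returns a (n_bins x states) frame; intervals crossing bin boundaries
    are split so every base pair lands in exactly one bin.
    """
    res = grid.resolution
    n = grid.n_bins
    states = list(seg.alphabet)
    out = np.zeros((n, len(states)))
    state_idx = {s: i for i, s in enumerate(states)}
    for chrom, sub in seg.intervals.groupby("chromosome", sort=False):
        if chrom not in grid.chromosome_sizes:
            raise ValueError(f"unknown chromosome {chrom!r} in segmentation")
        off = grid.offset_of(chrom)
        starts = sub["start"].to_numpy(int)
        ends = sub["end"].to_numpy(int)
        sidx = sub["state"].map(state_idx).to_numpy(int)
        first = starts // res
        last = (ends - 1) // res
        simple = first == last
        # fast path: interval within one bin
        np.add.at(out, (off + first[simple], sidx[simple]),
                  (ends - starts)[simple])
        # spanning intervals: split per bin
        for s, e, si in zip(starts[~simple], ends[~simple], sidx[~simple]):
            b = s // res
            while s < e:
                edge = min((b + 1) * res, e)
                out[off + b, si] += edge - s
                s = edge
                b += 1
    return pd.DataFrame(out, columns=states)


def corrected_state_frequencies(seg: StateSegmentation, groups: np.ndarray,
                                grid: BinGrid) -> pd.DataFrame:
    """Group x state table of genome-corrected state frequencies.

    ``frequency(state | group) / frequency(state | genome)``, both in
    base pairs of segmentation coverage.  A value of 1 means the state is
    as frequent in the group as genome-wide.
    """
    groups = np.asarray(groups)
    group_names = [g for g in pd.unique(groups) if g not in ("NA", "")]
    if not group_names:
        raise ValueError("no groups assigned")
    bp = state_bp_by_bin(seg, grid)
    genome_bp = bp.to_numpy().sum()
    if genome_bp == 0:
        raise ValueError("segmentation covers zero base pairs")
    genome_frac = bp.sum(axis=0) / genome_bp
    rows = {}
    for g in group_names:
        sel = groups == g
        if not sel.any():
            raise ValueError(f"group {g!r} has zero bins")
        g_bp = bp.loc[sel].sum(axis=0)
        g_total = g_bp.sum()
        if g_total == 0:
            raise ValueError(f"group {g!r} has zero covered base pairs")
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[g] = (g_bp / g_total) / genome_frac
    return pd.DataFrame(rows).T.loc[group_names]


def state_enrichment(segmentations: Sequence[StateSegmentation],
                     groups: np.ndarray, grid: BinGrid) -> pd.DataFrame:
    """Compartment-group x chromatin-state enrichment score matrix.

    Per replicate and group, the state frequency within the group's bins
    is divided by the state's genome-wide frequency (see
    :func:`corrected_state_frequencies`).  The enrichment score is the
    median of that corrected frequency across replicates, standardized by
    columns (states) and then by rows (groups).

    ``groups`` assigns every bin a group label; bins labeled ``"NA"`` (or
    empty) are ignored.  A group with zero assigned bins raises.
    """
    per_rep = [corrected_state_frequencies(seg, groups, grid)
               for seg in segmentations]
    med = pd.concat(per_rep).groupby(level=0, sort=False).median()
    med = med.loc[per_rep[0].index]
    return _scale_cols_then_rows(med)


def _zscore(a: np.ndarray, axis: int) -> np.ndarray:
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=0, keepdims=True)
    out = a - mean
    nonzero = np.broadcast_to(sd > 0, out.shape)
    out[nonzero] = out[nonzero] / np.broadcast_to(sd, out.shape)[nonzero]
    return out


def _scale_cols_then_rows(df: pd.DataFrame) -> pd.DataFrame:
    a = df.to_numpy(float)
    a = np.where(np.isfinite(a), a, 0.0)
    a = _zscore(a, axis=0)   # columns
    a = _zscore(a, axis=1)   # rows
    return pd.DataFrame(a, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# log-ratio comparison maps
# ---------------------------------------------------------------------------

def log_ratio_map(cm_a: ContactMatrix, cm_b: ContactMatrix,
                  cfg: CompareConfig | None = None) -> np.ndarray:
    """Gaussian-smoothed log ratio of two contact maps on the same grid.

    ``out = G_sigma * log_base((A + eps) / (B + eps))`` with the filter
    applied separably along both axes.  Bins masked in either matrix are
    filled with the nearest usable value before smoothing.
    """
    cfg = cfg or CompareConfig()
    if cm_a.grid != cm_b.grid:
        raise ValueError("contact maps must share the grid")
    eps = cfg.pseudocount
    ratio = (np.log((cm_a.values + eps) / (cm_b.values + eps))
             / np.log(cfg.log_base))
    bad = ~(cm_a.mask & cm_b.mask)
    if bad.any() and not bad.all():
        bad2d = bad[:, None] | bad[None, :]
        # nearest-neighbour fill of unusable rows/columns
        idx = ndimage.distance_transform_edt(
            bad2d, return_distances=False, return_indices=True)
        ratio = ratio[tuple(idx)]
    if cfg.sigma > 0:
        ratio = ndimage.gaussian_filter(ratio, cfg.sigma)
    return ratio
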