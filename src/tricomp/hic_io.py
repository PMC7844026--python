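"""Genomic I/O on a fixed bin grid.

Everything downstream of this module works on a :class:`BinGrid` — an
ordered tiling of each chromosome into fixed-width bins (100 kb for
compartment analysis, 50 kb for comparison maps, 200 bp for chromatin
states).  Coordinates are 0-based half-open (BED convention) throughout;
formats that need 1-based coordinates convert at the boundary.

Readers and writers are provided for dense contact-matrix TSVs, scored
interval files (BED with score / bedGraph), chromatin-state segmentations
(BED4) and per-bin compartment calls (BED4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BinGrid",
    "ContactMatrix",
    "BinTrack",
    "StateSegmentation",
    "RAW_STATES",
    "MERGED_STATE",
    "STATE_ALPHABET",
    "STATE_GROUPS",
    "read_chromosome_sizes",
    "load_contact_matrix",
    "contact_matrix_from_array",
    "write_contact_matrix",
    "bin_scored_intervals",
    "load_state_segmentation",
    "segmentation_from_frame",
    "write_compartment_bed",
    "read_compartment_bed",
    "write_bedgraph",
    "read_bedgraph",
]

# ---------------------------------------------------------------------------
# chromatin-state vocabulary
#
# The 12-state hidden-Markov segmentation of histone marks; active promoter
# and strong enhancer 1 behave as one regulatory state and are merged on
# load, giving the 11-state alphabet used for all enrichment analyses.
# States group by the compartment they track: active chromatin (A), poised/
# polycomb facultative heterochromatin (I), constitutive heterochromatin (B).
# ---------------------------------------------------------------------------

MERGED_STATE = "ActProm-StrEnh1"

RAW_STATES: tuple[str, ...] = (
    "ActProm", "StrEnh1", "WkProm", "StrEnh2", "WkEnh",
    "TxnTrans", "TxnElong", "WkTxn",
    "PoisProm", "PolycombRepr",
    "Het;Repr", "Het;LowSign",
)

STATE_ALPHABET: tuple[str, ...] = (
    MERGED_STATE, "WkProm", "StrEnh2", "WkEnh",
    "TxnTrans", "TxnElong", "WkTxn",
    "PoisProm", "PolycombRepr",
    "Het;Repr", "Het;LowSign",
)

STATE_GROUPS: dict[str, str] = {
    MERGED_STATE: "A-related",
    "WkProm": "A-related",
    "StrEnh2": "A-related",
    "WkEnh": "A-related",
    "TxnTrans": "A-related",
    "TxnElong": "A-related",
    "WkTxn": "A-related",
    "PoisProm": "I-related",
    "PolycombRepr": "I-related",
    "Het;Repr": "B-related",
    "Het;LowSign": "B-related",
}

_RAW_TO_MERGED = {s: (MERGED_STATE if s in ("ActProm", "StrEnh1") else s)
                  for s in RAW_STATES}


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome.

    Parameters
    ----------
    chromosome_sizes
        Ordered mapping chromosome name -> length in bp.  Chromosome order
        defines the genome-wide bin order.
    resolution
        Bin width in bp (default 100 kb).  The last bin of each chromosome
        may be shorter than ``resolution``.
    """

    chromosome_sizes: Mapping[str, int]
    resolution: int = 100_000

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for chrom, size in self.chromosome_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive size")

    # -- structure ---------------------------------------------------------

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.chromosome_sizes)

    def n_bins_of(self, chrom: str) -> int:
        size = self.chromosome_sizes[chrom]
        return -(-size // self.resolution)  # ceil division

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_of(c) for c in self.chromosomes)

    def offset_of(self, chrom: str) -> int:
        """Genome-wide index of the first bin of *chrom*."""
        off = 0
        for c in self.chromosomes:
            if c == chrom:
                return off
            off += self.n_bins_of(c)
        raise KeyError(chrom)

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offset_of(chrom)
        return slice(off, off + self.n_bins_of(chrom))

    def subset(self, chrom: str) -> "BinGrid":
        """Grid restricted to a single chromosome."""
        return BinGrid({chrom: self.chromosome_sizes[chrom]}, self.resolution)

    def bins(self) -> pd.DataFrame:
        """All bins as a (chromosome, start, end) frame in genome order."""
        rows = []
        for chrom in self.chromosomes:
            size = self.chromosome_sizes[chrom]
            starts = np.arange(0, size, self.resolution)
            ends = np.minimum(starts + self.resolution, size)
            rows.append(pd.DataFrame(
                {"chromosome": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def bin_ids(self) -> np.ndarray:
        """``chrom:start-end`` identifier per bin, genome order."""
        b = self.bins()
        return (b["chromosome"].astype(str) + ":" + b["start"].astype(str)
                + "-" + b["end"].astype(str)).to_numpy()

    def bin_chromosomes(self) -> np.ndarray:
        """Chromosome name per genome-wide bin."""
        return np.concatenate([
            np.repeat(c, self.n_bins_of(c)) for c in self.chromosomes])


@dataclass
class ContactMatrix:
    """Symmetric normalized Hi-C contact matrix for one chromosome.

    ``mask`` is True for usable bins; a bin whose row sums to exactly zero
    is unusable (too sparse to assign) and is excluded from all
    computation downstream.
    """

    grid: BinGrid
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if len(self.grid.chromosomes) != 1:
            raise ValueError("ContactMatrix grid must cover one chromosome")
        self.values = np.asarray(self.values, dtype=float)
        n = self.grid.n_bins
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix is {self.values.shape[0]}x{self.values.shape[1]} "
                f"but grid has {n} bins")
        if np.any(self.values < 0):
            raise ValueError("contact matrix has negative entries")
        if self.mask is None:
            self.mask = self.values.sum(axis=1) > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length does not match grid")

    @property
    def chromosome(self) -> str:
        return self.grid.chromosomes[0]

    @property
    def n_bins(self) -> int:
        return self.grid.n_bins


@dataclass
class BinTrack:
    """Per-bin real-valued signal on a grid; NaN marks missing bins."""

    grid: BinGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("track length does not match grid")
        present = np.isfinite(self.values) | np.isnan(self.values)
        if not present.all():
            raise ValueError("track contains non-finite, non-NaN values")


@dataclass
class StateSegmentation:
    """Chromatin-state intervals (200-bp granularity) over the 11-state
    alphabet, with the A/I/B-related grouping."""

    intervals: pd.DataFrame  # columns: chromosome, start, end, state
    alphabet: tuple[str, ...] = STATE_ALPHABET
    group_map: Mapping[str, str] = field(default_factory=lambda: dict(STATE_GROUPS))

    def __post_init__(self):
        required = {"chromosome", "start", "end", "state"}
        if not required.issubset(self.intervals.columns):
            raise ValueError(f"intervals need columns {sorted(required)}")
        unknown = set(self.intervals["state"]) - set(self.alphabet)
        if unknown:
            raise ValueError(
                f"states {sorted(unknown)} not in alphabet {self.alphabet}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chromosome_sizes(path) -> dict[str, int]:
    """Two-column whitespace TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chromosome", "size"])
    return dict(zip(df["chromosome"], df["size"].astype(int)))


def load_contact_matrix(path, chromosome: str, grid: BinGrid,
                        sym_tol: float = 1e-8) -> ContactMatrix:
    """Load a dense whitespace-separated square matrix for one chromosome.

    Bins with an all-zero row are masked.  Asymmetries beyond ``sym_tol``
    (relative to the largest entry) are symmetrized by ``(M + M.T)/2`` with
    a warning; smaller float noise is symmetrized silently.
    """
    values = np.loadtxt(path, ndmin=2)
    sub = grid.subset(chromosome)
    n = sub.n_bins
    if values.shape != (n, n):
        raise ValueError(
            f"matrix in {path} has {values.shape[0]}x{values.shape[1]} bins, "
            f"expected {n}x{n} for {chromosome} at {grid.resolution} bp")
    if np.any(values < 0):
        raise ValueError(f"matrix in {path} has negative entries")
    asym = np.abs(values - values.T).max()
    scale = max(np.abs(values).max(), 1.0)
    if asym > sym_tol * scale:
        warnings.warn(
            f"matrix in {path} asymmetric (max deviation {asym:.3g}); "
            "symmetrizing by averaging")
    if asym > 0:
        values = (values + values.T) / 2.0
    return ContactMatrix(grid=sub, values=values)


def contact_matrix_from_array(values: np.ndarray, chromosome: str,
                              grid: BinGrid) -> ContactMatrix:
    """Wrap an in-memory symmetric array as a ContactMatrix."""
    return ContactMatrix(grid=grid.subset(chromosome),
                         values=(np.asarray(values, float)
                                 + np.asarray(values, float).T) / 2.0)


def write_contact_matrix(cm: ContactMatrix, path) -> None:
    np.savetxt(path, cm.values, delimiter="\t", fmt="%.10g")


def bin_scored_intervals(peaks, grid: BinGrid, name: str = "") -> BinTrack:
    """Aggregate scored intervals to a per-bin track.

    The bin value is the unweighted mean of the scores of all peaks
    overlapping the bin (bedmap --mean semantics: a peak spanning two bins
    contributes its full score to both).  Bins with no overlapping peak are
    missing (NaN).

    ``peaks`` is a path to a BED5 (score in column 5) or bedGraph (value in
    column 4) file, or an equivalent DataFrame with columns
    (chromosome, start, end, score).
    """
    if isinstance(peaks, pd.DataFrame):
        df = peaks[["chromosome", "start", "end", "score"]].copy()
    else:
        df = _read_scored_intervals(peaks)
    res = grid.resolution
    total = np.zeros(grid.n_bins)
    count = np.zeros(grid.n_bins, dtype=int)
    for chrom, sub in df.groupby("chromosome", sort=False):
        if chrom not in grid.chromosome_sizes:
            raise ValueError(f"unknown chromosome {chrom!r} in peak file")
        size = grid.chromosome_sizes[chrom]
        if (sub["end"] > size).any():
            bad = sub.loc[sub["end"] > size].iloc[0]
            raise ValueError(
                f"interval {chrom}:{bad['start']}-{bad['end']} extends past "
                f"chromosome end ({size})")
        off = grid.offset_of(chrom)
        starts = sub["start"].to_numpy(int)
        ends = sub["end"].to_numpy(int)
        scores = sub["score"].to_numpy(float)
        first = starts // res
        last = (ends - 1) // res
        for f, l, s in zip(first, last, scores):
            total[off + f: off + l + 1] += s
            count[off + f: off + l + 1] += 1
    values = np.full(grid.n_bins, np.nan)
    hit = count > 0
    values[hit] = total[hit] / count[hit]
    return BinTrack(grid=grid, values=values, name=name)


def _read_scored_intervals(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if len(fields) >= 5:          # BED with name + score
                    chrom, start, end, score = (fields[0], int(fields[1]),
                                                int(fields[2]), float(fields[4]))
                elif len(fields) == 4:        # bedGraph
                    chrom, start, end, score = (fields[0], int(fields[1]),
                                                int(fields[2]), float(fields[3]))
                else:
                    raise ValueError("expected >= 4 fields")
                if not np.isfinite(score):
                    raise ValueError("non-finite score")
                if start >= end:
                    raise ValueError("start >= end")
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
            rows.append((chrom, start, end, score))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "score"])


def load_state_segmentation(path, grid: BinGrid | None = None) -> StateSegmentation:
    """Load a BED4 chromatin-state segmentation (state name in column 4).

    Records named ``ActProm`` or ``StrEnh1`` are merged into the single
    combined state, yielding the 11-state alphabet.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}, line {lineno}: expected BED4")
            chrom, start, end, state = (fields[0], int(fields[1]),
                                        int(fields[2]), fields[3])
            if state not in _RAW_TO_MERGED:
                raise ValueError(
                    f"{path}, line {lineno}: unknown state {state!r}; "
                    f"vocabulary is {sorted(RAW_STATES)}")
            rows.append((chrom, start, end, _RAW_TO_MERGED[state]))
    df = pd.DataFrame(rows,
                      columns=["chromosome", "start", "end", "state"])
    return StateSegmentation(intervals=df)


def segmentation_from_frame(df: pd.DataFrame) -> StateSegmentation:
    """Build a segmentation from an in-memory frame using the raw 12-state
    names, applying the same merge as :func:`load_state_segmentation`."""
    out = df.copy()
    unknown = set(out["state"]) - set(RAW_STATES) - set(STATE_ALPHABET)
    if unknown:
        raise ValueError(f"unknown states {sorted(unknown)}")
    out["state"] = out["state"].map(lambda s: _RAW_TO_MERGED.get(s, s))
    return StateSegmentation(intervals=out)


def write_compartment_bed(calls, path) -> None:
    """Write per-bin compartment labels as BED4; NA bins are omitted."""
    bins = calls.grid.bins()
    labels = np.asarray(calls.labels)
    with open(path, "w") as fh:
        for (_, row), lab in zip(bins.iterrows(), labels):
            if lab == "NA":
                continue
            fh.write(f"{row['chromosome']}\t{row['start']}\t{row['end']}\t{lab}\n")


def read_compartment_bed(path, grid: BinGrid) -> np.ndarray:
    """Read labels written by :func:`write_compartment_bed` back onto the
    grid.  Bins absent from the file are ``"NA"``."""
    labels = np.full(grid.n_bins, "NA", dtype="<U2")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}, line {lineno}: expected BED4")
            chrom, start, lab = fields[0], int(fields[1]), fields[3]
            idx = grid.offset_of(chrom) + start // grid.resolution
            labels[idx] = lab
    return labels


def write_bedgraph(track: BinTrack, path) -> None:
    """Write a per-bin track as bedGraph; missing bins are omitted."""
    bins = track.grid.bins()
    with open(path, "w") as fh:
        for (_, row), val in zip(bins.iterrows(), track.values):
            if np.isnan(val):
                continue
            fh.write(f"{row['chromosome']}\t{row['start']}\t{row['end']}"
                     f"\t{val:.10g}\n")


def read_bedgraph(path, grid: BinGrid, name: str = "") -> BinTrack:
    values = np.full(grid.n_bins, np.nan)
    df = _read_scored_intervals(path)
    for chrom, sub in df.groupby("chromosome", sort=False):
        off = grid.offset_of(chrom)
        idx = off + sub["start"].to_numpy(int) // grid.resolution
        values[idx] = sub["score"].to_numpy(float)
    return BinTrack(grid=grid, values=values, name=name)
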