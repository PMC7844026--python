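"""Synthetic Hi-C cohorts with planted compartment truth.

The generator emulates the data structure of a B-cell differentiation
and neoplasia Hi-C study, so every pipeline stage can be exercised with
exhaustively known ground truth:

* per-chromosome symmetric contact matrices with power-law distance
  decay and compartment-affinity block structure — like-with-like (A-A,
  B-B) contacts dominate, intermediate (I) bins contact all labels more
  promiscuously, which makes the I compartment's low self-interaction
  score an emergent property rather than an assertion;
* matched activity tracks (H3K4me1/ATAC-like, higher in A bins) and
  200-bp chromatin-state tracks over the 11-state alphabet, concordant
  with the planted compartment labels;
* a differentiation path (naive -> germinal-center -> memory / plasma)
  with planted activation, inactivation and reversal events;
* two disease groups with entity-specific, shared and subtype-specific
  planted compartment switches, mirroring the study design of
  3 replicates x 4 normal B-cell states, 7 CLL (5 mutated + 2 unmutated
  IGHV) and 5 MCL (2 conventional + 3 non-nodal).

Every output is a pure function of (config, design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .hic_io import (BinGrid, BinTrack, ContactMatrix, StateSegmentation,
                     STATE_ALPHABET)
from .differential import EVMatrix

__all__ = [
    "SimulationConfig",
    "CohortDesign",
    "CohortTruth",
    "Cohort",
    "simulate_labels",
    "simulate_contact_matrix",
    "simulate_tracks",
    "simulate_cohort",
]

LABELS = ("A", "I", "B")
_LAB_IDX = {l: i for i, l in enumerate(LABELS)}

# contact multiplier per label pair, order (A, I, B):
# like-with-like A/B contacts strong, A-B avoidance strong, I promiscuous
_DEFAULT_AFFINITY = np.array([
    [1.0, 0.5, 0.2],
    [0.5, 0.6, 0.5],
    [0.2, 0.5, 1.0],
])

# label-conditioned chromatin-state emission over the 11-state alphabet;
# columns follow STATE_ALPHABET order
_STATE_PROBS = {
    "A": np.array([0.14, 0.08, 0.08, 0.10, 0.08, 0.18, 0.20,
                   0.01, 0.03, 0.04, 0.06]),
    "I": np.array([0.02, 0.03, 0.02, 0.04, 0.02, 0.03, 0.09,
                   0.15, 0.45, 0.07, 0.08]),
    "B": np.array([0.01, 0.01, 0.01, 0.02, 0.01, 0.02, 0.06,
                   0.02, 0.06, 0.40, 0.38]),
}


@dataclass
class SimulationConfig:
    """Generator parameters.

    ``label_proportions`` (A, I, B) echo the roughly even three-way
    abundance of the compartments; ``affinity`` is the symmetric 3x3
    contact multiplier per label pair; ``depth`` is the expected contact
    count of a bin pair at distance 1; ``noise_sd`` is the lognormal
    replicate-level depth jitter.  ``ev_means``/``ev_sds`` place the
    three eigenvector modes; ``ev_within_sd`` is the replicate-level
    noise around a bin's mode.
    """

    chromosome_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 30_000_000})
    resolution: int = 100_000
    label_proportions: tuple[float, float, float] = (0.35, 0.33, 0.32)
    segment_length_mean: float = 8.0
    affinity: np.ndarray = field(
        default_factory=lambda: _DEFAULT_AFFINITY.copy())
    decay_exponent: float = 1.0
    depth: float = 100.0
    noise_sd: float = 0.1
    ev_means: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.70, "I": -0.08, "B": -0.85})
    ev_sds: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.12, "I": 0.18, "B": 0.10})
    ev_within_sd: float = 0.05
    activity_means: Mapping[str, float] = field(
        default_factory=lambda: {"A": 10.0, "I": 4.0, "B": 1.0})
    activity_sd: float = 2.0
    state_run_mean: float = 10.0   # mean chromatin-state run length, 200-bp windows

    def __post_init__(self):
        self.affinity = np.asarray(self.affinity, float)
        if abs(sum(self.label_proportions) - 1.0) > 1e-8:
            raise ValueError("label proportions must sum to 1")
        if not np.allclose(self.affinity, self.affinity.T):
            raise ValueError("affinity matrix must be symmetric")
        if np.any(self.affinity < 0):
            raise ValueError("affinity must be non-negative")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def grid(self) -> BinGrid:
        return BinGrid(dict(self.chromosome_sizes), self.resolution)


def simulate_labels(cfg: SimulationConfig, seed: int = 0) -> np.ndarray:
    """Genome-wide planted labels as alternating geometric-length segments.

    Segment lengths are geometric with mean ``segment_length_mean`` bins;
    each segment's label is drawn from ``label_proportions``.
    """
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    p = 1.0 / cfg.segment_length_mean
    out = np.empty(grid.n_bins, dtype="<U2")
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        n = sl.stop - sl.start
        pos = 0
        while pos < n:
            length = rng.geometric(p)
            lab = rng.choice(LABELS, p=cfg.label_proportions)
            out[sl.start + pos: sl.start + min(pos + length, n)] = lab
            pos += length
    return out


def simulate_contact_matrix(labels: np.ndarray, cfg: SimulationConfig,
                            chromosome: str, seed: int = 0) -> ContactMatrix:
    """Poisson contact matrix for one chromosome given planted labels.

    ``expected(i, j) = depth * |i - j|**(-alpha) * affinity(L_i, L_j)``
    for i != j, with the diagonal at ``depth * affinity(L_i, L_i)``; a
    single lognormal factor ``exp(N(0, noise_sd^2))`` jitters the whole
    matrix (replicate-level depth variation).  Counts are Poisson drawn
    on the upper triangle and mirrored, so the matrix is exactly
    symmetric with non-negative integers.
    """
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    lab = np.asarray(labels)[grid.chrom_slice(chromosome)]
    n = lab.shape[0]
    li = np.array([_LAB_IDX[l] for l in lab])
    aff = cfg.affinity[np.ix_(li, li)]
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(d > 0, d ** (-cfg.decay_exponent), 1.0)
    expected = cfg.depth * decay * aff
    expected *= np.exp(rng.normal(0.0, cfg.noise_sd))
    upper = np.triu(rng.poisson(expected)).astype(float)
    values = upper + np.triu(upper, 1).T
    return ContactMatrix(grid=grid.subset(chromosome), values=values)


def simulate_tracks(labels: np.ndarray, cfg: SimulationConfig,
                    seed: int = 0) -> tuple[BinTrack, StateSegmentation]:
    """Activity track and 200-bp chromatin-state segmentation concordant
    with planted labels.

    Activity is Gaussian per label with means ordered A > I > B (an
    H3K4me1/ATAC-like orientation signal).  States are emitted as
    geometric-length runs of 200-bp windows drawn from label-conditioned
    distributions that concentrate active states in A bins, poised/
    polycomb states in I bins and heterochromatin states in B bins.
    """
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    labels = np.asarray(labels)
    mu = np.array([cfg.activity_means[l] for l in labels])
    activity = BinTrack(grid=grid,
                        values=mu + rng.normal(0, cfg.activity_sd,
                                               grid.n_bins),
                        name="activity")
    window = 200
    run_p = 1.0 / cfg.state_run_mean
    rows = []
    bins = grid.bins()
    for (_, brow), lab in zip(bins.iterrows(), labels):
        chrom, start, end = brow["chromosome"], brow["start"], brow["end"]
        probs = _STATE_PROBS[lab]
        pos = start
        while pos < end:
            run = int(rng.geometric(run_p)) * window
            state = STATE_ALPHABET[rng.choice(len(STATE_ALPHABET), p=probs)]
            stop = min(pos + run, end)
            rows.append((chrom, pos, stop, state))
            pos = stop
    seg = StateSegmentation(intervals=pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "state"]))
    return activity, seg


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Study design: cell states along the differentiation path, disease
    groups with subtypes, and the planted effects.

    Planted effects are label switches (A<->I<->B), which imply
    eigenvector shifts of ~0.8 between adjacent labels under the default
    eigenvector modes.  Defaults mirror the study layout: 3 replicates
    per normal state, 7 CLL (5 mCLL + 2 uCLL), 5 MCL (2 cMCL + 3 nnMCL),
    ~30% dynamic bins of which ~60% activate at the second state, 75%
    reversal in memory cells and 30% in plasma cells.
    """

    cell_states: tuple[tuple[str, int], ...] = (
        ("NBC", 3), ("GCBC", 3), ("MBC", 3), ("PC", 3))
    dynamic_fraction: float = 0.30
    activation_share: float = 0.60
    reversibility: float = 0.75
    pc_reversibility: float = 0.30
    diseases: tuple[tuple[str, tuple[tuple[str, int], ...]], ...] = (
        ("CLL", (("mCLL", 5), ("uCLL", 2))),
        ("MCL", (("cMCL", 2), ("nnMCL", 3))))
    n_shared_regions: int = 15
    disease_specific_regions: Mapping[str, int] = field(
        default_factory=lambda: {"CLL": 60, "MCL": 20})
    subtype_specific_regions: Mapping[str, int] = field(
        default_factory=lambda: {"CLL": 10, "MCL": 40})
    effect_size: float = 0.8       # planted eigenvector shift at disease regions
    missing_rate: float = 0.01
    emit_matrices: bool = False
    emit_tracks: bool = False


@dataclass
class CohortTruth:
    """Exhaustive record of everything that was planted."""

    base_labels: np.ndarray                    # labels at the first state
    state_labels: dict[str, np.ndarray]        # cell state -> label map
    subtype_labels: dict[str, np.ndarray]      # disease subtype -> label map
    dynamic_bins: np.ndarray                   # indices planted as dynamic
    patterns: dict[int, str]                   # dynamic bin -> label pattern
    activated_bins: np.ndarray                 # activated at second state
    reverted_bins: np.ndarray                  # activated, reverted at MBC-like state
    shared_regions: np.ndarray                 # altered in every disease
    disease_regions: dict[str, np.ndarray]     # disease -> entity-specific bins
    disease_direction: dict[str, np.ndarray]   # 'activation'/'inactivation'
    disease_delta: dict[str, np.ndarray]       # realized planted EV shift
    subtype_regions: dict[str, np.ndarray]     # disease -> subtype-specific bins
    subtype_gainer: dict[str, np.ndarray]      # subtype ending with higher EV
    ev_modes: np.ndarray                       # (n_bins, 3) per-label eigen modes
    mode_patches: dict[str, dict[int, float]]  # subtype -> bin -> planted mode
    sample_state: dict[str, str]               # sample -> cell state / subtype
    sample_disease: dict[str, str]             # disease samples -> disease


@dataclass
class Cohort:
    """A simulated cohort: eigenvector matrix, optional raw material, truth."""

    config: SimulationConfig
    design: CohortDesign
    ev: EVMatrix
    truth: CohortTruth
    matrices: dict[str, dict[str, ContactMatrix]] = field(default_factory=dict)
    tracks: dict[str, tuple[BinTrack, StateSegmentation]] = field(
        default_factory=dict)

    def regroup(self, group_of: Mapping[str, str]) -> EVMatrix:
        """EVMatrix with samples re-assigned to coarser groups (e.g. all
        CLL subtypes -> 'CLL', all normal states -> 'Bcell')."""
        groups = {s: group_of.get(s, self.ev.sample_groups[s])
                  for s in self.ev.values.columns}
        return EVMatrix(grid=self.ev.grid, values=self.ev.values,
                        sample_groups=groups)


def _switch_up(label: str, rng) -> str:
    if label == "A":
        return "A"
    if label == "B":
        return "I" if rng.random() < 0.5 else "A"
    return "A"


def _switch_down(label: str, rng) -> str:
    if label == "B":
        return "B"
    if label == "A":
        return "I" if rng.random() < 0.5 else "B"
    return "B"


def simulate_cohort(cfg: SimulationConfig, design: CohortDesign | None = None,
                    seed: int = 0) -> Cohort:
    """Generate a full cohort with planted truth.

    Per sample, the eigenvector value of a bin is the bin's per-label
    mode (drawn once per cohort from the label's eigen distribution)
    plus replicate noise of sd ``cfg.ev_within_sd``, clipped to [-1, 1].
    Bins with any planted effect are never also planted missing.
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    n = grid.n_bins

    base = simulate_labels(cfg, seed=int(rng.integers(2**31)))

    # --- differentiation path -------------------------------------------
    state_names = [s for s, _ in design.cell_states]
    n_dyn = int(round(design.dynamic_fraction * n))
    dyn = rng.choice(n, size=n_dyn, replace=False) if n_dyn else np.array([], int)
    state_labels = {s: base.copy() for s in state_names}
    patterns: dict[int, str] = {}
    activated = []
    reverted = []
    if len(state_names) >= 2 and n_dyn:
        second = state_names[1]
        # honor the designed activation share: activations go to bins with
        # headroom (label != A), the rest inactivate unless pinned at B
        n_up = int(round(design.activation_share * n_dyn))
        up_set = set()
        for b in dyn:                     # dyn is already in random order
            if base[b] != "A" and len(up_set) < n_up:
                up_set.add(int(b))
        for b in dyn:
            if base[b] == "B":
                up_set.add(int(b))        # B bins can only activate
        for b in dyn:
            lab0 = base[b]
            want_up = int(b) in up_set
            lab1 = _switch_up(lab0, rng) if want_up else _switch_down(lab0, rng)
            state_labels[second][b] = lab1
            if want_up:
                activated.append(b)
            # later states: revert or keep
            for later, p_rev in zip(state_names[2:],
                                    (design.reversibility,
                                     design.pc_reversibility)):
                if rng.random() < p_rev:
                    state_labels[later][b] = lab0
                    if want_up and later == (state_names[2]
                                             if len(state_names) > 2 else None):
                        reverted.append(b)
                else:
                    state_labels[later][b] = lab1
        for b in dyn:
            patterns[int(b)] = ">".join(state_labels[s][b]
                                        for s in state_names)

    # --- disease planting ------------------------------------------------
    used = set(dyn.tolist())
    stable_pool = np.array([i for i in range(n) if i not in used])
    rng.shuffle(stable_pool)
    cursor = 0

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        if cursor + count > stable_pool.size:
            raise ValueError(
                "design inconsistent: more planted regions requested than "
                "stable bins available")
        out = stable_pool[cursor:cursor + count]
        cursor += count
        return np.sort(out)

    disease_names = [d for d, _ in design.diseases]
    shared = take(design.n_shared_regions)
    disease_regions = {d: take(design.disease_specific_regions.get(d, 0))
                       for d in disease_names}
    subtype_regions = {d: take(design.subtype_specific_regions.get(d, 0))
                       for d in disease_names}

    # per-bin eigenvector mode for each possible label, drawn once
    ev_modes = np.column_stack([
        rng.normal(cfg.ev_means[l], cfg.ev_sds[l], n) for l in LABELS])
    ev_modes = np.clip(ev_modes, -1.0, 1.0)

    def plant_effect(b: int) -> tuple[str, float, str]:
        """Shift bin b's eigenvector mode by +-effect_size and re-label.

        Direction is chosen by available headroom: inactive bins shift up,
        active bins shift down, intermediate bins away from their sign, so
        the realized shift equals the design effect size (clipping aside).
        """
        old_label = base[b]
        old_mode = ev_modes[b, _LAB_IDX[old_label]]
        if old_label == "B":
            sign = 1.0
        elif old_label == "A":
            sign = -1.0
        else:
            sign = -1.0 if old_mode > 0 else 1.0
        new_mode = float(np.clip(old_mode + sign * design.effect_size, -1, 1))
        new_label = min(LABELS,
                        key=lambda l: abs(new_mode - cfg.ev_means[l]))
        if new_label == old_label:   # extreme starting mode; force a switch
            new_label = "I"
        direction = "activation" if sign > 0 else "inactivation"
        return new_label, new_mode, direction

    shared_plants = {int(b): plant_effect(int(b)) for b in shared}
    subtype_labels: dict[str, np.ndarray] = {}
    mode_patches: dict[str, dict[int, float]] = {}
    disease_direction: dict[str, np.ndarray] = {}
    disease_delta: dict[str, np.ndarray] = {}
    subtype_gainer: dict[str, np.ndarray] = {}
    for disease, subtypes in design.diseases:
        disease_map = base.copy()
        disease_patch: dict[int, float] = {}
        for b, (nl, nm, _) in shared_plants.items():
            disease_map[b] = nl
            disease_patch[b] = nm
        directions, deltas = [], []
        for b in disease_regions[disease].astype(int):
            nl, nm, dirn = plant_effect(b)
            disease_map[b] = nl
            disease_patch[b] = nm
            directions.append(dirn)
            deltas.append(nm - ev_modes[b, _LAB_IDX[base[b]]])
        disease_direction[disease] = np.array(directions)
        disease_delta[disease] = np.array(deltas)
        sub_names = [s for s, _ in subtypes]
        per_sub = {s: disease_map.copy() for s in sub_names}
        per_patch = {s: dict(disease_patch) for s in sub_names}
        gainers = []
        for b in subtype_regions[disease].astype(int):
            modified = sub_names[int(rng.integers(len(sub_names)))]
            nl, nm, dirn = plant_effect(b)
            per_sub[modified][b] = nl
            per_patch[modified][b] = nm
            if dirn == "activation":
                gainers.append(modified)
            else:   # modified subtype lost activity; the other one "gains"
                others = [s for s in sub_names if s != modified]
                gainers.append(others[0] if len(others) == 1 else "NA")
        subtype_gainer[disease] = np.array(gainers)
        subtype_labels.update(per_sub)
        mode_patches.update(per_patch)

    planted = set(shared.tolist())
    for d in disease_names:
        planted |= set(disease_regions[d].tolist())
        planted |= set(subtype_regions[d].tolist())
    missable = np.array([i for i in range(n) if i not in planted])

    columns: dict[str, np.ndarray] = {}
    sample_state: dict[str, str] = {}
    sample_disease: dict[str, str] = {}

    def emit(label_map: np.ndarray,
             patch: Mapping[int, float] | None = None) -> np.ndarray:
        modes = ev_modes[np.arange(n), [_LAB_IDX[l] for l in label_map]]
        if patch:
            modes = modes.copy()
            modes[list(patch)] = list(patch.values())
        vals = np.clip(modes + rng.normal(0, cfg.ev_within_sd, n), -1, 1)
        if design.missing_rate > 0 and missable.size:
            n_miss = rng.binomial(missable.size, design.missing_rate)
            if n_miss:
                vals[rng.choice(missable, n_miss, replace=False)] = np.nan
        return vals

    for state, n_rep in design.cell_states:
        for r in range(1, n_rep + 1):
            name = f"{state}_{r}"
            columns[name] = emit(state_labels[state])
            sample_state[name] = state
    for disease, subtypes in design.diseases:
        for subtype, n_rep in subtypes:
            for r in range(1, n_rep + 1):
                name = f"{subtype}_{r}"
                columns[name] = emit(subtype_labels[subtype],
                                     mode_patches[subtype])
                sample_state[name] = subtype
                sample_disease[name] = disease

    ev = EVMatrix(grid=grid,
                  values=pd.DataFrame(columns, index=grid.bin_ids()),
                  sample_groups=dict(sample_state))

    truth = CohortTruth(
        base_labels=base, state_labels=state_labels,
        subtype_labels=subtype_labels,
        dynamic_bins=np.sort(dyn), patterns=patterns,
        activated_bins=np.array(sorted(activated), int),
        reverted_bins=np.array(sorted(reverted), int),
        shared_regions=shared, disease_regions=disease_regions,
        disease_direction=disease_direction,
        disease_delta=disease_delta,
        subtype_regions=subtype_regions,
        subtype_gainer=subtype_gainer,
        ev_modes=ev_modes, mode_patches=mode_patches,
        sample_state=sample_state,
        sample_disease=sample_disease)

    cohort = Cohort(config=cfg, design=design, ev=ev, truth=truth)

    if design.emit_matrices:
        for name in columns:
            label_map = (state_labels.get(sample_state[name])
                         if sample_state[name] in state_labels
                         else subtype_labels[sample_state[name]])
            cohort.matrices[name] = {
                chrom: simulate_contact_matrix(
                    label_map, cfg, chrom, seed=int(rng.integers(2**31)))
                for chrom in grid.chromosomes}
    if design.emit_tracks:
        for state in state_names:
            cohort.tracks[state] = simulate_tracks(
                state_labels[state], cfg, seed=int(rng.integers(2**31)))

    return cohort
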