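"""Compartment dynamics along cell differentiation paths.

Compartment labels carry a natural activity order A > I > B.  A step
along a differentiation path (e.g. naive -> germinal-center -> memory B
cells) is an *activation* if the label moves up that order (B->I, B->A,
I->A), an *inactivation* if it moves down, and *stable* otherwise.
Bins that are unassigned (NA) at any state of a path are excluded from
that path's denominators and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hic_io import BinGrid, StateSegmentation
from .segmentation import CompartmentCall

__all__ = [
    "ACTIVITY_ORDER",
    "TransitionTable",
    "ReversibilitySummary",
    "classify_transition",
    "path_dynamics",
    "reversibility",
    "transiently_activated",
    "state_group_foldchange",
]

ACTIVITY_ORDER = {"B": 0, "I": 1, "A": 2}


def classify_transition(from_label: str, to_label: str) -> str:
    """Classify an ordered label pair as activation/inactivation/stable."""
    try:
        a, b = ACTIVITY_ORDER[from_label], ACTIVITY_ORDER[to_label]
    except KeyError as exc:
        raise ValueError(f"cannot classify transition with label {exc}; "
                         "filter NA bins first") from None
    if b > a:
        return "activation"
    if b < a:
        return "inactivation"
    return "stable"


@dataclass
class TransitionTable:
    """Per-bin compartment trajectory along an ordered cell-state path."""

    grid: BinGrid
    state_names: tuple[str, ...]
    bin_index: np.ndarray          # genome-wide indices of path-complete bins
    labels: np.ndarray             # (n_complete, n_states) label matrix
    step_classes: np.ndarray       # (n_complete, n_states - 1)
    patterns: np.ndarray           # e.g. "B>A>B"
    step_summary: pd.DataFrame     # % activation/inactivation/stable per step
    dynamic_fraction: float        # bins with >= 1 non-stable step
    n_excluded: int                # bins NA somewhere along the path


def path_dynamics(calls_per_state: Sequence[CompartmentCall],
                  state_names: Sequence[str] | None = None) -> TransitionTable:
    """Classify every path-complete bin's transitions along a path.

    Summary percentages are computed over path-complete bins; the dynamic
    fraction is the share of path-complete bins with at least one
    non-stable step.
    """
    if len(calls_per_state) < 2:
        raise ValueError("need at least 2 cell states")
    grid = calls_per_state[0].grid
    for c in calls_per_state[1:]:
        if c.grid.n_bins != grid.n_bins:
            raise ValueError("all call sets must share the grid")
    names = tuple(state_names) if state_names is not None else tuple(
        c.sample_id or f"state{i}" for i, c in enumerate(calls_per_state))
    lab = np.stack([c.labels for c in calls_per_state], axis=1)
    complete = (lab != "NA").all(axis=1)
    idx = np.flatnonzero(complete)
    if idx.size == 0:
        raise ValueError("no path-complete bins")
    lab = lab[complete]
    n_steps = lab.shape[1] - 1
    order = np.vectorize(ACTIVITY_ORDER.get)(lab)
    diff = np.diff(order, axis=1)
    classes = np.where(diff > 0, "activation",
                       np.where(diff < 0, "inactivation", "stable"))
    rows = []
    for s in range(n_steps):
        col = classes[:, s]
        rows.append({
            "step": f"{names[s]}>{names[s + 1]}",
            "activation_pct": 100.0 * (col == "activation").mean(),
            "inactivation_pct": 100.0 * (col == "inactivation").mean(),
            "stable_pct": 100.0 * (col == "stable").mean(),
        })
    patterns = np.array([">".join(r) for r in lab])
    dynamic = (classes != "stable").any(axis=1).mean()
    return TransitionTable(
        grid=grid, state_names=names, bin_index=idx, labels=lab,
        step_classes=classes, patterns=patterns,
        step_summary=pd.DataFrame(rows),
        dynamic_fraction=float(dynamic),
        n_excluded=int((~complete).sum()))


@dataclass
class ReversibilitySummary:
    """How much of the genome returns to its initial compartment."""

    overall_match_fraction: float
    activated_reverting_fraction: float
    n_complete: int
    n_activated: int


def reversibility(initial: CompartmentCall, intermediate: CompartmentCall,
                  final: CompartmentCall) -> ReversibilitySummary:
    """Fraction of path-complete bins whose final label matches the
    initial one, and, among bins activated at the intermediate state, the
    fraction reverting (inactivating) at the final state."""
    table = path_dynamics([initial, intermediate, final])
    lab = table.labels
    match = float((lab[:, 2] == lab[:, 0]).mean())
    activated = table.step_classes[:, 0] == "activation"
    n_act = int(activated.sum())
    if n_act:
        reverting = float(
            (table.step_classes[activated, 1] == "inactivation").mean())
    else:
        reverting = float("nan")
    return ReversibilitySummary(
        overall_match_fraction=match,
        activated_reverting_fraction=reverting,
        n_complete=lab.shape[0], n_activated=n_act)


def transiently_activated(initial: CompartmentCall,
                          intermediate: CompartmentCall,
                          final: CompartmentCall) -> np.ndarray:
    """Genome-wide indices of bins active exclusively at the intermediate
    state: activated on the first step, then inactivated back on the
    second."""
    table = path_dynamics([initial, intermediate, final])
    sel = ((table.step_classes[:, 0] == "activation")
           & (table.step_classes[:, 1] == "inactivation"))
    return table.bin_index[sel]


def state_group_foldchange(states_t1: StateSegmentation,
                           states_t2: StateSegmentation,
                           bins: np.ndarray, grid: BinGrid) -> dict[str, float]:
    """Fold change of A/I/B-related chromatin-state coverage over a bin set.

    For each state group g, ``fc(g)`` is the bp fraction of g within the
    bins at t2 divided by the same fraction at t1.  Groups with zero
    coverage at t1 are reported as NaN (undefined).
    """
    bins = np.asarray(bins, dtype=int)
    if bins.size == 0:
        raise ValueError("empty bin subset")
    from .scores import state_bp_by_bin
    out: dict[str, float] = {}
    fracs = []
    for seg in (states_t1, states_t2):
        bp = state_bp_by_bin(seg, grid).iloc[bins]
        group_bp: dict[str, float] = {}
        for state in seg.alphabet:
            g = seg.group_map[state]
            group_bp[g] = group_bp.get(g, 0.0) + float(bp[state].sum())
        total = sum(group_bp.values())
        fracs.append({g: (v / total if total else np.nan)
                      for g, v in group_bp.items()})
    for g in ("A-related", "I-related", "B-related"):
        f1 = fracs[0].get(g, np.nan)
        f2 = fracs[1].get(g, np.nan)
        out[g] = float(f2 / f1) if f1 and np.isfinite(f1) else float("nan")
    return out
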