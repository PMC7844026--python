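"""Three-state compartment segmentation of eigenvector coefficients.

The distribution of compartment-eigenvector coefficients pooled across
chromosomes is multi-modal: a positive (active, A) mode, a negative
(inactive, B) mode and a broad intermediate valley.  A k-component 1-D
Gaussian mixture is fit by expectation-maximization; the Bayesian
Information Criterion selects k (k = 3 on data with the three-mode
structure).  The two intersection points of adjacent weighted component
densities — IV1 between the intermediate and active components, IV2
between the inactive and intermediate components — become the call
thresholds:

    label(v) = A  if v >  IV1
               I  if IV2 <= v <= IV1
               B  if v <  IV2

Replicate-level thresholds are averaged into consensus thresholds before
calling, mirroring the use of a single standard threshold pair across a
replicate panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .eigencomp import EigenTrack
from .hic_io import BinGrid

__all__ = [
    "MixtureModel",
    "Thresholds",
    "CompartmentCall",
    "fit_gaussian_mixture",
    "bic_scan",
    "mixture_intersections",
    "consensus_thresholds",
    "call_compartments",
]

LABELS = ("A", "I", "B")


@dataclass
class MixtureModel:
    """1-D Gaussian mixture with components sorted by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    n: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("component arrays must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("standard deviations must be positive")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("components must be sorted by mean")

    @property
    def k(self) -> int:
        return len(self.weights)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return np.sum([w * norm.pdf(x, m, s) for w, m, s in
                       zip(self.weights, self.means, self.sds)], axis=0)


@dataclass
class Thresholds:
    """Compartment call boundaries: IV1 (A/I) above IV2 (I/B)."""

    iv1: float
    iv2: float

    def __post_init__(self):
        if not self.iv2 < self.iv1:
            raise ValueError(f"need iv2 < iv1, got {self.iv2} >= {self.iv1}")


@dataclass
class CompartmentCall:
    """Per-bin compartment label in {A, I, B, NA} plus the thresholds used."""

    grid: BinGrid
    labels: np.ndarray
    thresholds: Thresholds | None = None
    sample_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="<U2")
        if self.labels.shape != (self.grid.n_bins,):
            raise ValueError("label vector length does not match grid")
        bad = set(np.unique(self.labels)) - {"A", "I", "B", "IA", "IB", "NA"}
        if bad:
            raise ValueError(f"invalid labels {sorted(bad)}")


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

def _em(x: np.ndarray, weights: np.ndarray, means: np.ndarray,
        sds: np.ndarray, tol: float, max_iter: int,
        min_sd: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Run EM to convergence; raises FloatingPointError on degeneracy."""
    n = x.size
    ll_prev = -np.inf
    for _ in range(max_iter):
        # E step: log responsibilities
        logp = (np.log(weights)[None, :]
                + norm.logpdf(x[:, None], means[None, :], sds[None, :]))
        log_norm = logsumexp(logp, axis=1)
        resp = np.exp(logp - log_norm[:, None])
        ll = float(log_norm.sum())
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise FloatingPointError("empty component")
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < min_sd):
            raise FloatingPointError("component variance collapsed")
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1e-300):
            ll_prev = ll
            break
        ll_prev = ll
    return weights, means, sds, ll_prev


def fit_gaussian_mixture(values: Iterable[float], k: int, seed: int = 0,
                         tol: float = 1e-8, max_iter: int = 1000) -> MixtureModel:
    """Fit a k-component 1-D Gaussian mixture by EM.

    Initialization is deterministic given the data: component means at the
    1/(k+1)..k/(k+1) quantiles, equal weights, pooled standard deviation.
    If a component degenerates (vanishing weight or variance) the fit is
    restarted with jittered initial means, up to 5 times; the ``seed``
    only feeds the jitter, so a clean fit is fully data-deterministic.

    BIC is computed as ``p ln(n) - 2 lnL`` with ``p = 3k - 1`` free
    parameters, to be minimized.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray)
                   else values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = x.size
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} finite values for k={k}, "
                         f"got {n}")
    pooled_sd = x.std()
    if pooled_sd == 0:
        raise ValueError("values are constant; cannot fit a mixture")
    min_sd = max(1e-6 * pooled_sd, 1e-12)
    q = np.quantile(x, [(i + 1) / (k + 1) for i in range(k)])
    weights0 = np.full(k, 1.0 / k)
    sds0 = np.full(k, pooled_sd)
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(6):
        means0 = q if attempt == 0 else q + rng.normal(0, pooled_sd / 2, k)
        try:
            w, m, s, ll = _em(x, weights0.copy(), np.sort(means0).copy(),
                              sds0.copy(), tol, max_iter, min_sd)
            break
        except FloatingPointError as exc:
            last_err = exc
    else:
        raise RuntimeError(
            f"EM degenerate after 5 jittered restarts: {last_err}")
    order = np.argsort(m)
    p = 3 * k - 1
    bic = p * np.log(n) - 2.0 * ll
    return MixtureModel(weights=w[order], means=m[order], sds=s[order],
                        log_likelihood=ll, bic=bic, n=n)


def bic_scan(values, k_range: Sequence[int] = range(1, 11),
             seed: int = 0, tol: float = 1e-8,
             max_iter: int = 1000) -> tuple[list[tuple[int, float]], int]:
    """Fit mixtures over ``k_range`` and select k minimizing BIC.

    Returns ``(table, selected_k)`` where ``table`` is a list of
    ``(k, bic)``.  Ties break toward smaller k; failed fits are skipped
    with a warning.
    """
    table: list[tuple[int, float]] = []
    for k in k_range:
        try:
            model = fit_gaussian_mixture(values, k, seed=seed, tol=tol,
                                         max_iter=max_iter)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"k={k} skipped: {exc}")
            continue
        table.append((k, model.bic))
    if not table:
        raise RuntimeError("all mixture fits failed")
    best_k = min(table, key=lambda kb: (kb[1], kb[0]))[0]
    return table, best_k


# ---------------------------------------------------------------------------
# intersections and calls
# ---------------------------------------------------------------------------

def _pair_intersection(w1: float, m1: float, s1: float,
                       w2: float, m2: float, s2: float) -> float:
    """Intersection of two weighted Gaussian densities inside (m1, m2).

    Solving ``w1 N(x; m1, s1) = w2 N(x; m2, s2)`` in logs gives a
    quadratic in x; the root strictly inside the open interval between
    the two means is the classification boundary.  If no root falls in
    the interval (heavily overlapping or identical components) the
    sd-weighted midpoint ``(s2 m1 + s1 m2) / (s1 + s2)`` is used with a
    warning.
    """
    if m1 > m2:
        raise ValueError("components must be ordered by mean")
    fallback = (s2 * m1 + s1 * m2) / (s1 + s2)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = (m2**2 / s2**2 - m1**2 / s1**2
         + 2.0 * np.log((w1 * s2) / (w2 * s1)))
    if abs(a) < 1e-14:
        # equal variances: linear equation
        if abs(b) < 1e-14:
            warnings.warn("identical components; using midpoint fallback")
            return fallback
        root = -c / b
        if m1 < root < m2:
            return float(root)
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            for root in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if m1 < root < m2:
                    return float(root)
    warnings.warn("no density intersection inside the component interval; "
                  "using sd-weighted midpoint fallback")
    return float(fallback)


def mixture_intersections(model: MixtureModel) -> Thresholds:
    """Thresholds from a 3-component mixture.

    IV2 is the weighted-density intersection between the inactive (lowest
    mean) and intermediate components; IV1 between the intermediate and
    active (highest mean) components.
    """
    if model.k != 3:
        raise ValueError(f"need exactly 3 components, got {model.k}")
    w, m, s = model.weights, model.means, model.sds
    iv2 = _pair_intersection(w[0], m[0], s[0], w[1], m[1], s[1])
    iv1 = _pair_intersection(w[1], m[1], s[1], w[2], m[2], s[2])
    return Thresholds(iv1=iv1, iv2=iv2)


def consensus_thresholds(models: Sequence[MixtureModel]) -> Thresholds:
    """Arithmetic mean of per-replicate IV1 and IV2."""
    if not models:
        raise ValueError("need at least one mixture model")
    pairs = [mixture_intersections(m) for m in models]
    return Thresholds(iv1=float(np.mean([p.iv1 for p in pairs])),
                      iv2=float(np.mean([p.iv2 for p in pairs])))


def call_compartments(ev: EigenTrack, thresholds: Thresholds,
                      tol: float = 1e-6) -> CompartmentCall:
    """Assign A/I/B labels from eigenvector coefficients.

    A strictly above IV1, B strictly below IV2, I in the closed band
    between them (boundary values belong to the intermediate class);
    missing coefficients give NA.
    """
    v = ev.values
    finite = np.isfinite(v)
    if finite.any() and (np.abs(v[finite]) > 1.0 + tol).any():
        raise ValueError("eigenvector values must lie in [-1, 1]")
    labels = np.full(v.shape[0], "NA", dtype="<U2")
    labels[finite & (v > thresholds.iv1)] = "A"
    labels[finite & (v < thresholds.iv2)] = "B"
    labels[finite & (v >= thresholds.iv2) & (v <= thresholds.iv1)] = "I"
    return CompartmentCall(grid=ev.grid, labels=labels,
                           thresholds=thresholds, sample_id=ev.sample_id)
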