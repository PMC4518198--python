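"""Similarity statistics between two metabolic phenotypes.

Scoring a query ("bait") against a reference ("prey") proceeds in stages:

1. keep only metabolites present in both phenotypes whose fold-change passes
   the minimum-response filter (|fold-change| >= 1.5 by default, i.e. SIR
   outside [1/1.5, 1.5]) in *both*;
2. transform each surviving SIR to a ResponseValue
   (RV = SIR - 1 for increases, RV = 1 - 1/SIR for decreases) — a linear
   centering about 0 that, unlike a log transform, does not down-weight
   large changes;
3. Pearson-correlate the paired RV vectors (R, R²);
4. tally the 2x2 directional-overlap table (up/up, down/down, up/down,
   down/up) and compute a two-tailed Fisher's Exact Test p-value (FET2p);
5. combine: ranking metric = R² x (-log10 FET2p), and the signed score

       PM score = sgn(R) x R² x (-log10 FET2p)

   whose magnitude ranks match strength and whose sign separates similar
   from inverse responses.  A match with R² = 0.8 and a marginally
   significant FET2p = 0.05 scores 1.040824, a convenient "rule of thumb"
   benchmark: scores well below 1 are weak, scores well above 1 are strong.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phenotypes import MetaboliteKey, Phenotype

__all__ = [
    "OverlapCounts",
    "AlignedPair",
    "ScorePair",
    "sir_to_rv",
    "passes_filter",
    "align",
    "fisher_two_tailed",
    "pearson_r",
    "bicor",
    "pm_score",
    "score_pair",
    "FET2P_FLOOR",
    "STATISTICS",
]

logger = logging.getLogger(__name__)

#: Floor on the Fisher p-value; prevents -log10 overflow in the score.
FET2P_FLOOR = 1e-300

#: Selectable ranking statistics for benchmark mode.
STATISTICS = ("pm", "r2", "bicor", "fet")


@dataclass(frozen=True)
class OverlapCounts:
    """Directional-overlap counts between query and reference.

    a: up in both; b: down in both; c: up in query / down in reference;
    d: down in query / up in reference.
    """

    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("overlap counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "OverlapCounts":
        """Counts with query and reference swapped (a, b fixed; c <-> d)."""
        return OverlapCounts(self.a, self.b, self.d, self.c)


@dataclass(frozen=True)
class AlignedPair:
    """Post-filter intersection of two phenotypes as paired RV vectors."""

    metabolites: tuple[MetaboliteKey, ...]
    rv_query: np.ndarray
    rv_ref: np.ndarray
    counts: OverlapCounts

    def __post_init__(self) -> None:
        n = len(self.metabolites)
        if len(self.rv_query) != n or len(self.rv_ref) != n:
            raise ValueError("RV vectors must match the metabolite list length")
        if self.counts.n != n:
            raise ValueError("overlap counts must sum to the pair length")

    @property
    def n(self) -> int:
        return len(self.metabolites)


@dataclass(frozen=True)
class ScorePair:
    """All statistics of one query-reference comparison."""

    R: float
    R2: float
    FET2p: float
    ranking_metric: float
    pm_score: float
    bicor: float | None = field(default=None, compare=False)


def sir_to_rv(sir: float) -> float:
    """Transform a signal-intensity ratio to a ResponseValue.

    RV = SIR - 1 when SIR > 1; RV = 1 - 1/SIR when SIR < 1; RV = 0 at
    SIR = 1.  Antisymmetric under inversion: rv(1/s) = -rv(s).
    """
    if not (math.isfinite(sir) and sir > 0):
        raise ValueError(f"SIR must be finite and > 0, got {sir!r}")
    if sir > 1.0:
        return sir - 1.0
    if sir < 1.0:
        return 1.0 - 1.0 / sir
    return 0.0


def passes_filter(sir: float, threshold: float = 1.5) -> bool:
    """True iff the fold-change is at least ``threshold``-fold in either
    direction (boundary values are kept; SIRs strictly between 1/threshold
    and threshold are removed)."""
    if threshold < 1.0:
        raise ValueError(f"threshold must be >= 1, got {threshold!r}")
    return sir >= threshold or sir <= 1.0 / threshold


def align(
    query: Phenotype,
    ref: Phenotype,
    threshold: float = 1.5,
    unknowns: str = "keep",
) -> AlignedPair:
    """Intersect two phenotypes, apply the fold-change filter in both, and
    tally directional-overlap counts.

    Metabolites are ordered by sorted canonical key so downstream
    floating-point reductions are reproducible.  ``unknowns="drop"``
    restricts the comparison to metabolites resolved through the synonym
    table.  With threshold == 1 an RV of exactly 0 can survive the filter;
    such ties are counted as "up".
    """
    shared = query.metabolites(unknowns) & ref.metabolites(unknowns)
    kept: list[MetaboliteKey] = []
    rv_q: list[float] = []
    rv_r: list[float] = []
    a = b = c = d = 0
    for key in sorted(shared):
        sq, sr = query.responses[key], ref.responses[key]
        if not (passes_filter(sq, threshold) and passes_filter(sr, threshold)):
            continue
        q, r = sir_to_rv(sq), sir_to_rv(sr)
        kept.append(key)
        rv_q.append(q)
        rv_r.append(r)
        if q >= 0 and r >= 0:
            a += 1
        elif q < 0 and r < 0:
            b += 1
        elif q >= 0:
            c += 1
        else:
            d += 1
    return AlignedPair(
        metabolites=tuple(kept),
        rv_query=np.asarray(rv_q, dtype=float),
        rv_ref=np.asarray(rv_r, dtype=float),
        counts=OverlapCounts(a, b, c, d),
    )


def fisher_two_tailed(counts: OverlapCounts) -> float:
    """Two-tailed Fisher's Exact Test p-value of the directional overlap.

    The 2x2 table is ``[[a, c], [d, b]]`` — same-direction counts on the
    diagonal — and the two-sided p sums the probabilities of all tables with
    the observed margins that are no more probable than the observed one.
    The result is clamped to ``>= 1e-300``; the empty table returns 1.
    """
    if counts.n == 0:
        return 1.0
    table = [[counts.a, counts.c], [counts.d, counts.b]]
    p = stats.fisher_exact(table, alternative="two-sided").pvalue
    return max(float(min(p, 1.0)), FET2P_FLOOR)


def pearson_r(pair: AlignedPair) -> float:
    """Pearson correlation of the paired RV vectors.

    Degenerate inputs (n < 2 or a constant vector) are defined as R = 0 so
    library scans never fail on sparse overlaps.
    """
    if pair.n < 2:
        return 0.0
    x, y = pair.rv_query, pair.rv_ref
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.info("pearson_r: degenerate pair (constant RVs, n=%d); R := 0", pair.n)
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def _bicor_weights(v: np.ndarray) -> tuple[np.ndarray, float]:
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0.0:
        return np.array([]), 0.0
    u = (v - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return (v - med) * w, mad


def bicor(pair: AlignedPair) -> float:
    """Biweight midcorrelation of the paired RV vectors.

    Robust correlation per Langfelder & Horvath: deviations from the median
    are down-weighted by Tukey biweights ``(1 - u²)²`` with ``u`` the
    deviation scaled by nine median absolute deviations; observations beyond
    that radius get weight zero.  Falls back to :func:`pearson_r` (with a
    warning) when either vector has zero MAD.
    """
    if pair.n < 2:
        return 0.0
    wx, mad_x = _bicor_weights(pair.rv_query)
    wy, mad_y = _bicor_weights(pair.rv_ref)
    if mad_x == 0.0 or mad_y == 0.0:
        logger.warning("bicor: zero MAD (n=%d); falling back to Pearson", pair.n)
        return pearson_r(pair)
    denom = math.sqrt(float(np.sum(wx**2)) * float(np.sum(wy**2)))
    if denom == 0.0:
        return 0.0
    r = float(np.sum(wx * wy)) / denom
    return max(-1.0, min(1.0, r))


def pm_score(R: float, FET2p: float, bicor_value: float | None = None) -> ScorePair:
    """Combine correlation and overlap significance into the signed score.

    ``ranking_metric = R² x (-log10 FET2p)`` is non-negative and ranks match
    strength; ``pm_score = sgn(R) x ranking_metric`` adds the direction of
    the relationship (negative for inverse matches).
    """
    if not -1.0 <= R <= 1.0:
        raise ValueError(f"R must be in [-1, 1], got {R!r}")
    if not 0.0 < FET2p <= 1.0:
        raise ValueError(f"FET2p must be in (0, 1], got {FET2p!r}")
    FET2p = max(FET2p, FET2P_FLOOR)
    ranking = R * R * (-math.log10(FET2p))
    signed = math.copysign(ranking, R) if R != 0.0 else 0.0
    return ScorePair(
        R=R, R2=R * R, FET2p=FET2p, ranking_metric=ranking, pm_score=signed,
        bicor=bicor_value,
    )


def score_pair(
    query: Phenotype,
    ref: Phenotype,
    threshold: float = 1.5,
    unknowns: str = "keep",
    *,
    with_bicor: bool = False,
) -> tuple[AlignedPair, ScorePair]:
    """Full scoring pipeline for one query-reference comparison."""
    pair = align(query, ref, threshold=threshold, unknowns=unknowns)
    R = pearson_r(pair)
    p = fisher_two_tailed(pair.counts)
    bc = bicor(pair) if with_bicor else None
    return pair, pm_score(R, p, bicor_value=bc)
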