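"""Library search with permutation-based significance.

A query phenotype is scored against every reference in a library and the
references are ranked by the chosen statistic.  Significance of each match is
assessed against a *null model* built by destroying the biological meaning of
the query: its metabolite labels are randomly reshuffled (by default 30
times) and each shuffled query is searched exactly like the real one, pooling
permutations x library-size null scores.  The null distribution is modeled
as a normal from the pooled mean and SD; each real score gets a z-score and
an upper-tail p-value, ``p_non_bio`` — the estimated probability that a
match of that magnitude did not arise from biology.  Because the shuffles
reuse the query's own metabolite set, the null inherently adjusts for
platform/coverage bias between query and references.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .config import RunConfig
from .phenotypes import Phenotype
from .simstats import OverlapCounts, bicor, score_pair

__all__ = [
    "MatchResult",
    "NullModel",
    "permute_labels",
    "build_null",
    "p_non_bio",
    "search",
    "benchmark_statistics",
    "write_results_tsv",
    "write_results_json",
    "P_NON_BIO_FLOOR",
]

logger = logging.getLogger(__name__)

#: Floor on the reported permutation p-value (double underflow limit).
P_NON_BIO_FLOOR = 1e-308

RESULT_COLUMNS = (
    "query_id", "ref_id", "n", "a", "b", "c", "d",
    "R", "R2", "FET2p", "ranking_metric", "pm_score", "z", "p_non_bio", "is_hit",
)


@dataclass(frozen=True)
class MatchResult:
    """All statistics for one query-reference comparison."""

    query_id: str
    ref_id: str
    n: int
    counts: OverlapCounts
    R: float
    R2: float
    FET2p: float
    ranking_metric: float
    pm_score: float
    z: float
    p_non_bio: float
    is_hit: bool
    bicor: float | None = field(default=None, compare=False)

    def to_row(self) -> dict:
        c = self.counts
        return {
            "query_id": self.query_id, "ref_id": self.ref_id, "n": self.n,
            "a": c.a, "b": c.b, "c": c.c, "d": c.d,
            "R": self.R, "R2": self.R2, "FET2p": self.FET2p,
            "ranking_metric": self.ranking_metric, "pm_score": self.pm_score,
            "z": self.z, "p_non_bio": self.p_non_bio, "is_hit": self.is_hit,
        }


@dataclass(frozen=True)
class NullModel:
    """Normal model of the pooled permutation score distribution."""

    mean: float
    sd: float
    n_scores: int
    permutations: int
    seed: int
    scores: np.ndarray | None = field(default=None, compare=False, repr=False)

    def quantile(self, q: float) -> float:
        """Empirical quantile of the pooled null scores (requires scores)."""
        if self.scores is None:
            raise ValueError("null scores were not retained")
        return float(np.quantile(self.scores, q))


def permute_labels(query: Phenotype, rng: np.random.Generator) -> Phenotype:
    """Reassign the query's SIR values to a uniformly random permutation of
    its own metabolite labels (same multiset of values, same keys)."""
    keys = sorted(query.responses)  # deterministic base order
    values = [query.responses[k] for k in keys]
    perm = rng.permutation(len(keys))
    responses = {keys[i]: values[perm[i]] for i in range(len(keys))}
    meta = dict(query.metadata)
    meta["permuted"] = "true"
    return Phenotype(id=f"{query.id}#perm", responses=responses, metadata=meta)


def _comparison_score(
    query: Phenotype, ref: Phenotype, cfg: RunConfig
) -> float:
    """Signed score of one comparison under the search's min-overlap gate."""
    pair, sp = score_pair(
        query, ref, threshold=cfg.fc_threshold, unknowns=cfg.unknowns
    )
    if pair.n < cfg.min_overlap:
        return 0.0
    return sp.pm_score


def build_null(
    query: Phenotype,
    refs: Sequence[Phenotype],
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
    *,
    keep_scores: bool = True,
) -> NullModel:
    """Pool permutation scores of the query against every reference.

    Each of ``cfg.permutations`` label shuffles is searched exactly like the
    real query (same threshold, unknowns policy, and min-overlap gate, with
    sub-threshold comparisons contributing score 0), giving
    ``permutations x len(refs)`` null scores.  By default magnitudes
    |score| are pooled — significance asks whether a score is *exceeded in
    magnitude* by chance, which also makes inverse matches testable;
    ``cfg.signed_null`` pools the signed scores instead.
    """
    if not refs:
        raise ValueError("reference library is empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scores = np.empty(cfg.permutations * len(refs), dtype=float)
    i = 0
    for _ in range(cfg.permutations):
        shuffled = permute_labels(query, rng)
        for ref in refs:
            s = _comparison_score(shuffled, ref, cfg)
            scores[i] = s if cfg.signed_null else abs(s)
            i += 1
    mean = float(scores.mean()) if scores.size else 0.0
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    if sd == 0.0:
        logger.warning(
            "build_null: degenerate null (sd=0) for query %r; p_non_bio will "
            "collapse to 1 or the floor", query.id,
        )
    return NullModel(
        mean=mean, sd=sd, n_scores=int(scores.size),
        permutations=cfg.permutations, seed=cfg.seed,
        scores=scores if keep_scores else None,
    )


def p_non_bio(score: float, null: NullModel) -> tuple[float, float]:
    """Upper-tail normal probability that |score| arose from a shuffled query.

    Returns ``(z, p)`` with ``z = (|score| - mean) / sd`` and ``p`` the
    standard-normal upper tail, floored at 1e-308.  A degenerate null
    (sd = 0) yields p = 1 when |score| <= mean, else the floor.
    """
    mag = abs(score)
    if null.sd == 0.0:
        return (0.0, 1.0) if mag <= null.mean else (float("inf"), P_NON_BIO_FLOOR)
    z = (mag - null.mean) / null.sd
    p = float(_sps.norm.sf(z))
    return z, max(min(p, 1.0), P_NON_BIO_FLOOR)


def _ranking_value(res: MatchResult, statistic: str) -> float:
    if statistic == "pm":
        return res.ranking_metric
    if statistic == "r2":
        return res.R2
    if statistic == "bicor":
        return abs(res.bicor) if res.bicor is not None else 0.0
    if statistic == "fet":
        return -np.log10(res.FET2p)
    raise ValueError(f"unknown statistic {statistic!r}")


def search(
    query: Phenotype,
    refs: Sequence[Phenotype],
    cfg: RunConfig,
    *,
    null: NullModel | None = None,
) -> list[MatchResult]:
    """Score a query against a reference library and rank the results.

    One shared :class:`NullModel` per query is reused for every reference.
    Results are ordered descending by the configured ranking statistic with
    ties broken by smaller FET2p, then larger R², then reference id.
    Self-matches (same phenotype id as the query) are excluded when
    ``cfg.exclude_self``.  Matches below the min-overlap gate are reported
    with ``is_hit=False`` ("no hit").
    """
    if not refs:
        raise ValueError("reference library is empty")
    targets = [r for r in refs if not (cfg.exclude_self and r.id == query.id)]
    if not targets:
        raise ValueError("reference library contains only the query itself")
    if null is None and cfg.permutations > 0:
        null = build_null(query, targets, cfg, keep_scores=False)
    alpha = cfg.alpha / len(targets) if cfg.bonferroni else cfg.alpha
    need_bicor = cfg.statistic == "bicor"
    results: list[MatchResult] = []
    for ref in targets:
        pair, sp = score_pair(
            query, ref, threshold=cfg.fc_threshold, unknowns=cfg.unknowns,
            with_bicor=need_bicor,
        )
        if null is not None:
            z, p = p_non_bio(sp.pm_score, null)
        else:
            z, p = float("nan"), float("nan")
        is_hit = pair.n >= cfg.min_overlap and (null is None or p <= alpha)
        results.append(
            MatchResult(
                query_id=query.id, ref_id=ref.id, n=pair.n, counts=pair.counts,
                R=sp.R, R2=sp.R2, FET2p=sp.FET2p,
                ranking_metric=sp.ranking_metric, pm_score=sp.pm_score,
                z=z, p_non_bio=p, is_hit=is_hit, bicor=sp.bicor,
            )
        )
    results.sort(
        key=lambda r: (-_ranking_value(r, cfg.statistic), r.FET2p, -r.R2, r.ref_id)
    )
    return results


def benchmark_statistics(
    queries: Sequence[Phenotype],
    refs: Sequence[Phenotype],
    truth: Mapping[str, set[str] | frozenset[str]],
    cfg: RunConfig,
    statistics: Iterable[str] = ("r2", "bicor", "fet", "pm"),
) -> dict[str, float]:
    """Top-match accuracy of each ranking statistic against known truth.

    For every statistic, the fraction of queries whose top-ranked reference
    is in that query's truth set.  Permutations are disabled here — ranking
    does not depend on the null model.
    """
    missing = [q.id for q in queries if q.id not in truth]
    if missing:
        raise ValueError(f"truth mapping missing queries: {missing}")
    cfg0 = cfg.with_(permutations=0)
    accuracy: dict[str, float] = {}
    for stat in statistics:
        correct = 0
        for q in queries:
            ranked = search(q, refs, cfg0.with_(statistic=stat))
            if ranked and ranked[0].ref_id in truth[q.id]:
                correct += 1
        accuracy[stat] = correct / len(queries) if queries else 0.0
    return accuracy


def write_results_tsv(
    results: Sequence[MatchResult], cfg: RunConfig, path: str | Path
) -> Path:
    """One MatchResult per row; the config and seed ride along as comments."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config: {json.dumps(cfg.to_dict(), sort_keys=True)}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for res in results:
            row = res.to_row()
            fh.write("\t".join(_fmt(row[c]) for c in RESULT_COLUMNS) + "\n")
    return path


def write_results_json(
    results: Sequence[MatchResult], cfg: RunConfig, path: str | Path
) -> Path:
    path = Path(path)
    payload = {
        "config": cfg.to_dict(),
        "results": [res.to_row() for res in results],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)
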