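"""Phenotype similarity networks.

All-vs-all scoring of a phenotype set yields an undirected weighted graph:
nodes are phenotypes (with their metadata, e.g. a functional-category label
for coloring), edges carry the symmetric match statistics.  Weak edges are
filtered out (by default FET2p > 0.007 or R² < 0.09, leaving moderate to
strong matches), and edges that are the best-ranked hit of at least one
endpoint are marked ``is_top_hit`` — top hits are identified on the
*pre-filter* rankings, so a node's top hit can be absent from the filtered
graph unless ``keep_top_hits`` forces its retention.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx

from .config import RunConfig
from .phenotypes import Phenotype
from .search import build_null, p_non_bio
from .simstats import score_pair

__all__ = ["build_network", "export_graph", "EXPORT_FORMATS"]

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("graphml", "gml", "edge_tsv")

EDGE_TSV_COLUMNS = (
    "source", "target", "pm_score", "R2", "FET2p", "p_non_bio", "is_top_hit"
)


def build_network(
    phenotypes: Sequence[Phenotype],
    cfg: RunConfig,
    *,
    keep_top_hits: bool = False,
    compute_p_non_bio: bool = False,
) -> nx.Graph:
    """Score all unordered phenotype pairs once and build the filtered graph.

    Scoring is symmetric, so each pair is computed in a single direction.
    Edges survive when ``FET2p <= cfg.max_fet2p`` and ``R2 >= cfg.min_r2``
    and the pair meets the min-overlap gate.  ``compute_p_non_bio`` attaches
    a permutation p-value per edge (the smaller of the two directional
    values, since the null model is built per query); it is off by default
    because the edge filters need only FET2p and R².
    """
    if len(phenotypes) < 2:
        raise ValueError("need at least 2 phenotypes to build a network")
    ids = [p.id for p in phenotypes]
    if len(set(ids)) != len(ids):
        raise ValueError("phenotype ids must be unique")

    graph = nx.Graph()
    for p in phenotypes:
        graph.add_node(p.id, **{k: str(v) for k, v in p.metadata.items()})

    nulls = {}
    if compute_p_non_bio and cfg.permutations > 0:
        for p in phenotypes:
            others = [q for q in phenotypes if q.id != p.id]
            nulls[p.id] = build_null(p, others, cfg, keep_scores=False)

    stats: dict[tuple[str, str], dict] = {}
    best: dict[str, tuple[float, float, float, str]] = {}
    for p, q in combinations(phenotypes, 2):
        pair, sp = score_pair(p, q, threshold=cfg.fc_threshold, unknowns=cfg.unknowns)
        if pair.n < cfg.min_overlap:
            continue
        attrs = {
            "pm_score": sp.pm_score, "R2": sp.R2, "FET2p": sp.FET2p,
            "n": pair.n, "is_top_hit": False,
        }
        if nulls:
            _, p_pq = p_non_bio(sp.pm_score, nulls[p.id])
            _, p_qp = p_non_bio(sp.pm_score, nulls[q.id])
            attrs["p_non_bio"] = min(p_pq, p_qp)
        stats[(p.id, q.id)] = attrs
        # pre-filter top-hit bookkeeping: same ordering key as search()
        key = (-sp.ranking_metric, sp.FET2p, -sp.R2)
        for u, v in ((p.id, q.id), (q.id, p.id)):
            cand = (*key, v)
            if u not in best or cand < best[u]:
                best[u] = cand

    top_edges = {
        frozenset((u, cand[3])) for u, cand in best.items()
    }
    for (u, v), attrs in stats.items():
        is_top = frozenset((u, v)) in top_edges
        attrs["is_top_hit"] = is_top
        passes = attrs["FET2p"] <= cfg.max_fet2p and attrs["R2"] >= cfg.min_r2
        if passes or (keep_top_hits and is_top):
            graph.add_edge(u, v, **attrs)
    logger.info(
        "build_network: %d nodes, %d edges after filters (max_fet2p=%g, min_r2=%g)",
        graph.number_of_nodes(), graph.number_of_edges(), cfg.max_fet2p, cfg.min_r2,
    )
    return graph


def export_graph(net: nx.Graph, fmt: str, path: str | Path) -> Path:
    """Write the network as GraphML (primary), GML, or a flat edge TSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "gml":
        # GML has no boolean type; encode flags as 0/1.
        g = net.copy()
        for _, _, attrs in g.edges(data=True):
            attrs["is_top_hit"] = int(attrs.get("is_top_hit", False))
        nx.write_gml(g, path)
    elif fmt == "edge_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(EDGE_TSV_COLUMNS) + "\n")
            for u, v, attrs in sorted(net.edges(data=True)):
                row = [
                    u, v,
                    repr(attrs["pm_score"]), repr(attrs["R2"]), repr(attrs["FET2p"]),
                    repr(attrs["p_non_bio"]) if "p_non_bio" in attrs else "NA",
                    "true" if attrs.get("is_top_hit") else "false",
                ]
                fh.write("\t".join(row) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; expected {EXPORT_FORMATS}")
    return path
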