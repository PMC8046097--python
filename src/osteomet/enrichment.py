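"""Pathway over-representation and topology-impact analysis.

Pathway definitions are user-supplied inputs (GMT-style membership files,
optional per-pathway reaction graphs); nothing is fetched.  Enrichment of a
query metabolite set against a measured background is the one-sided
hypergeometric tail (Fisher's exact test for over-representation), BH
adjusted across pathways.  The topology "impact" of a hit set is the share
of the pathway graph's relative betweenness centrality carried by the hit
nodes — the standard pathway-topology measure popularized by web-based
metabolomics tools, implemented here as a documented approximation of such
tools' internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats

from .univariate import adjust

logger = logging.getLogger(__name__)

__all__ = ["PathwaySet", "enrich", "impact"]


@dataclass
class PathwaySet:
    """One pathway: id, display name, member metabolites, optional graph."""

    id: str
    name: str
    members: frozenset
    graph: nx.Graph | None = None

    def __post_init__(self):
        self.members = frozenset(self.members)
        if self.graph is not None:
            extra = set(self.graph.nodes) - self.members
            if extra:
                raise ValueError(
                    f"pathway {self.id}: graph nodes not in member list: "
                    f"{sorted(extra)[:5]}")


def enrich(query, background, pathways) -> pd.DataFrame:
    """Over-representation of ``query`` within each pathway.

    Parameters
    ----------
    query:
        Differential metabolite ids; must be a subset of ``background``.
    background:
        All measured (filter-surviving) metabolite ids forming the sampling
        universe.
    pathways:
        Iterable of :class:`PathwaySet`.

    Returns a DataFrame sorted by p with columns (pathway, name, total,
    hits, hit_ids, p, p_adj, impact); ``total`` counts pathway members, and
    the hypergeometric universe is the background restricted to mappable
    members.  Pathways with no member in the background are skipped.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query set")
    if not query <= background:
        raise ValueError("query must be a subset of the background")

    N = len(background)
    n = len(query)
    rows = []
    for pw in pathways:
        mappable = pw.members & background
        if not mappable:
            logger.info("pathway %s has no mappable members; skipped", pw.id)
            continue
        hits = sorted(query & mappable)
        K = len(mappable)
        k = len(hits)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        imp = impact(pw.graph, hits) if pw.graph is not None else float("nan")
        rows.append({"pathway": pw.id, "name": pw.name,
                     "total": len(pw.members), "hits": k,
                     "hit_ids": ";".join(hits), "p": min(p, 1.0),
                     "impact": imp})
    if not rows:
        return pd.DataFrame(columns=["pathway", "name", "total", "hits",
                                     "hit_ids", "p", "p_adj", "impact"])
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust(out["p"].to_numpy(), "fdr_bh")
    return out.sort_values(["p", "pathway"],
                           kind="mergesort").reset_index(drop=True)


def impact(graph: nx.Graph | None, hit_ids) -> float:
    """Topology impact: hit share of total relative betweenness centrality.

    Returns sum of normalized betweenness centrality over hit nodes divided
    by the sum over all nodes, in [0, 1].  A star's leaves have centrality
    0, so leaf-only hits give impact 0; if every node is hit the impact is
    1.  Degenerate graphs in which all centralities are 0 (e.g. a single
    edge) fall back to the hit fraction of nodes so that saturation still
    reports 1.
    """
    if graph is None or graph.number_of_nodes() == 0:
        logger.warning("empty pathway graph; impact = 0")
        return 0.0
    hits = set(hit_ids) & set(graph.nodes)
    if not hits:
        return 0.0
    bc = nx.betweenness_centrality(graph, normalized=True)
    total = sum(bc.values())
    if total <= 0:
        return len(hits) / graph.number_of_nodes()
    return float(sum(bc[h] for h in hits) / total)
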