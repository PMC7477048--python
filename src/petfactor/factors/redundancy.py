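"""Redundancy filtering: remove the fewest features so no retained pair is
correlated above a threshold.

Pairs with |r| >= threshold define a graph; the removal set is a minimum
vertex cover of that graph — exact (branch and bound) for connected
components up to ``exact_limit`` nodes, greedy max-degree beyond that.
Ties are broken by removing the feature with the higher mean |r| first,
then lexicographically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.95


@dataclass
class RedundancyResult:
    retained: list[str]
    removed: dict[str, str]          # removed feature -> a partner that triggered it
    threshold: float
    constant_dropped: list[str] = field(default_factory=list)
    exact: bool = True               # False if any component used the greedy fallback


def _exact_cover(edges: list[tuple[str, str]], priority: dict[str, tuple]) -> set[str]:
    """Minimum vertex cover by branch and bound.

    ``priority[v]`` sorts candidate vertices (higher first) so that among
    equal-size covers the choice is deterministic.
    """
    best: set[str] | None = None

    def bound_ok(cover_size: int) -> bool:
        return best is None or cover_size < len(best)

    def bb(edges: list[tuple[str, str]], cover: set[str]) -> None:
        nonlocal best
        if not bound_ok(len(cover)):
            return
        if not edges:
            if best is None or len(cover) < len(best):
                best = set(cover)
            return
        deg: dict[str, int] = {}
        for u, v in edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        v = max(deg, key=lambda x: (deg[x],) + priority[x])
        # branch 1: v is removed
        bb([e for e in edges if v not in e], cover | {v})
        # branch 2: v stays, so all its neighbours are removed
        nbrs = {u for e in edges if v in e for u in e if u != v}
        covered = nbrs | {v}
        bb([e for e in edges if e[0] not in covered and e[1] not in covered],
           cover | nbrs)

    bb(edges, set())
    assert best is not None
    return best


def _greedy_cover(g: nx.Graph, priority: dict[str, tuple]) -> set[str]:
    g = g.copy()
    cover: set[str] = set()
    while g.number_of_edges() > 0:
        v = max(g.nodes, key=lambda x: (g.degree(x),) + priority[x])
        cover.add(v)
        g.remove_node(v)
    return cover


def redundancy_filter(table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                      exact_limit: int = 25) -> RedundancyResult:
    """Drop the minimum number of features so all retained |r| < threshold."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    constant = [c for c in table.columns if table[c].nunique() <= 1
                or float(table[c].std()) == 0.0]
    if constant:
        logger.info("dropping %d constant columns: %s", len(constant), constant)
    work = table.drop(columns=constant)

    corr = work.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    mean_r = corr.mean(axis=0)

    g = nx.Graph()
    g.add_nodes_from(work.columns)
    rows, cols = np.where(corr.values >= threshold)
    for i, j in zip(rows, cols):
        if i < j:
            g.add_edge(work.columns[i], work.columns[j])

    # higher mean |r| wins ties, then lexicographically smaller name
    priority = {c: (float(mean_r[c]), tuple(-ord(ch) for ch in c)) for c in work.columns}

    cover: set[str] = set()
    exact = True
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        if len(comp) <= exact_limit:
            cover |= _exact_cover(list(sub.edges), priority)
        else:
            exact = False
            cover |= _greedy_cover(sub, priority)
    if exact is False:
        logger.warning("greedy cover used for components larger than %d nodes",
                       exact_limit)

    retained = [c for c in work.columns if c not in cover]
    if not retained:
        # everything mutually redundant: keep a single representative
        keep = max(work.columns, key=lambda c: priority[c])
        retained = [keep]
        cover.discard(keep)
        logger.warning("all features mutually redundant; retaining %r only", keep)

    removed: dict[str, str] = {}
    for v in cover:
        partners = [u for u in g.neighbors(v)]
        removed[v] = min(partners, key=lambda u: -corr.loc[v, u]) if partners else ""
    return RedundancyResult(
        retained=retained,
        removed=removed,
        threshold=threshold,
        constant_dropped=constant,
        exact=exact,
    )
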