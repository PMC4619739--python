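"""The PPI graph substrate and the two interaction scores.

The network is an undirected simple graph over gene symbols (a
:class:`networkx.Graph`).  Against a seed set S of known disease genes, a
gene g receives

* ``direct_score(g)  = |N(g) ∩ (S \\ {g})|`` — the number of seed genes it
  directly interacts with (its level-1 score), and
* ``indirect_score(g) = Σ_{s ∈ S\\{g}} |N(g) ∩ N(s) \\ {g, s}|`` — the number
  of length-2 paths g–x–s to seed genes through common interactors x (its
  level-2 score).

A seed gene never contributes to its own score, so the scores of seed genes
measure connectivity to *other* seeds.  Intermediates x may be any node,
including other seeds.  By default several seeds sharing the same
intermediate each contribute one (seed, intermediate) pair; set
``intermediates="distinct"`` to count each common interactor once instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .io import EdgeList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScorePair:
    """A gene's direct (level-1) and indirect (level-2) interaction counts."""

    gene: str
    direct_score: int
    indirect_score: int


def build_network(edges: EdgeList | Iterable[tuple[str, str]]) -> nx.Graph:
    """Build an undirected simple graph from raw interaction pairs.

    Parallel edges collapse, orientation is ignored, and self-interactions
    are dropped (with a logged count).  The node set is exactly the symbols
    appearing in kept edges.
    """
    pairs = edges.edges if isinstance(edges, EdgeList) else list(edges)
    g = nx.Graph()
    n_self = 0
    for a, b in pairs:
        if a == b:
            n_self += 1
            continue
        g.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-interaction(s) at graph build", n_self)
    return g


def _check_seeds(seeds: set[str]) -> None:
    if not seeds:
        raise ValueError("seed set must be non-empty")


def _warn_if_absent(gene: str, net: nx.Graph) -> bool:
    if gene not in net:
        logger.warning("gene %s absent from the network; score 0", gene)
        return True
    return False


def direct_score(gene: str, seeds: set[str] | Iterable[str], net: nx.Graph) -> int:
    """Number of seed genes directly interacting with ``gene``.

    ``gene`` itself is excluded from the seed set, so a seed's direct score
    counts interactions with *other* seeds.  Genes absent from the network
    score 0 with a warning.
    """
    seeds = set(seeds)
    _check_seeds(seeds)
    if _warn_if_absent(gene, net):
        return 0
    return sum(1 for n in net[gene] if n in seeds and n != gene)


def indirect_score(
    gene: str,
    seeds: set[str] | Iterable[str],
    net: nx.Graph,
    intermediates: str = "per_seed",
) -> int:
    """Number of length-2 paths gene–x–s to seed genes s via interactors x.

    Each path requires edges gene–x and x–s with x distinct from both
    endpoints.  With ``intermediates="per_seed"`` (default) the count sums
    over (seed, intermediate) pairs; with ``"distinct"`` each intermediate
    counts once no matter how many seeds it reaches.
    """
    if intermediates not in ("per_seed", "distinct"):
        raise ValueError(f"unknown intermediates mode: {intermediates!r}")
    seeds = set(seeds)
    _check_seeds(seeds)
    if _warn_if_absent(gene, net):
        return 0
    neighbors = set(net[gene]) - {gene}
    if intermediates == "distinct":
        hit: set[str] = set()
        for s in seeds - {gene}:
            if s not in net:
                continue
            hit |= (neighbors & set(net[s])) - {gene, s}
        return len(hit)
    total = 0
    for s in seeds - {gene}:
        if s not in net:
            continue
        total += len((neighbors & set(net[s])) - {gene, s})
    return total


def score_all(
    net: nx.Graph,
    seeds: set[str] | Iterable[str],
    intermediates: str = "per_seed",
) -> list[ScorePair]:
    """Score every node of the network against the seed set.

    Returns one :class:`ScorePair` per node, seeds included (with the
    self-exclusion rule), in lexicographic gene order.  Implemented by a
    single accumulation pass over seed neighborhoods rather than per-gene
    set intersections, so it scales with the seeds' two-hop volume.
    """
    seeds = set(seeds)
    _check_seeds(seeds)

    direct: dict[str, int] = {}
    indirect: dict[str, int] = {}
    indirect_sources: dict[str, set[str]] = {}

    present = [s for s in seeds if s in net]
    for s in present:
        s_neighbors = set(net[s]) - {s}
        for g in s_neighbors:
            if g != s:
                direct[g] = direct.get(g, 0) + 1
        # every g adjacent to x adjacent to s (x != g, x != s) gains one path
        for x in s_neighbors:
            for g in net[x]:
                if g == s or g == x:
                    continue
                if intermediates == "distinct":
                    indirect_sources.setdefault(g, set()).add(x)
                else:
                    indirect[g] = indirect.get(g, 0) + 1
    if intermediates == "distinct":
        indirect = {g: len(xs) for g, xs in indirect_sources.items()}

    return [
        ScorePair(gene=g, direct_score=direct.get(g, 0), indirect_score=indirect.get(g, 0))
        for g in sorted(net.nodes)
    ]
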