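"""Candidate classification, ranking, prior thresholds, and summary statistics.

A non-seed gene is a *level-1 candidate* if it directly interacts with at
least one seed (direct score >= 1) and a *level-2 candidate* if it shares at
least one common interactor with a seed (indirect score >= 1).  *Prior
candidates* exceed strict score thresholds: indirect score > 50 for level-2
and direct score > 4 for level-1, both configurable.

Candidates are ranked by indirect score (descending), then direct score
(descending), then gene symbol — a total, deterministic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import networkx as nx

from .network import ScorePair

DEFAULT_DIRECT_THRESHOLD = 4
DEFAULT_INDIRECT_THRESHOLD = 50


@dataclass(frozen=True)
class CandidateRecord:
    """One candidate gene's scores, level memberships, prior flags and rank."""

    gene: str
    direct_score: int
    indirect_score: int
    level1_member: bool
    level2_member: bool
    level2_only: bool
    prior_level1: bool
    prior_level2: bool
    rank: int


@dataclass(frozen=True)
class NetworkSummary:
    """Level-1/level-2 network features relative to the seed set.

    Percentages are fractions of seeds with at least one direct (resp.
    indirect) interaction with another seed, rounded half-up to 2 decimals;
    the raw fractions are kept alongside.
    """

    n_seeds: int
    n_seeds_with_direct_link: int
    n_seeds_with_indirect_link: int
    pct_direct: float
    pct_indirect: float
    frac_direct: float
    frac_indirect: float
    n_level1_candidates: int
    n_level2_candidates: int
    n_direct_interactions: int
    n_indirect_interactions: int


@dataclass(frozen=True)
class DistributionComparison:
    """Fractions of positives vs candidates at/above a score threshold.

    ``fold`` is ``frac_positives_ge / frac_candidates_ge``; ``None`` when the
    candidate fraction is zero (undefined, not infinity).
    """

    threshold: int
    mode: str
    frac_positives_ge: float
    frac_candidates_ge: float
    fold: float | None


def _round_pct(numer: int, denom: int) -> tuple[float, float]:
    """(half-up 2-decimal percentage, raw fraction); 0.00 on empty denom."""
    if denom == 0:
        return 0.0, 0.0
    frac = numer / denom
    pct = float(
        (Decimal(100) * Decimal(numer) / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return pct, frac


def classify_and_rank(
    scores: Sequence[ScorePair],
    seeds: set[str] | Iterable[str],
    direct_threshold: int = DEFAULT_DIRECT_THRESHOLD,
    indirect_threshold: int = DEFAULT_INDIRECT_THRESHOLD,
) -> list[CandidateRecord]:
    """Turn raw scores into ranked candidate records.

    Seed genes are excluded from the output even when their scores would
    qualify.  Thresholds are strict: a prior level-2 candidate needs an
    indirect score strictly greater than ``indirect_threshold`` (default
    "more than 50"), a prior level-1 candidate a direct score strictly
    greater than ``direct_threshold`` (default "greater than 4").
    """
    seeds = set(seeds)
    candidates = [sp for sp in scores if sp.gene not in seeds]
    candidates.sort(key=lambda sp: (-sp.indirect_score, -sp.direct_score, sp.gene))
    records = []
    for rank, sp in enumerate(candidates, start=1):
        l1 = sp.direct_score >= 1
        l2 = sp.indirect_score >= 1
        records.append(
            CandidateRecord(
                gene=sp.gene,
                direct_score=sp.direct_score,
                indirect_score=sp.indirect_score,
                level1_member=l1,
                level2_member=l2,
                level2_only=l2 and not l1,
                prior_level1=sp.direct_score > direct_threshold,
                prior_level2=sp.indirect_score > indirect_threshold,
                rank=rank,
            )
        )
    return records


def summarize_network(
    scores: Sequence[ScorePair],
    seeds: set[str] | Iterable[str],
    net: nx.Graph,
) -> NetworkSummary:
    """Compute the level-1/level-2 feature summary of the network.

    Seeds absent from the network still count in ``n_seeds`` (their scores
    are 0).  ``n_direct_interactions`` is the number of graph edges incident
    to at least one seed (the level-1 network's edges);
    ``n_indirect_interactions`` is the total indirect score over non-seed
    candidates (length-2 path count, with the caveat that shared-hub paths
    are counted per (seed, intermediate) pair).
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    by_gene = {sp.gene: sp for sp in scores}
    seed_pairs = [by_gene[s] for s in seeds if s in by_gene]
    n_direct = sum(1 for sp in seed_pairs if sp.direct_score >= 1)
    n_indirect = sum(1 for sp in seed_pairs if sp.indirect_score >= 1)
    pct_d, frac_d = _round_pct(n_direct, len(seeds))
    pct_i, frac_i = _round_pct(n_indirect, len(seeds))
    cand = [sp for sp in scores if sp.gene not in seeds]
    return NetworkSummary(
        n_seeds=len(seeds),
        n_seeds_with_direct_link=n_direct,
        n_seeds_with_indirect_link=n_indirect,
        pct_direct=pct_d,
        pct_indirect=pct_i,
        frac_direct=frac_d,
        frac_indirect=frac_i,
        n_level1_candidates=sum(1 for sp in cand if sp.direct_score >= 1),
        n_level2_candidates=sum(1 for sp in cand if sp.indirect_score >= 1),
        n_direct_interactions=sum(
            1 for u, v in net.edges if u in seeds or v in seeds
        ),
        n_indirect_interactions=sum(sp.indirect_score for sp in cand),
    )


def format_summary(summary: NetworkSummary) -> str:
    """Pretty text block mirroring the feature-table layout."""
    rows = [
        ("Positive genes", summary.n_seeds, summary.n_seeds),
        (
            "Positive gene interactions",
            summary.n_seeds_with_direct_link,
            summary.n_seeds_with_indirect_link,
        ),
        (
            "Positive gene interaction percentage",
            f"{summary.pct_direct:.2f}%",
            f"{summary.pct_indirect:.2f}%",
        ),
        ("Candidate genes", summary.n_level1_candidates, summary.n_level2_candidates),
        (
            "Protein-protein interactions",
            summary.n_direct_interactions,
            summary.n_indirect_interactions,
        ),
    ]
    width = max(len(r[0]) for r in rows)
    lines = [f"{'':<{width}}\tLevel-1\tLevel-2"]
    lines += [f"{name:<{width}}\t{l1}\t{l2}" for name, l1, l2 in rows]
    return "\n".join(lines)


def compare_distributions(
    scores: Sequence[ScorePair],
    seeds: set[str] | Iterable[str],
    threshold: int,
    mode: str = "direct",
) -> DistributionComparison:
    """Compare positives' and candidates' score distributions at a threshold.

    Reports, for the chosen score (``direct`` or ``indirect``), the fraction
    of seed genes and the fraction of candidate genes scoring at least
    ``threshold``, plus their fold ratio.
    """
    if mode not in ("direct", "indirect"):
        raise ValueError(f"unknown mode: {mode!r}")
    seeds = set(seeds)
    pos = [sp for sp in scores if sp.gene in seeds]
    cand = [sp for sp in scores if sp.gene not in seeds]
    if not pos or not cand:
        raise ValueError("need at least one positive and one candidate with scores")
    get = (lambda sp: sp.direct_score) if mode == "direct" else (
        lambda sp: sp.indirect_score
    )
    frac_p = sum(1 for sp in pos if get(sp) >= threshold) / len(pos)
    frac_c = sum(1 for sp in cand if get(sp) >= threshold) / len(cand)
    fold = frac_p / frac_c if frac_c > 0 else None
    return DistributionComparison(
        threshold=threshold,
        mode=mode,
        frac_positives_ge=frac_p,
        frac_candidates_ge=frac_c,
        fold=fold,
    )
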