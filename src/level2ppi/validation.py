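"""Holdout cross-validation of the scoring rules and reference-list overlap.

Cross-validation deletes k seed genes at random from the eligible pool (seeds
with at least one direct AND one indirect interaction with another seed),
rescores the network with the reduced seed set, and compares the held-out
genes' mean score with the mean score of all non-seed candidate genes.  The
ratio is computed separately for the direct (level-1) and indirect (level-2)
scores on the SAME deletion set, so the two ratio series form matched pairs;
a two-sided paired t-test then asks whether the level-2 network recovers
held-out disease genes better than the level-1 network.

The coincidence profile bins ranked candidates (e.g. ranks 1-14, 15-76,
77-965, rest) and reports, per bin, the fraction found in an external
reference gene list such as a differential-expression hit list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .io import GeneList
from .network import score_all
from .prediction import CandidateRecord

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (14, 76, 965)


@dataclass
class CrossValResult:
    """Per-replicate holdout ratios for both scoring levels plus the paired test."""

    n_replicates: int
    k_deleted: int
    ratios_level1: list[float]
    ratios_level2: list[float]
    mean_ratio_level1: float
    mean_ratio_level2: float
    paired_t_stat: float
    paired_p: float
    rng_seed: int
    heldout_sets: list[tuple[str, ...]] = field(default_factory=list)
    #: per replicate, median rank of the held-out genes among all ranked
    #: genes (held-out plus candidates, by indirect score), as a fraction of
    #: the ranked universe in (0, 1]; small = recovered near the top
    heldout_median_rank_frac: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class OverlapBin:
    rank_lo: int
    rank_hi: int  # inclusive; 0 means open-ended
    n_candidates: int
    n_overlapping: int
    coincidence_ratio: float | None


@dataclass
class OverlapProfile:
    """Coincidence ratios of ranked candidate bins against a reference list."""

    reference_name: str
    bins: list[OverlapBin]


def _paired_test(level2: Sequence[float], level1: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test, with the zero-variance cases made explicit."""
    diffs = np.asarray(level2, dtype=float) - np.asarray(level1, dtype=float)
    if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, float(diffs.mean())), 0.0
    t, p = stats.ttest_rel(level2, level1)
    return float(t), float(p)


def eligible_seed_pool(net: nx.Graph, seeds: set[str] | Iterable[str]) -> list[str]:
    """Seeds with >=1 direct AND >=1 indirect interaction with another seed.

    This is the pool the holdout deletes from — the analog of the positive
    genes shared by the level-1 and level-2 networks.
    """
    seeds = set(seeds)
    by_gene = {sp.gene: sp for sp in score_all(net, seeds)}
    return sorted(
        s
        for s in seeds
        if s in by_gene
        and by_gene[s].direct_score >= 1
        and by_gene[s].indirect_score >= 1
    )


def holdout_cv(
    net: nx.Graph,
    seeds: set[str] | Iterable[str],
    k: int = 5,
    n_reps: int = 100,
    rng_seed: int = 0,
    comparison_group: str = "heldout",
    max_redraws_per_rep: int = 50,
) -> CrossValResult:
    """Leave-k-out cross-validation of level-1 vs level-2 scoring.

    Per replicate: draw k genes without replacement from the eligible pool,
    rescore the network against the remaining seeds, and take, for each
    scoring level, ``mean(score of held-out genes) / mean(score of all
    non-seed candidates)``.  A ratio above 1 means held-out disease genes
    score higher than the candidate background, i.e. the network would have
    prioritized them.

    ``comparison_group="remaining"`` swaps the numerator group for the seeds
    kept in the reduced set (an alternative reading of "positive group").
    Replicates with a zero candidate mean are redrawn (logged), preserving
    the paired design, up to ``max_redraws_per_rep`` attempts each.
    """
    if comparison_group not in ("heldout", "remaining"):
        raise ValueError(f"unknown comparison_group: {comparison_group!r}")
    seeds = set(seeds)
    pool = eligible_seed_pool(net, seeds)
    if len(pool) <= k:
        raise ValueError(
            f"eligible seed pool has {len(pool)} genes; need more than k={k}"
        )
    rng = np.random.default_rng(rng_seed)

    ratios1: list[float] = []
    ratios2: list[float] = []
    heldout_sets: list[tuple[str, ...]] = []
    rank_fracs: list[float] = []
    for rep in range(n_reps):
        for attempt in range(max_redraws_per_rep):
            held = tuple(sorted(rng.choice(pool, size=k, replace=False)))
            reduced = seeds - set(held)
            scores = score_all(net, reduced)
            by_gene = {sp.gene: sp for sp in scores}
            numer_group = held if comparison_group == "heldout" else tuple(
                sorted(reduced)
            )
            cand = [sp for sp in scores if sp.gene not in seeds]
            if not cand:
                raise ValueError("network has no non-seed candidate genes")
            mean_c1 = sum(sp.direct_score for sp in cand) / len(cand)
            mean_c2 = sum(sp.indirect_score for sp in cand) / len(cand)
            if mean_c1 == 0 or mean_c2 == 0:
                logger.info(
                    "replicate %d attempt %d: zero candidate mean, redrawing",
                    rep,
                    attempt,
                )
                continue
            # held-out genes absent from the network score 0
            num1 = [by_gene[g].direct_score if g in by_gene else 0 for g in numer_group]
            num2 = [
                by_gene[g].indirect_score if g in by_gene else 0 for g in numer_group
            ]
            ratios1.append((sum(num1) / len(num1)) / mean_c1)
            ratios2.append((sum(num2) / len(num2)) / mean_c2)
            heldout_sets.append(held)
            # where would the held-out genes rank among the candidates?
            universe = sorted(
                [sp for sp in scores if sp.gene not in reduced],
                key=lambda sp: (-sp.indirect_score, -sp.direct_score, sp.gene),
            )
            rank_of = {sp.gene: i for i, sp in enumerate(universe, start=1)}
            held_ranks = sorted(rank_of.get(g, len(universe)) for g in held)
            median = float(np.median(held_ranks))
            rank_fracs.append(median / len(universe))
            break
        else:
            raise RuntimeError(
                f"replicate {rep}: candidate mean score was zero in "
                f"{max_redraws_per_rep} consecutive draws"
            )

    t, p = _paired_test(ratios2, ratios1)
    return CrossValResult(
        n_replicates=n_reps,
        k_deleted=k,
        ratios_level1=ratios1,
        ratios_level2=ratios2,
        mean_ratio_level1=float(np.mean(ratios1)),
        mean_ratio_level2=float(np.mean(ratios2)),
        paired_t_stat=t,
        paired_p=p,
        rng_seed=rng_seed,
        heldout_sets=heldout_sets,
        heldout_median_rank_frac=rank_fracs,
    )


def write_cv_table(result: CrossValResult, path) -> None:
    """One row per replicate plus a summary block, as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("replicate\tratio_level1\tratio_level2\theldout_genes\n")
        for i, (r1, r2, held) in enumerate(
            zip(result.ratios_level1, result.ratios_level2, result.heldout_sets),
            start=1,
        ):
            fh.write(f"{i}\t{r1:.6g}\t{r2:.6g}\t{','.join(held)}\n")
        fh.write(f"# mean_ratio_level1\t{result.mean_ratio_level1:.6g}\n")
        fh.write(f"# mean_ratio_level2\t{result.mean_ratio_level2:.6g}\n")
        fh.write(f"# paired_t_stat\t{result.paired_t_stat:.6g}\n")
        fh.write(f"# paired_p\t{result.paired_p:.6g}\n")
        fh.write(f"# rng_seed\t{result.rng_seed}\n")


def coincidence_profile(
    records: Sequence[CandidateRecord],
    reference: GeneList,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> OverlapProfile:
    """Fraction of each rank bin of candidates found in a reference gene list.

    ``bin_edges`` are strictly increasing inclusive upper rank cutoffs; the
    default (14, 76, 965) yields bins 1-14, 15-76, 77-965 and an open-ended
    remainder.  Empty bins report an undefined (``None``) ratio.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or (edges and edges[0] < 1):
        raise ValueError("bin edges must be strictly increasing rank cutoffs >= 1")
    ref = reference.as_set()
    bounds = []
    lo = 1
    for hi in edges:
        bounds.append((lo, hi))
        lo = hi + 1
    bounds.append((lo, 0))  # open-ended tail

    bins: list[OverlapBin] = []
    for lo, hi in bounds:
        members = [
            r for r in records if r.rank >= lo and (hi == 0 or r.rank <= hi)
        ]
        n_over = sum(1 for r in members if r.gene in ref)
        ratio = n_over / len(members) if members else None
        bins.append(
            OverlapBin(
                rank_lo=lo,
                rank_hi=hi,
                n_candidates=len(members),
                n_overlapping=n_over,
                coincidence_ratio=ratio,
            )
        )
    return OverlapProfile(reference_name=reference.name, bins=bins)


def write_overlap_table(profile: OverlapProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank_lo\trank_hi\tn_candidates\tn_overlapping\tcoincidence_ratio\n")
        for b in profile.bins:
            hi = str(b.rank_hi) if b.rank_hi else "inf"
            ratio = f"{b.coincidence_ratio:.6g}" if b.coincidence_ratio is not None else "NA"
            fh.write(f"{b.rank_lo}\t{hi}\t{b.n_candidates}\t{b.n_overlapping}\t{ratio}\n")


def set_overlap(candidates: GeneList, reference: GeneList) -> tuple[int, float]:
    """|candidates ∩ reference| and its fraction of the candidate list."""
    if len(candidates) == 0:
        raise ValueError("candidate list must be non-empty")
    n = len(candidates.as_set() & reference.as_set())
    return n, n / len(candidates)
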