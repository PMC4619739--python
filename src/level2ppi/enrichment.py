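"""Hypergeometric gene-set enrichment and shared-pathway coherence.

For a query gene list (candidates or seeds) and a gene-set collection, each
set is tested with the one-sided hypergeometric upper tail (Fisher's exact,
"greater"): drawing ``n`` query genes from a background universe of ``N``
genes of which ``K`` belong to the set, the p-value is ``P[X >= k]`` for the
observed overlap ``k``.  Sets with p below the cutoff (default 0.01, on raw
p-values; Benjamini-Hochberg optional) are flagged enriched.  Functional
coherence between candidates and seeds is the intersection of their enriched
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneList, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.01


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    The probability that drawing ``n`` genes without replacement from a
    universe of ``N`` containing ``K`` set members yields at least ``k``
    members.
    """
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    n_set: int
    n_query: int
    n_overlap: int
    n_background: int
    p_value: float
    adjusted_p: float | None
    enriched: bool


def enrich(
    query: GeneList,
    collection: GeneSetCollection,
    background: GeneList,
    cutoff: float = DEFAULT_CUTOFF,
    adjust: str = "none",
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of ``query`` in each set of ``collection``.

    All counts are taken within the deduplicated background universe; query
    genes outside it are dropped with a warning.  Rows are sorted by
    p-value ascending (set name breaking ties).  With ``adjust="BH"`` the
    enriched flag is applied to Benjamini-Hochberg adjusted p-values, which
    are reported in either case only when requested.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjust: {adjust!r}")
    if len(collection) == 0:
        raise ValueError("gene-set collection is empty")
    bg = background.as_set()
    if not bg:
        raise ValueError("background is empty")
    q = query.as_set()
    dropped = q - bg
    if dropped:
        logger.warning(
            "%d query gene(s) outside the background dropped", len(dropped)
        )
    q &= bg
    N, n = len(bg), len(q)

    rows = []
    for name in collection.names():
        members = collection.members(name) & bg
        K = len(members)
        k = len(members & q)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append((name, K, k, p))

    pvals = [r[3] for r in rows]
    adj = (
        list(multipletests(pvals, method="fdr_bh")[1]) if adjust == "BH" else None
    )
    out = []
    for i, (name, K, k, p) in enumerate(rows):
        a = adj[i] if adj is not None else None
        stat = a if adjust == "BH" else p
        out.append(
            EnrichmentRow(
                set_name=name,
                n_set=K,
                n_query=n,
                n_overlap=k,
                n_background=N,
                p_value=p,
                adjusted_p=a,
                enriched=stat < cutoff,
            )
        )
    out.sort(key=lambda r: (r.p_value, r.set_name))
    return out


def shared_enrichment(
    cand_rows: Sequence[EnrichmentRow], seed_rows: Sequence[EnrichmentRow]
) -> list[str]:
    """Gene sets enriched in both the candidate and the seed analysis.

    Both inputs must come from the same collection and background; the result
    is sorted by the worse (max) of the two p-values, then name.
    """
    cand_by = {r.set_name: r for r in cand_rows}
    seed_by = {r.set_name: r for r in seed_rows}
    if set(cand_by) != set(seed_by):
        raise ValueError("enrichment row lists cover different gene-set collections")
    shared = [
        name
        for name in cand_by
        if cand_by[name].enriched and seed_by[name].enriched
    ]
    shared.sort(key=lambda n: (max(cand_by[n].p_value, seed_by[n].p_value), n))
    return shared


def write_enrichment_table(rows: Sequence[EnrichmentRow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "set_name\tn_set\tn_query\tn_overlap\tn_background\t"
            "p_value\tadjusted_p\tenriched\n"
        )
        for r in rows:
            adj = f"{r.adjusted_p:.6g}" if r.adjusted_p is not None else "NA"
            fh.write(
                f"{r.set_name}\t{r.n_set}\t{r.n_query}\t{r.n_overlap}\t"
                f"{r.n_background}\t{r.p_value:.6g}\t{adj}\t"
                f"{'1' if r.enriched else '0'}\n"
            )
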