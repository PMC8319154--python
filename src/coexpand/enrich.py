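"""Hypergeometric overlap tests and over-representation analysis (ORA).

Given a query gene list, a collection of gene sets, and a universe, each
set is tested for over-representation with the hypergeometric upper tail
``P(X >= k)``; p-values are Benjamini-Hochberg corrected across sets and
transformed to the enrichment score ``-log2(p_adj)``, with the usual
tiers: high (p_adj <= 1e-4), medium (1e-4 < p_adj <= 0.05), low
(p_adj > 0.05).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneList, GeneSetCollection

log = logging.getLogger(__name__)

TIER_HIGH_MAX = 1e-4
TIER_MEDIUM_MAX = 0.05

_P_FLOOR = 1e-300  # keeps -log2 finite


@dataclass
class OverlapTest:
    """Hypergeometric upper-tail test of the overlap of two lists."""

    k: int  # observed overlap
    K: int  # size of list 1
    n: int  # size of list 2
    N: int  # universe size
    p_upper: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_upper <= 1.0:
            raise ValueError("p_upper must lie in (0, 1]")


@dataclass
class EnrichmentRow:
    set_name: str
    overlap_genes: list[str]
    k: int
    set_size: int
    p: float
    p_adj: float
    score: float
    tier: str


def classify_tier(p_adj: float) -> str:
    if p_adj <= TIER_HIGH_MAX:
        return "high"
    if p_adj <= TIER_MEDIUM_MAX:
        return "medium"
    return "low"


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> OverlapTest:
    """Upper-tail probability of drawing >= k marked items.

    ``X ~ Hypergeometric(N, K, n)``: a draw of ``n`` items from a universe
    of ``N`` containing ``K`` marked ones; ``p_upper = P(X >= k)``.
    """
    if min(k, K, n, N) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError("list sizes cannot exceed the universe")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k < max(0, K + n - N):
        raise ValueError(f"overlap k={k} impossible given K={K}, n={n}, N={N}")
    # survival function of the hypergeometric; scipy evaluates the tail sum
    # stably in log space internally
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(k=k, K=K, n=n, N=N, p_upper=min(max(p, _P_FLOOR), 1.0))


def ora(
    query: GeneList,
    sets: GeneSetCollection,
    universe: GeneList,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` in each gene set, BH-corrected.

    Query genes outside the universe are dropped with a warning; each set
    is intersected with the universe before testing. Rows are sorted by
    adjusted p-value, then set name.
    """
    uni = set(universe.genes)
    if not uni:
        raise ValueError("universe is empty")
    q = [g for g in query.genes if g in uni]
    outside = len(query.genes) - len(q)
    if outside:
        log.warning("%d query genes outside the universe were dropped", outside)
    if not q:
        raise ValueError("no query genes inside the universe")
    qset = set(q)

    names, pvals, rows = [], [], []
    for name in sorted(sets.sets):
        members = sorted(set(sets.sets[name]) & uni)
        if not members:
            log.warning("set %r has no genes in the universe; skipped", name)
            continue
        overlap = sorted(qset & set(members))
        test = hypergeom_overlap(len(overlap), len(qset), len(members), len(uni))
        names.append(name)
        pvals.append(test.p_upper)
        rows.append((name, overlap, len(overlap), len(members), test.p_upper))
    if not rows:
        raise ValueError("no gene set intersects the universe")

    p_adj = multipletests(pvals, method="fdr_bh")[1]
    out = [
        EnrichmentRow(
            set_name=name,
            overlap_genes=overlap,
            k=k,
            set_size=size,
            p=p,
            p_adj=float(adj),
            score=float(-np.log2(max(adj, _P_FLOOR))),
            tier=classify_tier(float(adj)),
        )
        for (name, overlap, k, size, p), adj in zip(rows, p_adj)
    ]
    out.sort(key=lambda row: (row.p_adj, row.set_name))
    return out


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in rows],
            "k": [r.k for r in rows],
            "set_size": [r.set_size for r in rows],
            "p": [r.p for r in rows],
            "p_adj": [r.p_adj for r in rows],
            "score": [r.score for r in rows],
            "tier": [r.tier for r in rows],
            "genes": [",".join(r.overlap_genes) for r in rows],
        }
    )


def write_enrichment(
    rows: list[EnrichmentRow], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    enrichment_frame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "set": r.set_name,
                "k": r.k,
                "set_size": r.set_size,
                "p": r.p,
                "p_adj": r.p_adj,
                "score": r.score,
                "tier": r.tier,
                "genes": r.overlap_genes,
            }
            for r in rows
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def overlap_of_enrichments(
    rows_a: list[EnrichmentRow],
    rows_b: list[EnrichmentRow],
    universe_size: int,
    alpha: float = 0.05,
) -> OverlapTest:
    """Is the replication of enriched sets between two analyses surprising?

    Sets with ``p_adj <= alpha`` on each side are intersected and the
    overlap tested hypergeometrically against a universe of
    ``universe_size`` testable sets.
    """
    enriched_a = {r.set_name for r in rows_a if r.p_adj <= alpha}
    enriched_b = {r.set_name for r in rows_b if r.p_adj <= alpha}
    union = enriched_a | enriched_b
    if universe_size < len(union):
        raise ValueError(
            f"universe of {universe_size} sets smaller than the union "
            f"of enriched sets ({len(union)})"
        )
    return hypergeom_overlap(
        k=len(enriched_a & enriched_b),
        K=len(enriched_a),
        n=len(enriched_b),
        N=universe_size,
    )
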