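"""Pathway-level differential expression on a co-expression network.

Gene-level case/control differences in small post-mortem cohorts rarely
survive multiple-testing correction; a pathway can still shift coherently.
Three steps capture this:

1. per-gene deviation score ``d = (Mp - Mc) / Sc`` — the case mean
   expressed in control standard deviations;
2. a network of the pathway's genes with co-expression edges above a score
   threshold (isolated genes dropped), for display and connectivity;
3. an exact binomial sign test of whether the ``d`` values lean one way
   more than a fair coin would allow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import EdgeTable, ExpressionMatrix, GeneList, SampleMetadata

log = logging.getLogger(__name__)

EDGE_MIN_SCORE = 0.1


@dataclass
class DeviationScore:
    """Case-vs-control deviation of one gene, in control-SD units."""

    gene: str
    Mc: float  # control mean
    Sc: float  # control SD (ddof=1)
    Mp: float  # case mean
    d: float  # (Mp - Mc) / Sc


@dataclass
class DeviationNetwork:
    """Pathway genes (scored by deviation) joined by co-expression edges."""

    graph: nx.Graph
    pathway_name: str

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edge_tsv(self, path: str | Path) -> None:
        rows = [
            (min(a, b), max(a, b), data["score"])
            for a, b, data in self.graph.edges(data=True)
        ]
        pd.DataFrame(sorted(rows), columns=["gene_a", "gene_b", "score"]).to_csv(
            path, sep="\t", index=False, float_format="%.4f"
        )


@dataclass
class TendencyTest:
    """Exact binomial test of the sign balance of deviation scores."""

    n_pos: int
    n_neg: int
    direction: str  # "up" or "down"
    p_binomial: float  # one-sided, majority direction
    p_two_sided: float

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "direction": self.direction,
            "p_binomial": self.p_binomial,
            "p_two_sided": self.p_two_sided,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def deviation_scores(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    genes: GeneList,
    region: str | None = None,
) -> list[DeviationScore]:
    """Per-gene ``(Mp - Mc) / Sc`` with Mc, Sc from controls only.

    Genes absent from the matrix are dropped with a warning; genes whose
    control SD is zero are excluded (the score is undefined), also with a
    warning rather than an exception.
    """
    cases = metadata.samples(diagnosis="case", region=region)
    ctrls = metadata.samples(diagnosis="control", region=region)
    if len(cases) < 3 or len(ctrls) < 3:
        raise ValueError(
            f"need >= 3 case and >= 3 control samples "
            f"(case={len(cases)}, control={len(ctrls)})"
        )
    present = [g for g in genes.genes if g in matrix.data.index]
    missing = len(genes.genes) - len(present)
    if missing:
        log.warning("%d pathway genes absent from the matrix", missing)
    if not present:
        raise ValueError("no pathway genes present in the matrix")
    xc = matrix.data.loc[present, cases]
    xk = matrix.data.loc[present, ctrls]
    mc = xk.mean(axis=1)
    sc = xk.std(axis=1, ddof=1)
    mp = xc.mean(axis=1)
    scores = []
    for g in present:
        if sc[g] == 0:
            log.warning("gene %s has zero control SD; excluded", g)
            continue
        scores.append(
            DeviationScore(
                gene=g,
                Mc=float(mc[g]),
                Sc=float(sc[g]),
                Mp=float(mp[g]),
                d=float((mp[g] - mc[g]) / sc[g]),
            )
        )
    return scores


def build_network(
    scores: list[DeviationScore],
    edges: EdgeTable,
    min_score: float = EDGE_MIN_SCORE,
    pathway_name: str = "pathway",
) -> DeviationNetwork:
    """Restrict the edge table to scored genes and prune isolated nodes.

    Edges require both endpoints among the scored genes and a score
    strictly above ``min_score``. Nodes keep their deviation as the
    ``deviation`` attribute; genes without any retained edge are dropped.
    """
    if not scores:
        raise ValueError("no deviation scores supplied")
    d = {s.gene: s.d for s in scores}
    graph = nx.Graph()
    for row in edges.edges.itertuples(index=False):
        if row.score <= min_score:
            continue
        if row.gene_a in d and row.gene_b in d:
            a, b = sorted((row.gene_a, row.gene_b))
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], float(row.score))
            else:
                graph.add_edge(a, b, score=float(row.score))
    for node in graph.nodes:
        graph.nodes[node]["deviation"] = d[node]
    if graph.number_of_nodes() == 0:
        log.warning("no co-expression edges above %.2f among scored genes",
                    min_score)
    return DeviationNetwork(graph=graph, pathway_name=pathway_name)


def tendency_test(scores: list[DeviationScore]) -> TendencyTest:
    """Exact one-sided binomial test of the majority deviation direction.

    Genes with d exactly 0 are excluded; with counts ``n_pos`` and
    ``n_neg`` the p-value is ``P(X >= max(n_pos, n_neg))`` for
    ``X ~ Binomial(n_pos + n_neg, 1/2)``, computed exactly. Ties in the
    majority go to "up". The exact two-sided p is reported alongside.
    """
    d = np.array([s.d for s in scores])
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        raise ValueError("all deviation scores are zero; no direction to test")
    if len(nonzero) < 5:
        raise ValueError(
            f"need at least 5 genes with non-zero deviation, got {len(nonzero)}"
        )
    n_pos = int(np.sum(nonzero > 0))
    n_neg = int(np.sum(nonzero < 0))
    n = n_pos + n_neg
    m = max(n_pos, n_neg)
    p_one = float(stats.binom.sf(m - 1, n, 0.5))
    p_two = float(stats.binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue)
    return TendencyTest(
        n_pos=n_pos,
        n_neg=n_neg,
        direction="up" if n_pos >= n_neg else "down",
        p_binomial=min(p_one, 1.0),
        p_two_sided=min(p_two, 1.0),
    )
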