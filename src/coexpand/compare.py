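"""Cross-dataset comparability of differential expression.

Two datasets (or brain regions) are called comparable when their per-gene
case-vs-control t-statistics correlate positively over the shared genes:
Pearson rho > 0.1 with p < 0.001. This is the classic concordance measure
for deciding whether differential-expression signal replicates across
cohorts before any joint analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .corr import _r_pvalues
from .io import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)

COMPARABLE_MIN_RHO = 0.1
COMPARABLE_MAX_P = 0.001


@dataclass
class TStatVector:
    """Per-gene two-sample t-statistics (case minus control) for one region."""

    label: str
    gene_ids: list[str]
    t: np.ndarray
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.t):
            raise ValueError("t must align with gene_ids")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("t-statistics must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.t, index=self.gene_ids, name=self.label)


@dataclass
class ComparabilityEntry:
    region_a: str
    region_b: str
    rho: float
    p: float
    n_shared: int
    comparable: bool


def gene_t_stats(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    region: str | None = None,
    label: str | None = None,
    welch: bool = False,
) -> TStatVector:
    """Per-gene case-vs-control t-statistics within one region.

    Pooled-variance (Student) t by default, Welch optionally. Genes with
    zero variance in both groups get t = 0 and are flagged.
    """
    cases = metadata.samples(diagnosis="case", region=region)
    ctrls = metadata.samples(diagnosis="control", region=region)
    if len(cases) < 3 or len(ctrls) < 3:
        raise ValueError(
            f"need >= 3 samples per group in region {region!r} "
            f"(case={len(cases)}, control={len(ctrls)})"
        )
    xc = matrix.data.loc[:, cases].to_numpy()
    xk = matrix.data.loc[:, ctrls].to_numpy()
    n1, n2 = xc.shape[1], xk.shape[1]
    m1, m2 = xc.mean(axis=1), xk.mean(axis=1)
    v1, v2 = xc.var(axis=1, ddof=1), xk.var(axis=1, ddof=1)
    if welch:
        denom = np.sqrt(v1 / n1 + v2 / n2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = denom == 0
    denom[zero] = 1.0
    t = (m1 - m2) / denom
    t[zero] = 0.0
    flagged = [g for g, z in zip(matrix.gene_ids, zero) if z]
    if flagged:
        log.warning("%d genes with zero pooled variance got t = 0", len(flagged))
    return TStatVector(
        label=label or (region or "all"),
        gene_ids=matrix.gene_ids,
        t=t,
        zero_variance=flagged,
    )


def comparability_matrix(vectors: list[TStatVector]) -> list[ComparabilityEntry]:
    """All unordered pairwise comparability entries among the t-vectors.

    rho is the Pearson correlation of the two t-vectors over their shared
    genes, with a two-sided p from the t transform at ``n_shared - 2``
    degrees of freedom; ``comparable`` applies the rho > 0.1 and p < 0.001
    rule.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 t-vectors to compare")
    entries = []
    for va, vb in combinations(vectors, 2):
        sa, sb = va.to_series(), vb.to_series()
        shared = sa.index.intersection(sb.index)
        if len(shared) == 0:
            raise ValueError(
                f"no shared genes between {va.label!r} and {vb.label!r}"
            )
        if len(shared) < 100:
            log.warning(
                "only %d shared genes between %r and %r",
                len(shared), va.label, vb.label,
            )
        a = sa[shared].to_numpy()
        b = sb[shared].to_numpy()
        if a.std() == 0 or b.std() == 0:
            rho, p = 0.0, 1.0
        else:
            rho = float(np.corrcoef(a, b)[0, 1])
            p = float(_r_pvalues(np.array([[rho]]), len(shared))[0, 0])
        entries.append(
            ComparabilityEntry(
                region_a=va.label,
                region_b=vb.label,
                rho=rho,
                p=p,
                n_shared=len(shared),
                comparable=bool(rho > COMPARABLE_MIN_RHO and p < COMPARABLE_MAX_P),
            )
        )
    return entries


def comparability_frame(entries: list[ComparabilityEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_a": [e.region_a for e in entries],
            "region_b": [e.region_b for e in entries],
            "rho": [e.rho for e in entries],
            "p": [e.p for e in entries],
            "n_shared": [e.n_shared for e in entries],
            "comparable": [e.comparable for e in entries],
        }
    )


def write_comparability(entries: list[ComparabilityEntry], path: str | Path) -> None:
    comparability_frame(entries).to_csv(path, sep="\t", index=False)
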