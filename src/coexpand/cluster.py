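"""Seriation, co-expression cluster detection, and fixed-size list expansion.

A correlation matrix over a GWAS-derived list is first seriated (genes with
similar expression patterns made contiguous), a window of highly correlated
genes is selected, the cluster's per-sample average profile is computed, and
the gene list is expanded to a fixed size ``M`` by ranking every gene in the
matrix by its Pearson correlation to that profile — enabling gene-set
enrichment on a list large enough to be statistically meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .corr import CorrelationMatrix, _group_samples, _standardize_rows
from .io import ExpressionMatrix, GeneList, SampleMetadata

log = logging.getLogger(__name__)


@dataclass
class GeneCluster:
    """A contiguous window of mutually correlated genes from the seriation."""

    genes: list[str]
    mean_pairwise_r: float
    ordering: list[str]  # full seriated order of the input list

    def __post_init__(self) -> None:
        if len(self.genes) < 3:
            raise ValueError("a cluster needs at least 3 genes")


@dataclass
class ExpandedGeneList:
    """The seed cluster extended to ``M`` genes by profile correlation."""

    seed: GeneCluster
    profile: pd.Series  # per-sample average of z-scored seed genes
    members: list[str]  # size M, sorted by descending r to profile
    r_to_profile: pd.Series  # aligned to members
    min_r_attained: float

    def __post_init__(self) -> None:
        if not set(self.seed.genes) <= set(self.members):
            raise ValueError("seed genes must be contained in members")

    @property
    def M(self) -> int:
        return len(self.members)

    def write(self, genes_path: str | Path, table_path: str | Path | None = None) -> None:
        from .io import write_gene_list

        write_gene_list(self.members, genes_path)
        if table_path is not None:
            pd.DataFrame(
                {"gene": self.members, "r_to_profile": self.r_to_profile.to_numpy()}
            ).to_csv(table_path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# seriation
# ---------------------------------------------------------------------------


def seriate(corr: CorrelationMatrix) -> list[str]:
    """Order genes so that correlated genes become contiguous.

    Average-linkage hierarchical clustering on the distance ``1 - r``; the
    returned order is the dendrogram leaf order. Genes are fed to the
    linkage in lexicographic order, which makes the result deterministic
    and independent of the input ordering.
    """
    order = sorted(range(corr.n_genes), key=lambda i: corr.genes[i])
    names = [corr.genes[i] for i in order]
    r = corr.r[np.ix_(order, order)]
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(link)
    return [names[i] for i in leaves]


# ---------------------------------------------------------------------------
# cluster selection
# ---------------------------------------------------------------------------


def identify_cluster(
    corr: CorrelationMatrix,
    min_size: int = 3,
    min_mean_r: float = 0.5,
    override: list[str] | None = None,
    refine_ratio: float | None = 0.8,
) -> GeneCluster | None:
    """Select the window of the seriated order with the most excess correlation.

    Candidate windows are contiguous runs of the seriation with size >=
    ``min_size`` and mean pairwise r >= ``min_mean_r``. Among candidates the
    window maximising the summed excess correlation over its pairs,
    ``sum_pairs (r - min_mean_r)``, is chosen; this favours a full
    correlated block over chance-inflated sub-windows, which a bare
    mean-pairwise-r objective does not. Ties go to the larger window, then
    to the earlier seriation position.

    The winning window's boundaries are then refined: a boundary gene whose
    mean correlation to the rest of the window falls below ``refine_ratio``
    times the window's internal mean pairwise r is trimmed, and an adjacent
    gene reaching that bar is absorbed, until stable. At small sample sizes
    an unrelated gene can correlate with a genuine block at, say, r = 0.55
    purely by chance — above ``min_mean_r`` yet clearly below the block's
    own coherence — and the relative bar is what rejects it. Pass
    ``refine_ratio=None`` to keep the raw window.

    Returns ``None`` when no window qualifies. ``override`` bypasses
    detection with a caller-chosen gene list (e.g. a cluster read off a
    published figure); the genes must be present in the matrix.
    """
    if min_size < 3:
        raise ValueError("min_size must be at least 3")
    ordering = seriate(corr)

    if override is not None:
        missing = [g for g in override if g not in corr.genes]
        if missing:
            raise KeyError(f"override genes absent from correlation matrix: {missing}")
        return GeneCluster(
            genes=list(override),
            mean_pairwise_r=_mean_pairwise_r(corr, override),
            ordering=ordering,
        )

    pos = {g: i for i, g in enumerate(corr.genes)}
    order_idx = [pos[g] for g in ordering]
    r = corr.r[np.ix_(order_idx, order_idx)]
    k = len(ordering)

    best: tuple[float, int, int] | None = None  # (score, size, -start)
    best_window: tuple[int, int] | None = None
    for size in range(min_size, k + 1):
        n_pairs = size * (size - 1) // 2
        for start in range(0, k - size + 1):
            sub = r[start : start + size, start : start + size]
            pair_sum = (sub.sum() - size) / 2.0
            mean_r = pair_sum / n_pairs
            if mean_r < min_mean_r:
                continue
            score = pair_sum - min_mean_r * n_pairs
            key = (score, size, -start)
            if best is None or key > best:
                best = key
                best_window = (start, size)
    if best_window is None:
        log.info("no window of size >= %d reaches mean r >= %.2f", min_size, min_mean_r)
        return None
    start, size = best_window
    i, j = start, start + size
    if refine_ratio is not None:
        i, j = _refine_window(r, i, j, min_size, refine_ratio)
    genes = ordering[i:j]
    return GeneCluster(
        genes=genes,
        mean_pairwise_r=_mean_pairwise_r(corr, genes),
        ordering=ordering,
    )


def _window_mean_r(r: np.ndarray, i: int, j: int) -> float:
    size = j - i
    sub = r[i:j, i:j]
    return float((sub.sum() - size) / (size * (size - 1)))


def _refine_window(
    r: np.ndarray, i: int, j: int, min_size: int, ratio: float
) -> tuple[int, int]:
    """Trim/extend window boundaries against the window's own coherence."""
    k = r.shape[0]
    for _ in range(k):
        changed = False
        while j - i > min_size:
            m = _window_mean_r(r, i, j)
            size = j - i
            left = (r[i, i:j].sum() - 1.0) / (size - 1)
            right = (r[j - 1, i:j].sum() - 1.0) / (size - 1)
            if left < ratio * m and left <= right:
                i += 1
                changed = True
            elif right < ratio * m:
                j -= 1
                changed = True
            else:
                break
        while True:
            m = _window_mean_r(r, i, j)
            candidates = []
            if i > 0:
                candidates.append((float(r[i - 1, i:j].mean()), "L"))
            if j < k:
                candidates.append((float(r[j, i:j].mean()), "R"))
            candidates = [c for c in candidates if c[0] >= ratio * m]
            if not candidates:
                break
            if max(candidates)[1] == "L":
                i -= 1
            else:
                j += 1
            changed = True
        if not changed:
            break
    return i, j


def _mean_pairwise_r(corr: CorrelationMatrix, genes: list[str]) -> float:
    idx = [corr.genes.index(g) for g in genes]
    sub = corr.r[np.ix_(idx, idx)]
    k = len(idx)
    if k < 2:
        raise ValueError("need at least 2 genes for a mean pairwise r")
    return float((sub.sum() - k) / (k * (k - 1)))


# ---------------------------------------------------------------------------
# average profile and expansion
# ---------------------------------------------------------------------------


def average_profile(
    matrix: ExpressionMatrix,
    cluster: GeneCluster,
    metadata: SampleMetadata,
    diagnosis: str = "case",
    region: str | None = None,
) -> pd.Series:
    """Per-sample average of the z-scored cluster genes over one group.

    Z-scoring (per gene, across the group's samples, ddof=1) stops
    high-variance genes from dominating the average. Zero-variance genes
    are dropped with a warning.
    """
    samples = _group_samples(metadata, diagnosis, region)
    missing = [g for g in cluster.genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"cluster genes absent from matrix: {missing}")
    x = matrix.data.loc[cluster.genes, samples]
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping zero-variance cluster genes: %s",
                    list(sd.index[~keep]))
    if not keep.any():
        raise ValueError("all cluster genes have zero variance in the group")
    z = x.loc[keep].sub(x.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z.mean(axis=0)


def expand(
    matrix: ExpressionMatrix,
    profile: pd.Series,
    seed_cluster: GeneCluster,
    M: int,
) -> ExpandedGeneList:
    """Top-``M`` genes by Pearson correlation to the cluster's average profile.

    All genes of the matrix are ranked by descending correlation to
    ``profile`` over the profile's samples (ties broken by gene name). Seed
    genes are always retained — the expanded list counts them toward ``M``.
    ``min_r_attained`` is the correlation of the last (M-th) member.
    """
    if M > matrix.n_genes:
        raise ValueError(f"M={M} exceeds the {matrix.n_genes} genes available")
    if M < len(seed_cluster.genes):
        raise ValueError("M must be at least the seed cluster size")
    samples = list(profile.index)
    z, _ = _standardize_rows(matrix.data.loc[:, samples].to_numpy())
    pz = profile.to_numpy(dtype=float)
    pz = pz - pz.mean()
    norm = np.linalg.norm(pz)
    if norm == 0:
        raise ValueError("profile has zero variance")
    pz /= norm
    r = pd.Series(np.clip(z @ pz, -1.0, 1.0), index=matrix.gene_ids)

    ranked = sorted(r.index, key=lambda g: (-r[g], g))
    seed_set = set(seed_cluster.genes)
    members = list(seed_cluster.genes)
    for g in ranked:
        if len(members) >= M:
            break
        if g not in seed_set:
            members.append(g)
    members = sorted(members, key=lambda g: (-r[g], g))
    r_members = r[members]
    return ExpandedGeneList(
        seed=seed_cluster,
        profile=profile,
        members=members,
        r_to_profile=r_members,
        min_r_attained=float(r_members.iloc[-1]),
    )
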