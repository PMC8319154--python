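"""Synthetic case/control expression data with planted co-expression structure.

The generator emulates the statistical skeleton of a post-mortem brain
microarray study: a small cohort (16 cases vs 18 controls by default), a
block of mutually correlated "GWAS" genes driven by one latent factor, a
larger pool of genes loading on the same factor, and a pathway whose genes
carry a small case-vs-control mean shift that is individually invisible but
collectively directional.

Model, per sample ``s`` with latent factor ``f_s ~ N(0, 1)``:

* cluster / pool gene ``g`` with loading ``lambda_g``::

      x_gs = mu_g + lambda_g * f_s + sqrt(1 - lambda_g**2) * sigma * eps_gs

  With ``sigma = 1`` every such gene has unit variance and the expected
  Pearson correlation of two genes is the product of their loadings
  (``lambda**2`` for equal loadings).

* pathway gene ``g``::

      x_gs = mu_g + delta * sigma * 1[s is case] + sigma * eps_gs

  so the deviation score (case mean - control mean) / control SD recovers
  ``delta``. With ``pathway_loading > 0`` the pathway genes additionally
  load on the latent factor like pool genes — an enriched pathway that is
  also dysregulated, which is what an end-to-end run needs if the
  expansion stage is to find the pathway before the deviation stage
  tests it.

* background gene: independent ``N(mu_g, sigma**2)``.

Baselines ``mu_g ~ N(8, 1)`` mimic log2 microarray intensities. Gene roles
are assigned by a random permutation so planted structure is not tied to
row order. Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    EdgeTable,
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    build_edge_table,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_edges",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generative model; defaults mirror the study-sized cohort."""

    n_genes: int = 10_000
    n_case: int = 16
    n_ctrl: int = 18
    cluster_genes: int = 7
    cluster_loading: float = 0.8
    pool_genes: int = 100
    pool_loading_range: tuple[float, float] = (0.6, 0.9)
    pathway_genes: int = 20
    effect: float = 0.5  # delta: case shift in units of per-gene control SD
    pathway_loading: float = 0.0  # >0: pathway genes also ride the factor
    noise_sd: float = 1.0  # sigma
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    region: str = "region1"
    dataset: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_case, self.n_ctrl) <= 0:
            raise ValueError("n_genes, n_case and n_ctrl must be positive")
        if min(self.cluster_genes, self.pool_genes, self.pathway_genes) < 0:
            raise ValueError("planted gene counts must be non-negative")
        planted = self.cluster_genes + self.pool_genes + self.pathway_genes
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        lo, hi = self.pool_loading_range
        for lam in (self.cluster_loading, self.pathway_loading, lo, hi):
            if not 0.0 <= lam <= 1.0:
                raise ValueError("loadings must lie in [0, 1]")
        if lo > hi:
            raise ValueError("pool_loading_range must be (low, high)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    cluster: list[str]
    pool: list[str]
    pathway: list[str]
    background: list[str]
    loadings: pd.Series  # per cluster/pool gene
    shift: pd.Series  # per-gene true case shift (delta * sigma units)
    latent: pd.Series  # per-sample factor f_s

    def to_frame(self) -> pd.DataFrame:
        roles = (
            [(g, "cluster") for g in self.cluster]
            + [(g, "pool") for g in self.pool]
            + [(g, "pathway") for g in self.pathway]
        )
        frame = pd.DataFrame(roles, columns=["gene", "role"])
        frame["loading"] = [self.loadings.get(g, 0.0) for g in frame["gene"]]
        frame["shift"] = [self.shift.get(g, 0.0) for g in frame["gene"]]
        return frame


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Draw one dataset from the latent-factor model described above."""
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_case + cfg.n_ctrl
    genes = _gene_ids(cfg.n_genes)
    samples = [f"case_{i:03d}" for i in range(1, cfg.n_case + 1)] + [
        f"ctrl_{i:03d}" for i in range(1, cfg.n_ctrl + 1)
    ]
    is_case = np.array([s.startswith("case") for s in samples])

    perm = rng.permutation(cfg.n_genes)
    k, p, w = cfg.cluster_genes, cfg.pool_genes, cfg.pathway_genes
    cluster_idx = perm[:k]
    pool_idx = perm[k : k + p]
    pathway_idx = perm[k + p : k + p + w]
    background_idx = perm[k + p + w :]

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    f = rng.standard_normal(n_samples)
    eps = rng.standard_normal((cfg.n_genes, n_samples)) * cfg.noise_sd
    lo, hi = cfg.pool_loading_range
    pool_loadings = rng.uniform(lo, hi, p)

    x = mu[:, None] + eps  # background by default
    lam = np.zeros(cfg.n_genes)
    lam[cluster_idx] = cfg.cluster_loading
    lam[pool_idx] = pool_loadings
    factor_parts = [cluster_idx, pool_idx]
    if cfg.pathway_loading > 0 and w:
        # pathway genes co-expressed with the module AND shifted in cases,
        # mimicking an enriched pathway that is also dysregulated
        lam[pathway_idx] = cfg.pathway_loading
        factor_parts.append(pathway_idx)
    factor_idx = np.concatenate(factor_parts).astype(int)
    if factor_idx.size:
        lf = lam[factor_idx]
        x[factor_idx] = (
            mu[factor_idx, None]
            + lf[:, None] * f[None, :]
            + np.sqrt(1.0 - lf**2)[:, None] * eps[factor_idx]
        )
    shift = np.zeros(cfg.n_genes)
    if w:
        shift[pathway_idx] = cfg.effect * cfg.noise_sd
        x[pathway_idx] = x[pathway_idx] + shift[pathway_idx, None] * is_case[None, :]

    data = pd.DataFrame(x, index=genes, columns=samples)
    matrix = ExpressionMatrix(data)
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "diagnosis": np.where(is_case, "case", "control"),
                "region": cfg.region,
                "dataset": cfg.dataset,
            }
        )
    )
    gene_arr = np.array(genes)
    truth = SyntheticTruth(
        cluster=[str(g) for g in gene_arr[cluster_idx]],
        pool=[str(g) for g in gene_arr[pool_idx]],
        pathway=[str(g) for g in gene_arr[pathway_idx]],
        background=[str(g) for g in gene_arr[background_idx]],
        loadings=pd.Series(lam[factor_idx], index=gene_arr[factor_idx])
        if factor_idx.size
        else pd.Series(dtype=float),
        shift=pd.Series(shift, index=genes),
        latent=pd.Series(f, index=samples),
    )
    return matrix, metadata, truth


def simulate_gene_sets(
    truth: SyntheticTruth,
    n_decoy_sets: int = 50,
    sizes: int | Sequence[int] = 20,
    seed: int = 0,
    pathway_set_name: str = "planted_pathway",
) -> GeneSetCollection:
    """The planted pathway plus decoy sets drawn from background genes."""
    rng = np.random.default_rng(seed)
    if isinstance(sizes, int):
        sizes = [sizes] * n_decoy_sets
    if len(sizes) != n_decoy_sets:
        raise ValueError("sizes must be an int or one size per decoy set")
    if not truth.pathway:
        raise ValueError("truth has no planted pathway genes")
    sets: dict[str, list[str]] = {pathway_set_name: list(truth.pathway)}
    pool = np.array(truth.background)
    for i, size in enumerate(sizes, start=1):
        if size > len(pool):
            raise ValueError(
                f"decoy size {size} exceeds available background genes ({len(pool)})"
            )
        sets[f"decoy_{i:03d}"] = [
            str(g) for g in rng.choice(pool, size=size, replace=False)
        ]
    return GeneSetCollection(sets, source="synthetic")


def simulate_edges(
    truth: SyntheticTruth,
    p_within: float = 0.8,
    p_background: float = 0.05,
    n_background: int = 100,
    seed: int = 0,
) -> EdgeTable:
    """Co-expression edges: dense within the pathway, sparse elsewhere.

    Pairs of pathway genes are connected with probability ``p_within``
    (scores uniform on [0.4, 1.0]); pairs involving the sampled background
    genes with probability ``p_background`` (scores uniform on [0.1, 0.4]).
    Only ``n_background`` randomly chosen background genes participate —
    enough to exercise pruning without materialising all gene pairs.
    """
    for prob in (p_within, p_background):
        if not 0.0 <= prob <= 1.0:
            raise ValueError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pathway = list(truth.pathway)
    n_background = min(n_background, len(truth.background))
    extra = [
        str(g) for g in rng.choice(truth.background, size=n_background, replace=False)
    ]
    nodes = pathway + extra
    in_pathway = set(pathway)
    records: list[tuple[str, str, float]] = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            within = a in in_pathway and b in in_pathway
            prob = p_within if within else p_background
            if rng.random() < prob:
                score = rng.uniform(0.4, 1.0) if within else rng.uniform(0.1, 0.4)
                records.append((a, b, score))
    if not records:
        return EdgeTable(pd.DataFrame(columns=["gene_a", "gene_b", "score"]))
    return build_edge_table(records)


def write_dataset(
    out_dir: str | Path,
    cfg: SyntheticConfig,
    n_decoy_sets: int = 50,
    decoy_size: int = 20,
    p_within: float = 0.8,
    p_background: float = 0.05,
) -> dict[str, Path]:
    """Simulate and write a full dataset (expression, metadata, GMT, edges, truth)."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, metadata, truth = simulate_expression(cfg)
    sets = simulate_gene_sets(
        truth, n_decoy_sets=n_decoy_sets, sizes=decoy_size, seed=cfg.seed + 1
    )
    edges = simulate_edges(
        truth, p_within=p_within, p_background=p_background, seed=cfg.seed + 2
    )
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "edges": out / "edges.tsv",
        "truth": out / "truth.tsv",
        "gene_list": out / "gwas_genes.txt",
    }
    _io.write_expression(matrix, paths["expression"])
    _io.write_metadata(metadata, paths["metadata"])
    _io.write_gmt(sets, paths["gene_sets"])
    _io.write_edges(edges, paths["edges"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    # the "GWAS hit list": planted cluster plus random background genes,
    # mimicking a GWAS-derived list that is only partly co-expressed
    rng = np.random.default_rng(cfg.seed + 3)
    n_extra = max(0, 23 - len(truth.cluster))
    extras = list(rng.choice(truth.background, size=n_extra, replace=False))
    _io.write_gene_list(sorted(truth.cluster) + sorted(extras), paths["gene_list"])
    return paths
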