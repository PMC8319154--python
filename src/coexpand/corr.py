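"""Pairwise correlation of a gene list and its permutation-null significance.

The question asked here: does a GWAS-derived gene list show more
significantly correlated expression pairs, within one diagnosis group,
than a random gene group of the same size would? The null is built by
drawing ``B`` random same-size groups uniformly from the gene universe of
the matrix and counting, for each, the pairs passing the same threshold.
The empirical p-value is the fraction of null groups whose pair count
reaches the observed count.

Per-pair p-values come from the exact t transform of the Pearson
coefficient, ``t = r * sqrt((n-2) / (1-r^2))`` with ``n-2`` degrees of
freedom, two-sided — deterministic and equivalent in distribution to
permuting the sample order at these sample sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneList, SampleMetadata

log = logging.getLogger(__name__)

THRESHOLD_MODES = ("alpha", "abs_r")


@dataclass
class CorrelationMatrix:
    """Pearson correlations (and per-pair p-values) of genes over one group."""

    genes: list[str]
    r: np.ndarray
    p: np.ndarray
    n_samples: int
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.genes)
        if self.r.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("r and p must be square over the gene list")
        if not np.allclose(self.r, self.r.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(self.r).max() > 1 + 1e-9:
            raise ValueError("|r| must not exceed 1")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.genes, columns=self.genes)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f",
                               index_label="gene")


@dataclass
class PermutationNull:
    """Observed pair count against ``B`` random-group null counts."""

    observed_count: int
    null_counts: np.ndarray
    threshold_mode: str
    threshold_value: float
    n_genes: int
    n_samples: int
    seed: int | None = None

    @property
    def B(self) -> int:
        return int(len(self.null_counts))

    @property
    def empirical_p(self) -> float:
        """Fraction of null groups with a count >= observed."""
        return float(np.sum(self.null_counts >= self.observed_count)) / self.B

    @property
    def empirical_p_conservative(self) -> float:
        """(b+1)/(B+1) variant that never returns exactly zero."""
        b = int(np.sum(self.null_counts >= self.observed_count))
        return (b + 1) / (self.B + 1)

    def to_dict(self) -> dict:
        return {
            "observed_count": int(self.observed_count),
            "B": self.B,
            "threshold_mode": self.threshold_mode,
            "threshold_value": self.threshold_value,
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "empirical_p": self.empirical_p,
            "empirical_p_conservative": self.empirical_p_conservative,
            "seed": self.seed,
            "null_histogram": {
                str(int(v)): int(c)
                for v, c in zip(*np.unique(self.null_counts, return_counts=True))
            },
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _group_samples(
    metadata: SampleMetadata, diagnosis: str, region: str | None
) -> list[str]:
    samples = metadata.samples(diagnosis=diagnosis, region=region)
    if len(samples) < 4:
        raise ValueError(
            f"need at least 4 samples in group (diagnosis={diagnosis!r}, "
            f"region={region!r}); found {len(samples)}"
        )
    return samples


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm, so Z @ Z.T is the Pearson matrix.

    Returns (Z, zero_variance_mask); zero-variance rows become all-zero, so
    their correlations come out as 0.
    """
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = norms == 0
    norms[zero] = 1.0
    return centered / norms[:, None], zero


def _r_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson r via the exact t transform."""
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rr), 1.0)] = 0.0
    return np.clip(p, 0.0, 1.0)


def critical_r(alpha: float, n: int) -> float:
    """|r| above which the two-sided correlation p-value is < alpha."""
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def pairwise_correlation(
    matrix: ExpressionMatrix,
    genes: GeneList,
    metadata: SampleMetadata,
    diagnosis: str = "case",
    region: str | None = None,
) -> CorrelationMatrix:
    """Pearson correlation matrix of the listed genes over one sample group.

    Listed genes absent from the matrix are dropped with a warning; genes
    with zero variance in the group are flagged and their correlations set
    to 0 rather than raising.
    """
    samples = _group_samples(metadata, diagnosis, region)
    present = [g for g in genes.genes if g in matrix.data.index]
    missing = [g for g in genes.genes if g not in matrix.data.index]
    if missing:
        log.warning(
            "%d/%d listed genes absent from matrix (e.g. %s)",
            len(missing), len(genes.genes), missing[:5],
        )
    if len(present) < 2:
        raise ValueError("need at least 2 listed genes present in the matrix")
    x = matrix.data.loc[present, samples].to_numpy()
    n = len(samples)
    z, zero = _standardize_rows(x)
    r = np.clip(z @ z.T, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    p = _r_pvalues(r, n)
    np.fill_diagonal(p, 0.0)
    flagged = [g for g, zv in zip(present, zero) if zv]
    if flagged:
        log.warning("zero-variance genes in group, r set to 0: %s", flagged)
        p[zero, :] = 1.0
        p[:, zero] = 1.0
        np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(present, r, p, n, flagged)


def count_significant_pairs(
    corr: CorrelationMatrix, mode: str = "alpha", value: float = 0.05
) -> int:
    """Number of unordered off-diagonal pairs passing the threshold.

    ``mode='alpha'`` counts pairs whose two-sided correlation p-value is
    below ``value``; ``mode='abs_r'`` counts pairs with ``|r| > value``.
    """
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"mode must be one of {THRESHOLD_MODES}")
    if not 0.0 < value < 1.0:
        raise ValueError("threshold value must lie strictly inside (0, 1)")
    iu = np.triu_indices(corr.n_genes, k=1)
    if mode == "alpha":
        return int(np.sum(corr.p[iu] < value))
    return int(np.sum(np.abs(corr.r[iu]) > value))


def permutation_pattern_test(
    matrix: ExpressionMatrix,
    genes: GeneList,
    metadata: SampleMetadata,
    diagnosis: str = "case",
    region: str | None = None,
    mode: str = "alpha",
    value: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
    _chunk: int = 200,
) -> PermutationNull:
    """Empirical significance of the list's correlation pattern.

    Draws ``B`` random gene groups (uniformly, without replacement, size
    equal to the number of listed genes present) from all genes of the
    matrix and counts, per group, the pairs passing the same threshold over
    the same samples. The p-value is the fraction of null counts at or
    above the observed count.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    observed_corr = pairwise_correlation(matrix, genes, metadata, diagnosis, region)
    b0 = count_significant_pairs(observed_corr, mode, value)
    k = observed_corr.n_genes
    n = observed_corr.n_samples
    universe = matrix.n_genes
    if universe < 2 * k:
        raise ValueError(
            f"gene universe ({universe}) smaller than twice the group size ({k})"
        )

    samples = _group_samples(metadata, diagnosis, region)
    z, _ = _standardize_rows(matrix.data.loc[:, samples].to_numpy())
    # a single |r| cutoff reproduces both threshold modes
    r_crit = critical_r(value, n) if mode == "alpha" else value

    rng = np.random.default_rng(seed)
    idx = np.empty((B, k), dtype=np.intp)
    for b in range(B):
        idx[b] = rng.choice(universe, size=k, replace=False)
    iu = np.triu_indices(k, k=1)
    null_counts = np.empty(B, dtype=np.int64)
    for start in range(0, B, _chunk):
        block = idx[start : start + _chunk]
        zb = z[block]  # (chunk, k, n)
        rb = np.einsum("bks,bls->bkl", zb, zb)
        null_counts[start : start + len(block)] = np.sum(
            np.abs(rb[:, iu[0], iu[1]]) > r_crit, axis=1
        )
    return PermutationNull(
        observed_count=b0,
        null_counts=null_counts,
        threshold_mode=mode,
        threshold_value=value,
        n_genes=k,
        n_samples=n,
        seed=seed,
    )
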