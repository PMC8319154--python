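"""Readers, writers, and preprocessing for expression data and companion files.

The on-disk formats are deliberately plain: expression matrices and sample
metadata are tab-separated text (optionally gzipped), gene sets use the GMT
convention, and co-expression relations arrive as a three-column edge table
whose scores may be on the STRING per-mille integer scale (auto-normalised
to [0, 1]).

Expression values are assumed to be on a log2 intensity scale. When a file
is clearly on a linear scale (maximum value above 50) a ``log2(x + 1)``
transform is applied; this heuristic can be forced on or off.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DIAGNOSES = ("case", "control")

METADATA_COLUMNS = ("sample_id", "diagnosis", "region", "dataset")

#: linear-scale detection threshold for the automatic log2 transform
LOG2_AUTO_MAX = 50.0


class FormatError(ValueError):
    """A file violated the expected format; the message names the offender."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    ``data`` is a float DataFrame indexed by unique gene (or probe)
    identifiers with unique sample identifiers as columns. Missing values
    are not permitted.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicated gene identifier: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicated sample identifier: {dup!r}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise FormatError("expression matrix contains non-numeric columns")
        if self.data.isna().any().any():
            gene = self.data.index[self.data.isna().any(axis=1)][0]
            raise FormatError(f"missing value in expression row {gene!r}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)].copy())


@dataclass
class SampleMetadata:
    """Per-sample annotations: diagnosis (case/control), region, dataset."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicated sample_id in metadata: {dup!r}")
        bad = set(self.table["diagnosis"]) - set(DIAGNOSES)
        if bad:
            raise FormatError(
                f"diagnosis must be one of {DIAGNOSES}, found {sorted(bad)}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def samples(
        self,
        diagnosis: str | None = None,
        region: str | None = None,
        dataset: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given filters, in metadata order."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if diagnosis is not None:
            if diagnosis not in DIAGNOSES:
                raise ValueError(f"diagnosis must be one of {DIAGNOSES}")
            mask &= t["diagnosis"] == diagnosis
        if region is not None:
            mask &= t["region"] == region
        if dataset is not None:
            mask &= t["dataset"] == dataset
        return list(t.loc[mask, "sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleMetadata(keep.copy())


@dataclass
class GeneList:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = [g for g in self.genes if g in seen or seen.add(g)]
        if dupes:
            raise FormatError(f"duplicated genes in list {self.name!r}: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) as read from a GMT file."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EdgeTable:
    """Undirected weighted gene-gene edges with scores in [0, 1]."""

    edges: pd.DataFrame  # columns: gene_a, gene_b, score

    def __post_init__(self) -> None:
        required = ["gene_a", "gene_b", "score"]
        if list(self.edges.columns) != required:
            self.edges = self.edges.rename(
                columns=dict(zip(self.edges.columns, required))
            )
        e = self.edges
        if ((e["score"] < 0) | (e["score"] > 1)).any():
            bad = e.loc[(e["score"] < 0) | (e["score"] > 1)].iloc[0]
            raise FormatError(
                f"edge score outside [0,1]: {bad['gene_a']}-{bad['gene_b']} "
                f"= {bad['score']}"
            )
        if (e["gene_a"] == e["gene_b"]).any():
            raise FormatError("self-edge present after deduplication")
        self.edges = e.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# expression + metadata
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    metadata_path: str | Path,
    log2: str | bool = "auto",
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read a genes x samples TSV and its sample-metadata TSV.

    The expression file has a header row of sample ids and gene/probe ids in
    the first column. Every matrix sample must appear in the metadata and
    vice versa. ``log2`` may be True, False, or "auto" (apply ``log2(x+1)``
    when the maximum value exceeds 50, i.e. the data look linear-scale).
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"duplicated sample column {s!r} in {path}")
        seen.add(s)

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise FormatError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise FormatError(f"missing value at gene {gene!r}, sample {col!r}")
        values[col] = converted

    if log2 == "auto":
        apply_log = float(values.to_numpy().max()) > LOG2_AUTO_MAX
        if apply_log:
            log.info("values look linear-scale (max > %g); applying log2(x+1)",
                     LOG2_AUTO_MAX)
    else:
        apply_log = bool(log2)
    if apply_log:
        if (values.to_numpy() < 0).any():
            raise FormatError("cannot log2-transform: negative values present")
        values = np.log2(values + 1.0)

    matrix = ExpressionMatrix(values)
    metadata = read_metadata(metadata_path)

    mat_samples = set(matrix.sample_ids)
    meta_samples = set(metadata.sample_ids)
    only_matrix = sorted(mat_samples - meta_samples)
    if only_matrix:
        raise FormatError(f"samples missing from metadata: {only_matrix}")
    only_meta = sorted(meta_samples - mat_samples)
    if only_meta:
        raise FormatError(f"metadata samples missing from matrix: {only_meta}")
    return matrix, metadata


def read_metadata(path: str | Path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(table)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format="%.6f", index_label="gene")


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return GeneList(name or Path(path).stem, genes)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# probe collapsing and sample QC
# ---------------------------------------------------------------------------


def collapse_probes(
    matrix: ExpressionMatrix, mapping: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene.

    For genes measured by several probes the probe with the highest mean
    expression is kept, a standard deterministic microarray rule. Probes
    absent from ``mapping`` are dropped.
    """
    if not mapping:
        raise ValueError("probe-to-gene mapping is empty")
    data = matrix.data
    mapped = [p for p in data.index if p in mapping]
    if not mapped:
        raise ValueError("mapping covers none of the matrix rows")
    dropped = matrix.n_genes - len(mapped)
    if dropped:
        log.info("collapse_probes: dropping %d unmapped probes", dropped)

    sub = data.loc[mapped]
    means = sub.mean(axis=1)
    frame = pd.DataFrame(
        {"probe": mapped, "gene": [mapping[p] for p in mapped], "mean": means.to_numpy()}
    )
    # highest-mean probe wins; probe id breaks exact ties deterministically
    frame = frame.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    winners = frame.drop_duplicates("gene", keep="first")
    out = sub.loc[winners["probe"]].copy()
    out.index = winners["gene"].to_numpy()
    log.info("collapse_probes: %d probes -> %d genes", len(mapped), len(out))
    return ExpressionMatrix(out)


def qc_filter_samples(
    matrix: ExpressionMatrix,
    sd_mult: float = 3.0,
    max_removed_frac: float = 0.2,
) -> tuple[ExpressionMatrix, list[str]]:
    """Iteratively remove outlier samples by mean inter-sample correlation.

    A sample is removed when its mean Pearson correlation to all other
    samples falls more than ``sd_mult`` standard deviations below the mean
    of that statistic across samples; removal repeats until stable.
    Refuses to remove more than ``max_removed_frac`` of the samples.
    """
    if matrix.n_samples < 4:
        raise ValueError("sample QC needs at least 4 samples")
    data = matrix.data
    removed: list[str] = []
    n_start = matrix.n_samples
    while True:
        cols = data.columns
        corr = np.corrcoef(data.to_numpy().T)
        np.fill_diagonal(corr, np.nan)
        mean_r = np.nanmean(corr, axis=1)
        mu, sd = mean_r.mean(), mean_r.std(ddof=1)
        if sd == 0:
            break
        cutoff = mu - sd_mult * sd
        out = [c for c, r in zip(cols, mean_r) if r < cutoff]
        if not out:
            break
        removed.extend(out)
        if len(removed) > max_removed_frac * n_start:
            raise ValueError(
                f"QC would remove {len(removed)}/{n_start} samples "
                f"(> {max_removed_frac:.0%}); data likely corrupt"
            )
        log.info("qc_filter_samples: removing %s", out)
        data = data.drop(columns=out)
        if data.shape[1] < 4:
            break
    return ExpressionMatrix(data.copy()), removed


# ---------------------------------------------------------------------------
# gene sets (GMT) and edge tables
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicated set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


def read_edges(path: str | Path) -> EdgeTable:
    """Read a 3-column edge table (gene, gene, score).

    Scores on the STRING per-mille integer scale (any score > 1) are divided
    by 1000. Self-edges are dropped; duplicate unordered pairs keep the
    maximum score. A header line is tolerated when its third field is not
    numeric.
    """
    records: list[tuple[str, str, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            a, b, raw_score = fields
            try:
                score = float(raw_score)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {raw_score!r}"
                ) from None
            records.append((a, b, score))
    if not records:
        raise FormatError(f"{path}: no edges found")
    return build_edge_table(records)


def build_edge_table(records: Iterable[tuple[str, str, float]]) -> EdgeTable:
    """Normalise raw (gene, gene, score) records into an :class:`EdgeTable`."""
    best: dict[tuple[str, str], float] = {}
    max_score = 0.0
    rows = []
    for a, b, score in records:
        if a == b:
            continue
        max_score = max(max_score, score)
        rows.append((a, b, score))
    divisor = 1000.0 if max_score > 1.0 else 1.0
    for a, b, score in rows:
        key = (a, b) if a <= b else (b, a)
        score = score / divisor
        if key not in best or score > best[key]:
            best[key] = score
    frame = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(best.items())],
        columns=["gene_a", "gene_b", "score"],
    )
    return EdgeTable(frame)


def write_edges(table: EdgeTable, path: str | Path) -> None:
    table.edges.to_csv(path, sep="\t", index=False, header=False,
                       float_format="%.4f")
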