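"""End-to-end orchestration: correlation pattern -> cluster -> expansion ->
enrichment -> comparability -> pathway-level differential expression.

A run is driven by a :class:`RunConfig` (loadable from YAML or flat
``key=value`` text), writes every stage's output under one run directory,
and finishes with a ``manifest.json`` recording inputs, settings, seeds,
library versions and per-stage summaries. Outputs are deterministic given
the seed: running the same config twice produces byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import cluster as _cluster
from . import compare as _compare
from . import corr as _corr
from . import enrich as _enrich
from . import io as _io
from . import netde as _netde

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one full pipeline run."""

    expression: str
    metadata: str
    gene_list: str
    gene_sets: str | None = None
    edges: str | None = None
    out_dir: str = "run"
    region: str | None = None  # None: use every region in the metadata
    diagnosis: str = "case"
    qc_sd_mult: float = 3.0
    run_qc: bool = True
    B: int = 1000
    threshold_mode: str = "alpha"
    threshold_value: float = 0.05
    cluster_min_size: int = 3
    cluster_min_mean_r: float = 0.5
    cluster_override: list[str] | None = None
    M: int = 800
    enrich_alpha: float = 0.05
    edge_min_score: float = 0.1
    seed: int = 0

    def validate_paths(self) -> None:
        for name in ("expression", "metadata", "gene_list", "gene_sets", "edges"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} file not found: {value}")


_BOOL = {"true": True, "false": False, "yes": True, "no": False}


def _coerce(value: str):
    low = value.strip().lower()
    if low in _BOOL:
        return _BOOL[low]
    if low in ("none", "null", ""):
        return None
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if "," in value:
        return [v.strip() for v in value.split(",") if v.strip()]
    return value.strip()


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or flat ``key=value`` lines."""
    import yaml

    text = Path(path).read_text()
    data = None
    try:
        loaded = yaml.safe_load(text)
        if isinstance(loaded, dict):
            data = loaded
    except yaml.YAMLError:
        pass
    if data is None:
        data = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            data[key.strip()] = _coerce(value)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the manifest dictionary.

    Stage order mirrors the analysis: correlation pattern of the GWAS list,
    cluster identification, expansion, enrichment of the expanded list,
    cross-region comparability (skipped with a single region), and
    pathway-level differential expression of the top enriched set. A
    "no cluster" outcome short-circuits expansion and enrichment
    gracefully; the manifest records the skip.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(config.seed).spawn(1)[0]
    perm_seed = int(rng_seeds.generate_state(1)[0] % (2**31))

    matrix, metadata = _io.read_expression(config.expression, config.metadata)
    gene_list = _io.read_gene_list(config.gene_list)
    regions = metadata.regions
    region = config.region if config.region is not None else regions[0]
    manifest: dict = {
        "package": "coexpand",
        "version": __version__,
        "seed": config.seed,
        # out_dir is excluded so reruns into different directories stay
        # byte-identical
        "settings": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "inputs": {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "regions": regions,
            "gene_list_size": len(gene_list),
        },
        "stages": {},
    }

    if config.run_qc:
        matrix, removed = _io.qc_filter_samples(matrix, sd_mult=config.qc_sd_mult)
        metadata = metadata.subset(matrix.sample_ids)
        manifest["stages"]["qc"] = {"removed_samples": sorted(removed)}

    # --- stage 1: correlation pattern ------------------------------------
    null = _corr.permutation_pattern_test(
        matrix,
        gene_list,
        metadata,
        diagnosis=config.diagnosis,
        region=region,
        mode=config.threshold_mode,
        value=config.threshold_value,
        B=config.B,
        seed=perm_seed,
    )
    null.write_json(out / "corr_pattern.json")
    observed = _corr.pairwise_correlation(
        matrix, gene_list, metadata, diagnosis=config.diagnosis, region=region
    )
    observed.write_tsv(out / "correlation_matrix.tsv")
    manifest["stages"]["corr_pattern"] = {
        "region": region,
        "observed_count": null.observed_count,
        "empirical_p": null.empirical_p,
        "empirical_p_conservative": null.empirical_p_conservative,
    }

    # --- stage 2: cluster --------------------------------------------------
    found = _cluster.identify_cluster(
        observed,
        min_size=config.cluster_min_size,
        min_mean_r=config.cluster_min_mean_r,
        override=config.cluster_override,
    )
    if found is None:
        manifest["stages"]["cluster"] = {"found": False}
        manifest["stages"]["expand"] = {"skipped": "no cluster"}
        manifest["stages"]["enrichment"] = {"skipped": "no cluster"}
        log.info("no co-expression cluster found; expansion and enrichment skipped")
        expanded = None
    else:
        _write_json(
            {
                "genes": found.genes,
                "mean_pairwise_r": found.mean_pairwise_r,
                "ordering": found.ordering,
            },
            out / "cluster.json",
        )
        manifest["stages"]["cluster"] = {
            "found": True,
            "size": len(found.genes),
            "mean_pairwise_r": found.mean_pairwise_r,
        }

        # --- stage 3: expansion ------------------------------------------
        profile = _cluster.average_profile(
            matrix, found, metadata, diagnosis=config.diagnosis, region=region
        )
        profile.to_csv(out / "profile.tsv", sep="\t", header=["profile"],
                       index_label="sample")
        M = min(config.M, matrix.n_genes)
        expanded = _cluster.expand(matrix, profile, found, M)
        expanded.write(out / "expanded_genes.txt", out / "expanded.tsv")
        manifest["stages"]["expand"] = {
            "M": M,
            "n_added": M - len(found.genes),
            "min_r_attained": expanded.min_r_attained,
        }

    # --- stage 4: enrichment ----------------------------------------------
    if expanded is not None and config.gene_sets is not None:
        sets = _io.read_gmt(config.gene_sets)
        universe = _io.GeneList("universe", matrix.gene_ids)
        query = _io.GeneList("expanded", expanded.members)
        rows = _enrich.ora(query, sets, universe)
        _enrich.write_enrichment(rows, out / "enrichment.tsv",
                                 out / "enrichment.json")
        n_enriched = sum(r.p_adj <= config.enrich_alpha for r in rows)
        manifest["stages"]["enrichment"] = {
            "n_sets_tested": len(rows),
            "n_enriched": n_enriched,
            "top_set": rows[0].set_name,
            "top_p_adj": rows[0].p_adj,
        }
        top_rows = rows
    elif expanded is not None:
        manifest["stages"]["enrichment"] = {"skipped": "no gene_sets file"}
        top_rows = None
    else:
        top_rows = None

    # --- stage 5: comparability -------------------------------------------
    if len(regions) >= 2:
        vectors = [
            _compare.gene_t_stats(matrix, metadata, region=r) for r in regions
        ]
        entries = _compare.comparability_matrix(vectors)
        _compare.write_comparability(entries, out / "comparability.tsv")
        manifest["stages"]["comparability"] = {
            "n_pairs": len(entries),
            "n_comparable": sum(e.comparable for e in entries),
        }
    else:
        manifest["stages"]["comparability"] = {"skipped": "single region"}
        log.info("single region in metadata; comparability stage skipped")

    # --- stage 6: pathway-level differential expression --------------------
    if top_rows is not None and config.edges is not None:
        top = top_rows[0]
        sets = _io.read_gmt(config.gene_sets)
        pathway_genes = _io.GeneList(top.set_name, sorted(set(sets.sets[top.set_name])))
        scores = _netde.deviation_scores(matrix, metadata, pathway_genes,
                                         region=region)
        edges = _io.read_edges(config.edges)
        network = _netde.build_network(
            scores, edges, min_score=config.edge_min_score,
            pathway_name=top.set_name,
        )
        network.write_graphml(out / "deviation_network.graphml")
        network.write_edge_tsv(out / "network_edges.tsv")
        tendency = _netde.tendency_test(scores)
        tendency.write_json(out / "tendency.json")
        manifest["stages"]["pathway_de"] = {
            "pathway": top.set_name,
            "n_scored": len(scores),
            "n_network_nodes": network.n_nodes,
            "n_network_edges": network.n_edges,
            "mean_deviation": float(np.mean([s.d for s in scores])),
            "direction": tendency.direction,
            "p_binomial": tendency.p_binomial,
        }
    else:
        manifest["stages"]["pathway_de"] = {
            "skipped": "no enrichment result or no edges file"
        }

    _write_json(manifest, out / "manifest.json")
    return manifest
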