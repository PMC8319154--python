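# coexpand

GWAS-guided co-expression analysis for case/control transcriptomics.

GWAS of polygenic disorders yield lists of candidate genes that are too
short, and too contaminated with false positives, for pathway enrichment
analysis to say anything reliable. `coexpand` implements the
expression-based rescue of such lists:

1. **Correlation pattern test** — are the listed genes more co-expressed,
   within one diagnosis group, than a random same-size gene group? For a
   list of k genes the statistic is the number of gene pairs whose Pearson
   correlation is significant at level α (two-sided, via
   t = r√((n−2)/(1−r²)) with n−2 df); the p-value is empirical, against B
   random gene groups drawn from the expression matrix.
2. **Cluster detection and expansion** — the correlation matrix is
   seriated (average-linkage on 1−r, leaf order), the most coherent window
   becomes the seed cluster, and the gene list is expanded to M genes (the
   seed plus the genes best correlated with the cluster's average z-scored
   profile), large enough for enrichment analysis.
3. **Enrichment (ORA)** — hypergeometric upper-tail tests of the expanded
   list against GMT gene sets, BH-corrected, reported as scores
   −log₂(p_adj) with high/medium/low tiers (p_adj ≤ 1e−4 / ≤ 0.05 / else).
4. **Comparability** — two datasets/regions are comparable in differential
   expression when their per-gene case-vs-control t-statistics correlate
   (Pearson ρ > 0.1, p < 0.001) over shared genes.
5. **Pathway-level differential expression** — per-gene deviation scores
   d = (Mp − Mc)/Sc (case mean minus control mean, in control-SD units) on
   a co-expression network (edges with score > 0.1, isolated genes
   dropped), with an exact binomial sign test for a coordinated
   up-/down-regulation tendency.

A synthetic-data generator (`coexpand.simulate`) produces datasets with
this exact structure planted — a latent-factor co-expression block, a
correlated gene pool, a pathway with a small case shift — plus matching
GMT and edge tables and the ground truth, so every stage can be tested for
calibration, power, and parameter recovery. See `docs/methods.md` for the
models and design choices.

## Worked example

Simulate a study-shaped dataset (2,000 genes; 16 cases vs 18 controls; a
7-gene co-expressed "GWAS" cluster at loading 0.8; a 100-gene correlated
pool; a 30-gene pathway that is both co-expressed, loading 0.7, and
shifted up by 0.5 control-SD in cases) and run the full pipeline:

```bash
coexpand simulate --out-dir demo/sim --seed 11 --n-genes 2000 \
    --pool-genes 100 --pathway-genes 30 --pathway-loading 0.7

cat > demo/run.cfg <<EOF
expression=demo/sim/expression.tsv
metadata=demo/sim/metadata.tsv
gene_list=demo/sim/gwas_genes.txt
gene_sets=demo/sim/gene_sets.gmt
edges=demo/sim/edges.tsv
out_dir=demo/run
B=1000
M=800
seed=11
EOF

coexpand run-all --config demo/run.cfg
```

which prints the stage summaries (full outputs land in `demo/run/`):

```json
{
  "cluster": {"found": true, "mean_pairwise_r": 0.583545575718392, "size": 4},
  "comparability": {"skipped": "single region"},
  "corr_pattern": {
    "empirical_p": 0.003,
    "empirical_p_conservative": 0.003996003996003996,
    "observed_count": 25,
    "region": "region1"
  },
  "enrichment": {
    "n_enriched": 1,
    "n_sets_tested": 51,
    "top_p_adj": 4.218828356140015e-11,
    "top_set": "planted_pathway"
  },
  "expand": {"M": 800, "min_r_attained": 0.09470388032268319, "n_added": 796},
  "pathway_de": {
    "direction": "up",
    "mean_deviation": 1.016586906128538,
    "n_network_edges": 356,
    "n_network_nodes": 30,
    "n_scored": 30,
    "p_binomial": 9.313225746154785e-10,
    "pathway": "planted_pathway"
  },
  "qc": {"removed_samples": ["ctrl_010", "ctrl_011"]}
}
```

Reading the numbers: the 23-gene "GWAS" list shows 25 significantly
correlated pairs where random gene groups almost never reach that many
(empirical p = 0.003 over B = 1000 draws) — the signature of genes sharing
a biological process. The detected seed cluster here is a 4-gene core
(this seed's realized block coherence is weak, mean pairwise r ≈ 0.42, so
at n = 16 the selector keeps only the tightest window — three planted
genes plus one admixed background gene). Expansion to 800 genes by profile
correlation still sweeps in the co-expressed pool and pathway, so the
planted pathway tops the enrichment at p_adj ≈ 4×10⁻¹¹ (score 34.5,
"high" tier). On that pathway the deviation scores lean upward in cases —
30 of 30 genes with d > 0, exact binomial p ≈ 9×10⁻¹⁰ — over a network of
30 genes and 356 co-expression edges. Two control samples failed the
inter-sample-correlation QC and were removed first.

Each stage is also a subcommand (`coexpand corr-pattern`, `expand`,
`enrich`, `compare`, `pathway-de`, `qc`) over the same file formats:
expression and metadata as TSV, gene sets as GMT, edges as a three-column
table (STRING-style 0–1000 integer scores are auto-normalised), all
readable gzipped. The same functionality is importable
(`import coexpand as cx`).

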