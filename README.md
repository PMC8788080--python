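# tecmap

Annotation machinery for body-wide tissue RNA-seq atlases. Given a gene ×
sample expression matrix (raw counts with gene lengths, or TPM), a sample
sheet mapping samples to tissues, grouped tissues and organ systems, and a
protein-coding gene list, `tecmap` computes:

- **NX normalization** — TPM → pTPM (renormalized over protein-coding genes)
  → per-tissue means → between-column TMM correction (trimmed mean of
  M-values) → gene-wise pareto scaling (divide by √SD), plus grouped-tissue
  expression as the maximum over member tissues.
- **Tissue specificity and distribution categories** — each gene is
  classified on its grouped NX profile as *tissue enriched* (one tissue ≥
  4× any other), *group enriched* (2–5 tissues whose mean is ≥ 4× any
  outside tissue), *tissue enhanced* (≥ 4× the all-tissue mean), *low
  specificity*, or *not detected* (NX < 1 everywhere); and as detected in
  all / many (≥ 31% of tissues, i.e. 14 of 44) / some / single / none.
- **Tissue Expression Clustering** — genes are Z-scored on
  log10(TMM + 1) across all samples, embedded in 2-D with UMAP
  (n_neighbors = 15, n_epochs = 1000, unscaled input), partitioned by
  k-means seeded from DBSCAN density clusters (eps = 0.1; the two largest
  clusters receive extra centers in proportion to their convex-hull area),
  and adjacent clusters significantly enriched (BH-adjusted p < 0.05,
  hypergeometric test) for identical tissue sets are merged to a fixed
  point. Final cluster–tissue associations use BH-adjusted p < 0.001.
- **Tissue similarity trees** — pairwise Spearman ρ between tissues,
  clustered on the distance 1 − ρ with Ward or UPGMA linkage, exported as
  Newick.
- **Enriched-gene networks** — a bipartite graph of tissues and
  elevated-tissue combinations with the three display-filtering rules
  (contains tissue-enriched genes; ≥ 5 genes; top-2 node for a connected
  tissue with ≥ 2 genes).
- **Cross-species comparison** — ortholog filtering (one2one plus
  single-high-confidence one2many pairs), 5×5 classification-overlap
  contingency, tissue-pair hypergeometric enrichment (with the protocol's
  literal parameterization), and per-tissue Spearman correlations.

A synthetic-data generator (`tecmap.synthetic`) produces tissue-structured
negative-binomial count matrices with planted specificity categories and
co-expression modules, so every stage is testable end to end with known
ground truth and no external downloads.

## Worked example

Generate the default benchmark fixture (2,000 coding genes, 12 tissues × 3
replicates, 8 planted modules, fold change 8), normalize, and classify:

```python
from tecmap import PipelineConfig, classify_all, normalize_ladder
from tecmap.classify import specificity_summary, distribution_summary
from tecmap.synthetic import generate, low_noise_config

ds = generate(low_noise_config(), seed=1)
ladder = normalize_ladder(ds.counts, ds.sheet, ds.annotation)
spec, dist = classify_all(ladder["nx_grouped"], PipelineConfig())
print(specificity_summary(spec).to_string())
print(distribution_summary(dist).to_string())
```

```
tissue_enriched    750
group_enriched     500
tissue_enhanced    250
low_specificity    250
not_detected       250
detected_in_all       1707
detected_in_many        33
detected_in_some         7
detected_in_single       3
not_detected           250
```

The specificity counts equal the planted module sizes: the 750 genes
planted as enriched in a single tissue, the 500 planted in 2–3-tissue
groups, and the 250 with a graded enhanced profile are all recovered, and
the 250 near-zero genes are called not detected. Most detected genes are
expressed in all tissues because elevation is relative — a gene 8× higher
in testis is still detectable elsewhere.

Clustering the same fixture assigns every gene to one Tissue Expression
Cluster:

```python
from tecmap import run_tissue_expression_clustering
emb, assignment = run_tissue_expression_clustering(
    ladder["sample_tmm"], spec, PipelineConfig(), seed=1
)
print(assignment.n_clusters)                 # 8
print(assignment.clusters[["cluster_id", "n_genes", "significant_tissues"]])
```

yields 8 clusters matching the planted modules (adjusted Rand index 0.99),
each annotated with its significantly associated tissues, e.g. cluster 4 →
`[T03, T04]`, the planted group-enriched pair.

The same pipeline is available from the shell:

```bash
tecmap run --config run.yaml --out out/
tecmap simulate --seed 1 --out-prefix sim
tecmap normalize --counts sim_counts.tsv --lengths sim_lengths.tsv \
    --samples sim_samples.tsv --annotation sim_annotation.tsv \
    --out-nx nx.tsv --out-nx-grouped nxg.tsv --out-tmm-samples tmm.tsv
tecmap classify --nx nxg.tsv --out calls.tsv
tecmap cluster --tmm-samples tmm.tsv --calls calls.tsv --seed 1 --out-prefix tec
tecmap network --calls calls.tsv --out net.graphml
```

Every `run` writes a `manifest.json` with the config snapshot, input
digests, per-stage dimensions and the seed; re-running with the same seed
reproduces all outputs bit for bit.

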