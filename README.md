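# curategap

Detect incompletely curated gene-expression data sets in a
literature-curated genomics database.

The per-gene count of curated expression experiments is predicted from
literature/annotation features — journal-publication counts, the fraction of
publications already curated for expression, the gene symbol, and the
transgenic-construct count — with an L2-regularized, no-intercept linear
model. Genes whose residuals (actual − predicted) fall outside a band of
twice the held-out RMSE are flagged: a *lower* call means the database holds
fewer experiments than the literature suggests, i.e. published data is
likely waiting to be curated.

## Layout

| module | purpose |
| --- | --- |
| `curategap.ingest` | read/write the three tab-separated export dialects (per-gene report, gene–publication links, construct components) |
| `curategap.feature_table` | join the sources into one modeling row per gene |
| `curategap.gene_filter` | exclusion rules producing the modeling gene set, with a per-rule audit tally |
| `curategap.regression` | one-hot + numeric encoding, stratified split, closed-form ridge, metrics, permutation importance |
| `curategap.gap_calling` | residuals, the 2×RMSE band, per-gene calls, residual histogram |
| `curategap.validation` | blinded validation sampling, worksheet round-trip, confusion matrices, `ZDB-PUB-YYMMDD-N` date parsing |
| `curategap.synthetic` | generator for export-dialect datasets with ground-truth curation gaps, plus targeted gap injection |
| `curategap.cli` | pipeline orchestration and the `curategap` command line |

## Command line

```sh
# generate a synthetic database with known curation gaps
curategap simulate --n-genes 2000 --seed 1 --out sim/

# run the full pipeline from a YAML config
curategap run --config pipeline.yaml

# inspect inputs / apply filters standalone
curategap ingest --gene-report sim/MachineLearningReport.txt \
                 --gene-pubs sim/GenePublication.txt \
                 --constructs sim/ConstructComponents.txt
curategap filter --feature-table out/feature_table.tsv

# blinded manual-validation workflow
curategap validate-sample --run-dir out/ --out worksheet.tsv
curategap validate-score  --run-dir out/ --worksheet worksheet.tsv
```

A minimal `pipeline.yaml`:

```yaml
gene_report: sim/MachineLearningReport.txt
gene_pubs: sim/GenePublication.txt
constructs: sim/ConstructComponents.txt
out_dir: out
seed: 112
l2_weight: 10
train_fraction: 0.25
ci_multiplier: 2
filter:
  max_expression_experiments: 200
```

The run directory receives the feature table, filter tally, serialized
model, metrics, permutation importances, full per-gene calls, the flagged
gap report, and a manifest recording the config and seed; reruns with the
same config are byte-identical.

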