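# regflow

From GWAS summary statistics to master regulators, as a tested, reusable
pipeline:

1. **gwas_genes** — SNP filtering at genome-wide significance, SNP→gene
   window mapping (gene body ± 10 kb by default), gene-level p-value
   aggregation (Fisher's method, or Brown's correlated-chi-square
   approximation given an LD correlation matrix), Bonferroni gene
   thresholds, and competitive / gene-property enrichment regression.
2. **twas_meta** — summary-statistic TWAS gene z-scores from eQTL weight
   models, direction-consistent selection across brain regions (same-sign
   significance in ≥ 3 regions), Fisher sum-of-logs meta-analysis with
   Benjamini–Hochberg adjustment inside the selected family.
3. **enrichment** — uncertainty-weighted regression enrichment (per-gene
   cross-validation r² as WLS weights) and weighted-KS rank enrichment,
   both with gene-label permutation nulls, NES, and BH adjustment.
4. **dge** — CPM filtering, TMM normalization, sex-stratified
   covariate-adjusted differential expression on log2-CPM, soft/strict DEG
   classification, and TWAS-vs-transcriptome direction concordance.
5. **regulators** — regulon-based TF activity scoring with permutation
   nulls, tissue-specific network pruning (tpm > 1), signed shortest-path
   consensus (max length 5), causal agreement scoring of candidate
   regulators under active/inactive hypotheses, and the two-criterion
   (TWAS or DEG) support filter.

A first-class **simulate** module generates every input — summary
statistics, per-region TWAS tables with shared cross-region effects,
negative-binomial count matrices with sex-specific/sex-opposite planted
effects and confounding covariates, regulons and layered signed networks
with planted master regulators — with machine-readable ground truth
(`ground_truth.json`), so the full chain is testable offline.

## CLI

```bash
# everything end to end on a synthetic fixture
regflow run-all --seed 1 --out runs/demo

# individual stages
regflow simulate  --seed 1 --out runs/inputs
regflow map-genes --summary-stats runs/inputs/summary_stats.tsv \
                  --gene-models runs/inputs/gene_models.tsv \
                  --window-bp 10000 --out runs/stage1
regflow twas-meta --gene-stats runs/inputs/twas_gene_stats.tsv \
                  --min-regions 3 --alpha 0.05 --meta-alpha 0.05 --out runs/stage2
regflow enrich    --signature sig.tsv --gene-sets sets.gmt \
                  --mode regression --n-perm 1000 --out runs/stage3
regflow dge       --counts runs/inputs/counts.tsv \
                  --sample-meta runs/inputs/sample_meta.tsv \
                  --covariates age,PMI,pH,RIN --out runs/stage4
regflow find-mr   --signature sig.tsv --regulons runs/inputs/regulons.tsv \
                  --network-edges runs/inputs/network_edges.tsv \
                  --network-roles runs/inputs/network_roles.tsv \
                  --tpm runs/inputs/tpm.tsv --max-path-len 5 --out runs/stage5
```

All formats are plain TSV (plus GMT for gene sets, SIF-like TSV for the
signed network, YAML for configuration). Each stage writes a
`manifest.json` with the config hash, seed, and file inventory; the same
config + seed reproduces outputs byte-identically.

## Layout

```
src/regflow/
  io.py          readers/writers, RunConfig, SignedNetwork, manifests
  simulate.py    synthetic inputs with planted ground truth
  gwas_genes.py  stage 1: SNP→gene aggregation + enrichment regression
  twas_meta.py   stage 2: TWAS z, consistency selection, Fisher meta, BH
  enrichment.py  stage 3: weighted-regression and weighted-KS enrichment
  dge.py         stage 4: TMM, stratified DE, DEG flags, concordance
  regulators.py  stage 5: TF activity, signed paths, MR scoring
  pipeline.py    run-all orchestration
  cli.py         click CLI
  report.py      rounding/percentage helpers for headline numbers
tests/           pytest suite (oracles.py holds independent references)
scripts/acceptance.py
```
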