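# hma-kit

Integrative drug-response analysis toolkit for hypomethylating-agent-style
pharmacogenomics: cell-line sensitivity profiling, responder-stratified
multi-omic biomarker discovery with a permutation-validated region-set
methylation score, methylome demethylation analysis stratified by genomic /
chromatin / replication-timing context, and Chou–Talalay combination-index
synergy. A seeded synthetic-data module generates panels, methylomes, and
omics matrices with the statistical structure each stage assumes, so the
whole pipeline runs and is tested fully offline.

## Modules

| Module | What it does |
| --- | --- |
| `hma_kit.synthetic` | Seeded generators: sensitivity panel (dose–response curves from planted AUCs), panel + treatment methylomes (β via the intensity formula path, planted responder-hypermethylated regions, timing-coupled Δβ), expression/mutation/protein matrices, additive/synergistic combination grids. |
| `hma_kit.dose_response` | Normalized AUC over log10(dose), 4PL IC50 with right-censoring, lowest-50%-AUC sensitive flag, AUC-tertile responder/nonresponder split, Haldane-corrected tissue odds ratios with Wald CIs and Fisher p, feature–metric Pearson correlations. |
| `hma_kit.methylome` | β = max(M,0)/(\|U\|+\|M\|+100), DMC calling (unpaired t-test, nested Δβ cutoffs {0, −0.05, −0.1, −0.2} at p < 0.05), shared-DMC counts, per-feature normalized demethylation ratios. |
| `hma_kit.annotation` | BED (0-based half-open) chromatin-mark and replication-timing annotation of probe manifests; timing classes late (<0) / mid-early ([0,1)) / early (≥1); per-class DMC distributions and Δβ–timing correlation. |
| `hma_kit.biomarkers` | Covariate-adjusted (group + lineage) OLS screens for expression and region methylation with BH FDR, logistic mutation association with Haldane 2×2 fallback on separation, mutation burden, region-set methylation score vs log2 IC50 with an add-one permutation null. |
| `hma_kit.synergy` | Median-effect fits and two-term (mutually exclusive) combination indices over dose matrices. |
| `hma_kit.pipeline` | YAML-configured end-to-end orchestration with a JSON run manifest and sha256-based stage caching. |

Note on AUC scale: AUC here is standardized to [0, 1] (normalized trapezoid
of mean viability over log10 dose; 0 = fully killed). Public CTRP-style AUCs
live on unnormalized scales; orderings, not absolute values, are comparable.

## CLI

```bash
# full synthetic pipeline from a YAML config
hma-kit run --config config.yaml --outdir runs/demo

# individual stages
hma-kit sensitivity --curves curves.tsv --metadata meta.tsv --out records.tsv
hma-kit annotate --manifest probes.tsv --marks H3K27ac.bed,H3K9me3.bed \
    --timing repli.bed --out annotated.tsv
hma-kit dmc --beta beta.tsv --design design.tsv --drug drugA --out dmc.tsv
hma-kit demeth-ratio --dmc-a a.tsv --dmc-b b.tsv --manifest probes.tsv \
    --cutoff -0.05 --out ratio.tsv
hma-kit de  --expression expr.tsv --classes sensitivity.tsv --out de.tsv
hma-kit mut --mutations mut.tsv --classes sensitivity.tsv --out mut.tsv
hma-kit dmr --beta beta.tsv --region-map regions.tsv \
    --classes sensitivity.tsv --out dmr.tsv
hma-kit dmr-score --beta beta.tsv --region-map regions.tsv \
    --regions sig_regions.txt --sensitivity sensitivity.tsv \
    --iterations 100000 --seed 1 --out score.json
hma-kit ci --mono-a a.tsv --mono-b b.tsv --combo combo.tsv --out ci.tsv
```

A minimal `config.yaml`:

```yaml
seed: 7
n_iterations: 10000
fdr: 0.05
panel: {n_cell_lines: 199}
methylome: {n_regions: 500, planted_dmr_count: 50}
omics: {n_genes: 1000}
```

Rerunning `hma-kit run` with an unchanged config reuses cached stage outputs
(validated by sha256 in `manifest.json`); editing any upstream file
invalidates dependent stages.

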