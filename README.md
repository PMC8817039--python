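# phenonet

A deep-phenotype PheWAS pipeline with the systematic post-PheWAS analyses:
cross-phenotype bipartite networks, split-sample network-wide Mendelian
randomization, LD-aware significance calibration, LD-score-regression
heritability, cross-cohort locus overlap and fixed-effect meta-analysis, and
PheWAS-driven vs EHR-driven phenotype-pair concordance.  A synthetic cohort
generator with known pleiotropic and causal architecture provides ground
truth for every stage.

## Layout

| Module | Purpose |
| --- | --- |
| `phenonet.datatypes` / `phenonet.io` | Domain types; VCF / PLINK-binary / dosage-TSV genotypes, phenotype tables, summary statistics, BED/GFF3 gene models |
| `phenonet.simulate` | HWE genotypes with block-wise LD; additive polygenic traits, liability-threshold binary traits, phenotype-on-phenotype causal effects, covariates; returns `GroundTruth` |
| `phenonet.phewas` | PCA covariates, vectorized linear and ML logistic association scans, greedy LD pruning, LD-aware Bonferroni threshold, Benjamini-Hochberg FDR |
| `phenonet.annotation` | Variant-to-gene mapping with a 5 kb flank; coding / impact-group classification |
| `phenonet.networks` | Cross-phenotype association extraction; bipartite phenotype and gene networks; intersection (Venn) classes; cross-phenotype star maps |
| `phenonet.mr` | Sample splitting, strict LD clumping, IVW / MR-Egger / weighted-median estimators, directed causal map with FDR-based direction calls |
| `phenonet.heritability` | In-sample LD scores, chi-square-on-LD-score heritability with block-jackknife SE, impact-group vs heritability correlation |
| `phenonet.comparative` | Trans-cohort locus overlap ratios, inverse-variance meta-analysis with allele harmonization, EHR pair concordance |

## CLI

Each stage ships its own executable; all exchange plain tab-separated files.

```bash
# simulate a cohort (JSON config; see tests/test_cli.py for the schema)
pheno-sim --config cfg.json --out cohort/

# validate inputs
pheno-io -g cohort/genotypes.tsv --format dosage-tsv \
         -p cohort/phenotypes.tsv --pheno-meta cohort/phenotypes.meta.json

# association scan + LD-aware threshold
pheno-assoc -g cohort/genotypes.tsv -p cohort/phenotypes.tsv \
            --pheno-meta cohort/phenotypes.meta.json -o stats.tsv --pcs 3

# cross-phenotype network
pheno-net -s stats.tsv -o network --p 1e-4

# split-sample Mendelian randomization over the network
pheno-mr -g cohort/genotypes.tsv -p cohort/phenotypes.tsv \
         --pheno-meta cohort/phenotypes.meta.json -o causal_map.tsv

# heritability per phenotype
pheno-h2 -s stats.tsv -g cohort/genotypes.tsv -o h2.tsv --window-kb 100

# cross-cohort comparisons
pheno-compare overlap --stats1 a.tsv --stats2 b.tsv -o overlap.tsv
pheno-compare meta --stats a.tsv --stats b.tsv -o meta.tsv
```

## Conventions

- Coordinates are 1-based inclusive internally; BED is converted on read.
- Dosages are alt-allele counts in {0, 1, 2} with `nan` for missing calls;
  association tests are complete-case per (variant, phenotype).
- Multi-allelic VCF sites are split into bi-allelic records by default
  (`multiallelic="reject"` to refuse them).
- Binary traits use 0/1 coding and logistic regression; fits that hit
  perfect separation or fail to converge are flagged, never fabricated.
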