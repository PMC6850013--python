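# mockbarcode

Simulation and analysis toolkit for benchmarking COI metabarcoding of a
diverse arthropod mock community. It generates a synthetic community with
known ground truth (barcode sequences spaced >2% apart, a ~7,500-fold
body-mass range, degenerate-primer binding sites with controlled mismatch
counts), pushes it through a biased forward model (mass-scaled template
pooling, mismatch-penalized PCR, platform-specific sequencing errors), and
provides the downstream analysis stages: read QC, reference assignment and
OTU clustering, rarefaction with an asymptote criterion, diversity
statistics, primer-mismatch profiling, and a coupon-collector model of the
sequencing depth required for PCR-free barcode recovery.

## Package layout

| module                    | contents |
|---------------------------|----------|
| `mockbarcode.community`   | community generator, treatment/platform models, read simulator, FASTA/TSV ground truth |
| `mockbarcode.qc`          | paired-read merging, QV filters, trimming, per-sample QC report |
| `mockbarcode.assign`      | semi-global distances (p / K2P), <3% reference assignment, greedy 2% OTU clustering, abundance tables |
| `mockbarcode.rarefaction` | subsampled richness curves over the standard depth grid, slope<0.01 asymptote rule |
| `mockbarcode.diversity`   | abundance floor (>0.01%), Shannon/Simpson/Pielou/Renyi, recovery rates, Bray–Curtis + single-link tree, Kendall tau, CV |
| `mockbarcode.primers`     | IUPAC-aware primer mismatch counting, cocktail best-match, mismatch–abundance profiles |
| `mockbarcode.depth`       | coupon-collector depth model, retained-fraction and biomass-scaling arithmetic, Monte-Carlo sampler |

## CLI

One `mockbarcode` entry point with subcommands:

```bash
# simulate a biased read set with ground truth
mockbarcode simulate --treatment bulk_abdomen --platform miseq_like \
    --amplicon 407 --depth 10000 --seed 1 --out sim/

# merge + filter + trim
mockbarcode qc sim/reads_R1.fastq sim/reads_R2.fastq --paired \
    --amplicon-class 407 --out-prefix sim/sample1

# assign to the reference library, cluster the rest into OTUs
mockbarcode assign sim/sample1.filtered.fastq --library sim/library.fasta \
    --out sim/table.tsv

# rarefaction curve + asymptote verdict
mockbarcode rarefy sim/table.tsv --reps 10000 --seed 1 --out sim/curve.tsv

# diversity report + Bray-Curtis single-link tree
mockbarcode diversity sim/table.tsv --out-prefix sim/report

# the sequencing-depth requirement model (raw + rounded values)
mockbarcode depth-model --json
```

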