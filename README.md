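# corsivscreen

Screen multi-tissue whole-genome bisulfite (WGBS) cohorts for **CoRSIVs** —
correlated regions of systemic interindividual variation in DNA methylation —
and compare two-group cohorts (e.g. embryo-culture vs in-vivo control) at
those regions. Every stage is driven end-to-end by a synthetic methylome
generator with a planted ground truth, so the whole pipeline is testable with
no external downloads.

## What it does

1. **simulate** — generate a toy genome (CpG coordinates), per-(subject,
   tissue) beta-binomial read counts, planted systemic-variant /
   tissue-DMR / null regions, CpG-destroying SNPs with genotypes, and toy
   gene/repeat/CpG-island tracks.
2. **bins** — tile the genome into 100-bp bins, apply the coverage-adequacy
   rule (all CpGs ≥ 5 reads when n ≤ 2, else ⌈n/2⌉ CpGs), mask CpG-SNPs that
   are discordant between the two screen subjects (qual ≥ 30, C or G of the
   CpG), and compute per-bin inter-individual methylation residuals.
3. **call** — build blocks from runs of ≥ 2 consecutive bins with
   same-direction residuals ≥ 10 points, compute the systemic
   interindividual variation index `SIVI = ∛|x·y·z| − sd(x,y,z)` from the
   three per-tissue block residuals, run a 1000-iteration library-label
   permutation null, and emit candidate CoRSIVs (SIVI ≥ 20) and CoRSIVs
   (≥ 5 CpGs).
4. **controls** — sample chromosome-, CpG-count- and size-matched
   non-CoRSIV control regions (exact CpG match; +100 bp size relaxation
   after 1000 failed draws).
5. **annotate** — genic context (TSS/TES within 2.5 kb, gene body,
   intergenic), genetic-variant concordance in 1-kb windows, repeat-class
   profiles ± 50 kb at 5-kb increments.
6. **group-test** — per-region 2×2 read-count chi-square (Yates) between two
   groups, BH adjustment, DMR-overlap enrichment (valid overlap = half the
   smaller feature), per-tissue and combined significant-region enrichment,
   sign tests for direction bias, clustering sanity checks, and the
   inter-tissue correlation (r ≥ 0.71) validation rule.

## CLI

```bash
corsiv-screen simulate --config sim.yaml --out cohort/
corsiv-screen bins --coverage s1:cortex=cohort/s1_cortex.cov ... \
    --genome cohort/ --vcf cohort/genotypes.vcf \
    --subject-a s1 --subject-b s2 --out bins.tsv
corsiv-screen call --bins bins.tsv --subject-a s1 --subject-b s2 \
    --out corsivs.tsv
corsiv-screen controls --corsivs corsivs.tsv --bins bins.tsv \
    --genome cohort/ --seed 7 --out controls.tsv
corsiv-screen annotate --regions corsivs.tsv --genes cohort/genes.tsv \
    --repeats cohort/repeats.tsv --vcf cohort/genotypes.vcf \
    --subject-a s1 --subject-b s2 --out annot.tsv
corsiv-screen group-test --corsivs corsivs.tsv --controls controls.tsv \
    --group1 ivp1:liver=... --group2 moet1:liver=... --out results.tsv
corsiv-screen run-all --config run.yaml --out run/   # whole pipeline + manifest
```

A minimal `sim.yaml`:

```yaml
chrom_sizes: {chr1: 2000000}
n_planted_systemic: 20
n_planted_dmr: 20
n_planted_null: 20
depth_mean: 20.0
systemic_effect: 0.25
systemic_effect_max: 0.30
seed: 1
```

Exit codes: 0 success, 2 configuration error, 3 data/format error.
`run-all` writes a `manifest.json` with parameters, seeds and SHA-256 of
every output; reruns with the same config are byte-identical.

## Package layout

| module | contents |
|---|---|
| `corsivscreen.types` | core domain types (intervals, libraries, variants) |
| `corsivscreen.meth_io` | coverage / VCF-lite / BED / gene / repeat / DMR I/O |
| `corsivscreen.synthetic` | seeded cohort generator with planted truth |
| `corsivscreen.binning` | bins, adequacy, CpG-SNP masking, residuals |
| `corsivscreen.screen` | blocks, SIVI, CoRSIV calls, permutation null |
| `corsivscreen.context` | matched controls, genic/variant/repeat annotation |
| `corsivscreen.group` | two-group tests, direction bias, clustering, validation |
| `corsivscreen.cli` | `corsiv-screen` subcommands and `run-all` |

All internal coordinates are 0-based half-open; the 1-based conventions of
coverage files and VCF are converted at the file boundary only.
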