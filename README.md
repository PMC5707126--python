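# hervex

Endogenous-retrovirus expression screening for short single-end RNA-seq
reads, exercised end-to-end on synthetic data with recorded ground truth.

The pipeline stages:

1. **synthetic_data** — generates a host genome, retroviral domain proteins,
   planted ERV-like loci (diverged back-translations), a viral reference set
   with one exogenous virus, a three-group design table (demyelination /
   control / OND), and per-specimen FASTQ reads with per-read provenance.
2. **read_screening** — quality filtering to "HQ reads" (mean Phred,
   ambiguous-base caps), then host subtraction by seeded end-to-end
   alignment against the host genome and transcript set, yielding
   "screened reads".
3. **viral_search** — exact 28-mer seeding with ungapped extension against
   the viral reference set; distinct-read hit counts per taxon normalized by
   HQ reads (viral hit rates), log display with a half-hit floor, and a
   Bonferroni-corrected z-screen for overrepresented taxa.
4. **catalog_builder** — six-frame translation of the genome, local
   BLOSUM62 alignment of stop-free segments against the domain proteins,
   an expect cutoff plus a 50%-of-subject coverage rule, and union-merged,
   sequentially numbered nucleotide catalog entries
   (`GAG_U1|RV-GAG1|host_genome|2350|855`).
5. **rvgc_quant** — end-to-end read alignment to the catalog (bounded
   substitutions, pigeonhole-seeded, verified against an exhaustive oracle);
   best-alignment and comprehensive-alignment counting; FPKM x 1000;
   Mann-Whitney case/control comparison with Benjamini-Hochberg q-values
   computed within each domain type.
6. **domain_discrimination** — domain-binned hit rates, log2 transform and
   domain-axis centering, average-linkage clustering on 1 - Pearson
   correlation, and a two-tailed Fisher exact test on the root split.
7. **group_stats** — the shared statistics: z-test, Bonferroni,
   Mann-Whitney U (exact and approximate), Benjamini-Hochberg, Fisher exact
   (probability-mass summation), Yates chi-square, one-way ANOVA, Tukey HSD.
8. **cohort** — the bundled specimen demographics / read-yield design table
   and its group summaries.
9. **pipeline** — one-command orchestration with a checksum manifest and a
   plain-text report.

## CLI

```bash
hervex run --seed 1 --out out/            # full synthetic study
hervex simulate --seed 1 --out sim/
hervex screen --reads sim/reads/DEM01.fastq --host-genome sim/host_screen.fasta \
    --host-tx sim/transcripts.fasta --out screened.fastq --summary summary.tsv
hervex build-catalog --genome sim/genome.fasta --domains sim/domains.fasta \
    --expect 0.1 --min-coverage 0.5 --out catalog.fasta --table catalog.tsv
hervex quantify --reads-dir sim/reads --catalog catalog.fasta \
    --catalog-table catalog.tsv --design sim/design.tsv \
    --scheme comprehensive --out expression.tsv --compare-out comparison.tsv
hervex viral-screen --reads screened.fastq --viral-db sim/viral.fasta \
    --taxa sim/taxa.tsv --hq-count 100000 --out vhr.tsv
hervex discriminate --profile profile.tsv --design sim/design.tsv \
    --test demyelination:control --out split.json
hervex stats --values values.tsv --method mann-whitney
```

## Notes

- All inputs and outputs are plain text (FASTA / FASTQ / TSV / JSON);
  FASTQ may be gzipped.
- Every stage is deterministic under a fixed seed; reruns produce
  byte-identical outputs and stable manifest checksums.
- Group-effect simulation is multiplicative on locus sampling probability,
  so configured expression ratios are recovered exactly in expectation when
  FPKM uses the HQ-read denominator (`norm_mass_mode="hq"`).
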