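# sweepscan

Selective-sweep scan statistics on phased haplotypes, with synthetic
fixtures so the whole pipeline is testable end to end without any data
download.

Implemented statistics:

- **SFS / sliding windows** — nucleotide diversity (θπ), Watterson's θ,
  segregating sites, Tajima's D and Fay & Wu's H in sliding windows
  (default 5 kb window, 1 kb step).
- **Haplotype homozygosity** — EHH decay curves, integrated haplotype
  homozygosity, per-SNP iHS and nSL with derived-allele-frequency-bin
  standardization (selscan-style defaults: EHH cutoff 0.05, 1 Mb maximum
  extension, 200 kb gap abort, 20 kb gap scaling, MAF > 5%, 100 bins).
- **Population differentiation** — Hudson FST (per-site with finite-sample
  correction; ratio-of-averages across sites), the population branch
  statistic PBS via T = −ln(1 − FST), and phased LD r².
- **Scan engine** — genome-wide empirical distributions, empirical
  p-values (proportion of values as or more extreme, ties included),
  top-5%/1% cutoffs and flags, per-population allele-frequency reports,
  region reports and BED export.
- **Synthetic data** — Kingman-coalescent neutral loci (infinite sites,
  E[S] = θ·a1), Balding–Nichols structured populations with controlled FST,
  haplotype-copy sweep injection, and VCF 4.2 + panel fixture writing with
  bit-exact round trips.

Input is phased, biallelic-SNP VCF 4.x with an `AA` (ancestral allele)
INFO tag, plus a 1000 Genomes-style sample panel (`sample`, `pop`,
`super_pop` columns). Alleles are polarized to ancestral/derived before
the polarity-sensitive statistics; sites without usable ancestral
information are dropped by default.

## CLI

All commands are under a single `scan` entry point:

```sh
# simulate fixtures (VCF + panel + ground-truth JSON)
scan --seed 7 simulate neutral --n 40 --theta 30 --length-bp 200000 --out-dir fx/
scan --seed 7 simulate structured --fst 0.2,0.05,0.05 --n-diploids 30 --out-dir fx2/
scan --seed 7 simulate sweep --n 100 --theta 20 --span-bp 300000 --out-dir fx3/

# statistics
scan sfs --vcf fx/neutral.vcf --panel fx/neutral.panel --window 5000 --step 1000 --out sfs.tsv
scan ihs --vcf fx/neutral.vcf --maf 0.05 --bins 100 --out ihs.tsv
scan nsl --vcf fx/neutral.vcf --maf 0.05 --out nsl.tsv
scan pbs --vcf fx2/structured.vcf --panel fx2/structured.panel \
    --focal P1 --ref1 P2 --ref2 P3 --out pbs.tsv

# reporting
scan freq --vcf fx/neutral.vcf --panel fx/neutral.panel --variants sim_12345 --allele DERIVED
scan pvalue --track sfs.tsv --background sfs_genomewide.tsv --column tajima_d --tail lower --out flagged.tsv
```

`--config file.yaml` supplies per-subcommand option defaults; `--seed`
drives every source of randomness.

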