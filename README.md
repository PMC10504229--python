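# gwhap

Gene-based haplotype association testing for inbred genotype panels.

Given a biallelic SNP panel (VCF), a gene annotation (GFF3) and a
quantitative trait table (CSV), `gwhap`:

1. filters SNPs by minor allele frequency (>= 0.05) and missing-call rate
   (<= 20%),
2. assigns SNPs to gene bodies (1-based inclusive intervals, UTRs/introns
   included) and builds per-gene haplotype classes from the homozygous
   allele strings (het/missing calls exclude an accession at that gene;
   rare classes below a configurable count are excluded),
3. estimates population structure by PCA on spacing-thinned SNP dosages
   (k-means subpopulation labels, centered-dosage kinship as a diagnostic),
4. tests each gene x trait pair with an OLS F-test of the haplotype-class
   indicators against a PCs-only reduced model (default alpha = 1e-4),
5. runs a PC-corrected per-SNP dosage regression inside each significant
   gene and nominates the lowest-p SNP as the key variant, and
6. writes result TSVs, Manhattan/QQ plot data, a gene-trait report and a
   JSON run manifest.

A synthetic-data module generates structured inbred panels (two diverged
subpopulations, founder haplotypes per gene, planted causal class effects
with a target explained-variance fraction) so the whole pipeline is
testable end to end without external data. A phenotype-statistics module
provides trait summaries, pairwise-complete Pearson correlations,
pooled-variance subgroup t-tests and top-k accession mining with half-up
rounded per-accession totals.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the slower calibration/power suites
(null calibration over 10 seeds, 200-replicate power recovery,
determinism); the rest of the suite runs in a few seconds.

## CLI

Every stage is a subcommand; `run` executes the full pipeline from a YAML
config:

```sh
gwhap simulate --config sim.yaml --out fixtures/
gwhap filter --vcf panel.vcf --maf-min 0.05 --miss-max 0.20 --out filtered.vcf
gwhap thin --vcf filtered.vcf --spacing-bp 50000 --out thinned.vcf
gwhap haplotypes --vcf filtered.vcf --gff genes.gff3 --min-count 5 --out hist.tsv
gwhap structure --vcf filtered.vcf --pcs 10 --k 2 --seed 11 --out pcs.tsv
gwhap gwha --vcf filtered.vcf --gff genes.gff3 --traits traits.csv \
    --pcs 2 --alpha 1e-4 --min-count 5 --out gwha.tsv
gwhap snpscan --vcf filtered.vcf --gff genes.gff3 --traits traits.csv \
    --genes significant.tsv --out snps.tsv
gwhap phenostats --traits traits.csv --groups groups.csv --top-k 5 --out pheno/
gwhap report --gwha-results gwha.tsv --snp-results snps.tsv --out gta.tsv
gwhap run --config pipeline.yaml
```

Pipeline YAML keys: `vcf`, `gff3`, `traits`, `out_dir`, `seed` (required);
`maf_min`, `miss_max`, `spacing_bp`, `pcs`, `k`, `alpha`,
`min_class_count` (optional, with the defaults above). Exit codes:
0 success, 2 config error, 3 data error.

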