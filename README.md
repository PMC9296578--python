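# rareburden

Rare-variant discovery for case–control exome studies: a collapsing gene
burden test with exact statistics, Mendelian segregation scanning in multiplex
families, and severity-stratified genotype-frequency tables — plus a synthetic
cohort/family generator with recorded ground truth for validating every stage.

## Who this is for

Statistical geneticists running (or auditing) a two-stage rare-variant design:
a discovery case–control exome cohort is screened gene by gene for an excess
of rare, potentially protein-altering variants; the top candidates are
re-tested in an independent replication cohort; and orthogonal evidence is
collected from family segregation and targeted genotyping. The package was
built around an adolescent idiopathic scoliosis (AIS) study of this shape
(73 vs 70 discovery exomes, a 24-gene replication panel in 96 vs 96, a
three-affected-sister family, and nine genotyped SNPs stratified by Cobb-angle
severity), but every cohort size, filter and threshold is a parameter.

## The statistics

**Qualifying variants.** A variant qualifies when it passes quality, is
potentially protein-altering (missense, stop gain/loss, frameshift, in-frame
indel, splice region; near-intronic within a configurable window of an exon
boundary; synonymous excluded by default), and is rare: max MAF over the
consulted population panels < 1% by default, with absence from all panels
counting as rare. Optionally a REVEL pathogenicity filter requires the
effective score — truncating variants imputed to 1.0 — to exceed a threshold.

**Collapsing burden test.** Per gene g, qualifying observations collapse into
a gene-allele burden count

&nbsp;&nbsp;&nbsp;&nbsp;b<sub>g</sub> = Σ<sub>samples i</sub> Σ<sub>variants v∈g</sub> dosage<sub>iv</sub>,

so a sample with two rare variants in one gene contributes two events. Each
gene is tested on the 2×2 table [[b<sub>case</sub>, N<sub>case</sub>−b<sub>case</sub>],
[b<sub>ctrl</sub>, N<sub>ctrl</sub>−b<sub>ctrl</sub>]] with Fisher's exact test
(two-tailed, minimum-likelihood convention, for the exome-wide discovery
screen; one-tailed P(case count ≥ observed) for directional replication) and
the 1-df chi-square. Exome-wide significance is Bonferroni over the genes
actually tested: α = 0.05 / n_genes_tested.

**Segregation models.** For unaffected parents and affected siblings: shared
de novo (all sibs het, parents observed 0/0), homozygous recessive (sibs
hom-alt, parents het), and trans compound heterozygote (two variants in one
gene, all sibs het at both, each parent heterozygous for exactly one — which
both phases the pair and keeps the unaffected parents from carrying both).

See `docs/methods.md` for the full model description, parameter defaults,
what the synthetic generator does and does not emulate, and known limitations.

## Worked example

From the published collapsed counts, using the library directly:

```python
from rareburden import fisher_exact_2x2, significance_threshold

p_disc = fisher_exact_2x2(10, 63, 0, 70, tail="two")   # gene with 10 case / 0 control events, 73 vs 70
p_repl = fisher_exact_2x2(21, 75, 11, 85, tail="one")  # 21 vs 11 events, 96 vs 96
print(f"discovery GLP1R 10 vs 0 (73/70), two-tailed Fisher p = {p_disc:.3f}")
print(f"replication FAT3 21 vs 11 (96/96), one-tailed Fisher p = {p_repl:.2f}")
print(f"exome-wide threshold for 8150 tested genes = {significance_threshold(8150):.1e}")
```

prints

```
discovery GLP1R 10 vs 0 (73/70), two-tailed Fisher p = 0.001
replication FAT3 21 vs 11 (96/96), one-tailed Fisher p = 0.04
exome-wide threshold for 8150 tested genes = 6.1e-06
```

— the discovery gene is nominally associated (p = 0.001) but far above the
exome-wide bound of 6×10⁻⁶, which is exactly why the design carries candidates
into a replication stage; the replication excess (21 vs 11) is suggestive
(one-tailed p = 0.04) but uncorrected for the panel size.

The same numbers fall out of the full pipeline on files. Generate a synthetic
cohort and run the burden stage:

```
$ rareburden simulate cohort --seed 7 --out sim
cohort written to sim; 145 qualifying variants planted
$ rareburden burden --stage discovery --vcf sim/cohort.vcf \
    --annotations sim/annotations.tsv --phenotypes sim/phenotypes.tsv \
    --top-k 3 --out burden_out
114 genes tested; threshold 0.000439
```

`burden_out/gene_burden.tsv` then holds one row per tested gene with burden
and carrier counts, both Fisher tails and the chi-square p in full precision
plus display-rounded columns; `filter_trace.tsv` records per-rule attrition;
`run_summary.json` holds the threshold, gene count and top candidates.

Other subcommands: `rareburden run` (two-stage: discovery → top-k candidates →
replication restricted to them, with a machine-readable run report),
`rareburden segregate` (family VCF + PED → hits per inheritance model),
`rareburden genotab` (severity-stratified genotype count/percentage tables),
`rareburden simulate family` (Mendelian background plus planted hits).

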