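# Methods

## The problem

Adolescent idiopathic scoliosis (AIS) is a common, genetically heterogeneous
spinal deformity in which common-variant association studies explain little of
the heritability. A standard strategy for recovering the rare-variant
component is a two-stage collapsing burden design: define *qualifying*
variants (rare, potentially protein-altering), collapse them per gene into a
single count per cohort, test every gene in a discovery case–control exome
cohort, and re-test the strongest candidates in an independent replication
cohort with a targeted panel. `rareburden` implements that design end to end,
together with the two companion analyses such studies run: Mendelian
segregation scanning in a multiplex family, and severity-stratified genotype
frequency tables for individually genotyped SNPs.

## Qualifying-variant definition (`rare_filter`)

A variant qualifies when it passes, in order:

1. **quality** — the upstream caller's `quality_pass` flag. The package never
   recomputes call quality; the criterion belongs to the sequencing pipeline.
2. **consequence** — missense, stop gain/loss, frameshift, in-frame indel and
   splice-region variants qualify; synonymous variants are excluded by default
   (`keep_synonymous` restores them — including them is known to dilute the
   case/control contrast); near-intronic variants qualify when their distance
   to the nearest exon boundary is ≤ `near_intron_window`. The window defaults
   to 10 bp, a conventional splice-region span; the boundary of "near" is not
   standardised anywhere, so the knob is explicit and documented.
3. **rarity** — the *maximum* minor allele frequency over the consulted
   population panels must be `< maf_cutoff` (default 1%). Strictness follows
   the removal rule "MAF ≥ cutoff is removed"; the family analysis uses the
   inclusive variant (`maf_inclusive=True`, MAF ≤ 1% kept) because that is how
   family screens are conventionally phrased. Taking the maximum across panels
   is the conservative reading of screening against several databases at once:
   common in *any* consulted panel means not rare. A variant absent from every
   panel has frequency 0 — novel variants qualify. Default panels are
   1000 Genomes EUR + ESP-EA for discovery and 1000 Genomes EUR + gnomAD
   genomes/exomes for replication, both configurable.
4. **REVEL** (optional) — when `revel_threshold` is set, the *effective* REVEL
   score must be strictly above it. Protein-truncating classes (stop gain,
   frameshift), which REVEL does not score, are imputed the maximal score 1.0.
   Intronic and splice-region variants are never scored; by default they are
   *retained* under REVEL filtering (`revel_unassigned_policy="retain"`),
   because dropping them would silently undo the deliberate inclusion of
   near-intronic variants; a `drop` policy is available. Two named operating
   points ship (`balanced` = 0.3, `sens_eq_spec` = 0.38); neither is treated
   as canonical.

Each stage records `(variants in, variants removed)` in a `FilterTrace`, so
input − Σremoved = output always holds and a run is auditable.

## Collapsing burden test (`burden`)

Qualifying variants collapse per gene into a **gene-allele burden count**:
each (sample, variant) observation contributes its allele dosage — one for a
heterozygote, two for a homozygote — so a sample with two rare variants in one
gene contributes two independent events, not one carrier. Distinct-carrier
counts are kept alongside, and a `counting="carriers"` mode tests carriers
against non-carriers instead; the two modes coincide whenever no sample
carries two qualifying alleles in one gene.

Each gene's 2×2 table is `(burden, cohort_size − burden)` per group. This cell
construction reproduces the published p-values from published collapsed counts
with 73/70 and 96/96 denominators. Tests:

- **Fisher's exact test**, both tails. The two-sided p uses the
  minimum-likelihood convention (sum the point probabilities of all tables,
  under fixed margins, no more likely than the observed one), the convention
  of the common online calculators. The one-sided p is P(case count ≥
  observed): rare damaging alleles are not plausibly protective, so the
  directional alternative is case enrichment. Degenerate (all-zero) tables get
  p = 1.
- **1-df chi-square** without continuity correction, p = 1 on degenerate
  margins, reported alongside Fisher for the discovery stage.

Every gene with ≥ 1 qualifying observation in cases ∪ controls is tested —
including genes with variants only in controls. The exome-wide significance
bound is Bonferroni over the genes actually tested, `0.05 / n_genes_tested`.
Candidate ranking is by stage p-value ascending, then case count descending,
then control count ascending, then gene symbol — a deterministic tie-break, an
artifact convention rather than a claim about how any particular study broke
ties.

The replication stage reports one-tailed p-values by default, discovery
two-tailed; both are always computed and stored on every record, since
published tables in this literature are not always consistent about which
convention a given row uses.

## Segregation models (`segregation`)

For a nuclear pedigree with unaffected parents and ≥ 1 affected siblings,
three fully penetrant models are scanned over filtered variants:

- **shared de novo** — every affected sibling heterozygous, both parents
  *observed* homozygous reference (a missing parental genotype never certifies
  absence, even under the relaxed missing policy);
- **homozygous recessive** — every affected sibling homozygous alternate, both
  parents heterozygous;
- **trans compound heterozygote** — for every unordered pair of distinct
  variants in one gene: all affected siblings heterozygous at both, one parent
  heterozygous at exactly one variant and carrying zero copies of the other,
  the other parent the mirror image. The parental constraint simultaneously
  phases the pair in trans and enforces that neither unaffected parent carries
  both alleles, as full penetrance requires. `allow_cis_unknown=True` relaxes
  the parental clause to "each variant present in ≥ 1 parent" for pedigrees
  without informative parental genotypes.

Genotypes are unphased throughout; phase is inferred only from parents.
Missing genotypes disqualify a variant from a model by default
(`missing_policy="strict"`); `"compatible"` treats missing as consistent with
whatever the model requires. The family filter defaults to MAF ≤ 1%
(inclusive) and the protein-altering consequence rule, synonymous excluded —
"potential protein-altering" is read as excluding synonymous changes.

No significance statistic is attached to family hits; segregation evidence is
reported qualitatively, as is standard for a single pedigree.

## Genotype-frequency stratification (`genotype_assoc`)

For individually genotyped SNPs in a severity-stratified cohort (severe ⇔
Cobb angle ≥ 40°), genotype classes are labelled from ref/alt alleles
(AA/AG/GG) in hom-ref, het, hom-alt order. Samples missing a genotype at a SNP
are excluded from that SNP's stratum total, so n varies per SNP. Display
percentages are 100·count/n rounded **half-up** to one decimal (matching how
such tables are printed: 4.504 → 4.5, 2.678 → 2.7); they are derived on
demand and never stored. An optional two-tailed Fisher test compares carrier
(het + hom-alt) frequencies between two strata; the underlying study design
reports these tables descriptively, so the test is a convenience, not a claim.

## Synthetic data (`synthetic_data`)

The generator reproduces the statistical structure the pipeline assumes —
nothing more. Cohort model: for each (gene, sample) pair a qualifying carrier
event occurs with probability `baseline_rate` (default 0.01 per gene per
sample), multiplied by the gene's enrichment factor for cases of genes in
`enriched_genes`; each event places one heterozygous observation on a site
from the gene's pool (`variants_per_gene` = 3 by default;
`multi_variant_rate` optionally doubles an event onto two distinct sites to
exercise the allele-counting rule). Default cohort sizes are 73 cases / 70
controls, the discovery-stage design. Sites draw consequence class from a
configurable mix (default: 75% protein-altering, 15% synonymous, 10%
near-intronic with exon distances straddling the 10 bp window), population
frequencies from a rare/common mixture (90% rare, 30% of rare sites absent
from all panels; common sites are genotyped binomially from their frequency
across all samples), REVEL from Beta(2, 3) for missense, and a 2% chance of
failing quality. Non-qualifying sites are generated on purpose so the filter
chain has real attrition to remove.

The **truth record** is tallied from the final genotype matrix (after
missingness) restricted to sites that qualify under the generator's own
cutoff, so a correct filter + collapse run must recover it exactly; tests
verify this with independent nested-loop oracles.

Family model: background variants segregate Mendelianly from parental
genotypes drawn at the site's population frequency; planted hits (at most one
gene per model; colliding requests are rejected) are constructed to satisfy
their model's definition, and missingness never touches planted columns. The
truth record also lists background genes that satisfy a model by chance,
found by re-scanning the generated genotypes.

All draws flow from one `numpy` generator stream per config; identical config
and seed give byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium, a realistic
site-frequency spectrum, sequencing or genotyping error, population
structure, or relatedness beyond the one nuclear family. Passing tests on
synthetic cohorts therefore demonstrate the correctness of counting,
filtering and testing logic under the assumed model — not robustness to the
confounders real exome data carry.

## Statistical properties verified

- **Exact-test correctness**: both Fisher tails agree with a full enumeration
  oracle (exact integer combinatorics) over *all* 2×2 tables with total ≤ 40.
- **Null calibration**: on unenriched synthetic cohorts (500 genes × 20
  seeds, 73/70), the fraction of genes with one-tailed p < 0.05 stays below
  0.05 + 3 Monte-Carlo standard errors. Empirically the fraction is near
  zero: with ~1 expected observation per gene the exact test is deeply
  conservative, which is the expected behaviour for sparse collapsed counts.
- **Planted-signal recovery**: a gene enriched ×6 in cases with 15 expected
  case observations (baseline 0.026, 96 vs 96) ranks first by the one-tailed
  test among a 24-gene candidate panel — the replication-stage design — in
  ≥ 90% of 50 seeds (measured 94%). The panel size matters: with 100–200
  competing genes at exome-like baseline rates, top-1 recovery drops to
  ~70–85%, because among hundreds of sparse Fisher tests some null gene
  occasionally produces a more extreme table (two-tailed ranking in
  particular rewards control-only depletion patterns). This is an inherent
  property of ranking sparse exact tests, and is precisely why two-stage
  designs re-test candidates in an independent cohort rather than trusting a
  single exome-wide ranking.

## Numerical and design notes

- p-values are kept in full double precision; display rounding (3 decimals
  for discovery tables, 2 for replication) happens only in output columns.
- Coordinates are 1-based point positions as in VCF; multi-allelic records
  are split into biallelic keys at read time and annotations join on
  (chrom, pos, ref, alt) — rsids are informational only, since they can be
  merged or renamed across dbSNP builds.
- Sex chromosomes receive no ploidy adjustment: dosages are taken as given
  (the gene under study here is autosomal).
- Missing-dosage policy is owned by the consuming module, not the readers:
  collapse counts missing as zero contribution; segregation disqualifies (or
  relaxes, per flag); genotype tables exclude from n.
- In burden mode the allele count could in principle exceed the cohort size
  for an extremely multi-variant gene; the 2×2 construction then fails fast
  with a pointer to carrier mode rather than producing a negative cell.
- Problem sizes in the test and acceptance suites (500-gene null panels, 20–50
  seeds, enumeration to table total 40) were chosen as the smallest sizes at
  which the Monte-Carlo bounds quoted above are meaningful.

## Known limitations

- No covariate adjustment, relatedness correction or population-structure
  modelling; no weighted or variance-component (SKAT-style) burden tests.
- Quality filtering trusts the upstream `quality_pass` flag entirely.
- The compound-heterozygote scan requires genotyped parents (or the explicit
  `allow_cis_unknown` relaxation); it never phases from reads.
- The two-sided Fisher convention is minimum-likelihood; studies using
  2×one-tailed or central conventions will differ in borderline tables.
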