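"""Synthetic cohort and family generators with recorded ground truth.

The generators emulate the statistical structure the pipeline assumes, not
sequencing itself: no linkage disequilibrium, site-frequency spectrum, or
error model — just per-gene carrier processes, annotation distributions, and
Mendelian transmission in a nuclear family.

Cohort model: for every (gene, sample) pair a qualifying-variant carrier event
occurs with probability ``baseline_rate`` (multiplied by the gene's enrichment
factor for case samples in ``enriched_genes``). Each event places one
heterozygous observation on a site drawn from the gene's site pool. Sites get
consequence class, population frequencies and REVEL scores from configurable
distributions, so a realistic fraction of generated sites is deliberately
*non-qualifying* (synonymous, common, low-quality, or intronic beyond the
splice window) and must be removed by the filter chain. The truth record
tallies, from the final genotype matrix, the per-gene case/control allele
burden over qualifying sites — exactly what a correct filter + collapse run
should recover.

Family model: background variants segregate Mendelianly from randomly drawn
parental genotypes; planted hits are constructed to satisfy one inheritance
model each. All randomness flows from one seeded generator stream, and equal
config + seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rare_filter import FilterConfig, is_protein_altering, is_rare
from .segregation import (
    FamilyGenotypes,
    find_compound_het,
    find_de_novo_shared,
    find_recessive_homozygous,
)
from .variant_io import (
    AnnotatedVariant,
    CohortDataset,
    Pedigree,
    PedigreeMember,
    VariantKey,
    write_annotation_table,
)

__all__ = [
    "MafDistribution",
    "RevelDistribution",
    "SimulationConfig",
    "FamilySimulationConfig",
    "CohortTruth",
    "FamilyTruth",
    "simulate_cohort",
    "generate_cohort",
    "simulate_family",
    "generate_family",
    "fixture_study_family",
    "write_vcf",
    "write_pedigree",
]

# Default consequence mix for generated sites. Mass on synonymous and
# (partly out-of-window) near-intronic classes gives the filter real attrition.
DEFAULT_CONSEQUENCE_MIX: dict[str, float] = {
    "missense": 0.55,
    "frameshift": 0.05,
    "stop_gain": 0.04,
    "stop_loss": 0.01,
    "inframe_indel": 0.05,
    "splice_region": 0.05,
    "near_intronic": 0.10,
    "synonymous": 0.15,
}

_BASES = ("A", "C", "G", "T")
_MAF_SOURCES = ("1000G_EUR", "ESP_EA", "gnomAD_genomes", "gnomAD_exomes")


@dataclass(frozen=True)
class MafDistribution:
    """Population-frequency model for generated sites.

    ``rare_mass`` is the probability a site is rare (below the cutoff);
    rare sites draw MAF ~ U(0, 0.8 * cutoff) and are, with probability
    ``absent_mass``, absent from every panel (novel variants). Common sites
    draw MAF ~ U(2 * cutoff, common_max).
    """

    rare_mass: float = 0.9
    absent_mass: float = 0.3
    common_max: float = 0.05


@dataclass(frozen=True)
class RevelDistribution:
    """Beta(alpha, beta) REVEL scores for missense sites; other classes follow
    the scoring convention (truncating and intronic sites unassigned)."""

    alpha: float = 2.0
    beta: float = 3.0


@dataclass(frozen=True)
class SimulationConfig:
    """All cohort-generator knobs.

    Defaults mirror the discovery-stage study conditions: 73 cases, 70
    controls, rarity cutoff 1%. ``baseline_rate`` is the per-sample per-gene
    probability of one qualifying carrier event; ``enriched_genes`` maps gene
    symbols to the multiplicative factor applied to that rate in cases.
    ``multi_variant_rate`` is the probability a carrier event doubles into two
    distinct sites in the same gene (exercises the gene-allele counting rule).
    """

    n_cases: int = 73
    n_controls: int = 70
    n_genes: int = 200
    variants_per_gene: int = 3
    baseline_rate: float = 0.01
    enriched_genes: dict[str, float] = field(default_factory=dict)
    maf_cutoff: float = 0.01
    maf_distribution: MafDistribution = MafDistribution()
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    revel_distribution: RevelDistribution = RevelDistribution()
    missing_rate: float = 0.0
    multi_variant_rate: float = 0.0
    low_quality_rate: float = 0.02
    severe_fraction: float = 0.68
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "missing_rate", "multi_variant_rate",
                     "low_quality_rate", "severe_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if any(f < 0 for f in self.enriched_genes.values()):
            raise ValueError("enrichment factors must be >= 0")
        total = sum(self.consequence_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"consequence_mix must sum to 1, got {total}")

    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class CohortTruth:
    """Planted structure of a generated cohort.

    ``case_burden``/``control_burden`` are per-gene qualifying allele counts
    tallied from the emitted genotype matrix (after missingness), restricted
    to sites that qualify under the generator's own filter definition — the
    counts a correct filter + collapse run must reproduce exactly.
    """

    enriched_genes: dict[str, float]
    case_burden: dict[str, int]
    control_burden: dict[str, int]
    qualifying_variants: list[str]
    n_cases: int
    n_controls: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def _draw_site(
    rng: np.random.Generator,
    key: VariantKey,
    gene: str,
    config: SimulationConfig,
) -> AnnotatedVariant:
    mix = config.consequence_mix
    classes = sorted(mix)
    consequence = str(rng.choice(classes, p=[mix[c] for c in classes]))
    dist = config.maf_distribution

    maf_by_source: dict[str, float] = {}
    if rng.random() < dist.rare_mass:
        if rng.random() >= dist.absent_mass:  # observed rare variant
            freq = float(rng.uniform(0.0, 0.8 * config.maf_cutoff))
            for source in _MAF_SOURCES:
                if rng.random() < 0.7:
                    maf_by_source[source] = round(freq * rng.uniform(0.8, 1.2), 6)
    else:  # common variant: present everywhere
        freq = float(rng.uniform(2 * config.maf_cutoff, dist.common_max))
        for source in _MAF_SOURCES:
            maf_by_source[source] = round(min(freq * rng.uniform(0.9, 1.1), 1.0), 6)

    revel = None
    if consequence in {"missense", "inframe_indel"}:
        revel = round(float(rng.beta(config.revel_distribution.alpha,
                                     config.revel_distribution.beta)), 3)
    exon_distance = None
    if consequence == "near_intronic":
        exon_distance = int(rng.integers(1, 31))  # some in, some out of the 10 bp window

    return AnnotatedVariant(
        key=key,
        gene=gene,
        consequence=consequence,
        maf_by_source=maf_by_source,
        revel=revel,
        quality_pass=bool(rng.random() >= config.low_quality_rate),
        exon_distance=exon_distance,
    )


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, CohortTruth]:
    """Generate an in-memory annotated cohort plus its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    samples = [f"CASE{i + 1:04d}" for i in range(config.n_cases)] + [
        f"CTRL{i + 1:04d}" for i in range(config.n_controls)
    ]
    phenotypes = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    severity: dict[str, str] = {}
    for s in samples:
        if phenotypes[s] == "control":
            severity[s] = "control"
        else:
            severity[s] = "severe" if rng.random() < config.severe_fraction else "moderate"

    # Site pools: variants_per_gene sites per gene on a synthetic contig.
    variants: list[AnnotatedVariant] = []
    site_ids_by_gene: dict[str, list[str]] = {}
    for g_index, gene in enumerate(genes):
        pool = []
        for s_index in range(config.variants_per_gene):
            pos = (g_index + 1) * 10_000 + s_index * 10 + 1
            ref, alt = _draw_alleles(rng)
            variant = _draw_site(rng, VariantKey("chrS", pos, ref, alt), gene, config)
            variants.append(variant)
            pool.append(variant.key.id)
        site_ids_by_gene[gene] = pool

    matrix = pd.DataFrame(
        0.0, index=pd.Index(samples, name="sample"), columns=[v.key.id for v in variants]
    )

    # Common sites: genotypes drawn binomially from their panel frequency.
    qualifies = _qualifying_map(variants, config)
    for variant in variants:
        freqs = variant.maf_by_source
        if freqs and max(freqs.values()) >= config.maf_cutoff:
            dosages = rng.binomial(2, max(freqs.values()), size=len(samples))
            matrix[variant.key.id] = dosages.astype(float)

    # Carrier process on each gene's pool (enriched in cases where configured).
    for gene in genes:
        factor = config.enriched_genes.get(gene, 1.0)
        pool = site_ids_by_gene[gene]
        for sample in samples:
            rate = config.baseline_rate * (factor if phenotypes[sample] == "case" else 1.0)
            if rng.random() >= min(rate, 1.0):
                continue
            if config.multi_variant_rate > 0 and rng.random() < config.multi_variant_rate:
                chosen = list(rng.choice(pool, size=min(2, len(pool)), replace=False))
            else:
                chosen = [pool[int(rng.integers(len(pool)))]]
            for vid in chosen:
                matrix.at[sample, vid] = min(matrix.at[sample, vid] + 1.0, 2.0)

    if config.missing_rate > 0:
        mask = rng.random(matrix.shape) < config.missing_rate
        matrix = matrix.mask(mask)

    # Drop monomorphic sites: a VCF only contains observed variants.
    observed = [vid for vid in matrix.columns if np.nansum(matrix[vid].to_numpy()) > 0]
    variants = [v for v in variants if v.key.id in set(observed)]
    matrix = matrix[observed]

    dataset = CohortDataset(
        variants=variants, genotypes=matrix, phenotypes=phenotypes, severity=severity
    )
    truth = _tally_truth(dataset, qualifies, config)
    return dataset, truth


def _qualifying_map(variants: Sequence[AnnotatedVariant], config: SimulationConfig) -> dict[str, bool]:
    reference = FilterConfig(maf_cutoff=config.maf_cutoff)
    return {
        v.key.id: (v.quality_pass and is_protein_altering(v, reference) and is_rare(v, reference))
        for v in variants
    }


def _tally_truth(
    dataset: CohortDataset, qualifies: dict[str, bool], config: SimulationConfig
) -> CohortTruth:
    gene_of = {v.key.id: v.gene for v in dataset.variants}
    case_burden: dict[str, int] = {}
    control_burden: dict[str, int] = {}
    cases = set(dataset.cases)
    for vid in dataset.genotypes.columns:
        if not qualifies.get(vid, False):
            continue
        gene = gene_of[vid]
        for sample, dosage in dataset.genotypes[vid].items():
            if np.isfinite(dosage) and dosage > 0:
                bucket = case_burden if sample in cases else control_burden
                bucket[gene] = bucket.get(gene, 0) + int(dosage)
    return CohortTruth(
        enriched_genes=dict(config.enriched_genes),
        case_burden=case_burden,
        control_burden=control_burden,
        qualifying_variants=sorted(
            vid for vid in dataset.genotypes.columns if qualifies.get(vid, False)
        ),
        n_cases=dataset.n_cases,
        n_controls=dataset.n_controls,
        seed=config.seed,
    )


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_vcf(
    samples: Sequence[str],
    variants: Sequence[VariantKey],
    dosages: pd.DataFrame,
    path: str | Path,
) -> None:
    """Emit a minimal VCF v4.2 with GT-only FORMAT fields.

    One biallelic record per variant, sorted by (chrom, pos, ref, alt).
    Dosage 0/1/2 becomes 0/0, 0/1, 1/1; NaN becomes ./. .
    """
    ordered = sorted(variants)
    contigs: list[str] = []
    for key in ordered:
        if key.chrom not in contigs:
            contigs.append(key.chrom)
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = ["##fileformat=VCFv4.2", "##source=rareburden-simulator"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for key in ordered:
        column = dosages[key.id]
        calls = []
        for sample in samples:
            value = column[sample]
            calls.append("./." if not np.isfinite(value) else gt[int(value)])
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pedigree(pedigree: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    lines = []
    for m in pedigree.members:
        lines.append(
            "\t".join(
                [
                    family_id,
                    m.individual_id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    sex_code[m.sex],
                    "2" if m.affected else "1",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_phenotypes(dataset: CohortDataset, path: Path) -> None:
    rows = ["sample_id\tphenotype\tseverity"]
    for sample in dataset.samples:
        stratum = dataset.severity[sample] if dataset.severity else ""
        rows.append(f"{sample}\t{dataset.phenotypes[sample]}\t{stratum}")
    path.write_text("\n".join(rows) + "\n")


def generate_cohort(config: SimulationConfig, out_dir: str | Path) -> CohortTruth:
    """Generate a cohort and write cohort.vcf, annotations.tsv, phenotypes.tsv
    and truth.json under ``out_dir``. Returns the truth record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_cohort(config)
    write_vcf(dataset.samples, [v.key for v in dataset.variants], dataset.genotypes,
              out / "cohort.vcf")
    write_annotation_table(dataset.variants, out / "annotations.tsv")
    _write_phenotypes(dataset, out / "phenotypes.tsv")
    truth.to_json(out / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySimulationConfig:
    """Generator knobs for a two-parent nuclear family.

    The default shape matches the study family: three affected siblings and
    no unaffected ones. ``plant_models`` names the inheritance models to plant
    (one gene each, assigned from the end of the gene list so background genes
    keep low indices); contradictory requests — the same gene planted twice —
    are rejected.
    """

    n_affected: int = 3
    n_unaffected: int = 0
    n_genes: int = 30
    variants_per_gene: int = 3
    background_maf_max: float = 0.008
    maf_cutoff: float = 0.01
    plant_models: tuple[str, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_affected < 1:
            raise ValueError("need at least one affected sibling")
        bad = [m for m in self.plant_models if m not in ("de_novo", "hom_recessive", "compound_het")]
        if bad:
            raise ValueError(f"unknown plant models: {bad}")
        if len(set(self.plant_models)) != len(self.plant_models):
            raise ValueError("cannot plant the same model twice (gene collision)")


@dataclass
class FamilyTruth:
    """Planted hits per model plus background genes that happen to satisfy a
    model by chance (found by re-scanning the emitted genotypes)."""

    planted: dict[str, str]  # model -> gene
    chance_consistent: dict[str, list[str]]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def _family_pedigree(config: FamilySimulationConfig) -> Pedigree:
    members = [
        PedigreeMember("FATHER", None, None, "male", False),
        PedigreeMember("MOTHER", None, None, "female", False),
    ]
    for i in range(config.n_affected):
        members.append(PedigreeMember(f"SIB{i + 1}", "FATHER", "MOTHER", "female", True))
    for i in range(config.n_unaffected):
        members.append(PedigreeMember(f"UNAFF{i + 1}", "FATHER", "MOTHER", "female", False))
    return Pedigree(members=members)


def simulate_family(config: FamilySimulationConfig) -> tuple[FamilyGenotypes, FamilyTruth]:
    """Generate a family dataset with Mendelian background and planted hits."""
    rng = np.random.default_rng(config.seed)
    pedigree = _family_pedigree(config)
    individuals = [m.individual_id for m in pedigree.members]
    children = [m.individual_id for m in pedigree.members if m.father_id is not None]
    sibs = [m.individual_id for m in pedigree.affected]

    genes = [f"FGENE{i + 1:03d}" for i in range(config.n_genes)]
    planted_gene = {
        model: genes[-(i + 1)] for i, model in enumerate(config.plant_models)
    }
    planted_genes = set(planted_gene.values())

    variants: list[AnnotatedVariant] = []
    rows: dict[str, dict[str, float]] = {ind: {} for ind in individuals}

    def add_variant(gene: str, g_index: int, s_index: int, *, consequence: str = "missense",
                    maf: Optional[float] = None) -> AnnotatedVariant:
        pos = (g_index + 1) * 10_000 + s_index * 10 + 1
        ref, alt = _draw_alleles(rng)
        freq = maf if maf is not None else float(rng.uniform(0.0005, config.background_maf_max))
        variant = AnnotatedVariant(
            key=VariantKey("chrF", pos, ref, alt),
            gene=gene,
            consequence=consequence,
            maf_by_source={"1000G_EUR": round(freq, 6), "gnomAD_genomes": round(freq, 6)},
            revel=round(float(rng.beta(2, 3)), 3) if consequence == "missense" else None,
            quality_pass=True,
        )
        variants.append(variant)
        return variant

    # Background: parents drawn from MAF, children transmit Mendelianly.
    for g_index, gene in enumerate(genes):
        if gene in planted_genes:
            continue
        for s_index in range(config.variants_per_gene):
            variant = add_variant(gene, g_index, s_index)
            freq = variant.maf_by_source["1000G_EUR"]
            father_alleles = rng.binomial(1, freq, size=2)
            mother_alleles = rng.binomial(1, freq, size=2)
            rows["FATHER"][variant.key.id] = float(father_alleles.sum())
            rows["MOTHER"][variant.key.id] = float(mother_alleles.sum())
            for child in children:
                paternal = father_alleles[int(rng.integers(2))]
                maternal = mother_alleles[int(rng.integers(2))]
                rows[child][variant.key.id] = float(paternal + maternal)

    # Planted hits, one gene per requested model.
    for model, gene in planted_gene.items():
        g_index = genes.index(gene)
        if model == "compound_het":
            v1 = add_variant(gene, g_index, 0)
            v2 = add_variant(gene, g_index, 1)
            for ind in individuals:
                rows[ind][v1.key.id] = 0.0
                rows[ind][v2.key.id] = 0.0
            rows["FATHER"][v1.key.id] = 1.0
            rows["MOTHER"][v2.key.id] = 1.0
            for sib in sibs:
                rows[sib][v1.key.id] = 1.0
                rows[sib][v2.key.id] = 1.0
        else:
            v = add_variant(gene, g_index, 0)
            sib_dosage = 1.0 if model == "de_novo" else 2.0
            parent_dosage = 0.0 if model == "de_novo" else 1.0
            for ind in individuals:
                rows[ind][v.key.id] = parent_dosage if ind in ("FATHER", "MOTHER") else 0.0
            for sib in sibs:
                rows[sib][v.key.id] = sib_dosage

    matrix = pd.DataFrame(
        [[rows[ind].get(v.key.id, 0.0) for v in variants] for ind in individuals],
        index=pd.Index(individuals, name="individual"),
        columns=[v.key.id for v in variants],
    )
    if config.missing_rate > 0:
        # Missingness never touches planted columns: the truth must stay exact.
        planted_cols = {
            vid for vid in matrix.columns
            if any(v.key.id == vid and v.gene in planted_genes for v in variants)
        }
        mask = rng.random(matrix.shape) < config.missing_rate
        for j, col in enumerate(matrix.columns):
            if col in planted_cols:
                mask[:, j] = False
        matrix = matrix.mask(mask)

    # Keep only sites observed in the family (a VCF holds variant sites only).
    observed = [c for c in matrix.columns if np.nansum(matrix[c].to_numpy()) > 0]
    variants = [v for v in variants if v.key.id in set(observed)]
    matrix = matrix[observed]

    family = FamilyGenotypes(pedigree=pedigree, variants=variants, dosages=matrix)
    truth = FamilyTruth(
        planted=dict(planted_gene),
        chance_consistent=_rescan_chance_hits(family, planted_gene),
        seed=config.seed,
    )
    return family, truth


def _rescan_chance_hits(
    family: FamilyGenotypes, planted: dict[str, str]
) -> dict[str, list[str]]:
    finders = {
        "de_novo": find_de_novo_shared,
        "hom_recessive": find_recessive_homozygous,
        "compound_het": find_compound_het,
    }
    out: dict[str, list[str]] = {}
    for model, finder in finders.items():
        genes = sorted({h.gene for h in finder(family)})
        out[model] = [g for g in genes if planted.get(model) != g]
    return out


def generate_family(config: FamilySimulationConfig, out_dir: str | Path) -> FamilyTruth:
    """Generate a family and write family.vcf, family.ped, annotations.tsv and
    truth.json under ``out_dir``. Returns the truth record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    family, truth = simulate_family(config)
    write_vcf(list(family.dosages.index), [v.key for v in family.variants],
              family.dosages, out / "family.vcf")
    write_pedigree(family.pedigree, out / "family.ped")
    write_annotation_table(family.variants, out / "annotations.tsv")
    truth.to_json(out / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# The study family, as a deterministic fixture
# ---------------------------------------------------------------------------


def fixture_study_family() -> FamilyGenotypes:
    """Deterministic fixture mirroring the published multiplex family.

    Three affected sisters are compound heterozygous for two rare missense
    FAT3 variants — chr11:92086828 T>C (p.L517S, rs139595720, REVEL 0.303,
    gnomAD genomes MAF 0.0054) and chr11:92624235 C>T (p.L4544F, rs187159256,
    REVEL 0.223, MAF 0.0035) — with each unaffected parent a single
    heterozygote for one of the two. Decoy variants violate each model clause
    in turn: a cis pair carried by one parent, a shared-het variant also
    present in a parent (not de novo), a homozygous-sibling variant with a
    homozygous parent (not recessive), a common variant pair and a synonymous
    pair that only the filters remove.
    """
    pedigree = Pedigree(
        members=[
            PedigreeMember("FATHER", None, None, "male", False),
            PedigreeMember("MOTHER", None, None, "female", False),
            PedigreeMember("SIB1", "FATHER", "MOTHER", "female", True),
            PedigreeMember("SIB2", "FATHER", "MOTHER", "female", True),
            PedigreeMember("SIB3", "FATHER", "MOTHER", "female", True),
        ]
    )

    def fat3(pos: int, ref: str, alt: str, protein: str, rsid: str, revel: float,
             maf: float) -> AnnotatedVariant:
        return AnnotatedVariant(
            key=VariantKey("chr11", pos, ref, alt),
            gene="FAT3",
            consequence="missense",
            maf_by_source={"gnomAD_genomes": maf},
            revel=revel,
            protein_change=protein,
            rsid=rsid,
        )

    v_l517s = fat3(92086828, "T", "C", "p.L517S", "rs139595720", 0.303, 0.0054)
    v_l4544f = fat3(92624235, "C", "T", "p.L4544F", "rs187159256", 0.223, 0.0035)

    def decoy(gene: str, pos: int, consequence: str = "missense",
              maf: float = 0.002) -> AnnotatedVariant:
        return AnnotatedVariant(
            key=VariantKey("chrF", pos, "A", "G"),
            gene=gene,
            consequence=consequence,
            maf_by_source={"gnomAD_genomes": maf},
            revel=0.5 if consequence == "missense" else None,
        )

    cis_1 = decoy("DECOYCIS", 1001)
    cis_2 = decoy("DECOYCIS", 1011)
    not_denovo = decoy("DECOYDN", 2001)
    partial_hom = decoy("DECOYHOM", 3001)
    common_1 = decoy("DECOYCOMMON", 4001, maf=0.05)
    common_2 = decoy("DECOYCOMMON", 4011, maf=0.08)
    syn_1 = decoy("DECOYSYN", 5001, consequence="synonymous")
    syn_2 = decoy("DECOYSYN", 5011, consequence="synonymous")

    variants = [v_l517s, v_l4544f, cis_1, cis_2, not_denovo, partial_hom,
                common_1, common_2, syn_1, syn_2]
    individuals = ["FATHER", "MOTHER", "SIB1", "SIB2", "SIB3"]
    dosage = {
        # trans compound het in FAT3: father carries L517S, mother L4544F.
        v_l517s.key.id: {"FATHER": 1, "MOTHER": 0, "SIB1": 1, "SIB2": 1, "SIB3": 1},
        v_l4544f.key.id: {"FATHER": 0, "MOTHER": 1, "SIB1": 1, "SIB2": 1, "SIB3": 1},
        # cis pair: both from the father — sibs het at both, but not trans.
        cis_1.key.id: {"FATHER": 1, "MOTHER": 0, "SIB1": 1, "SIB2": 1, "SIB3": 1},
        cis_2.key.id: {"FATHER": 1, "MOTHER": 0, "SIB1": 1, "SIB2": 1, "SIB3": 1},
        # shared het but inherited: present in the mother, so not de novo.
        not_denovo.key.id: {"FATHER": 0, "MOTHER": 1, "SIB1": 1, "SIB2": 1, "SIB3": 1},
        # hom in two sibs only, and the father is homozygous, not het.
        partial_hom.key.id: {"FATHER": 2, "MOTHER": 1, "SIB1": 2, "SIB2": 2, "SIB3": 1},
        # a perfect trans pair that is too common to qualify.
        common_1.key.id: {"FATHER": 1, "MOTHER": 0, "SIB1": 1, "SIB2": 1, "SIB3": 1},
        common_2.key.id: {"FATHER": 0, "MOTHER": 1, "SIB1": 1, "SIB2": 1, "SIB3": 1},
        # a perfect trans pair that is synonymous.
        syn_1.key.id: {"FATHER": 1, "MOTHER": 0, "SIB1": 1, "SIB2": 1, "SIB3": 1},
        syn_2.key.id: {"FATHER": 0, "MOTHER": 1, "SIB1": 1, "SIB2": 1, "SIB3": 1},
    }
    matrix = pd.DataFrame(
        [[float(dosage[v.key.id][ind]) for v in variants] for ind in individuals],
        index=pd.Index(individuals, name="individual"),
        columns=[v.key.id for v in variants],
    )
    return FamilyGenotypes(pedigree=pedigree, variants=variants, dosages=matrix)
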