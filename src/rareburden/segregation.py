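"""Mendelian segregation scanning in a multiplex family.

Given a nuclear pedigree with unaffected parents and one or more affected
siblings, three fully penetrant inheritance models are scanned over the
qualifying variants:

* **shared de novo** — every affected sibling heterozygous, both parents
  explicitly homozygous reference;
* **homozygous recessive** — every affected sibling homozygous alternate,
  both parents heterozygous;
* **trans compound heterozygote** — two distinct variants in one gene, every
  affected sibling heterozygous at both, one parent heterozygous at exactly
  one of them and carrying zero copies of the other (so the two alleles are
  on opposite haplotypes and no unaffected parent carries both).

Genotypes are unphased; phase for the compound-heterozygote model is inferred
entirely from the parental genotypes. By default a missing genotype in any
required individual disqualifies a variant from a model (conservative); the
``missing_policy="compatible"`` relaxation treats missing as compatible with
whatever the model requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .rare_filter import REPLICATION_MAF_SOURCES, FilterConfig, FilterTrace, apply_filters
from .variant_io import AnnotatedVariant, CohortDataset, Pedigree, ValidationError, VariantKey

__all__ = [
    "FamilyGenotypes",
    "SegregationHit",
    "FamilyAnalysisReport",
    "find_de_novo_shared",
    "find_recessive_homozygous",
    "find_compound_het",
    "run_family_analysis",
]

MODELS = ("de_novo", "hom_recessive", "compound_het")


@dataclass
class FamilyGenotypes:
    """Pedigree plus a per-individual dosage matrix over annotated variants.

    ``dosages`` is indexed by individual id with one column per variant id.
    Every pedigree member must have a dosage row and at least one member must
    be affected.
    """

    pedigree: Pedigree
    variants: list[AnnotatedVariant]
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        for m in self.pedigree.members:
            if m.individual_id not in self.dosages.index:
                raise ValidationError(f"no genotypes for pedigree member {m.individual_id}")
        if not self.pedigree.affected:
            raise ValidationError("pedigree has no affected members")
        known = {v.key.id for v in self.variants}
        unknown = [c for c in self.dosages.columns if c not in known]
        if unknown:
            raise ValidationError(f"dosage columns without annotation: {unknown[:5]}")

    def subset_variants(self, keep_ids) -> "FamilyGenotypes":
        keep = set(keep_ids)
        return FamilyGenotypes(
            pedigree=self.pedigree,
            variants=[v for v in self.variants if v.key.id in keep],
            dosages=self.dosages[[c for c in self.dosages.columns if c in keep]],
        )


@dataclass
class SegregationHit:
    """A gene consistent with one inheritance model, with its evidence."""

    gene: str
    model: str
    supporting_variants: list[VariantKey]
    per_individual_dosages: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        minimum = 2 if self.model == "compound_het" else 1
        if len(self.supporting_variants) < minimum:
            raise ValueError(f"{self.model} hit needs >= {minimum} variants")


@dataclass
class FamilyAnalysisReport:
    hits_by_model: dict[str, list[SegregationHit]]
    filter_trace: FilterTrace

    def genes(self, model: str) -> list[str]:
        return sorted({h.gene for h in self.hits_by_model.get(model, [])})


def _family_roles(family: FamilyGenotypes) -> tuple[list[str], list[str]]:
    """Return (affected sibling ids, parent ids) for a nuclear family.

    The affected members must share the same genotyped father and mother.
    """
    affected = family.pedigree.affected
    fathers = {m.father_id for m in affected}
    mothers = {m.mother_id for m in affected}
    if len(fathers) != 1 or len(mothers) != 1 or None in fathers or None in mothers:
        raise ValidationError(
            "segregation models need affected siblings sharing two genotyped parents"
        )
    father, mother = fathers.pop(), mothers.pop()
    return [m.individual_id for m in affected], [father, mother]


def _dosage(family: FamilyGenotypes, individual: str, vid: str) -> float:
    return float(family.dosages.at[individual, vid])


def _matches(value: float, required: int, missing_ok: bool) -> bool:
    if np.isnan(value):
        return missing_ok
    return int(value) == required


def find_de_novo_shared(
    family: FamilyGenotypes, missing_policy: str = "strict"
) -> list[SegregationHit]:
    """Variants heterozygous in every affected sibling and absent (dosage 0,
    not merely missing) in both parents."""
    return _scan_single_variant_model(family, model="de_novo", sib_dosage=1,
                                      parent_dosage=0, missing_policy=missing_policy)


def find_recessive_homozygous(
    family: FamilyGenotypes, missing_policy: str = "strict"
) -> list[SegregationHit]:
    """Variants homozygous alternate in every affected sibling with both
    parents heterozygous."""
    return _scan_single_variant_model(family, model="hom_recessive", sib_dosage=2,
                                      parent_dosage=1, missing_policy=missing_policy)


def _scan_single_variant_model(
    family: FamilyGenotypes,
    model: str,
    sib_dosage: int,
    parent_dosage: int,
    missing_policy: str,
) -> list[SegregationHit]:
    if missing_policy not in {"strict", "compatible"}:
        raise ValueError(f"missing_policy must be 'strict' or 'compatible': {missing_policy!r}")
    missing_ok = missing_policy == "compatible"
    sibs, parents = _family_roles(family)
    # De novo sharing demands positively observed 0/0 parents even under the
    # relaxed policy: a missing parental genotype can never certify absence.
    parent_missing_ok = missing_ok and model != "de_novo"
    gene_of = {v.key.id: v for v in family.variants}
    hits = []
    for vid in family.dosages.columns:
        ok = all(_matches(_dosage(family, s, vid), sib_dosage, missing_ok) for s in sibs) and all(
            _matches(_dosage(family, p, vid), parent_dosage, parent_missing_ok) for p in parents
        )
        if ok:
            variant = gene_of[vid]
            hits.append(
                SegregationHit(
                    gene=variant.gene,
                    model=model,
                    supporting_variants=[variant.key],
                    per_individual_dosages={
                        vid: {i: _dosage(family, i, vid) for i in sibs + parents}
                    },
                )
            )
    return hits


def find_compound_het(
    family: FamilyGenotypes,
    missing_policy: str = "strict",
    allow_cis_unknown: bool = False,
) -> list[SegregationHit]:
    """Gene-level trans compound-heterozygote hits.

    For each gene, every unordered pair of distinct variants (v1, v2) is
    tested: all affected siblings heterozygous at both; one parent
    heterozygous at v1 with zero copies of v2, the other heterozygous at v2
    with zero copies of v1. The parental constraint both phases the pair in
    trans and enforces that neither unaffected parent carries both alleles,
    as full penetrance requires. ``allow_cis_unknown=True`` relaxes the
    parental side to "each variant present in at least one parent" for
    families without informative parental genotypes. One hit per qualifying
    pair is returned.
    """
    missing_ok = missing_policy == "compatible"
    sibs, parents = _family_roles(family)
    p1, p2 = parents
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in family.variants:
        if v.key.id in family.dosages.columns:
            by_gene.setdefault(v.gene, []).append(v)

    def het(ind: str, vid: str) -> bool:
        return _matches(_dosage(family, ind, vid), 1, missing_ok)

    def absent(ind: str, vid: str) -> bool:
        return _matches(_dosage(family, ind, vid), 0, missing_ok)

    def carries(ind: str, vid: str) -> bool:
        value = _dosage(family, ind, vid)
        return missing_ok if np.isnan(value) else value >= 1

    hits = []
    for gene, variants in sorted(by_gene.items()):
        for va, vb in combinations(sorted(variants, key=lambda v: v.key), 2):
            ia, ib = va.key.id, vb.key.id
            if not all(het(s, ia) and het(s, ib) for s in sibs):
                continue
            if allow_cis_unknown:
                ok = (carries(p1, ia) or carries(p2, ia)) and (
                    carries(p1, ib) or carries(p2, ib)
                )
            else:
                trans_1 = het(p1, ia) and absent(p1, ib) and het(p2, ib) and absent(p2, ia)
                trans_2 = het(p2, ia) and absent(p2, ib) and het(p1, ib) and absent(p1, ia)
                ok = trans_1 or trans_2
            if ok:
                hits.append(
                    SegregationHit(
                        gene=gene,
                        model="compound_het",
                        supporting_variants=[va.key, vb.key],
                        per_individual_dosages={
                            vid: {i: _dosage(family, i, vid) for i in sibs + parents}
                            for vid in (ia, ib)
                        },
                    )
                )
    return hits


def run_family_analysis(
    family: FamilyGenotypes,
    config: Optional[FilterConfig] = None,
    missing_policy: str = "strict",
    allow_cis_unknown: bool = False,
) -> FamilyAnalysisReport:
    """Filter the family's variants and scan all three inheritance models.

    The default qualifying-variant definition for a family analysis is rare
    (MAF <= 1%, inclusive bound) and protein-altering, matching the cohort
    filters except for the inclusive rarity boundary.
    """
    if config is None:
        config = FilterConfig(
            maf_cutoff=0.01, maf_inclusive=True, maf_sources=REPLICATION_MAF_SOURCES
        )
    # Reuse the cohort filter by wrapping the family as an all-case dataset;
    # the filter only touches variant annotations, never phenotypes.
    pseudo = CohortDataset(
        variants=family.variants,
        genotypes=family.dosages,
        phenotypes={i: "case" for i in family.dosages.index},
    )
    filtered, trace = apply_filters(pseudo, config)
    scoped = family.subset_variants([v.key.id for v in filtered.variants])
    return FamilyAnalysisReport(
        hits_by_model={
            "de_novo": find_de_novo_shared(scoped, missing_policy),
            "hom_recessive": find_recessive_homozygous(scoped, missing_policy),
            "compound_het": find_compound_het(scoped, missing_policy, allow_cis_unknown),
        },
        filter_trace=trace,
    )
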