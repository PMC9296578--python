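"""Per-SNP genotype count tables stratified by disease severity.

For a genotyped replication cohort stratified into healthy controls, severe
cases (Cobb angle >= 40 degrees) and moderate cases (< 40 degrees), each SNP
is tabulated into genotype-class counts per stratum (hom-ref, het, hom-alt,
labelled from the ref/alt alleles, e.g. AA / AG / GG). Samples with a missing
genotype at a SNP are excluded from that SNP's stratum totals, so n varies by
SNP. Percentages are display values — 100 * count / n rounded half-up to one
decimal — and are always derived from the counts, never stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np

from .burden import fisher_exact_2x2
from .variant_io import CohortDataset, VariantKey

__all__ = [
    "GenotypeCountTable",
    "tabulate_genotypes",
    "genotype_percentages",
    "carrier_test_between_strata",
    "round_half_up",
]

logger = logging.getLogger(__name__)

DEFAULT_STRATA = ("control", "severe", "moderate")


@dataclass
class GenotypeCountTable:
    """Genotype-class counts for one SNP across severity strata.

    ``counts`` maps (stratum, genotype class) to a count; ``n`` maps each
    stratum to its genotyped total at this SNP. Per stratum the class counts
    sum to n. ``classes`` lists the genotype labels in hom-ref, het, hom-alt
    order.
    """

    key: VariantKey
    rsid: Optional[str]
    strata: tuple[str, ...]
    classes: tuple[str, str, str]
    counts: dict[tuple[str, str], int]
    n: dict[str, int]

    def __post_init__(self) -> None:
        for stratum in self.strata:
            total = sum(self.counts.get((stratum, g), 0) for g in self.classes)
            if total != self.n[stratum]:
                raise ValueError(
                    f"{self.key.id} {stratum}: class counts sum to {total}, n={self.n[stratum]}"
                )

    def carriers(self, stratum: str) -> int:
        """Samples carrying at least one alternate allele (het + hom-alt)."""
        return self.counts.get((stratum, self.classes[1]), 0) + self.counts.get(
            (stratum, self.classes[2]), 0
        )


def genotype_classes(key: VariantKey) -> tuple[str, str, str]:
    """Display labels (hom-ref, het, hom-alt) built from the ref/alt alleles."""
    return (key.ref + key.ref, key.ref + key.alt, key.alt + key.alt)


def tabulate_genotypes(
    dataset: CohortDataset,
    snps: Sequence[VariantKey],
    strata: Sequence[str] = DEFAULT_STRATA,
) -> list[GenotypeCountTable]:
    """Count genotype classes per severity stratum for the requested SNPs.

    Requires the dataset to carry severity strata. A requested SNP absent
    from the dataset raises ``KeyError`` naming it. A stratum in which every
    sample is missing at a SNP gets n = 0 (flagged in the log).
    """
    if dataset.severity is None:
        raise ValueError("dataset has no severity strata")
    rsid_of = {v.key: v.rsid for v in dataset.variants}
    tables = []
    for key in snps:
        if key.id not in dataset.genotypes.columns:
            raise KeyError(f"SNP {key.id} not present in dataset")
        classes = genotype_classes(key)
        counts: dict[tuple[str, str], int] = {}
        n: dict[str, int] = {s: 0 for s in strata}
        column = dataset.genotypes[key.id]
        for sample, dosage in column.items():
            stratum = dataset.severity[sample]
            if stratum not in n:
                continue
            if not np.isfinite(dosage):
                continue
            label = classes[int(dosage)]
            counts[(stratum, label)] = counts.get((stratum, label), 0) + 1
            n[stratum] += 1
        for stratum in strata:
            if n[stratum] == 0:
                logger.warning("%s: stratum %s fully missing (n=0)", key.id, stratum)
        tables.append(
            GenotypeCountTable(
                key=key,
                rsid=rsid_of.get(key),
                strata=tuple(strata),
                classes=classes,
                counts=counts,
                n=n,
            )
        )
    return tables


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (4.45 -> 4.5), as printed tables do."""
    exponent = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(exponent, rounding=ROUND_HALF_UP))


def genotype_percentages(table: GenotypeCountTable) -> dict[tuple[str, str], float]:
    """Display percentages 100 * count / n per (stratum, class), one decimal.

    Strata with n = 0 are omitted (and logged): a percentage of nothing is
    undefined, not zero.
    """
    out: dict[tuple[str, str], float] = {}
    for stratum in table.strata:
        n = table.n[stratum]
        if n == 0:
            logger.warning("%s: omitting stratum %s with n=0", table.key.id, stratum)
            continue
        for cls in table.classes:
            count = table.counts.get((stratum, cls), 0)
            out[(stratum, cls)] = round_half_up(100.0 * count / n, 1)
    return out


def carrier_test_between_strata(
    table: GenotypeCountTable, s1: str, s2: str
) -> float:
    """Two-tailed Fisher exact p comparing carrier frequency between two strata.

    Carriers are het + hom-alt samples. Degenerate tables (either stratum
    empty, or no carriers anywhere) give p = 1.
    """
    for s in (s1, s2):
        if s not in table.strata:
            raise KeyError(f"stratum {s!r} not in table for {table.key.id}")
    a = table.carriers(s1)
    c = table.carriers(s2)
    return fisher_exact_2x2(a, table.n[s1] - a, c, table.n[s2] - c, tail="two")
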