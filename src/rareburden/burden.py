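"""Collapsing gene burden test with exact statistics.

Qualifying variants are collapsed per gene into a *gene-allele burden count*:
every (sample, variant) observation contributes its allele dosage, so one
sample carrying two rare heterozygous variants in the same gene contributes
two, not one. Each gene's burden in cases versus controls is then tested on a
2x2 table against the cohort sizes — cells (burden, cohort_size - burden) per
group — with Fisher's exact test (two-tailed for an exome-wide discovery
screen, one-tailed for a directional replication of pre-selected candidates)
and the 1-df chi-square. The exome-wide significance threshold is the
Bonferroni bound 0.05 divided by the number of genes that harboured at least
one qualifying variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .variant_io import CohortDataset

__all__ = [
    "GeneBurdenRecord",
    "BurdenResult",
    "collapse_by_gene",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "significance_threshold",
    "run_stage",
    "rank_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneBurdenRecord:
    """Per-gene collapsed counts and test p-values.

    ``case_burden``/``control_burden`` are gene-allele counts (het = 1,
    hom-alt = 2, summed over samples and qualifying variants);
    ``case_carriers``/``control_carriers`` count distinct samples with at
    least one qualifying allele in the gene. p-value fields are ``None``
    until the record has been tested.
    """

    gene: str
    case_burden: int
    control_burden: int
    case_carriers: int
    control_carriers: int
    n_cases: int
    n_controls: int
    p_two_tailed: Optional[float] = None
    p_one_tailed: Optional[float] = None
    p_chisq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.case_carriers > self.n_cases or self.control_carriers > self.n_controls:
            raise ValueError(f"{self.gene}: more carriers than cohort members")
        if self.case_carriers > self.case_burden or self.control_carriers > self.control_burden:
            raise ValueError(f"{self.gene}: carriers exceed allele burden")


@dataclass
class BurdenResult:
    """One stage's burden scan: tested records, gene count, Bonferroni bound."""

    records: list[GeneBurdenRecord]
    n_genes_tested: int
    significance_threshold: float
    stage: str = "discovery"
    counting: str = "burden"
    trace_rows: list[dict] = field(default_factory=list)


def collapse_by_gene(dataset: CohortDataset) -> list[GeneBurdenRecord]:
    """Collapse a filtered dataset into per-gene burden and carrier counts.

    Only genes with at least one qualifying observation in cases or controls
    appear in the output (genes whose variants all filtered out, or were
    never observed, are not tested). Missing dosages contribute nothing.
    Output is sorted by gene symbol; p-value fields are left unset.
    """
    gene_of = {v.key.id: v.gene for v in dataset.variants}
    case_set = set(dataset.cases)
    burden: dict[str, dict[str, float]] = {}
    carriers: dict[str, dict[str, set]] = {}
    matrix = dataset.genotypes
    for vid in matrix.columns:
        gene = gene_of[vid]
        b = burden.setdefault(gene, {"case": 0, "control": 0})
        c = carriers.setdefault(gene, {"case": set(), "control": set()})
        column = matrix[vid]
        for sample, dosage in column.items():
            if not np.isfinite(dosage) or dosage <= 0:
                continue
            group = "case" if sample in case_set else "control"
            b[group] += dosage
            c[group].add(sample)

    records = []
    for gene in sorted(burden):
        case_b = int(burden[gene]["case"])
        control_b = int(burden[gene]["control"])
        if case_b + control_b < 1:
            continue
        records.append(
            GeneBurdenRecord(
                gene=gene,
                case_burden=case_b,
                control_burden=control_b,
                case_carriers=len(carriers[gene]["case"]),
                control_carriers=len(carriers[gene]["control"]),
                n_cases=dataset.n_cases,
                n_controls=dataset.n_controls,
            )
        )
    return records


def fisher_exact_2x2(a: int, b: int, c: int, d: int, tail: str = "two") -> float:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    ``tail="two"`` uses the minimum-likelihood two-sided convention (sum the
    point probabilities of all tables, under fixed margins, no more likely
    than the observed one), matching the common online calculators.
    ``tail="one"`` is the probability of a top-left cell >= a under fixed
    margins, i.e. the direction of case enrichment when a is the case count.
    A degenerate table (an all-zero margin) has p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if tail not in {"one", "two"}:
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    table = [[a, b], [c, d]]
    if a + b + c + d == 0:
        return 1.0
    alternative = "greater" if tail == "one" else "two-sided"
    return float(stats.fisher_exact(table, alternative=alternative).pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> float:
    """1-df chi-square p (no continuity correction) for [[a, b], [c, d]].

    Degenerate margins (a zero row or column total) give p = 1: there is no
    association to test.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    _, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(p)


def significance_threshold(n_genes_tested: int) -> float:
    """Bonferroni significance bound: 0.05 / number of genes tested."""
    if n_genes_tested < 1:
        raise ValueError("n_genes_tested must be >= 1")
    return 0.05 / n_genes_tested


def _table_for(record: GeneBurdenRecord, counting: str) -> tuple[int, int, int, int]:
    if counting == "burden":
        a, c = record.case_burden, record.control_burden
        if a > record.n_cases or c > record.n_controls:
            raise ValueError(
                f"{record.gene}: allele burden exceeds cohort size; "
                "use counting='carriers' for heavily multi-variant genes"
            )
    elif counting == "carriers":
        a, c = record.case_carriers, record.control_carriers
    else:
        raise ValueError(f"counting must be 'burden' or 'carriers', got {counting!r}")
    return a, record.n_cases - a, c, record.n_controls - c


def run_stage(
    dataset: CohortDataset,
    stage: str = "discovery",
    counting: str = "burden",
) -> BurdenResult:
    """Collapse and test every gene with at least one qualifying variant.

    The dataset must already be filtered with the stage's qualifying-variant
    definition. Both Fisher tails and the chi-square are computed for every
    gene; the stage determines the default report column (two-tailed Fisher
    for discovery, one-tailed for replication) and nothing else. With
    ``counting="burden"`` the 2x2 cells are gene-allele counts against cohort
    sizes; ``"carriers"`` uses distinct carrier counts instead (the two
    coincide when no sample carries two variants in one gene). Records are
    sorted by the stage's p-value with deterministic tie-breaks.
    """
    if stage not in {"discovery", "replication"}:
        raise ValueError(f"stage must be 'discovery' or 'replication', got {stage!r}")
    records = collapse_by_gene(dataset)
    for record in records:
        a, b, c, d = _table_for(record, counting)
        record.p_two_tailed = fisher_exact_2x2(a, b, c, d, tail="two")
        record.p_one_tailed = fisher_exact_2x2(a, b, c, d, tail="one")
        record.p_chisq = chi_square_2x2(a, b, c, d)
    n_genes = len(records)
    key = _ranking_key(stage)
    records.sort(key=key)
    return BurdenResult(
        records=records,
        n_genes_tested=n_genes,
        significance_threshold=significance_threshold(n_genes) if n_genes else float("nan"),
        stage=stage,
        counting=counting,
    )


def _ranking_key(stage: str):
    p_field = "p_two_tailed" if stage == "discovery" else "p_one_tailed"

    def key(record: GeneBurdenRecord):
        p = getattr(record, p_field)
        return (
            p if p is not None else 1.0,
            -record.case_burden,
            record.control_burden,
            record.gene,
        )

    return key


def rank_candidates(result: BurdenResult, k: int) -> list[str]:
    """Top-k candidate genes: p ascending, then case count descending, then
    control count ascending, then gene symbol. Asking for more genes than
    exist returns all of them (logged)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(result.records, key=_ranking_key(result.stage))
    if k > len(ordered):
        logger.info("requested top %d but only %d genes tested; returning all", k, len(ordered))
    return [record.gene for record in ordered[:k]]
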