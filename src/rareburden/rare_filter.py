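"""Variant-inclusion rules: quality, rarity, consequence class, REVEL score.

The filter chain mirrors the qualifying-variant definition used in two-stage
rare-variant association studies: drop poor-quality calls, keep only
protein-altering consequences (near-intronic sites within a configurable
window of an exon boundary count as potentially splice-affecting; synonymous
sites are excluded by default), require rarity across every consulted
population panel, and optionally require a REVEL pathogenicity score above a
threshold. Every stage records its attrition so a run can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .variant_io import (
    AnnotatedVariant,
    CohortDataset,
    TRUNCATING_CONSEQUENCES,
    ValidationError,
)

__all__ = [
    "FilterConfig",
    "FilterTrace",
    "REVEL_PRESETS",
    "DISCOVERY_MAF_SOURCES",
    "REPLICATION_MAF_SOURCES",
    "population_maf",
    "is_rare",
    "is_protein_altering",
    "effective_revel",
    "apply_filters",
]

# Named REVEL operating points: 0.3 is the threshold at which sensitivity and
# specificity are approximately equal in practice; 0.38 is the exact
# sensitivity=specificity crossing reported for the score's reference tables.
# Both ship because published analyses use either; neither is canonical here.
REVEL_PRESETS: dict[str, float] = {"balanced": 0.3, "sens_eq_spec": 0.38}

# Default panel lists per study stage. Discovery exomes were screened against
# 1000 Genomes European and Exome Sequencing Project European-American
# frequencies; the replication stage additionally consulted gnomAD genomes and
# exomes.
DISCOVERY_MAF_SOURCES = ("1000G_EUR", "ESP_EA")
REPLICATION_MAF_SOURCES = ("1000G_EUR", "gnomAD_genomes", "gnomAD_exomes")

PROTEIN_ALTERING = frozenset(
    {"missense", "stop_gain", "stop_loss", "frameshift", "inframe_indel", "splice_region"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Qualifying-variant definition.

    Parameters
    ----------
    maf_cutoff
        Rarity bound on the maximum population frequency, in (0, 1].
    maf_inclusive
        If False (default), a variant qualifies when MAF < cutoff (a variant
        at exactly 1% is removed); if True, MAF <= cutoff qualifies. The
        family analysis uses the inclusive form.
    maf_sources
        Ordered panel names consulted for rarity. A variant common in any
        consulted panel is not rare.
    keep_synonymous
        Retain synonymous variants (off by default; including them is known to
        dilute case-control burden differences).
    near_intron_window
        Maximum distance in bp from an exon boundary for a near-intronic
        variant to count as potentially splice-affecting. Default 10 bp, a
        conventional splice-region span.
    revel_threshold
        When set, require effective REVEL strictly above this value.
    revel_unassigned_policy
        "retain" (default) keeps variants with no effective REVEL score under
        REVEL filtering — near-intronic variants are never scored, and
        dropping them would silently undo their deliberate inclusion.
        "drop" removes them.
    truncating_revel_score
        Score imputed for protein-truncating classes (stop gain, frameshift),
        which REVEL does not cover; 1.0 = maximal predicted pathogenicity.
    """

    maf_cutoff: float = 0.01
    maf_inclusive: bool = False
    maf_sources: tuple[str, ...] = DISCOVERY_MAF_SOURCES
    keep_synonymous: bool = False
    near_intron_window: int = 10
    revel_threshold: Optional[float] = None
    revel_unassigned_policy: str = "retain"
    truncating_revel_score: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_cutoff <= 1.0):
            raise ValidationError(f"maf_cutoff must be in (0,1], got {self.maf_cutoff}")
        if self.near_intron_window < 0:
            raise ValidationError("near_intron_window must be >= 0")
        if self.revel_threshold is not None and not (0.0 <= self.revel_threshold <= 1.0):
            raise ValidationError(f"revel_threshold out of [0,1]: {self.revel_threshold}")
        if self.revel_unassigned_policy not in {"retain", "drop"}:
            raise ValidationError(
                f"revel_unassigned_policy must be 'retain' or 'drop', "
                f"got {self.revel_unassigned_policy!r}"
            )
        if not self.maf_sources:
            raise ValidationError("maf_sources must be non-empty")


@dataclass
class FilterTrace:
    """Ordered per-rule attrition: rule name -> (variants in, variants removed)."""

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def record(self, rule: str, n_in: int, n_removed: int) -> None:
        if n_removed < 0 or n_removed > n_in:
            raise ValueError(f"inconsistent trace for {rule}: in={n_in} removed={n_removed}")
        self.counts[rule] = (n_in, n_removed)

    @property
    def n_input(self) -> int:
        return next(iter(self.counts.values()))[0] if self.counts else 0

    @property
    def n_output(self) -> int:
        if not self.counts:
            return 0
        last_in, last_removed = list(self.counts.values())[-1]
        return last_in - last_removed

    def to_rows(self) -> list[dict]:
        return [
            {"rule": rule, "variants_in": n_in, "variants_removed": removed,
             "variants_out": n_in - removed}
            for rule, (n_in, removed) in self.counts.items()
        ]


def population_maf(variant: AnnotatedVariant, sources: tuple[str, ...] | list[str]) -> float:
    """Maximum allele frequency of the variant over the consulted panels.

    A variant absent from every consulted panel has frequency 0: unobserved in
    the reference populations means rare, which is what lets novel variants
    qualify. Taking the maximum is the conservative reading of screening
    against several panels at once — common anywhere means not rare.
    """
    if not sources:
        raise ValueError("sources must be non-empty")
    present = [variant.maf_by_source[s] for s in sources if s in variant.maf_by_source]
    return max(present) if present else 0.0


def is_rare(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """Rarity under the configured cutoff (strict by default: MAF >= cutoff fails)."""
    maf = population_maf(variant, config.maf_sources)
    return maf <= config.maf_cutoff if config.maf_inclusive else maf < config.maf_cutoff


def is_protein_altering(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """Whether the consequence class can plausibly alter the protein product.

    Missense, stop gain/loss, frameshift, in-frame indel and splice-region
    variants qualify unconditionally. Near-intronic variants qualify when
    their exon distance is within ``config.near_intron_window`` (an
    unannotated distance disqualifies: there is no evidence of splice
    proximity). Synonymous variants are excluded unless ``keep_synonymous``.
    """
    if variant.consequence in PROTEIN_ALTERING:
        return True
    if variant.consequence == "near_intronic":
        return (
            variant.exon_distance is not None
            and variant.exon_distance <= config.near_intron_window
        )
    if variant.consequence == "synonymous":
        return config.keep_synonymous
    return False


def effective_revel(variant: AnnotatedVariant, config: FilterConfig) -> Optional[float]:
    """REVEL score used for filtering, with the truncating-class imputation.

    Protein-truncating variants (stop gain, frameshift) are not scored by
    REVEL; they receive ``config.truncating_revel_score`` (default 1.0,
    maximal predicted pathogenicity) regardless of any annotated value.
    Otherwise the annotated score is returned as-is; intronic and
    splice-region variants with no annotation stay unassigned (``None``).
    """
    if variant.consequence in TRUNCATING_CONSEQUENCES:
        return config.truncating_revel_score
    return variant.revel


def apply_filters(
    dataset: CohortDataset, config: FilterConfig
) -> tuple[CohortDataset, FilterTrace]:
    """Apply the filter chain, returning the surviving dataset and its trace.

    Stage order: ``quality`` -> ``protein_altering`` -> ``rarity`` ->
    ``revel`` (last stage only when ``config.revel_threshold`` is set; the
    comparison is strict, score > threshold). The trace records
    (variants in, variants removed) for every stage that ran, so
    input - sum(removed) always equals the surviving count.
    """
    trace = FilterTrace()
    surviving = list(dataset.variants)

    def stage(name: str, predicate) -> None:
        nonlocal surviving
        n_in = len(surviving)
        kept = [v for v in surviving if predicate(v)]
        trace.record(name, n_in, n_in - len(kept))
        surviving = kept

    stage("quality", lambda v: v.quality_pass)
    stage("protein_altering", lambda v: is_protein_altering(v, config))
    stage("rarity", lambda v: is_rare(v, config))
    if config.revel_threshold is not None:
        def revel_pass(v: AnnotatedVariant) -> bool:
            score = effective_revel(v, config)
            if score is None:
                return config.revel_unassigned_policy == "retain"
            return score > config.revel_threshold

        stage("revel", revel_pass)

    filtered = dataset.subset_variants([v.key.id for v in surviving])
    return filtered, trace
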