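"""Two-stage study orchestration: discovery screen, candidate replication,
family segregation — with config validation and a machine-readable run report.

The two-stage design tests every gene exome-wide in a discovery cohort,
carries the top-k candidates (default 24) into an independent replication
cohort, and tests *only* those candidates there — the replication
multiple-testing base is therefore 0.05/k, not an exome-wide bound, and the
report surfaces that explicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import __version__
from .burden import BurdenResult, rank_candidates, run_stage, significance_threshold
from .rare_filter import (
    DISCOVERY_MAF_SOURCES,
    FilterConfig,
    REPLICATION_MAF_SOURCES,
    apply_filters,
)
from .variant_io import (
    CohortDataset,
    ValidationError,
    build_cohort,
    read_annotation_table,
    read_phenotype_table,
    read_vcf,
)

__all__ = ["RunReport", "load_cohort", "validate_config", "run_two_stage"]

logger = logging.getLogger(__name__)

_CONFIG_SCHEMA: dict[str, tuple] = {
    # key: (type, validator or None, description)
    "maf_cutoff": (float, lambda v: 0.0 < v <= 1.0, "frequency in (0,1]"),
    "maf_inclusive": (bool, None, "true/false"),
    "maf_sources": (list, lambda v: len(v) > 0, "non-empty list of panel names"),
    "keep_synonymous": (bool, None, "true/false"),
    "near_intron_window": (int, lambda v: v >= 0, "non-negative bp"),
    "revel_threshold": (float, lambda v: 0.0 <= v <= 1.0, "score in [0,1]"),
    "revel_unassigned_policy": (str, lambda v: v in ("retain", "drop"), "retain|drop"),
    "truncating_revel_score": (float, lambda v: 0.0 <= v <= 1.0, "score in [0,1]"),
}


def validate_config(
    source: str | Path | Mapping | None, stage: Optional[str] = None
) -> FilterConfig:
    """Build a :class:`FilterConfig` from a flat key/value mapping or YAML file.

    Unknown keys are rejected by name; out-of-range values are rejected with
    the accepted range. Omitted keys take their documented defaults; in
    particular an absent ``revel_threshold`` disables REVEL filtering. When
    ``stage`` is given and ``maf_sources`` is not, the stage's default panel
    list applies.
    """
    if source is None:
        mapping: dict = {}
    elif isinstance(source, Mapping):
        mapping = dict(source)
    else:
        loaded = yaml.safe_load(Path(source).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{source}: config must be a flat key/value mapping")
        mapping = loaded

    unknown = [k for k in mapping if k not in _CONFIG_SCHEMA]
    if unknown:
        raise ValidationError(
            f"unknown config keys {unknown}; accepted: {sorted(_CONFIG_SCHEMA)}"
        )
    kwargs: dict = {}
    for key, raw in mapping.items():
        expected, check, description = _CONFIG_SCHEMA[key]
        if raw is None:
            continue
        try:
            value = expected(raw) if not isinstance(raw, expected) else raw
        except (TypeError, ValueError):
            raise ValidationError(f"config key {key!r}: expected {description}, got {raw!r}")
        if check is not None and not check(value):
            raise ValidationError(f"config key {key!r}: expected {description}, got {raw!r}")
        kwargs[key] = value
    if "maf_sources" in kwargs:
        kwargs["maf_sources"] = tuple(kwargs["maf_sources"])
    elif stage == "discovery":
        kwargs["maf_sources"] = DISCOVERY_MAF_SOURCES
    elif stage == "replication":
        kwargs["maf_sources"] = REPLICATION_MAF_SOURCES
    return FilterConfig(**kwargs)


def load_cohort(
    vcf_path: str | Path, annotation_path: str | Path, phenotype_path: str | Path
) -> CohortDataset:
    """Read and join the three cohort input artifacts."""
    keys, genotypes = read_vcf(vcf_path)
    annotations = read_annotation_table(annotation_path)
    phenotypes, severity = read_phenotype_table(phenotype_path)
    return build_cohort(keys, genotypes, annotations, phenotypes, severity)


@dataclass
class StageSummary:
    n_variants_in: int
    n_variants_qualifying: int
    filter_trace: list[dict]
    n_genes_tested: int
    significance_threshold: float
    records: list[dict]


@dataclass
class RunReport:
    """Machine-readable summary of a two-stage run.

    Every number here is re-derivable from the stage TSVs the CLI writes
    alongside it; the report is a convenience, not a second source of truth.
    """

    version: str
    config_echo: dict
    k: int
    discovery: Optional[StageSummary] = None
    top_candidates: list[str] = field(default_factory=list)
    replication: Optional[StageSummary] = None
    replication_threshold: Optional[float] = None
    replication_p_by_gene: dict[str, float] = field(default_factory=dict)
    skipped_candidates: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=float) + "\n")


def _summarize(result: BurdenResult, n_in: int, trace) -> StageSummary:
    return StageSummary(
        n_variants_in=n_in,
        n_variants_qualifying=trace.n_output,
        filter_trace=trace.to_rows(),
        n_genes_tested=result.n_genes_tested,
        significance_threshold=result.significance_threshold,
        records=[asdict(r) for r in result.records],
    )


def run_two_stage(
    discovery: CohortDataset,
    replication: Optional[CohortDataset],
    k: int = 24,
    discovery_config: Optional[FilterConfig] = None,
    replication_config: Optional[FilterConfig] = None,
) -> tuple[RunReport, Optional[BurdenResult], Optional[BurdenResult]]:
    """Run discovery, carry the top-k genes into replication, report.

    Replication is restricted to the discovery candidates; candidate genes
    with no variant in the replication annotations are skipped with a warning
    and listed in the report. A missing or empty replication dataset yields a
    discovery-only report with an explicit note.
    """
    discovery_config = discovery_config or FilterConfig(maf_sources=DISCOVERY_MAF_SOURCES)
    replication_config = replication_config or FilterConfig(maf_sources=REPLICATION_MAF_SOURCES)

    report = RunReport(
        version=__version__,
        config_echo={
            "discovery": asdict_config(discovery_config),
            "replication": asdict_config(replication_config),
        },
        k=k,
    )

    n_in = len(discovery.variants)
    filtered, trace = apply_filters(discovery, discovery_config)
    disc_result = run_stage(filtered, stage="discovery")
    report.discovery = _summarize(disc_result, n_in, trace)
    if disc_result.n_genes_tested == 0:
        report.notes.append("discovery produced no testable genes")
        return report, disc_result, None
    if k > disc_result.n_genes_tested:
        report.notes.append(
            f"requested top {k} but only {disc_result.n_genes_tested} genes tested; "
            "carrying all forward"
        )
    candidates = rank_candidates(disc_result, k)
    report.top_candidates = candidates

    if replication is None or not replication.variants:
        report.notes.append("replication stage skipped: no replication data")
        return report, disc_result, None

    available = {v.gene for v in replication.variants}
    skipped = [g for g in candidates if g not in available]
    if skipped:
        logger.warning("candidates absent from replication annotations: %s", skipped)
        report.skipped_candidates = skipped
    candidate_set = set(candidates)
    restricted = replication.subset_variants(
        [v.key.id for v in replication.variants if v.gene in candidate_set]
    )
    n_in = len(restricted.variants)
    filtered, trace = apply_filters(restricted, replication_config)
    repl_result = run_stage(filtered, stage="replication")
    report.replication = _summarize(repl_result, n_in, trace)
    report.replication_threshold = significance_threshold(len(candidates))
    report.replication_p_by_gene = {
        r.gene: r.p_one_tailed for r in repl_result.records if r.p_one_tailed is not None
    }
    report.notes.append(
        f"replication p-values are uncorrected; the {len(candidates)}-candidate "
        f"Bonferroni bound is {report.replication_threshold:.3g}"
    )
    return report, disc_result, repl_result


def asdict_config(config: FilterConfig) -> dict:
    d = asdict(config)
    d["maf_sources"] = list(d["maf_sources"])
    return d
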