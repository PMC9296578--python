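"""Input/output layer: VCF genotypes, variant annotations, pedigrees, phenotypes.

This module owns the shared data model for the whole pipeline. Genotypes are
represented as alternate-allele dosages (0, 1, 2, or missing) in a pandas
DataFrame indexed by sample with one column per biallelic variant; multi-allelic
VCF records are split into one column per alternate allele at read time.
Coordinates are 1-based point positions as in VCF. Genotypes are treated as
unphased throughout; only the segregation module infers phase, and it does so
from parental genotypes, never from the GT separator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dataclass_fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "CONSEQUENCES",
    "TRUNCATING_CONSEQUENCES",
    "VariantKey",
    "AnnotatedVariant",
    "CohortDataset",
    "PedigreeMember",
    "Pedigree",
    "VcfParseError",
    "ValidationError",
    "read_vcf",
    "read_annotation_table",
    "write_annotation_table",
    "read_phenotype_table",
    "read_pedigree",
    "write_results_table",
    "read_results_table",
    "build_cohort",
]

# Consequence vocabulary. "near_intronic" covers intronic sites close enough to
# an exon boundary to plausibly affect splicing; their distance is carried in
# AnnotatedVariant.exon_distance and judged by the filter, not here.
CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gain",
        "stop_loss",
        "frameshift",
        "inframe_indel",
        "splice_region",
        "near_intronic",
        "synonymous",
        "other",
    }
)

# Classes that truncate the protein; the filter assigns these a maximal
# pathogenicity score when REVEL (a missense-only ensemble score) is absent.
TRUNCATING_CONSEQUENCES = frozenset({"stop_gain", "frameshift"})


class VcfParseError(ValueError):
    """A VCF could not be parsed; the message names the offending record."""


class ValidationError(ValueError):
    """An input table violated the documented schema or an invariant."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one biallelic variant: chromosome, 1-based position, ref, alt.

    Multi-allelic records are split upstream, so ``alt`` is always a single
    allele. Two keys are equal iff all four coordinates match; rsids are never
    part of identity (they can be merged or renamed across dbSNP builds).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValidationError(
                f"multi-allelic alt {self.alt!r} at {self.chrom}:{self.pos}; split first"
            )

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_id(cls, vid: str) -> "VariantKey":
        chrom, pos, ref, alt = vid.split(":")
        return cls(chrom, int(pos), ref, alt)


@dataclass
class AnnotatedVariant:
    """One variant with its functional and population-frequency annotations.

    ``maf_by_source`` maps a panel name (e.g. ``"1000G_EUR"``, ``"gnomAD_genomes"``)
    to an allele frequency in [0, 1]; a source absent from the map means the
    variant was not observed in that panel. ``revel`` is the REVEL ensemble
    pathogenicity score in [0, 1], or ``None`` when unassigned (intronic and
    truncating variants are not scored by REVEL). ``exon_distance`` is the
    distance in bp from the nearest exon boundary, meaningful for
    ``near_intronic`` variants. ``quality_pass`` carries the upstream caller's
    site-quality verdict; this package never recomputes it.
    """

    key: VariantKey
    gene: str
    consequence: str
    maf_by_source: dict[str, float] = field(default_factory=dict)
    revel: Optional[float] = None
    protein_change: Optional[str] = None
    rsid: Optional[str] = None
    quality_pass: bool = True
    exon_distance: Optional[int] = None
    predictions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r} for {self.key.id}; "
                f"accepted: {sorted(CONSEQUENCES)}"
            )
        for source, freq in self.maf_by_source.items():
            if not (0.0 <= freq <= 1.0):
                raise ValidationError(
                    f"MAF {freq} from {source} out of [0,1] for {self.key.id}"
                )
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValidationError(f"REVEL {self.revel} out of [0,1] for {self.key.id}")


@dataclass
class CohortDataset:
    """A case-control cohort: annotated variants, dosage matrix, phenotypes.

    ``genotypes`` is indexed by sample id with one column per variant id
    (``VariantKey.id``); entries are alternate-allele dosages as floats with
    ``NaN`` for missing calls. ``phenotypes`` maps every sample to ``"case"``
    or ``"control"``. ``severity``, when present, maps every sample to
    ``"severe"`` (Cobb angle >= 40 degrees), ``"moderate"``, or ``"control"``.
    """

    variants: list[AnnotatedVariant]
    genotypes: pd.DataFrame
    phenotypes: dict[str, str]
    severity: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        samples = list(self.genotypes.index)
        if len(set(samples)) != len(samples):
            raise ValidationError("duplicate sample ids in genotype matrix")
        missing = [s for s in samples if s not in self.phenotypes]
        if missing:
            raise ValidationError(f"samples without phenotype: {missing[:5]}")
        bad = {p for p in self.phenotypes.values()} - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown phenotype labels: {sorted(bad)}")
        if self.severity is not None:
            unstratified = [s for s in samples if s not in self.severity]
            if unstratified:
                raise ValidationError(
                    f"severity strata do not cover samples: {unstratified[:5]}"
                )
        known = {v.key.id for v in self.variants}
        unknown = [c for c in self.genotypes.columns if c not in known]
        if unknown:
            raise ValidationError(f"genotype columns without annotation: {unknown[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def cases(self) -> list[str]:
        return [s for s in self.samples if self.phenotypes[s] == "case"]

    @property
    def controls(self) -> list[str]:
        return [s for s in self.samples if self.phenotypes[s] == "control"]

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    def variant_by_id(self, vid: str) -> AnnotatedVariant:
        for v in self.variants:
            if v.key.id == vid:
                return v
        raise KeyError(vid)

    def subset_variants(self, keep_ids: Sequence[str]) -> "CohortDataset":
        keep = set(keep_ids)
        variants = [v for v in self.variants if v.key.id in keep]
        cols = [c for c in self.genotypes.columns if c in keep]
        return CohortDataset(
            variants=variants,
            genotypes=self.genotypes[cols],
            phenotypes=dict(self.phenotypes),
            severity=None if self.severity is None else dict(self.severity),
        )


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" | "female" | "unknown"
    affected: bool


@dataclass
class Pedigree:
    """A pedigree as a list of members with resolved parent references."""

    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate individual ids in pedigree")
        known = set(ids)
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in known:
                    raise ValidationError(
                        f"{m.individual_id} references unknown parent {parent}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            m.individual_id: [p for p in (m.father_id, m.mother_id) if p is not None]
            for m in self.members
        }
        # colour: 0 unvisited, 1 on stack, 2 done
        colour = {i: 0 for i in parents}

        def visit(node: str, stack: list[str]) -> None:
            if colour[node] == 1:
                raise ValidationError(
                    f"cyclic parentage involving {node}: {' -> '.join(stack + [node])}"
                )
            if colour[node] == 2:
                return
            colour[node] = 1
            for p in parents[node]:
                visit(p, stack + [node])
            colour[node] = 2

        for node in parents:
            visit(node, [])

    def member(self, individual_id: str) -> PedigreeMember:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)

    @property
    def affected(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affected]

    @property
    def unaffected(self) -> list[PedigreeMember]:
        return [m for m in self.members if not m.affected]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> tuple[list[VariantKey], pd.DataFrame]:
    """Read a VCF into variant keys and a sample x variant dosage matrix.

    Multi-allelic records are split into one biallelic :class:`VariantKey` per
    alternate allele, with dosages recomputed per alternate (an allele that is
    neither REF nor the focal ALT contributes 0 to that ALT's dosage). Missing
    genotypes (``./.``) become ``NaN``.

    Raises
    ------
    VcfParseError
        If the file cannot be parsed; the message names the failing record.
    ValidationError
        If the header declares duplicate sample ids.
    """
    path = Path(path)
    _check_duplicate_samples(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports open/header failures here
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.samples)

    keys: list[VariantKey] = []
    columns: list[np.ndarray] = []
    record_no = 0
    try:
        for record in vcf:
            record_no += 1
            # genotypes: per sample [allele1, allele2, phased]; -1 = missing
            gts = record.genotypes
            for alt_index, alt in enumerate(record.ALT, start=1):
                key = VariantKey(record.CHROM, record.POS, record.REF, alt)
                dosages = np.full(len(samples), np.nan)
                for i, gt in enumerate(gts):
                    alleles = gt[:-1]
                    if any(a < 0 for a in alleles):
                        continue
                    dosages[i] = sum(1 for a in alleles if a == alt_index)
                keys.append(key)
                columns.append(dosages)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: malformed VCF at record {record_no + 1} "
            f"(after {record_no} parsed records): {exc}"
        ) from exc

    matrix = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample"),
        columns=[k.id for k in keys],
    )
    return keys, matrix


def _check_duplicate_samples(path: Path) -> None:
    # htslib reports duplicated sample columns as a generic header failure;
    # checking the #CHROM line directly gives a named validation error instead.
    try:
        with open(path, "rt") as handle:
            for line in handle:
                if line.startswith("#CHROM"):
                    samples = line.rstrip("\n").split("\t")[9:]
                    if len(set(samples)) != len(samples):
                        dupes = sorted({s for s in samples if samples.count(s) > 1})
                        raise ValidationError(f"{path}: duplicate sample ids: {dupes}")
                    return
                if not line.startswith("#"):
                    return
    except (OSError, UnicodeDecodeError):
        return  # compressed or unreadable here; leave diagnosis to htslib


_REQUIRED_ANNOTATION_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "consequence")
_MAF_PREFIX = "maf_"
_PREDICTION_COLUMNS = ("sift", "polyphen2", "mutation_taster")


def read_annotation_table(path: str | Path) -> list[AnnotatedVariant]:
    """Read a per-variant annotation TSV into :class:`AnnotatedVariant` records.

    Required columns: ``chrom pos ref alt gene consequence``. Population
    frequencies live in columns named ``maf_<source>`` (e.g. ``maf_1000G_EUR``,
    ``maf_gnomAD_genomes``); an empty cell means the variant is absent from
    that panel. Optional columns: ``revel`` (empty = unassigned), ``rsid``,
    ``protein_change``, ``quality_pass`` (default true), ``exon_distance``,
    and carried-through prediction strings ``sift``/``polyphen2``/``mutation_taster``.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _REQUIRED_ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing annotation columns: {missing}")
    maf_columns = [c for c in table.columns if c.startswith(_MAF_PREFIX)]

    variants: list[AnnotatedVariant] = []
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        rec = row._asdict()
        consequence = str(rec["consequence"])
        if consequence not in CONSEQUENCES:
            raise ValidationError(
                f"{path} line {row_no}: unknown consequence {consequence!r}; "
                f"accepted: {sorted(CONSEQUENCES)}"
            )
        maf_by_source = {}
        for col in maf_columns:
            value = rec[col]
            if value is not None and not (isinstance(value, float) and math.isnan(value)):
                maf_by_source[col[len(_MAF_PREFIX):]] = float(value)
        variants.append(
            AnnotatedVariant(
                key=VariantKey(str(rec["chrom"]), int(rec["pos"]), str(rec["ref"]), str(rec["alt"])),
                gene=str(rec["gene"]),
                consequence=consequence,
                maf_by_source=maf_by_source,
                revel=_optional_float(rec.get("revel")),
                protein_change=_optional_str(rec.get("protein_change")),
                rsid=_optional_str(rec.get("rsid")),
                quality_pass=_optional_bool(rec.get("quality_pass"), default=True),
                exon_distance=_optional_int(rec.get("exon_distance")),
                predictions={
                    c: str(rec[c])
                    for c in _PREDICTION_COLUMNS
                    if c in rec and _optional_str(rec.get(c)) is not None
                },
            )
        )
    return variants


def write_annotation_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    """Write annotations as a TSV readable by :func:`read_annotation_table`."""
    rows = []
    sources: list[str] = []
    variants = list(variants)
    for v in variants:
        for s in v.maf_by_source:
            if s not in sources:
                sources.append(s)
    for v in variants:
        row = {
            "chrom": v.key.chrom,
            "pos": v.key.pos,
            "ref": v.key.ref,
            "alt": v.key.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "revel": v.revel,
            "protein_change": v.protein_change,
            "rsid": v.rsid,
            "quality_pass": v.quality_pass,
            "exon_distance": v.exon_distance,
        }
        for s in sources:
            row[_MAF_PREFIX + s] = v.maf_by_source.get(s)
        for name, verdict in v.predictions.items():
            row[name] = verdict
        rows.append(row)
    columns = list(_REQUIRED_ANNOTATION_COLUMNS) + [_MAF_PREFIX + s for s in sources] + [
        "revel",
        "protein_change",
        "rsid",
        "quality_pass",
        "exon_distance",
    ]
    extra = [c for c in _PREDICTION_COLUMNS if any(c in r for r in rows)]
    frame = pd.DataFrame(rows, columns=columns + extra) if rows else pd.DataFrame(columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path) -> tuple[dict[str, str], Optional[dict[str, str]]]:
    """Read a sample-phenotype TSV: columns ``sample_id``, ``phenotype``,
    optional ``severity`` (severe/moderate/control)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "phenotype"):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing phenotype column {col!r}")
    phenotypes = dict(zip(table["sample_id"], table["phenotype"]))
    severity = None
    if "severity" in table.columns and table["severity"].notna().any():
        severity = dict(zip(table["sample_id"], table["severity"]))
    return phenotypes, severity


_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (family, individual, father, mother, sex, phenotype).

    Phenotype 2 means affected, 1 unaffected; 0 and -9 (unknown status) are
    rejected because the segregation models require a definite status for
    every member. Parent id "0" means founder.
    """
    members = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValidationError(f"{path} line {line_no}: expected 6 columns, got {len(parts)}")
        _family, individual, father, mother, sex, phenotype = parts
        if phenotype == "2":
            affected = True
        elif phenotype == "1":
            affected = False
        else:
            raise ValidationError(
                f"{path} line {line_no}: phenotype {phenotype!r} (unknown status) "
                "not supported; use 1 (unaffected) or 2 (affected)"
            )
        members.append(
            PedigreeMember(
                individual_id=individual,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX_CODES.get(sex, "unknown"),
                affected=affected,
            )
        )
    return Pedigree(members=members)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_results_table(
    records: Sequence,
    path: str | Path,
    display_decimals: int = 3,
    json_mirror: bool = False,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write homogeneous result records as a TSV with a stable column order.

    p-value columns (names starting with ``p_``) are written in full double
    precision plus a rounded ``*_display`` companion column. With an empty
    record list, ``columns`` supplies the header (header-only file).
    """
    path = Path(path)
    rows: list[dict] = []
    columns = list(columns) if columns is not None else []
    for rec in records:
        if is_dataclass(rec):
            row = asdict(rec)
        elif isinstance(rec, Mapping):
            row = dict(rec)
        else:
            raise TypeError(f"unsupported record type {type(rec).__name__}")
        row = {k: (v.id if isinstance(v, VariantKey) else v) for k, v in row.items()}
        rows.append(row)
        for k in row:
            if k not in columns:
                columns.append(k)
    frame = pd.DataFrame(rows, columns=columns)
    for col in [c for c in columns if c.startswith("p_")]:
        frame[col + "_display"] = pd.to_numeric(frame[col], errors="coerce").round(
            display_decimals
        )
    frame.to_csv(path, sep="\t", index=False)
    if json_mirror:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(frame.to_dict(orient="records"), indent=1, default=str) + "\n"
        )


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def build_cohort(
    variant_keys: Sequence[VariantKey],
    genotypes: pd.DataFrame,
    annotations: Sequence[AnnotatedVariant],
    phenotypes: Mapping[str, str],
    severity: Optional[Mapping[str, str]] = None,
) -> CohortDataset:
    """Join genotypes with annotations on (chrom, pos, ref, alt).

    Variants present in the VCF but absent from the annotation table are
    rejected: every tested variant must carry gene and consequence
    annotations for the filters to be meaningful.
    """
    by_key = {a.key: a for a in annotations}
    missing = [k.id for k in variant_keys if k not in by_key]
    if missing:
        raise ValidationError(f"variants without annotation: {missing[:5]}")
    variants = [by_key[k] for k in variant_keys]
    return CohortDataset(
        variants=variants,
        genotypes=genotypes,
        phenotypes=dict(phenotypes),
        severity=None if severity is None else dict(severity),
    )


# small cell parsers --------------------------------------------------------


def _optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _optional_int(value) -> Optional[int]:
    f = _optional_float(value)
    return None if f is None else int(f)


def _optional_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value)
    return s if s and s.lower() != "nan" else None


def _optional_bool(value, default: bool) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"1", "true", "yes", "pass"}
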