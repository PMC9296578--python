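import hypothesis
import numpy as np
import pandas as pd
import pytest

from rareburden import (
    AnnotatedVariant,
    CohortDataset,
    Pedigree,
    PedigreeMember,
    VariantKey,
)
from rareburden.segregation import FamilyGenotypes

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("suite")


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t./.
1\t200\t.\tC\tA,T\t.\tPASS\t.\tGT\t1/2\t0/1\t2/2
1\t300\t.\tG\tT\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


def make_variant(
    vid="1:100:A:G",
    gene="GENEA",
    consequence="missense",
    maf=None,
    revel=None,
    quality_pass=True,
    exon_distance=None,
    **kwargs,
):
    return AnnotatedVariant(
        key=VariantKey.from_id(vid),
        gene=gene,
        consequence=consequence,
        maf_by_source=dict(maf or {}),
        revel=revel,
        quality_pass=quality_pass,
        exon_distance=exon_distance,
        **kwargs,
    )


def make_cohort(variants, dosage_rows, phenotypes, severity=None):
    """dosage_rows: {sample: [dosage per variant, in order]}"""
    matrix = pd.DataFrame(
        {v.key.id: [dosage_rows[s][i] for s in dosage_rows] for i, v in enumerate(variants)},
        index=pd.Index(list(dosage_rows), name="sample"),
        dtype=float,
    )
    return CohortDataset(
        variants=list(variants), genotypes=matrix, phenotypes=dict(phenotypes),
        severity=severity,
    )


def make_family(variant_specs, dosage_rows, n_affected=3):
    """variant_specs: list of (gene, vid) or AnnotatedVariant;
    dosage_rows: {individual: [dosages]} over FATHER/MOTHER/SIB1..n."""
    variants = [
        spec if isinstance(spec, AnnotatedVariant) else make_variant(vid=spec[1], gene=spec[0])
        for spec in variant_specs
    ]
    members = [
        PedigreeMember("FATHER", None, None, "male", False),
        PedigreeMember("MOTHER", None, None, "female", False),
    ] + [
        PedigreeMember(f"SIB{i + 1}", "FATHER", "MOTHER", "female", True)
        for i in range(n_affected)
    ]
    matrix = pd.DataFrame(
        [[float(x) if x is not None else np.nan for x in dosage_rows[ind]]
         for ind in dosage_rows],
        index=pd.Index(list(dosage_rows), name="individual"),
        columns=[v.key.id for v in variants],
    )
    return FamilyGenotypes(
        pedigree=Pedigree(members=members), variants=variants, dosages=matrix
    )


def random_family(rng, n_variants=50, n_genes=8, n_affected=3, missing_rate=0.0):
    """A random family fixture for oracle-equivalence checks."""
    specs = []
    for i in range(n_variants):
        gene = f"G{int(rng.integers(n_genes)) + 1}"
        specs.append((gene, f"1:{(i + 1) * 100}:A:G"))
    individuals = ["FATHER", "MOTHER"] + [f"SIB{i + 1}" for i in range(n_affected)]
    rows = {}
    for ind in individuals:
        dosages = rng.choice([0, 0, 0, 1, 1, 2], size=n_variants).astype(float)
        if missing_rate > 0:
            dosages[rng.random(n_variants) < missing_rate] = np.nan
        rows[ind] = list(dosages)
    return make_family(specs, rows, n_affected=n_affected)
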