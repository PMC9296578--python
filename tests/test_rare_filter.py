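from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rareburden import (
    FilterConfig,
    apply_filters,
    effective_revel,
    is_protein_altering,
    is_rare,
    population_maf,
)
from rareburden.rare_filter import REVEL_PRESETS
from rareburden.variant_io import ValidationError
from conftest import make_cohort, make_variant

SOURCES = ("1000G_EUR", "ESP_EA", "gnomAD_genomes", "gnomAD_exomes")


class TestPopulationMaf:
    def test_single_source_value(self):
        variant = make_variant(maf={"gnomAD_genomes": 0.0054})
        assert population_maf(variant, SOURCES) == 0.0054

    def test_absent_everywhere_is_zero(self):
        assert population_maf(make_variant(), SOURCES) == 0.0

    def test_max_rule_over_permuted_source_orders(self):
        variant = make_variant(maf={"1000G_EUR": 0.004, "gnomAD_genomes": 0.012})
        for order in permutations(SOURCES):
            assert population_maf(variant, order) == 0.012
        # the max fails a 0.01 cutoff even though one source passes
        assert not is_rare(variant, FilterConfig(maf_cutoff=0.01, maf_sources=SOURCES))

    def test_unconsulted_sources_ignored(self):
        variant = make_variant(maf={"gnomAD_genomes": 0.2})
        assert population_maf(variant, ("1000G_EUR",)) == 0.0


class TestIsRare:
    CONFIG = FilterConfig(maf_cutoff=0.01, maf_sources=SOURCES)

    def test_below_cutoff(self):
        assert is_rare(make_variant(maf={"gnomAD_genomes": 0.0054}), self.CONFIG)

    def test_boundary_is_excluded_by_strict_cutoff(self):
        variant = make_variant(maf={"gnomAD_genomes": 0.01})
        assert not is_rare(variant, self.CONFIG)
        inclusive = FilterConfig(maf_cutoff=0.01, maf_inclusive=True, maf_sources=SOURCES)
        assert is_rare(variant, inclusive)

    def test_relaxed_two_percent_model(self):
        variant = make_variant(maf={"gnomAD_genomes": 0.012})
        assert is_rare(variant, FilterConfig(maf_cutoff=0.02, maf_sources=SOURCES))


class TestProteinAltering:
    CONFIG = FilterConfig()

    @pytest.mark.parametrize(
        "consequence", ["missense", "stop_gain", "stop_loss", "frameshift",
                        "inframe_indel", "splice_region"]
    )
    def test_altering_classes(self, consequence):
        assert is_protein_altering(make_variant(consequence=consequence), self.CONFIG)

    def test_synonymous_excluded_by_default(self):
        variant = make_variant(consequence="synonymous")
        assert not is_protein_altering(variant, self.CONFIG)
        assert is_protein_altering(variant, FilterConfig(keep_synonymous=True))

    @pytest.mark.parametrize(
        "distance,window,expected",
        [(8, 10, True), (10, 10, True), (11, 10, False), (25, 10, False),
         (25, 30, True), (None, 10, False)],
    )
    def test_near_intronic_window_rule(self, distance, window, expected):
        variant = make_variant(consequence="near_intronic", exon_distance=distance)
        config = FilterConfig(near_intron_window=window)
        assert is_protein_altering(variant, config) is expected


class TestEffectiveRevel:
    CONFIG = FilterConfig()

    def test_truncating_gets_maximal_score(self):
        assert effective_revel(make_variant(consequence="frameshift"), self.CONFIG) == 1.0
        assert effective_revel(make_variant(consequence="stop_gain"), self.CONFIG) == 1.0

    def test_missense_uses_annotation(self):
        assert effective_revel(make_variant(revel=0.303), self.CONFIG) == 0.303

    def test_intronic_stays_unassigned(self):
        variant = make_variant(consequence="near_intronic", exon_distance=5)
        assert effective_revel(variant, self.CONFIG) is None

    def test_presets_exist(self):
        assert REVEL_PRESETS["balanced"] == 0.3
        assert REVEL_PRESETS["sens_eq_spec"] == 0.38


def five_variant_cohort():
    variants = [
        make_variant(vid="1:100:A:G", gene="G1", revel=0.5, quality_pass=False),
        make_variant(vid="1:200:A:G", gene="G1", consequence="synonymous"),
        make_variant(vid="1:300:A:G", gene="G2", maf={"1000G_EUR": 0.05}),
        make_variant(vid="1:400:A:G", gene="G2", revel=0.9,
                     maf={"1000G_EUR": 0.001}),
        make_variant(vid="1:500:A:G", gene="G3", consequence="frameshift"),
    ]
    rows = {"CASE1": [1, 0, 1, 1, 0], "CTRL1": [0, 1, 0, 0, 1]}
    return make_cohort(variants, rows, {"CASE1": "case", "CTRL1": "control"})


class TestApplyFilters:
    def test_staged_attrition_matches_hand_count(self):
        dataset = five_variant_cohort()
        config = FilterConfig(maf_sources=("1000G_EUR",), revel_threshold=0.3)
        filtered, trace = apply_filters(dataset, config)
        assert [v.key.id for v in filtered.variants] == ["1:400:A:G", "1:500:A:G"]
        assert trace.counts == {
            "quality": (5, 1),
            "protein_altering": (4, 1),
            "rarity": (3, 1),
            "revel": (2, 0),
        }

    def test_empty_dataset(self):
        dataset = five_variant_cohort().subset_variants([])
        filtered, trace = apply_filters(dataset, FilterConfig())
        assert not filtered.variants
        assert all(n_in == 0 and removed == 0 for n_in, removed in trace.counts.values())

    def test_revel_threshold_retains_scores_above_threshold(self):
        # published missense REVEL scores plus an unscored frameshift
        scores = [0.303, 0.543, 0.488, 0.074, 0.298, 0.383, 0.743, 0.223]
        variants = [
            make_variant(vid=f"1:{100 * (i + 1)}:A:G", gene="FAT3", revel=s,
                         maf={"1000G_EUR": 0.001})
            for i, s in enumerate(scores)
        ]
        variants.append(make_variant(vid="1:9999:A:G", gene="FAT3",
                                     consequence="frameshift"))
        rows = {"CASE1": [1] * len(variants), "CTRL1": [0] * len(variants)}
        dataset = make_cohort(variants, rows, {"CASE1": "case", "CTRL1": "control"})
        config = FilterConfig(maf_sources=("1000G_EUR",), revel_threshold=0.3)
        filtered, _ = apply_filters(dataset, config)
        survivors = {v.key.id for v in filtered.variants}
        expected = {
            v.key.id for v in variants
            if (effective_revel(v, config) or 0) > 0.3
        }
        assert survivors == expected
        assert "1:9999:A:G" in survivors  # frameshift imputed to 1.0

    def test_unassigned_policy_drop(self):
        intronic = make_variant(consequence="near_intronic", exon_distance=3)
        rows = {"CASE1": [1], "CTRL1": [0]}
        dataset = make_cohort([intronic], rows, {"CASE1": "case", "CTRL1": "control"})
        retain = FilterConfig(revel_threshold=0.3)
        drop = FilterConfig(revel_threshold=0.3, revel_unassigned_policy="drop")
        assert apply_filters(dataset, retain)[0].variants
        assert not apply_filters(dataset, drop)[0].variants


@st.composite
def random_cohorts(draw):
    n = draw(st.integers(1, 12))
    variants = []
    for i in range(n):
        consequence = draw(st.sampled_from(
            ["missense", "synonymous", "frameshift", "near_intronic", "splice_region"]))
        maf = draw(st.one_of(st.none(), st.floats(0, 0.1)))
        variants.append(
            make_variant(
                vid=f"1:{(i + 1) * 50}:A:G",
                gene=f"G{i % 3}",
                consequence=consequence,
                maf=None if maf is None else {"1000G_EUR": maf},
                revel=draw(st.one_of(st.none(), st.floats(0, 1)))
                if consequence == "missense" else None,
                quality_pass=draw(st.booleans()),
                exon_distance=draw(st.integers(0, 30))
                if consequence == "near_intronic" else None,
            )
        )
    rows = {
        "CASE1": [draw(st.sampled_from([0, 1, 2])) for _ in range(n)],
        "CTRL1": [draw(st.sampled_from([0, 1, 2])) for _ in range(n)],
    }
    return make_cohort(variants, rows, {"CASE1": "case", "CTRL1": "control"})


class TestFilterProperties:
    @given(dataset=random_cohorts(), revel=st.one_of(st.none(), st.floats(0, 1)))
    def test_idempotent(self, dataset, revel):
        config = FilterConfig(maf_sources=("1000G_EUR",), revel_threshold=revel)
        once, _ = apply_filters(dataset, config)
        twice, _ = apply_filters(once, config)
        assert [v.key.id for v in twice.variants] == [v.key.id for v in once.variants]

    @given(dataset=random_cohorts(), c1=st.floats(0.001, 1), c2=st.floats(0.001, 1))
    def test_monotone_in_maf_cutoff(self, dataset, c1, c2):
        lo, hi = sorted((c1, c2))
        survivors_lo, _ = apply_filters(dataset, FilterConfig(maf_cutoff=lo,
                                                              maf_sources=("1000G_EUR",)))
        survivors_hi, _ = apply_filters(dataset, FilterConfig(maf_cutoff=hi,
                                                              maf_sources=("1000G_EUR",)))
        assert {v.key.id for v in survivors_lo.variants} <= {
            v.key.id for v in survivors_hi.variants
        }

    @given(dataset=random_cohorts(), t1=st.floats(0, 1), t2=st.floats(0, 1))
    def test_monotone_in_revel_threshold(self, dataset, t1, t2):
        lo, hi = sorted((t1, t2))
        survivors_hi, _ = apply_filters(
            dataset, FilterConfig(maf_sources=("1000G_EUR",), revel_threshold=hi))
        survivors_lo, _ = apply_filters(
            dataset, FilterConfig(maf_sources=("1000G_EUR",), revel_threshold=lo))
        assert {v.key.id for v in survivors_hi.variants} <= {
            v.key.id for v in survivors_lo.variants
        }

    @given(dataset=random_cohorts())
    def test_trace_conserves_counts(self, dataset):
        filtered, trace = apply_filters(dataset, FilterConfig(maf_sources=("1000G_EUR",)))
        removed = sum(r for _, r in trace.counts.values())
        assert len(dataset.variants) - removed == len(filtered.variants)
        assert trace.n_output == len(filtered.variants)


def test_config_validation():
    with pytest.raises(ValidationError):
        FilterConfig(maf_cutoff=0.0)
    with pytest.raises(ValidationError):
        FilterConfig(maf_cutoff=1.5)
    with pytest.raises(ValidationError):
        FilterConfig(revel_unassigned_policy="ignore")
    with pytest.raises(ValidationError):
        FilterConfig(maf_sources=())
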