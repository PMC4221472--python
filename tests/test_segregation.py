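"""Segregation filtering and the known-variant exclusion funnel."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from rumpmap import (
    Genotype,
    GenotypeClass,
    KnownVariantSet,
    MissingPolicy,
    count_by_kind,
    exclude_known,
    genotype_matches_model,
    segregation_filter,
)

from conftest import HET, HOM, MISS, REF, make_variant

CLASSES = (REF, HET, HOM)


def brute_force_filter(variants, design, missing_policy=MissingPolicy.FAIL):
    """Independent checker: test each sample's genotype one by one."""
    expected = design.expected_classes
    kept = []
    for v in variants:
        ok = True
        for sid, exp in expected.items():
            cls = v.genotypes[sid].gt_class
            if cls is MISS:
                if missing_policy is MissingPolicy.FAIL:
                    ok = False
            elif cls is not exp:
                ok = False
        if ok:
            kept.append(v)
    return kept


class TestGenotypeMatchesModel:
    @pytest.mark.parametrize(
        "cls, expected, policy, result",
        [
            (HOM, HOM, MissingPolicy.FAIL, True),
            (HET, HOM, MissingPolicy.FAIL, False),
            (MISS, HET, MissingPolicy.FAIL, False),
            (MISS, HET, MissingPolicy.PASS, True),
            (REF, REF, MissingPolicy.FAIL, True),
        ],
    )
    def test_match_rules(self, cls, expected, policy, result):
        g = Genotype.from_class("s", cls)
        assert genotype_matches_model(g, expected, policy) is result


class TestSegregationFilter:
    def test_perfect_pattern_retained(self, design_321):
        v = make_variant(design_321, [HOM, HOM, HOM, HET, HET, REF])
        assert segregation_filter([v], design_321) == [v]

    def test_het_unaffected_rejected(self, design_321):
        v = make_variant(design_321, [HOM, HOM, HOM, HET, HET, HET])
        assert segregation_filter([v], design_321) == []

    def test_missing_genotype_disqualifies_by_default(self, design_321):
        v = make_variant(design_321, [MISS, HOM, HOM, HET, HET, REF])
        assert segregation_filter([v], design_321) == []
        assert segregation_filter([v], design_321, MissingPolicy.PASS) == [v]

    def test_sample_mismatch_fatal(self, design_321):
        v = make_variant(design_321, [HOM, HOM, HOM, HET, HET, REF])
        gts = dict(v.genotypes)
        del gts["TA1"]
        from rumpmap import Variant

        bad = Variant(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                      genotypes=gts)
        with pytest.raises(ValueError, match="TA1"):
            segregation_filter([bad], design_321)

    def test_exactly_one_of_729_assignments_passes(self, design_321):
        """Exhaustive sweep of all 3^6 non-missing genotype-class
        assignments for the 3/2/1 cohort: only the model pattern
        survives, and the filter agrees with the brute-force checker on
        every assignment."""
        variants = [
            make_variant(design_321, pattern, pos=1000 + i)
            for i, pattern in enumerate(itertools.product(CLASSES, repeat=6))
        ]
        assert len(variants) == 729
        kept = segregation_filter(variants, design_321)
        assert len(kept) == 1
        classes = [kept[0].gt_class(s) for s in design_321.sample_ids]
        assert classes == [HOM, HOM, HOM, HET, HET, REF]
        assert kept == brute_force_filter(variants, design_321)

    @settings(max_examples=60, derandomize=True)
    @given(
        patterns=st.lists(
            st.tuples(*[st.sampled_from(CLASSES + (MISS,))] * 6),
            min_size=0, max_size=40,
        ),
        policy=st.sampled_from([MissingPolicy.FAIL, MissingPolicy.PASS]),
    )
    def test_filter_matches_oracle_and_is_idempotent(self, patterns, policy):
        design = _design()
        variants = [
            make_variant(design, p, pos=10 + i) for i, p in enumerate(patterns)
        ]
        kept = segregation_filter(variants, design, policy)
        assert kept == brute_force_filter(variants, design, policy)
        # subset, idempotence, order invariance
        assert all(v in variants for v in kept)
        assert segregation_filter(kept, design, policy) == kept
        rev = segregation_filter(list(reversed(variants)), design, policy)
        assert set(v.key for v in rev) == set(v.key for v in kept)


def _design():
    from rumpmap import CohortDesign, Phenotype

    return CohortDesign(
        samples=(
            ("HOM1", Phenotype.AFFECTED, HOM),
            ("HOM2", Phenotype.AFFECTED, HOM),
            ("HOM3", Phenotype.AFFECTED, HOM),
            ("HET1", Phenotype.AFFECTED, HET),
            ("HET2", Phenotype.AFFECTED, HET),
            ("TA1", Phenotype.UNAFFECTED, REF),
        )
    )


class TestExcludeKnown:
    def _variants(self, design, n, start_pos=1000):
        return [
            make_variant(design, [HOM, HOM, HOM, HET, HET, REF], pos=start_pos + i)
            for i in range(n)
        ]

    def test_funnel_316_minus_18_leaves_298(self, design_321):
        variants = self._variants(design_321, 316)
        known = KnownVariantSet.from_keys(v.key for v in variants[:18])
        kept = exclude_known(variants, known)
        assert len(kept) == 298
        assert all(v.key not in known for v in kept)

    def test_empty_known_set_is_identity(self, design_321):
        variants = self._variants(design_321, 5)
        assert exclude_known(variants, KnownVariantSet.from_keys([])) == variants

    def test_all_known_annihilates(self, design_321):
        variants = self._variants(design_321, 5)
        known = KnownVariantSet.from_keys(v.key for v in variants)
        assert exclude_known(variants, known) == []

    def test_match_requires_all_four_fields(self, design_321):
        v = make_variant(design_321, [HOM, HOM, HOM, HET, HET, REF],
                         pos=1000, ref="A", alt="G")
        known_other_alt = KnownVariantSet.from_keys([("chr2", 1000, "A", "T")])
        assert exclude_known([v], known_other_alt) == [v]
        assert exclude_known([v], known_other_alt, match_position_only=True) == []

    def test_commutes_with_segregation_filter(self, design_321):
        good = self._variants(design_321, 10)
        bad = [
            make_variant(design_321, [HOM, HOM, HOM, HET, HET, HET],
                         pos=5000 + i)
            for i in range(10)
        ]
        variants = [x for pair in zip(good, bad) for x in pair]
        known = KnownVariantSet.from_keys(
            [good[0].key, good[3].key, bad[2].key]
        )
        a = exclude_known(segregation_filter(variants, design_321), known)
        b = segregation_filter(exclude_known(variants, known), design_321)
        assert a == b


class TestCountByKind:
    def test_funnel_kind_partition(self, design_321):
        pattern = [HOM, HOM, HOM, HET, HET, REF]
        variants = [
            make_variant(design_321, pattern, pos=1000 + i) for i in range(274)
        ]
        variants += [
            make_variant(design_321, pattern, pos=3000 + i, ref="A", alt="AT")
            for i in range(14)
        ]
        variants += [
            make_variant(design_321, pattern, pos=5000 + i, ref="AC", alt="A")
            for i in range(10)
        ]
        counts = count_by_kind(variants)
        assert counts["SNP"] == 274
        assert counts["indel"] == 24
        assert counts["INS"] == 14 and counts["DEL"] == 10
        assert counts["total"] == 298

    def test_empty_list_all_zero(self):
        counts = count_by_kind([])
        assert counts == {"SNP": 0, "INS": 0, "DEL": 0, "MNV": 0,
                          "indel": 0, "total": 0}

    def test_hand_count(self, design_321):
        pattern = [HOM, HOM, HOM, HET, HET, REF]
        variants = (
            [make_variant(design_321, pattern, pos=10 + i) for i in range(5)]
            + [make_variant(design_321, pattern, pos=100 + i, ref="A", alt="ATG")
               for i in range(3)]
            + [make_variant(design_321, pattern, pos=200 + i, ref="ACC", alt="A")
               for i in range(2)]
        )
        counts = count_by_kind(variants)
        assert (counts["SNP"], counts["INS"], counts["DEL"], counts["indel"]) == (
            5, 3, 2, 5
        )
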