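"""Recombinant exclusion mapping against a run-scanning oracle."""

from __future__ import annotations

import numpy as np
import pytest

from rumpmap import (
    BoundaryMode,
    GenomicInterval,
    HaplotypeOrigin,
    MarkerHaplotypeTable,
    assign_haplotype,
    exclusion_map,
    variants_in_interval,
)

from conftest import HET, HOM, REF, make_variant

AFF = HaplotypeOrigin.AFFECTED_HAP
UNAFF = HaplotypeOrigin.UNAFFECTED_HAP
UNINF = HaplotypeOrigin.UNINFORMATIVE


def scan_oracle(table, original, excluders):
    """Brute-force re-derivation: combine per-marker origin calls, then
    scan every maximal run free of affected-haplotype markers and report
    it clipped at its outermost unaffected-haplotype markers (or at the
    original bounds when the run touches the ladder edge)."""
    n = len(table.markers)
    pos = table.positions
    status = []
    for i in range(n):
        calls = [table.calls[e][i] for e in excluders]
        if AFF in calls:
            status.append("aff")
        elif all(c is UNINF for c in calls):
            status.append("trans")
        else:
            status.append("unaff")
    if "aff" not in status and "unaff" not in status:
        return [original]
    out = []
    run: list[int] = []
    for i in range(n + 1):
        if i < n and status[i] != "aff":
            run.append(i)
            continue
        informative = [k for k in run if status[k] == "unaff"]
        if informative:
            left = original.start if run[0] == 0 else pos[informative[0]]
            right = original.end if run[-1] == n - 1 else pos[informative[-1]]
            out.append(GenomicInterval(original.chrom, left, right))
        run = []
    return out


def make_table(positions, calls_by_ind):
    markers = [(p, "A", "G") for p in positions]
    return MarkerHaplotypeTable(
        markers=tuple(markers),
        calls={k: tuple(v) for k, v in calls_by_ind.items()},
    )


class TestAssignHaplotype:
    @pytest.mark.parametrize(
        "gt, expected",
        [
            (("A", "G"), AFF),
            (("A", "A"), AFF),
            (("G", "G"), UNAFF),
            (("T", "T"), UNINF),
            (("G", "T"), UNINF),
        ],
    )
    def test_single_carrier_rules(self, gt, expected):
        assert assign_haplotype(gt, "A", "G") is expected

    def test_identical_marker_alleles_fatal(self):
        with pytest.raises(ValueError):
            assign_haplotype(("A", "A"), "A", "A")


class TestExclusionMap:
    def test_rb1_layout_reproduces_critical_interval(self, region):
        """Nine markers; the recombinant shows the unaffected haplotype
        only at markers 3-5, whose outermost positions delimit the
        125,146 bp interval."""
        positions = [
            86_150_000, 86_300_000, 86_476_559, 86_540_000, 86_601_705,
            86_700_000, 86_750_000, 86_800_000, 86_840_000,
        ]
        calls = [AFF, AFF, UNAFF, UNAFF, UNAFF, AFF, AFF, AFF, AFF]
        table = make_table(positions, {"RB1": calls})
        result = exclusion_map(table, region, ["RB1"])
        assert result == [GenomicInterval("chr2", 86_476_559, 86_601_705)]
        assert result[0].span == 125_146

    def test_all_unaffected_returns_original(self, region):
        table = make_table([86_200_000, 86_400_000, 86_600_000],
                           {"RB1": [UNAFF, UNAFF, UNAFF]})
        assert exclusion_map(table, region, ["RB1"]) == [region]

    def test_zero_excluders_returns_original(self, region):
        table = make_table([86_200_000], {"RB1": [AFF]})
        assert exclusion_map(table, region, []) == [region]

    def test_no_informative_markers_returns_original(self, region, caplog):
        table = make_table([86_200_000, 86_400_000],
                           {"RB1": [UNINF, UNINF]})
        with caplog.at_level("WARNING"):
            result = exclusion_map(table, region, ["RB1"])
        assert result == [region]
        assert any("informative" in r.message for r in caplog.records)

    def test_uninformative_markers_are_transparent(self, region):
        positions = [86_200_000, 86_300_000, 86_400_000, 86_500_000, 86_600_000]
        table = make_table(
            positions, {"RB1": [AFF, UNAFF, UNINF, UNAFF, AFF]}
        )
        result = exclusion_map(table, region, ["RB1"])
        assert result == [GenomicInterval("chr2", 86_300_000, 86_500_000)]

    def test_unknown_excluder_fatal(self, region):
        table = make_table([86_200_000], {"RB1": [UNAFF]})
        with pytest.raises(ValueError, match="RB9"):
            exclusion_map(table, region, ["RB9"])

    def test_matches_scan_oracle_on_random_tables(self, region):
        """Fifty random 12-marker call patterns over one or two
        excluders agree with the exhaustive run-scanning oracle."""
        rng = np.random.default_rng(42)
        origins = [AFF, UNAFF, UNINF]
        for _ in range(50):
            positions = sorted(
                int(p) for p in rng.choice(700_000, size=12, replace=False)
                + region.start
            )
            n_exc = int(rng.integers(1, 3))
            calls = {
                f"E{i}": [origins[int(k)] for k in rng.integers(0, 3, size=12)]
                for i in range(n_exc)
            }
            table = make_table(positions, calls)
            excluders = sorted(calls)
            got = exclusion_map(table, region, excluders)
            expected = scan_oracle(table, region, excluders)
            assert got == expected
            # structural invariants
            for iv in got:
                assert region.start <= iv.start <= iv.end <= region.end
            for a, b in zip(got, got[1:]):
                assert a.end < b.start
            for iv in got:
                for e in excluders:
                    for k, p in enumerate(table.positions):
                        if iv.contains(region.chrom, p):
                            assert table.calls[e][k] is not AFF

    def test_adding_excluder_never_grows_union(self, region):
        """With fully informative calls, more excluders can only shrink
        the retained union. (An excluder that turns a previously
        uninformative marker informative can instead extend a
        marker-clipped bound outward — evidence refinement, so the
        property is stated for informative calls only.)"""
        rng = np.random.default_rng(7)
        origins = [AFF, UNAFF]
        for _ in range(20):
            positions = sorted(
                int(p) for p in rng.choice(700_000, size=10, replace=False)
                + region.start
            )
            calls = {
                f"E{i}": [origins[int(k)] for k in rng.integers(0, 2, size=10)]
                for i in range(2)
            }
            table = make_table(positions, calls)
            one = exclusion_map(table, region, ["E0"])
            both = exclusion_map(table, region, ["E0", "E1"])
            union_one = sum(iv.span for iv in one)
            union_both = sum(iv.span for iv in both)
            assert union_both <= union_one
            for iv in both:
                assert any(
                    o.start <= iv.start and iv.end <= o.end for o in one
                )

    def test_boundary_modes_nest(self, region):
        positions = [86_200_000, 86_400_000, 86_600_000, 86_800_000]
        table = make_table(positions, {"RB1": [AFF, UNAFF, UNAFF, AFF]})
        marker = exclusion_map(table, region, ["RB1"], BoundaryMode.MARKER)[0]
        mid = exclusion_map(table, region, ["RB1"], BoundaryMode.MIDPOINT)[0]
        outer = exclusion_map(table, region, ["RB1"], BoundaryMode.OUTER)[0]
        assert outer.start <= mid.start <= marker.start
        assert marker.end <= mid.end <= outer.end
        assert marker == GenomicInterval("chr2", 86_400_000, 86_600_000)
        assert outer == GenomicInterval("chr2", 86_200_001, 86_799_999)


class TestVariantsInInterval:
    def test_coordinates_from_the_mapping_study(self, design_321):
        interval = GenomicInterval("chr2", 86_476_559, 86_601_705)
        snp = make_variant(design_321, [HOM] * 3 + [HET] * 2 + [REF],
                           pos=86_594_449)
        deletion = make_variant(
            design_321, [HOM] * 3 + [HET] * 2 + [REF],
            pos=86_830_975, ref="A" * 56, alt="A",
        )
        assert variants_in_interval([snp, deletion], interval) == [snp]

    def test_kind_filter(self, design_321):
        from rumpmap import VariantKind

        interval = GenomicInterval("chr2", 1, 10_000)
        snp = make_variant(design_321, [HOM] * 3 + [HET] * 2 + [REF], pos=100)
        ins = make_variant(design_321, [HOM] * 3 + [HET] * 2 + [REF],
                           pos=200, ref="A", alt="AT")
        assert variants_in_interval([snp, ins], interval,
                                    VariantKind.SNP) == [snp]

    def test_empty_input(self):
        assert variants_in_interval([], GenomicInterval("chr2", 1, 10)) == []


class TestMarkerTableTsv:
    def test_tsv_round_trip_calls(self, tmp_path):
        markers = [(100, "A", "G"), (200, "C", "T")]
        genotypes = {
            "HOM1": [("A", "A"), ("C", "C")],
            "RB1": [("A", "G"), ("T", "T")],
        }
        table = MarkerHaplotypeTable.from_genotypes(markers, genotypes)
        path = tmp_path / "markers.tsv"
        table.to_tsv(path, genotypes)
        back = MarkerHaplotypeTable.from_tsv(path)
        assert back == table
        assert back.calls["RB1"] == (AFF, UNAFF)
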