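"""Genotype-pattern segregation filtering and known-variant exclusion.

The variant funnel for a fully penetrant autosomal dominant trait: a
variant is a candidate only if every homozygous affected sample is
homozygous for the alternate allele, every heterozygous affected sample
is heterozygous, and every unaffected sample is homozygous reference.
Candidates matching a previously catalogued (known) variant set are then
removed.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .models import (
    CohortDesign,
    Genotype,
    GenotypeClass,
    KnownVariantSet,
    MissingPolicy,
    Variant,
    VariantKind,
)


def genotype_matches_model(
    g: Genotype,
    expected: GenotypeClass,
    missing_policy: MissingPolicy = MissingPolicy.FAIL,
) -> bool:
    """True iff the observed genotype class equals the expected class.

    A MISSING genotype resolves via ``missing_policy``: FAIL disqualifies
    (returns False), PASS is compatible with any expectation.
    """
    if g.gt_class is GenotypeClass.MISSING:
        return missing_policy is MissingPolicy.PASS
    return g.gt_class is expected


def segregation_filter(
    variants: Iterable[Variant],
    design: CohortDesign,
    missing_policy: MissingPolicy = MissingPolicy.FAIL,
) -> list[Variant]:
    """Retain variants whose genotype pattern matches the design exactly.

    Every design sample must have a genotype on every variant; a sample
    mismatch is fatal. Output order follows input order; the result is a
    subset of the input.
    """
    expected = design.expected_classes
    out: list[Variant] = []
    for v in variants:
        missing = [s for s in expected if s not in v.genotypes]
        if missing:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} lacks genotypes for design "
                f"sample(s): {', '.join(missing)}"
            )
        if all(
            genotype_matches_model(v.genotypes[s], exp, missing_policy)
            for s, exp in expected.items()
        ):
            out.append(v)
    return out


def exclude_known(
    variants: Iterable[Variant],
    known: KnownVariantSet,
    match_position_only: bool = False,
) -> list[Variant]:
    """Drop variants present in the known set.

    Matching is exact on (chrom, pos, ref, alt) by default; with
    ``match_position_only`` any catalogued variant at the same (chrom,
    pos) excludes.
    """
    if match_position_only:
        known_pos = known.positions()
        return [v for v in variants if (v.chrom, v.pos) not in known_pos]
    return [v for v in variants if v.key not in known]


def count_by_kind(variants: Iterable[Variant]) -> dict[str, int]:
    """Count variants per kind, with INS+DEL also combined as ``indel``.

    Keys: SNP, INS, DEL, MNV, indel, total.
    """
    counts = Counter(v.kind for v in variants)
    result = {kind.value: counts.get(kind, 0) for kind in VariantKind}
    result["indel"] = result["INS"] + result["DEL"]
    result["total"] = sum(counts.values())
    return result
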