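"""Core domain types for dominant-trait causal-variant mapping.

Coordinate convention
---------------------
All positions are 1-based, as in VCF. The span of a
:class:`GenomicInterval` is defined as ``end - start`` (NOT
``end - start + 1``). This matches the arithmetic used throughout the
mapping analysis: the 86,476,559–86,601,705 critical interval is reported
as 125,146 bp and the 86,830,975–86,831,030 deletion as 55 bp.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class GenotypeClass(enum.Enum):
    """Diploid genotype class of one sample at one biallelic variant."""

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


class VariantKind(enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"


class Phenotype(enum.Enum):
    AFFECTED = "AFFECTED"
    UNAFFECTED = "UNAFFECTED"


class MissingPolicy(enum.Enum):
    """How a MISSING genotype behaves in the segregation filter.

    FAIL: a missing call disqualifies the variant (conservative default).
    PASS: a missing call is compatible with any expected class.
    """

    FAIL = "FAIL"
    PASS = "PASS"


@dataclass(frozen=True)
class Genotype:
    """One sample's genotype: class plus the underlying allele indices.

    ``alleles`` is a pair of allele indices relative to the (split,
    biallelic) variant: 0 = reference, 1 = the retained alternate. Either
    index may be ``None`` for a missing/half call, in which case
    ``gt_class`` is MISSING.
    """

    sample_id: str
    gt_class: GenotypeClass
    alleles: tuple[Optional[int], Optional[int]] = (None, None)

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a is None or b is None:
            expected = GenotypeClass.MISSING
        elif a == 0 and b == 0:
            expected = GenotypeClass.HOM_REF
        elif a > 0 and b > 0 and a == b:
            expected = GenotypeClass.HOM_ALT
        else:
            expected = GenotypeClass.HET
        if self.gt_class is not expected:
            raise ValueError(
                f"genotype class {self.gt_class.value} inconsistent with "
                f"alleles {self.alleles} for sample {self.sample_id!r}"
            )

    @classmethod
    def from_alleles(
        cls, sample_id: str, alleles: tuple[Optional[int], Optional[int]]
    ) -> "Genotype":
        a, b = alleles
        if a is None or b is None:
            gc = GenotypeClass.MISSING
        elif a == 0 and b == 0:
            gc = GenotypeClass.HOM_REF
        elif a > 0 and b > 0 and a == b:
            gc = GenotypeClass.HOM_ALT
        else:
            gc = GenotypeClass.HET
        return cls(sample_id=sample_id, gt_class=gc, alleles=alleles)

    @classmethod
    def from_class(cls, sample_id: str, gt_class: GenotypeClass) -> "Genotype":
        """Build a genotype from a class alone, with canonical alleles."""
        alleles: tuple[Optional[int], Optional[int]] = {
            GenotypeClass.HOM_REF: (0, 0),
            GenotypeClass.HET: (0, 1),
            GenotypeClass.HOM_ALT: (1, 1),
            GenotypeClass.MISSING: (None, None),
        }[gt_class]
        return cls(sample_id=sample_id, gt_class=gt_class, alleles=alleles)


def classify_variant_kind(ref: str, alt: str) -> VariantKind:
    """Classify a biallelic ref/alt pair by allele lengths.

    Single-base substitution → SNP; equal-length multi-base → MNV; longer
    alt → INS; shorter alt → DEL.
    """
    if not ref or not alt:
        raise ValueError("ref and alt alleles must be non-empty")
    if len(ref) == len(alt):
        return VariantKind.SNP if len(ref) == 1 else VariantKind.MNV
    return VariantKind.INS if len(alt) > len(ref) else VariantKind.DEL


@dataclass(frozen=True)
class Variant:
    """One biallelic small variant with per-sample genotypes.

    Multiallelic VCF records are split upstream, so ``alt`` is always a
    single allele and genotypes are classified relative to it.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def kind(self) -> VariantKind:
        return classify_variant_kind(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def gt_class(self, sample_id: str) -> GenotypeClass:
        return self.genotypes[sample_id].gt_class


@dataclass(frozen=True)
class CohortDesign:
    """Study design: each sample's phenotype and the genotype class it is
    expected to show at the causal variant under the dominant model.

    Affected samples carry the causal allele (HOM_ALT or HET); unaffected
    samples do not (HOM_REF).
    """

    samples: tuple[tuple[str, Phenotype, GenotypeClass], ...]

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_id in design")
        for sid, pheno, expected in self.samples:
            if pheno is Phenotype.AFFECTED and expected not in (
                GenotypeClass.HOM_ALT,
                GenotypeClass.HET,
            ):
                raise ValueError(
                    f"affected sample {sid!r} must expect HOM_ALT or HET"
                )
            if pheno is Phenotype.UNAFFECTED and expected is not GenotypeClass.HOM_REF:
                raise ValueError(f"unaffected sample {sid!r} must expect HOM_REF")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _, _ in self.samples)

    @property
    def expected_classes(self) -> dict[str, GenotypeClass]:
        return {s: e for s, _, e in self.samples}

    @property
    def phenotypes(self) -> dict[str, Phenotype]:
        return {s: p for s, p, _ in self.samples}


@dataclass(frozen=True)
class GenomicInterval:
    """1-based chromosomal interval with span = end - start."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"start > end ({self.start} > {self.end}) on {self.chrom}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        chrom, _, rng = text.partition(":")
        if not rng:
            raise ValueError(f"cannot parse interval {text!r}")
        lo, _, hi = rng.replace(",", "").partition("-")
        return cls(chrom=chrom, start=int(lo), end=int(hi))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_span(interval: GenomicInterval) -> int:
    """Span in bp under the end - start convention (see module docstring)."""
    return interval.span


@dataclass(frozen=True)
class KnownVariantSet:
    """Previously catalogued variants, matched exactly on (chrom, pos, ref, alt)."""

    keys: frozenset[tuple[str, int, str, str]]

    @classmethod
    def from_keys(cls, keys: Iterable[tuple[str, int, str, str]]) -> "KnownVariantSet":
        return cls(keys=frozenset(keys))

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    def positions(self) -> frozenset[tuple[str, int]]:
        return frozenset((c, p) for c, p, _, _ in self.keys)


@dataclass(frozen=True)
class GeneModel:
    """A gene's span and exon structure on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    gene_span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"exon chrom {ex.chrom} != gene chrom {self.chrom}")
            if ex.start < self.gene_span.start or ex.end > self.gene_span.end:
                raise ValueError(f"exon {ex} outside gene span {self.gene_span}")
            if prev_end is not None and ex.start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = ex.end
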