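"""Shared fixtures: the 3/2/1 cohort design and variant builders."""

from __future__ import annotations

import pytest

from rumpmap import (
    CohortDesign,
    GenomicInterval,
    Genotype,
    GenotypeClass,
    Phenotype,
    Variant,
)

HOM = GenotypeClass.HOM_ALT
HET = GenotypeClass.HET
REF = GenotypeClass.HOM_REF
MISS = GenotypeClass.MISSING


@pytest.fixture
def design_321() -> CohortDesign:
    """Three homozygous affected, two heterozygous affected, one
    homozygous unaffected — the mapping cohort layout."""
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


def make_variant(
    design: CohortDesign,
    classes,
    pos: int = 1000,
    chrom: str = "chr2",
    ref: str = "A",
    alt: str = "G",
) -> Variant:
    """Variant with the given genotype classes in design sample order."""
    gts = {
        sid: Genotype.from_class(sid, cls)
        for sid, cls in zip(design.sample_ids, classes, strict=True)
    }
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=gts)


@pytest.fixture
def region() -> GenomicInterval:
    return GenomicInterval(chrom="chr2", start=86_110_000, end=86_850_000)
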