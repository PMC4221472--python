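"""Gene-context annotation and marker–phenotype concordance."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .models import GeneModel, Phenotype, Variant


class GeneContext(enum.Enum):
    EXONIC = "EXONIC"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class GeneAnnotation:
    context: GeneContext
    nearest_gene_id: Optional[str]
    distance_bp: Optional[int]


def annotate_gene_context(
    v: Variant, genes: Sequence[GeneModel]
) -> GeneAnnotation:
    """Place a variant relative to gene models on its chromosome.

    EXONIC if the position lies in any exon; INTRONIC if inside a gene
    span but no exon; otherwise INTERGENIC with the distance to the
    nearest gene-span boundary (0 when inside a gene). With no genes on
    the chromosome the variant is INTERGENIC with no nearest gene.
    """
    same_chrom = [g for g in genes if g.chrom == v.chrom]
    if not same_chrom:
        return GeneAnnotation(GeneContext.INTERGENIC, None, None)
    best_gene: Optional[GeneModel] = None
    best_dist: Optional[int] = None
    for g in same_chrom:
        if g.gene_span.contains(v.chrom, v.pos):
            for ex in g.exons:
                if ex.contains(v.chrom, v.pos):
                    return GeneAnnotation(GeneContext.EXONIC, g.gene_id, 0)
            return GeneAnnotation(GeneContext.INTRONIC, g.gene_id, 0)
        dist = (
            g.gene_span.start - v.pos
            if v.pos < g.gene_span.start
            else v.pos - g.gene_span.end
        )
        if best_dist is None or dist < best_dist:
            best_dist, best_gene = dist, g
    assert best_gene is not None
    return GeneAnnotation(GeneContext.INTERGENIC, best_gene.gene_id, best_dist)


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between carrier status and phenotype under a dominant model."""

    n_total: int
    n_concordant: int
    n_discordant: int
    discordant_ids: tuple[str, ...]
    per_group: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_discordant != self.n_total:
            raise ValueError("concordant + discordant must equal total")
        if len(self.discordant_ids) != self.n_discordant:
            raise ValueError("discordant_ids length must equal n_discordant")


def concordance(
    carriers: Mapping[str, bool],
    phenotypes: Mapping[str, Phenotype],
    groups: Optional[Mapping[str, str]] = None,
) -> ConcordanceResult:
    """Count individuals whose carrier status predicts their phenotype.

    Under the fully penetrant dominant model an individual is concordant
    iff it carries the marker and is affected, or carries nothing and is
    unaffected. ``groups`` optionally labels individuals (e.g. by breed)
    for per-group totals.
    """
    if set(carriers) != set(phenotypes):
        only_c = sorted(set(carriers) - set(phenotypes))
        only_p = sorted(set(phenotypes) - set(carriers))
        raise ValueError(
            f"carrier/phenotype key mismatch; only in carriers: {only_c}; "
            f"only in phenotypes: {only_p}"
        )
    discordant: list[str] = []
    per_group: dict[str, list[int]] = {}
    for ind in sorted(carriers):
        ok = carriers[ind] == (phenotypes[ind] is Phenotype.AFFECTED)
        if not ok:
            discordant.append(ind)
        if groups is not None:
            g = per_group.setdefault(groups.get(ind, "ungrouped"), [0, 0])
            g[0] += 1
            g[1] += int(ok)
    n = len(carriers)
    return ConcordanceResult(
        n_total=n,
        n_concordant=n - len(discordant),
        n_discordant=len(discordant),
        discordant_ids=tuple(discordant),
        per_group={k: (t, c) for k, (t, c) in per_group.items()},
    )
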