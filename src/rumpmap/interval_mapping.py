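"""Recombinant-haplotype exclusion mapping.

An unaffected individual that carries part of the affected-associated
founder haplotype (a historical recombinant) excludes from the critical
interval every region where it carries the affected haplotype: the
causal variant cannot lie there, or the individual would be affected.
Marker-by-marker haplotype-origin calls over such "excluder" individuals
narrow the critical interval to the regions where all excluders carry
only the unaffected haplotype.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .models import GenomicInterval, Variant, VariantKind

logger = logging.getLogger(__name__)


class HaplotypeOrigin(enum.Enum):
    AFFECTED_HAP = "AFFECTED_HAP"
    UNAFFECTED_HAP = "UNAFFECTED_HAP"
    UNINFORMATIVE = "UNINFORMATIVE"


class CarrierState(enum.Enum):
    """How many affected haplotypes the individual is assumed to carry."""

    HET_CARRIER = "HET_CARRIER"
    HOM_CARRIER = "HOM_CARRIER"
    NON_CARRIER = "NON_CARRIER"


class BoundaryMode(enum.Enum):
    """Where a retained interval ends next to an excluded marker.

    MARKER (default): at the outermost marker where all excluders show the
    unaffected haplotype (conservative inner bound). MIDPOINT: halfway to
    the adjacent inconsistent marker. OUTER: immediately inside the
    adjacent inconsistent marker. Used for sensitivity analysis only.
    """

    MARKER = "marker"
    MIDPOINT = "midpoint"
    OUTER = "outer"


def assign_haplotype(
    genotype: tuple[str, str],
    affected_allele: str,
    unaffected_allele: str,
    carrier_state: CarrierState = CarrierState.HET_CARRIER,
) -> HaplotypeOrigin:
    """Call the haplotype origin of one unphased marker genotype.

    Under the single-carrier assumption (at most one affected haplotype,
    heterozygous dominant): any copy of the affected-associated allele
    means the individual carries the affected haplotype at this marker;
    homozygosity for the unaffected-associated allele means it does not;
    alleles matching neither ladder entry are uninformative.
    """
    if affected_allele == unaffected_allele:
        raise ValueError("marker alleles must be distinct")
    a, b = (x.upper() for x in genotype)
    aff, unaff = affected_allele.upper(), unaffected_allele.upper()
    if carrier_state is CarrierState.HOM_CARRIER:
        if a == aff and b == aff:
            return HaplotypeOrigin.AFFECTED_HAP
        if unaff in (a, b):
            return HaplotypeOrigin.UNAFFECTED_HAP
        return HaplotypeOrigin.UNINFORMATIVE
    if aff in (a, b):
        return HaplotypeOrigin.AFFECTED_HAP
    if a == unaff and b == unaff:
        return HaplotypeOrigin.UNAFFECTED_HAP
    return HaplotypeOrigin.UNINFORMATIVE


@dataclass(frozen=True)
class MarkerHaplotypeTable:
    """Haplotype-origin calls over a ladder of phase-informative markers.

    ``markers`` is a strictly increasing list of (pos, affected_allele,
    unaffected_allele); ``calls`` maps individual id → one origin call per
    marker, aligned with ``markers``.
    """

    markers: tuple[tuple[int, str, str], ...]
    calls: dict[str, tuple[HaplotypeOrigin, ...]]

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.markers]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("marker positions must be strictly increasing")
        for pos, aff, unaff in self.markers:
            if aff == unaff:
                raise ValueError(f"marker at {pos} has identical alleles")
        for ind, origins in self.calls.items():
            if len(origins) != len(self.markers):
                raise ValueError(
                    f"individual {ind!r} has {len(origins)} calls for "
                    f"{len(self.markers)} markers"
                )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.markers)

    @classmethod
    def from_genotypes(
        cls,
        markers: Sequence[tuple[int, str, str]],
        genotypes: dict[str, Sequence[tuple[str, str]]],
    ) -> "MarkerHaplotypeTable":
        """Build origin calls from raw diploid marker genotypes."""
        calls = {
            ind: tuple(
                assign_haplotype(gt, aff, unaff)
                for gt, (_, aff, unaff) in zip(gts, markers, strict=True)
            )
            for ind, gts in genotypes.items()
        }
        return cls(markers=tuple(markers), calls=calls)

    @classmethod
    def from_tsv(cls, path) -> "MarkerHaplotypeTable":
        """Read the marker TSV: pos, affected_allele, unaffected_allele,
        then one genotype column (e.g. ``A/G``) per individual."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        fixed = ["pos", "affected_allele", "unaffected_allele"]
        if list(df.columns[:3]) != fixed:
            raise ValueError(f"marker table must start with columns {fixed}")
        markers = [
            (int(r.pos), str(r.affected_allele), str(r.unaffected_allele))
            for r in df.itertuples()
        ]
        genotypes = {
            ind: [tuple(gt.split("/")) for gt in df[ind]]
            for ind in df.columns[3:]
        }
        return cls.from_genotypes(markers, genotypes)

    def to_tsv(self, path, genotypes: dict[str, Sequence[tuple[str, str]]]) -> None:
        data = {
            "pos": [p for p, _, _ in self.markers],
            "affected_allele": [a for _, a, _ in self.markers],
            "unaffected_allele": [u for _, _, u in self.markers],
        }
        for ind, gts in genotypes.items():
            data[ind] = ["/".join(gt) for gt in gts]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def exclusion_map(
    table: MarkerHaplotypeTable,
    original: GenomicInterval,
    excluders: Sequence[str],
    boundary: BoundaryMode = BoundaryMode.MARKER,
) -> list[GenomicInterval]:
    """Narrow the critical interval using recombinant excluders.

    Returns the maximal sub-intervals of ``original`` in which every
    excluder shows only the unaffected haplotype at all informative
    markers, sorted and non-overlapping. Interval bounds adjacent to an
    inconsistent (affected-haplotype) marker follow ``boundary``; bounds
    at the edge of the marker ladder fall back to ``original``'s bounds,
    since markers give no exclusion evidence beyond their range.

    With no excluders, or no informative marker for any excluder, the
    original interval is returned unchanged (with a warning in the latter
    case).
    """
    unknown = [e for e in excluders if e not in table.calls]
    if unknown:
        raise ValueError(f"excluder(s) not in marker table: {', '.join(unknown)}")
    if not excluders:
        return [original]

    # Per-marker combined status over all excluders.
    AFF, UNAFF, TRANS = "aff", "unaff", "trans"
    statuses: list[str] = []
    for i in range(len(table.markers)):
        origins = [table.calls[e][i] for e in excluders]
        if any(o is HaplotypeOrigin.AFFECTED_HAP for o in origins):
            statuses.append(AFF)
        elif all(o is HaplotypeOrigin.UNINFORMATIVE for o in origins):
            statuses.append(TRANS)
        else:
            statuses.append(UNAFF)

    if UNAFF not in statuses and AFF not in statuses:
        logger.warning(
            "no informative markers for excluders %s; interval not narrowed",
            list(excluders),
        )
        return [original]

    positions = table.positions
    n = len(positions)
    intervals: list[GenomicInterval] = []
    i = 0
    while i < n:
        if statuses[i] == AFF:
            i += 1
            continue
        j = i
        while j < n and statuses[j] != AFF:
            j += 1
        # segment [i, j) bounded by AFF markers (or ladder edges)
        unaff_idx = [k for k in range(i, j) if statuses[k] == UNAFF]
        if unaff_idx:
            if i == 0:
                left = original.start
            else:
                left = _bound(positions, unaff_idx[0], i - 1, boundary, side="left")
            if j == n:
                right = original.end
            else:
                right = _bound(positions, unaff_idx[-1], j, boundary, side="right")
            left = max(left, original.start)
            right = min(right, original.end)
            if left <= right:
                intervals.append(
                    GenomicInterval(chrom=original.chrom, start=left, end=right)
                )
        i = j
    return intervals


def _bound(
    positions: Sequence[int],
    inner_idx: int,
    outer_idx: int,
    boundary: BoundaryMode,
    side: str,
) -> int:
    inner, outer = positions[inner_idx], positions[outer_idx]
    if boundary is BoundaryMode.MARKER:
        return inner
    if boundary is BoundaryMode.MIDPOINT:
        return (inner + outer) // 2 if side == "left" else (inner + outer + 1) // 2
    return outer + 1 if side == "left" else outer - 1


def variants_in_interval(
    variants: Iterable[Variant],
    interval: GenomicInterval,
    kind_filter: Optional[VariantKind] = None,
) -> list[Variant]:
    """Variants whose position falls inside the (closed) interval."""
    out = [v for v in variants if interval.contains(v.chrom, v.pos)]
    if kind_filter is not None:
        out = [v for v in out if v.kind is kind_filter]
    return out
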