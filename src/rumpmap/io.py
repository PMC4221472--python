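"""Readers and writers for the pipeline's file formats.

VCF 4.x (plain or bgzipped) via pysam, GFF3 via gffutils, FASTA via
Biopython, and the small TSV tables (cohort design, marker haplotypes)
via pandas.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CohortDesign,
    GenomicInterval,
    Genotype,
    GenotypeClass,
    GeneModel,
    KnownVariantSet,
    Phenotype,
    Variant,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _split_record(rec, sample_ids: Sequence[str]) -> list[Variant]:
    """Split one (possibly multiallelic) VCF record into per-alt Variants.

    Genotypes are reclassified relative to each retained alt by counting
    copies of that alt: 2 → HOM_ALT, 1 → HET, 0 → HOM_REF. A genotype
    carrying a different alt therefore reads as HET w.r.t. this alt only
    when it also carries one copy of this alt. Any missing allele (./., or
    a half call) yields MISSING.
    """
    out: list[Variant] = []
    alts = rec.alts or ()
    for alt_index, alt in enumerate(alts, start=1):
        if alt is None or alt in ("<*>", "<NON_REF>", "*"):
            continue
        genotypes: dict[str, Genotype] = {}
        for sid in sample_ids:
            sample = rec.samples[sid]
            raw = sample.get("GT")
            if raw is None or len(raw) != 2 or any(a is None for a in raw):
                if raw is not None and any(a is not None for a in (raw or ())):
                    logger.warning(
                        "half call %s for sample %s at %s:%d treated as MISSING",
                        raw, sid, rec.chrom, rec.pos,
                    )
                genotypes[sid] = Genotype.from_class(sid, GenotypeClass.MISSING)
                continue
            n_alt = sum(1 for a in raw if a == alt_index)
            if n_alt == 2:
                alleles: tuple[Optional[int], Optional[int]] = (1, 1)
            elif n_alt == 1:
                alleles = (0, 1)
            else:
                alleles = (0, 0)
            genotypes[sid] = Genotype.from_alleles(sid, alleles)
        out.append(
            Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    genotypes=genotypes)
        )
    return out


def read_vcf(
    path: PathLike,
    design: Optional[CohortDesign] = None,
    region: Optional[GenomicInterval] = None,
) -> list[Variant]:
    """Read a VCF into per-alt Variants, sorted by (chrom, pos).

    If ``design`` is given, its samples must all be present in the VCF
    header (missing samples are fatal) and genotypes are read for exactly
    those samples. ``region`` optionally restricts to records whose POS
    lies within it.
    """
    path = str(path)
    variants: list[Variant] = []
    with pysam.VariantFile(path) as vcf:
        header_samples = list(vcf.header.samples)
        if design is not None:
            missing = [s for s in design.sample_ids if s not in header_samples]
            if missing:
                raise ValueError(
                    f"VCF {path} lacks sample column(s): {', '.join(missing)}"
                )
            sample_ids: Sequence[str] = design.sample_ids
        else:
            sample_ids = header_samples
        for rec in vcf:
            if region is not None and not region.contains(rec.chrom, rec.pos):
                continue
            variants.extend(_split_record(rec, sample_ids))
    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return variants


_CLASS_TO_GT = {
    GenotypeClass.HOM_REF: (0, 0),
    GenotypeClass.HET: (0, 1),
    GenotypeClass.HOM_ALT: (1, 1),
    GenotypeClass.MISSING: (None, None),
}


def write_vcf(
    path: PathLike,
    variants: Iterable[Variant],
    sample_ids: Sequence[str],
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write biallelic Variants as a plain-text VCF 4.2 file."""
    variants = list(variants)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if contigs is None:
        contigs = {}
        for v in variants:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + len(v.ref) + 1000)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for sid in sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            for sid in sample_ids:
                g = v.genotypes.get(sid)
                gt = _CLASS_TO_GT[g.gt_class] if g is not None else (None, None)
                rec.samples[sid]["GT"] = gt
                rec.samples[sid].phased = False
            out.write(rec)


def read_known_variants(path: PathLike) -> KnownVariantSet:
    """Read a known-variant set from a VCF or a 4-column TSV.

    TSV columns: chrom, pos, ref, alt (with header). Multiallelic VCF
    records contribute one key per alt.
    """
    path = Path(path)
    if path.suffix in (".tsv", ".txt", ".csv"):
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype={"chrom": str, "ref": str, "alt": str})
        keys = [
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples()
        ]
        return KnownVariantSet.from_keys(keys)
    keys = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                keys.append((rec.chrom, rec.pos, rec.ref, alt))
    return KnownVariantSet.from_keys(keys)


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------

def read_design_table(path: PathLike) -> CohortDesign:
    """Read the 3-column design TSV: sample_id, phenotype, expected_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "phenotype", "expected_class"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"design table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    samples = tuple(
        (
            str(r.sample_id),
            Phenotype[str(r.phenotype).upper()],
            GenotypeClass[str(r.expected_class).upper()],
        )
        for r in df.itertuples()
    )
    return CohortDesign(samples=samples)


def write_design_table(path: PathLike, design: CohortDesign) -> None:
    df = pd.DataFrame(
        [(s, p.value, e.value) for s, p, e in design.samples],
        columns=["sample_id", "phenotype", "expected_class"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Build GeneModel objects from a GFF3 file (genes with exon children)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exon_ivals = sorted(
            (
                GenomicInterval(chrom=ex.seqid, start=ex.start, end=ex.end)
                for ex in db.children(gene, featuretype="exon")
            ),
            key=lambda iv: iv.start,
        )
        # collapse overlapping exons across isoforms into a sorted
        # non-overlapping set
        merged: list[GenomicInterval] = []
        for iv in exon_ivals:
            if merged and iv.start <= merged[-1].end:
                merged[-1] = GenomicInterval(
                    chrom=iv.chrom, start=merged[-1].start,
                    end=max(merged[-1].end, iv.end),
                )
            else:
                merged.append(iv)
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in ("+", "-") else "+",
                exons=tuple(merged),
                gene_span=GenomicInterval(
                    chrom=gene.seqid, start=gene.start, end=gene.end
                ),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into {record_id: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: PathLike, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
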