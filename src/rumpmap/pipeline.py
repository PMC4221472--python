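"""End-to-end mapping pipeline: filter → exclude → narrow → intersect →
annotate → conserve → concord, driven by one config mapping.

The report records, per stage, input and output counts and the
parameters used, so the variant funnel (e.g. 2092 → 316 → 298 → 2 on a
full-scale study) is machine-checkable. Rerunning with identical config
and inputs yields an identical report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import io as rio
from .annotation import annotate_gene_context, concordance
from .conservation import conservation_score
from .interval_mapping import (
    BoundaryMode,
    MarkerHaplotypeTable,
    exclusion_map,
    variants_in_interval,
)
from .models import GenomicInterval, MissingPolicy, Phenotype
from .segregation import count_by_kind, exclude_known, segregation_filter

logger = logging.getLogger(__name__)

REPORT_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def _stage(report: dict, name: str, n_in: int, n_out: int, **params) -> None:
    report["stages"].append(
        {"name": name, "n_in": n_in, "n_out": n_out, "params": params}
    )


def _read_id_table(path, value_col: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "individual" not in df.columns or value_col not in df.columns:
        raise ValueError(
            f"table {path} must have columns 'individual' and {value_col!r}"
        )
    return dict(zip(df["individual"], df[value_col]))


def run_pipeline(config: dict[str, Any], outdir) -> dict[str, Any]:
    """Run the configured stages and write ``report.json`` plus
    ``candidates.vcf`` into ``outdir``.

    Required config keys: ``vcf``, ``design``. Optional: ``region``
    (``chrom:start-end``), ``known``, ``known_match`` ("exact" |
    "position"), ``missing_policy`` ("fail" | "pass"), ``markers``,
    ``excluders`` (list of ids), ``original_interval``, ``boundary``,
    ``gff``, ``orthologs`` (FASTA of windows with a ``query`` record),
    ``conservation_threshold``, ``genotypes_tsv``/``phenotypes_tsv`` for
    concordance. Any stage fatal error aborts with the stage name, and
    partial outputs are removed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "report_version": REPORT_VERSION,
        "config": {k: str(v) for k, v in config.items()},
        "stages": [],
    }
    written: list[Path] = []
    t0 = time.perf_counter()
    try:
        result = _run_stages(config, outdir, report, written)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("unknown", str(exc)) from exc
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2) + "\n")
    return result


def _run_stages(
    config: dict[str, Any],
    outdir: Path,
    report: dict[str, Any],
    written: list[Path],
) -> dict[str, Any]:
    # --- load ---------------------------------------------------------
    stage = "load"
    try:
        design = rio.read_design_table(config["design"])
        region: Optional[GenomicInterval] = (
            GenomicInterval.from_string(str(config["region"]))
            if config.get("region")
            else None
        )
        variants = rio.read_vcf(config["vcf"], design, region=region)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    _stage(report, stage, len(variants), len(variants),
           region=str(region) if region else None)
    logger.info("loaded %d variants", len(variants))

    # --- segregation pattern ------------------------------------------
    stage = "pattern"
    policy = MissingPolicy[str(config.get("missing_policy", "fail")).upper()]
    try:
        matched = segregation_filter(variants, design, policy)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    _stage(report, stage, len(variants), len(matched),
           missing_policy=policy.value)
    logger.info("pattern-matched %d variants", len(matched))

    # --- known-variant exclusion --------------------------------------
    stage = "exclude_known"
    surviving = matched
    if config.get("known"):
        try:
            known = rio.read_known_variants(config["known"])
            pos_only = str(config.get("known_match", "exact")) == "position"
            surviving = exclude_known(matched, known, match_position_only=pos_only)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        _stage(report, stage, len(matched), len(surviving),
               n_known=len(known),
               match="position" if pos_only else "exact")
    report["counts_by_kind"] = count_by_kind(surviving)
    logger.info("post-exclusion: %d variants", len(surviving))

    # --- interval narrowing -------------------------------------------
    stage = "interval"
    intervals: list[GenomicInterval]
    excluders = list(config.get("excluders", []))
    if excluders and not config.get("markers"):
        raise PipelineError(stage, "interval narrowing requested (excluders "
                                   "given) but no marker table configured")
    if config.get("markers"):
        try:
            table = MarkerHaplotypeTable.from_tsv(config["markers"])
            original = (
                GenomicInterval.from_string(str(config["original_interval"]))
                if config.get("original_interval")
                else region
            )
            if original is None:
                raise ValueError(
                    "interval narrowing needs 'original_interval' or 'region'"
                )
            boundary = BoundaryMode(str(config.get("boundary", "marker")))
            intervals = exclusion_map(table, original, excluders, boundary)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        _stage(report, stage, 1, len(intervals),
               excluders=excluders, boundary=boundary.value)
        report["intervals"] = [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "span_bp": iv.span}
            for iv in intervals
        ]
        candidates = [
            v for iv in intervals for v in variants_in_interval(surviving, iv)
        ]
        _stage(report, "intersect", len(surviving), len(candidates))
    else:
        intervals = [region] if region else []
        candidates = surviving

    logger.info("candidates: %d", len(candidates))

    # --- annotation ----------------------------------------------------
    annotations = []
    if config.get("gff"):
        stage = "annotate"
        try:
            genes = rio.read_gene_models(config["gff"])
            for v in candidates:
                ann = annotate_gene_context(v, genes)
                annotations.append(
                    {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                     "context": ann.context.value,
                     "nearest_gene": ann.nearest_gene_id,
                     "distance_bp": ann.distance_bp}
                )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        _stage(report, stage, len(candidates), len(annotations),
               n_genes=len(genes))
        report["annotations"] = annotations

    # --- conservation --------------------------------------------------
    if config.get("orthologs"):
        stage = "conserve"
        try:
            windows = rio.read_fasta(config["orthologs"])
            if "query" not in windows:
                raise ValueError("ortholog FASTA must contain a 'query' record")
            query = windows.pop("query")
            threshold = float(config.get("conservation_threshold", 0.70))
            cons = conservation_score(query, windows, threshold=threshold)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        _stage(report, stage, 1, 1, threshold=threshold,
               species=sorted(windows))
        report["conservation"] = {
            "per_species": cons.per_species,
            "conserved": cons.conserved,
            "threshold": threshold,
        }

    # --- concordance ----------------------------------------------------
    if config.get("genotypes_tsv") and config.get("phenotypes_tsv"):
        stage = "concord"
        try:
            carriers_raw = _read_id_table(config["genotypes_tsv"], "carrier")
            pheno_raw = _read_id_table(config["phenotypes_tsv"], "phenotype")
            carriers = {k: v in ("1", "true", "True") for k, v in carriers_raw.items()}
            phenos = {k: Phenotype[v.upper()] for k, v in pheno_raw.items()}
            conc = concordance(carriers, phenos)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        _stage(report, stage, conc.n_total, conc.n_concordant)
        report["concordance"] = {
            "n_total": conc.n_total,
            "n_concordant": conc.n_concordant,
            "n_discordant": conc.n_discordant,
            "discordant_ids": list(conc.discordant_ids),
        }

    # --- outputs --------------------------------------------------------
    cand_path = outdir / "candidates.vcf"
    written.append(cand_path)
    rio.write_vcf(cand_path, candidates, design.sample_ids)
    report["candidates"] = [
        {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
         "kind": v.kind.value}
        for v in candidates
    ]
    report["funnel"] = {
        "input": len(variants),
        "pattern": len(matched),
        "post_exclusion": len(surviving),
        "candidates": len(candidates),
    }
    return report
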