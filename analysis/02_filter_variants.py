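#!/usr/bin/env python
"""Run the variant funnel on the simulated cohort.

Segregation-pattern filter (HOM_ALT in all three homozygous affected,
HET in both heterozygous affected, HOM_REF in the unaffected) followed
by known-variant exclusion. On the full-scale study this reproduces the
2092 -> 316 -> 298 funnel with 274 SNPs + 24 indels. Counts go to
results/02_funnel.json; surviving variants to scratch/filtered.vcf.
"""

import json
from pathlib import Path

from rumpmap import MissingPolicy, count_by_kind, exclude_known, segregation_filter
from rumpmap.io import read_design_table, read_known_variants, read_vcf, write_vcf

ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "scratch" / "study"


def main() -> None:
    if not (STUDY_DIR / "variants.vcf").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    design = read_design_table(STUDY_DIR / "design.tsv")
    variants = read_vcf(STUDY_DIR / "variants.vcf", design)
    matched = segregation_filter(variants, design, MissingPolicy.FAIL)
    known = read_known_variants(STUDY_DIR / "known.vcf")
    surviving = exclude_known(matched, known)
    counts = count_by_kind(surviving)
    funnel = {
        "input": len(variants),
        "pattern_matched": len(matched),
        "known_removed": len(matched) - len(surviving),
        "post_exclusion": len(surviving),
        "by_kind": counts,
    }
    out = ROOT / "results" / "02_funnel.json"
    out.write_text(json.dumps(funnel, indent=2) + "\n")
    write_vcf(ROOT / "scratch" / "filtered.vcf", surviving, design.sample_ids)
    print(f"funnel: {funnel['input']} input -> "
          f"{funnel['pattern_matched']} pattern-matched -> "
          f"{funnel['post_exclusion']} after removing "
          f"{funnel['known_removed']} known variants")
    print(f"  kinds: {counts['SNP']} SNPs + {counts['indel']} indels "
          f"({counts['INS']} insertions, {counts['DEL']} deletions)")
    print(f"counts -> {out}")


if __name__ == "__main__":
    main()
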