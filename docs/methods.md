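# Methods

## Inheritance model and the segregation filter

The trait is modelled as autosomal dominant with full penetrance: every
carrier of the causal allele is affected, every non-carrier is not.
Each cohort sample therefore has a single expected genotype class at the
causal site — HOM_ALT for homozygous affected, HET for heterozygous
affected, HOM_REF for unaffected — recorded in the design table. The
segregation filter keeps exactly the variants whose observed genotype
class equals the expected class in **every** sample. For the 3/2/1
cohort (three homozygous affected, two heterozygous affected, one
unaffected) this is 1 of 3⁶ = 729 possible non-missing class
assignments, so under independent genotype noise the filter's false
positive rate per variant is ≲ 1/729.

Genotype classes are taken from VCF GT fields. Multiallelic records are
split into per-alt variants, and each sample is reclassified by its copy
number of the retained alt (2 → HOM_ALT, 1 → HET, 0 → HOM_REF), so a
1/2 genotype is HET with respect to either alt. Half calls (`./1`) and
no-calls are MISSING. The `missing_policy` decides whether a MISSING
genotype disqualifies a variant (`FAIL`, the default — conservative, at
the cost of losing a true candidate whose genotype dropped out) or is
treated as compatible (`PASS`). Known-variant exclusion matches on the
full (chrom, pos, ref, alt) key by default; position-only matching is a
flag, since database match criteria differ.

## Coordinate and span conventions

All positions are 1-based as in VCF. The span of an interval is defined
as `end − start`, **not** `end − start + 1`: the critical interval
chr2:86,476,559–86,601,705 is reported as 125,146 bp and the
chr2:86,830,975–86,831,030 deletion as 55 bp, and the package keeps its
arithmetic consistent with those printed values. Interval membership
(e.g. `variants_in_interval`) is closed on both ends.

## Recombinant exclusion mapping

Haplotype origin at each ladder marker is called from the unphased
genotype under the single-carrier assumption: any copy of the
affected-associated allele ⇒ the individual carries the affected
haplotype there (AFFECTED_HAP); homozygous for the unaffected-associated
allele ⇒ UNAFFECTED_HAP; anything else ⇒ UNINFORMATIVE. No statistical
phasing is attempted.

`exclusion_map` combines the calls of all excluder individuals per
marker (AFFECTED_HAP dominates; all-UNINFORMATIVE is transparent) and
returns the maximal marker runs free of AFFECTED_HAP. Boundary
convention: a run bound adjacent to an AFFECTED_HAP marker is clipped at
the run's outermost UNAFFECTED_HAP marker (conservative inner bound,
matching the reporting of the interval by its flanking marker
coordinates); a run bound at the edge of the marker ladder falls back to
the original interval bound, because markers carry no exclusion evidence
beyond their range — hence an excluder that is UNAFFECTED_HAP everywhere
leaves the original interval unchanged. `BoundaryMode.MIDPOINT` and
`.OUTER` extend clipped bounds to the midpoint of, or to just inside,
the adjacent inconsistent marker for sensitivity analysis.

Two properties follow and are tested: the retained union never contains
a marker where any excluder shows AFFECTED_HAP, and (for fully
informative calls) adding an excluder can only shrink the union. The
second property does **not** hold in general with uninformative calls:
an added excluder that makes a previously uninformative marker
informative can extend a marker-clipped bound outward. That is
refinement of evidence, not a loss of exclusions, but it means interval
unions are only guaranteed anti-monotone in excluders when every marker
is informative.

A consequence of the conservative marker clipping: a causal variant
lying between a recombinant's true breakpoint and the nearest flanking
marker is outside the reported interval. The synthetic generator
therefore guarantees recovery only when the causal position lies within
the marker-bounded interval, which it arranges by construction.

## Candidate characterization

Gene context partitions a position into EXONIC (inside any exon),
INTRONIC (inside a gene span but no exon) or INTERGENIC (distance in bp
to the nearest gene-span boundary). Concordance counts, under the
dominant model, individuals whose marker carrier status predicts their
phenotype; the discordant list is what identifies recombinants worth
haplotyping (as RB1 was).

Conservation of a candidate's neighborhood is scored on a fixed-width
window (default 300 bp, centered with 149 bp left / 150 bp right of the
site, clipped with a warning at sequence ends) against pre-extracted
orthologous windows, one per species. Windows are aligned with
Needleman–Wunsch (match +1, mismatch −1, linear gap −2; traceback ties
break diagonal → up → left, so alignments are bit-reproducible);
identity = identical columns / aligned columns, gaps counting as
columns and `N` never counting as identical. A window is conserved when
every species reaches the identity threshold (default 0.70; a
configurable default, not an empirical constant). This pairwise-identity
scorer is a declared stand-in for whatever genome-browser comparison a
given study used; it takes FASTA windows as input precisely so that no
external alignment resource is required.

## Synthetic cohort generator

`simulate_study` emulates the statistical structure the funnel assumes,
over a 740,000 bp region (chr2:86,110,000–86,850,000 under the span
convention) with six diploid genomes:

- one causal SNP (default position 86,594,449) plus `n_linked_private`
  variants private to the affected founder haplotype, all genotyped
  exactly per the design (the founder haplotype is assumed fully intact
  in the six genomes — no recombination within the cohort itself);
- `n_known_overlap` of the linked variants also emitted into the
  known-variant set (they survive the pattern filter and are removed by
  exclusion); `n_linked_indels` of the remaining linked variants are
  1–3 bp insertions/deletions, the rest SNPs;
- `n_noise` variants whose genotype patterns are drawn uniformly from
  the 728 non-segregating class assignments, so a noise variant can
  never collide with the causal pattern and expected funnel counts are
  exact: pattern-matched = 1 + n_linked_private, surviving =
  1 + n_linked_private − n_known_overlap;
- optionally one recombinant unaffected individual (RB1) present only in
  the marker table, heterozygous for the affected haplotype outside its
  two breakpoints and clean inside them; marker ladders are drawn (or
  given explicitly) with at least one marker outside each breakpoint and
  inside markers flanking the causal position;
- per-species ortholog windows generated by mutating the query window at
  fixed per-site substitution rates (defaults 0.05 / 0.10 / 0.15, i.e.
  all three species conserved at the 0.70 threshold);
- `missing_rate` masks genotypes to `./.` uniformly at random.

Variant positions are drawn without replacement; allele pairs uniformly
from distinct bases. A single `numpy` PCG64 stream seeded once per study
drives all sampling in a fixed order (markers, marker alleles,
positions, alleles/kinds, noise patterns, missing mask, ortholog
windows), so outputs are byte-identical for a given spec and every
masked genotype is reproducible from the seed.

What the generator does **not** emulate: read-level noise and coverage
(genotypes are classes, not likelihoods), linkage-disequilibrium decay,
mutation-rate heterogeneity, genotyping error other than missingness,
and within-cohort recombination. Passing tests therefore demonstrate the
pipeline's correctness given called genotypes, not robustness to
upstream calling artifacts.

## Study sizes used in the shipped analyses

The full-scale study (`paper_scale_spec`) fixes n_linked_private = 315,
n_known_overlap = 18, n_linked_indels = 24 and n_noise = 1776, giving
the funnel 2092 → 316 → 298 (274 SNPs + 24 indels), with a nine-marker
ladder whose narrowed interval is chr2:86,476,559–86,601,705 (125,146
bp) containing 2 surviving SNPs including the causal. The
parameter-recovery sweep runs 100 studies at the generator defaults
(20 linked, 5 known-overlap, 100 noise variants), sizes chosen to keep
each study's files small while leaving every funnel stage non-trivial;
a companion sweep at 5% missingness under the FAIL policy shows
recovery degrading to roughly the fraction of studies whose causal
genotypes all survive masking (0.95⁶ ≈ 0.74), while interval narrowing
— which uses the marker table, not the masked VCF — is unaffected.

The gene models used in the annotation driver are synthetic stand-ins
for the two flanking homeobox genes, placed inside the region but
outside the narrowed interval, consistent with a critical interval
containing no coding sequence.

## Degenerate inputs and error behavior

Empty VCFs yield empty funnels and exit cleanly. A design sample absent
from a VCF header, identical marker alleles, an empty ortholog map, a
window center outside its sequence, non-ACGTN characters, and
carrier/phenotype key mismatches are all fatal with the offending names
in the message. A marker ladder with no informative marker returns the
original interval with a warning. Pipeline stage failures abort with
the stage name and remove partial outputs.
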