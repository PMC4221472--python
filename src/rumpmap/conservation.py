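"""Cross-species conservation scoring of fixed-width sequence windows.

A candidate regulatory variant is supported when its sequence
neighborhood (default 300 bp, centered) is conserved across related
species. Orthologous windows are compared by optimal global alignment
(Needleman–Wunsch) and summarized as fraction identity over aligned
columns; the window is called conserved when every species meets an
identity threshold.

The alignment is deliberately bit-reproducible: fixed scores
(match +1, mismatch −1, gap −2) and a fixed traceback tie-break
(diagonal, then up, then left).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .models import GenomicInterval

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")


def extract_window(
    sequence: str,
    center_pos: int,
    width: int = 300,
    chrom: str = "",
) -> tuple[str, GenomicInterval]:
    """Cut the width-bp window centered on a 1-based position.

    The center sits at window offset ``(width - 1) // 2`` (rounding
    toward the start): a 300 bp window spans 149 bp left and 150 bp right
    of the center. Windows overhanging a sequence end are clipped with a
    warning; a center outside the sequence is fatal.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    n = len(sequence)
    if not 1 <= center_pos <= n:
        raise ValueError(
            f"center {center_pos} outside sequence of length {n}"
        )
    start = center_pos - (width - 1) // 2
    end = start + width - 1
    if start < 1 or end > n:
        logger.warning(
            "window [%d, %d] clipped to sequence bounds [1, %d]", start, end, n
        )
        start, end = max(start, 1), min(end, n)
    window = sequence[start - 1 : end]
    return window, GenomicInterval(chrom=chrom or "seq", start=start, end=end)


def _check_sequence(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    if bad:
        raise ValueError(
            f"{label} sequence contains non-ACGTN characters: {sorted(bad)}"
        )
    return seq


def needleman_wunsch(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[int, str, str]:
    """Optimal global alignment of two nucleotide sequences.

    Returns (score, aligned_a, aligned_b) with ``-`` for gaps. Traceback
    ties break diagonal, then up (gap in b), then left (gap in a), so the
    alignment is deterministic. ``N`` never counts as a match.
    """
    a = _check_sequence(a, "first")
    b = _check_sequence(b, "second")
    n, m = len(a), len(b)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0, :] = np.arange(m + 1) * gap
    H[:, 0] = np.arange(n + 1) * gap
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    is_n = ord("N")
    sub = np.where(
        (a_arr[:, None] == b_arr[None, :])
        & (a_arr[:, None] != is_n),
        match,
        mismatch,
    )
    for i in range(1, n + 1):
        row = H[i]
        prev = H[i - 1]
        diag = prev[:-1] + sub[i - 1]
        up = prev[1:] + gap
        best = np.maximum(diag, up)
        # left-dependency forces a scan within the row
        acc = row[0]
        for j in range(1, m + 1):
            acc = max(best[j - 1], acc + gap)
            row[j] = acc
    # traceback: diagonal > up > left
    ai: list[str] = []
    bi: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            ai.append(a[i - 1])
            bi.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            ai.append(a[i - 1])
            bi.append("-")
            i -= 1
        else:
            ai.append("-")
            bi.append(b[j - 1])
            j -= 1
    return int(H[n, m]), "".join(reversed(ai)), "".join(reversed(bi))


def global_align_identity(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> float:
    """Fraction of identical columns in the optimal global alignment.

    Identity = matched columns / total aligned columns (gaps included),
    in [0, 1]; symmetric in its arguments.
    """
    _, aln_a, aln_b = needleman_wunsch(a, b, match=match, mismatch=mismatch, gap=gap)
    cols = len(aln_a)
    matches = sum(
        1 for x, y in zip(aln_a, aln_b) if x == y and x != "-" and x != "N"
    )
    return matches / cols


@dataclass(frozen=True)
class ConservationResult:
    """Per-species identity of one query window and the overall call."""

    query_pos: int
    window: GenomicInterval
    per_species: dict[str, float]
    conserved: bool
    threshold: float

    def __post_init__(self) -> None:
        for sp, ident in self.per_species.items():
            if not 0.0 <= ident <= 1.0:
                raise ValueError(f"identity for {sp} out of [0,1]: {ident}")


def conservation_score(
    query_window: str,
    ortholog_windows: Mapping[str, str],
    threshold: float = 0.70,
    query_pos: int = 0,
    window: GenomicInterval | None = None,
) -> ConservationResult:
    """Score a query window against orthologous windows per species.

    ``conserved`` is True iff the minimum per-species identity reaches
    ``threshold``. An empty ortholog map is fatal.
    """
    if not ortholog_windows:
        raise ValueError("at least one ortholog window is required")
    per_species = {
        sp: global_align_identity(query_window, seq)
        for sp, seq in ortholog_windows.items()
    }
    if window is None:
        window = GenomicInterval(chrom="seq", start=1, end=max(1, len(query_window)))
    return ConservationResult(
        query_pos=query_pos,
        window=window,
        per_species=per_species,
        conserved=min(per_species.values()) >= threshold,
        threshold=threshold,
    )
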