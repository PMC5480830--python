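"""Internal pairwise and multiple alignment helpers.

Pairwise alignment is delegated to Biopython's C-accelerated
:class:`Bio.Align.PairwiseAligner`.  Multiple alignment uses a center-star
strategy (align every sequence to the most central one and merge with the
once-a-gap-always-a-gap rule), which is accurate for the near-identical,
nearly equal-length sequences this pipeline aligns (mature miRNAs and
orthologous hairpins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_SCORING = ScoringScheme()


def make_aligner(mode: str, scoring: ScoringScheme = DEFAULT_SCORING) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    # N is treated as matching nothing (used for masking scanned regions)
    matrix = np.full((5, 5), scoring.mismatch)
    np.fill_diagonal(matrix, scoring.match)
    matrix[4, :] = scoring.mismatch
    matrix[:, 4] = scoring.mismatch
    aligner.substitution_matrix = Align.substitution_matrices.Array(
        "ACGTN", dims=2, data=matrix
    )
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def identity_from_rows(row_a: str, row_b: str) -> tuple[int, int]:
    """(matched columns, aligned columns); gap columns count as mismatch."""
    matched = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    return matched, len(row_a)


def global_align(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> tuple[str, str, float]:
    """Global alignment; returns (gapped a, gapped b, score). Deterministic."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aligner = make_aligner("global", scoring)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def global_identity(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    ra, rb, _ = global_align(a, b, scoring)
    m, n = identity_from_rows(ra, rb)
    return m / n


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact common substring (simple DP)."""
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    best = 0
    for ca in a:
        cur = np.zeros(len(b) + 1, dtype=np.int32)
        eq = np.frombuffer(b.encode(), dtype=np.uint8) == ord(ca)
        cur[1:][eq] = prev[:-1][eq] + 1
        best = max(best, int(cur.max()))
        prev = cur
    return best


def _pairwise_to_center(center: str, seq: str, scoring: ScoringScheme):
    """Describe seq relative to center: per center position an aligned char
    (or gap), plus insertions (seq chars aligned to center gaps) keyed by the
    center position they precede."""
    rc, rs, _ = global_align(center, seq, scoring)
    aligned = [GAP] * len(center)
    insertions: dict[int, list[str]] = {}
    cpos = 0
    for x, y in zip(rc, rs):
        if x == GAP:
            insertions.setdefault(cpos, []).append(y)
        else:
            if y != GAP:
                aligned[cpos] = y
            cpos += 1
    return aligned, insertions


def center_star_msa(
    seqs: dict[str, str], scoring: ScoringScheme = DEFAULT_SCORING
) -> dict[str, str]:
    """Multiple alignment of labelled sequences via center-star merging.

    The center is the sequence with the highest mean pairwise identity to
    the others (ties broken by label).  Returns gapped rows keyed by label,
    all of equal length, input order preserved.
    """
    labels = list(seqs)
    if len(labels) == 0:
        return {}
    if len(labels) == 1:
        return dict(seqs)
    # pick the center: max mean identity, tie -> lexicographically first label
    mean_ident = {}
    for la in labels:
        idents = [global_identity(seqs[la], seqs[lb], scoring) for lb in labels if lb != la]
        mean_ident[la] = sum(idents) / len(idents)
    center_label = max(labels, key=lambda l: (mean_ident[l], [ -ord(c) for c in l ]))
    center = seqs[center_label]

    per_seq = {}
    max_ins = [0] * (len(center) + 1)
    for label in labels:
        if label == center_label:
            continue
        aligned, insertions = _pairwise_to_center(center, seqs[label], scoring)
        per_seq[label] = (aligned, insertions)
        for pos, chars in insertions.items():
            max_ins[pos] = max(max_ins[pos], len(chars))

    def build_row(aligned, insertions):
        parts = []
        for pos in range(len(center) + 1):
            ins = insertions.get(pos, [])
            parts.append("".join(ins) + GAP * (max_ins[pos] - len(ins)))
            if pos < len(center):
                parts.append(aligned[pos])
        return "".join(parts)

    rows = {}
    center_aligned = list(center)
    for label in labels:
        if label == center_label:
            rows[label] = build_row(center_aligned, {})
        else:
            rows[label] = build_row(*per_seq[label])
    return rows


def ungap(row: str) -> str:
    return row.replace(GAP, "")


def column_of_position(row: str, position: int) -> int:
    """Alignment column (0-based) holding the row's 0-based ungapped position."""
    seen = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            if seen == position:
                return col
            seen += 1
    raise IndexError(f"position {position} beyond ungapped length of row")
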