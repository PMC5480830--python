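"""Flank-anchored presence/absence calling of miRNA paralog loci.

A locus query is the pre-miRNA plus flanking sequence; it is scanned
against each target genome with a local aligner and hits are filtered at
70% identity over >= 300 aligned columns (configurable).  A species is
called ``present`` when a retained match overlaps the pre-miRNA portion of
the query, ``absent_flanks_conserved`` when only the flanks match and the
extracted hypothetical-location region lacks the pre-miRNA, and
``not_found`` when nothing matches — the signature of a lineage-specific
insertion/deletion with conserved flanking sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import DEFAULT_SCORING, ScoringScheme, identity_from_rows, make_aligner
from .homology import local_align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusQuery:
    paralog_id: str
    window: str  # pre-miRNA plus up to ~1000 nt flank each side
    premirna_span: tuple[int, int]  # within window

    def __post_init__(self):
        a, b = self.premirna_span
        if not (0 <= a < b <= len(self.window)):
            raise ValueError("pre-miRNA span outside query window")

    @property
    def premirna(self) -> str:
        a, b = self.premirna_span
        return self.window[a:b]


@dataclass(frozen=True)
class GenomeMatch:
    contig: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    identity: float
    aligned_length: int
    score: float


@dataclass(frozen=True)
class ScanThresholds:
    min_identity: float = 0.70
    min_length: int = 300
    min_score: float = 50.0
    max_rounds: int = 20
    #: alignments are split into separate matches at gaps longer than this
    #: (the behaviour of a seeded search: a long indel ends the hit)
    max_gap: int = 30


@dataclass(frozen=True)
class PresenceCall:
    species: str
    paralog_id: str
    status: str  # present | absent_flanks_conserved | not_found
    best_match: Optional[GenomeMatch]
    note: str = ""


def _split_alignment(
    aln, qseq: str, tseq: str, contig: str, thresholds: ScanThresholds,
    scoring: ScoringScheme,
) -> list[GenomeMatch]:
    """Break one local alignment into HSP-like pieces at long gaps and
    score each piece independently."""
    qblocks, tblocks = aln.aligned
    groups: list[list[int]] = [[0]]
    for k in range(1, len(qblocks)):
        qgap = int(qblocks[k][0] - qblocks[k - 1][1])
        tgap = int(tblocks[k][0] - tblocks[k - 1][1])
        if max(qgap, tgap) > thresholds.max_gap:
            groups.append([k])
        else:
            groups[-1].append(k)
    out = []
    for group in groups:
        matched = 0
        columns = 0
        score = 0.0
        for pos, k in enumerate(group):
            qa, qb = int(qblocks[k][0]), int(qblocks[k][1])
            ta, tb = int(tblocks[k][0]), int(tblocks[k][1])
            eq = sum(1 for x, y in zip(qseq[qa:qb], tseq[ta:tb]) if x == y)
            matched += eq
            columns += qb - qa
            score += eq * scoring.match + (qb - qa - eq) * scoring.mismatch
            if pos > 0:
                prev = group[pos - 1]
                qgap = qa - int(qblocks[prev][1])
                tgap = ta - int(tblocks[prev][1])
                columns += qgap + tgap
                for gap in (qgap, tgap):
                    if gap > 0:
                        score += scoring.gap_open + (gap - 1) * scoring.gap_extend
        qspan = (int(qblocks[group[0]][0]), int(qblocks[group[-1]][1]))
        tspan = (int(tblocks[group[0]][0]), int(tblocks[group[-1]][1]))
        identity = matched / columns if columns else 0.0
        out.append(
            GenomeMatch(
                contig=contig,
                query_span=qspan,
                target_span=tspan,
                identity=identity,
                aligned_length=columns,
                score=score,
            )
        )
    return out


def scan_genome(
    query: LocusQuery,
    genome: dict[str, str],
    thresholds: ScanThresholds = ScanThresholds(),
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[GenomeMatch]:
    """Local-alignment scan of a locus query against a multi-contig genome.

    Multiple matches per contig are recovered by iteratively masking the
    best hit's target span (with N) and re-aligning until the raw score
    drops below ``min_score``; alignments containing a gap longer than
    ``max_gap`` are split into separate matches (a deletion of the whole
    pre-miRNA must not be bridged into one hit).  Returned matches satisfy
    the identity / aligned-length filter, sorted by score descending.
    """
    aligner = make_aligner("local", scoring)
    matches: list[GenomeMatch] = []
    for contig in sorted(genome):
        target = genome[contig]
        if len(target) == 0:
            continue
        masked = target
        for _ in range(thresholds.max_rounds):
            alns = aligner.align(query.window, masked)
            if len(alns) == 0:
                break
            aln = alns[0]
            if float(aln.score) < thresholds.min_score:
                break
            blocks = aln.aligned
            if len(blocks[0]) == 0:
                break
            for piece in _split_alignment(
                aln, query.window, masked, contig, thresholds, scoring
            ):
                if (
                    piece.identity >= thresholds.min_identity
                    and piece.aligned_length >= thresholds.min_length
                ):
                    matches.append(piece)
            tspan = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
            masked = masked[: tspan[0]] + "N" * (tspan[1] - tspan[0]) + masked[tspan[1]:]
    matches.sort(key=lambda m: (-m.score, m.contig, m.target_span))
    return matches


def filter_repetitive(
    matches: Sequence[GenomeMatch], query_length: int, max_hits: int = 100
) -> list[GenomeMatch]:
    """Drop matches dominated by repetitive query sub-regions.

    Query positions covered by more than ``max_hits`` matches are masked as
    repetitive; a match is dropped when more than half of its query span is
    masked.
    """
    coverage = np.zeros(query_length, dtype=int)
    for m in matches:
        coverage[m.query_span[0]:m.query_span[1]] += 1
    repetitive = coverage > max_hits
    kept = []
    for m in matches:
        span = repetitive[m.query_span[0]:m.query_span[1]]
        if span.size and span.mean() > 0.5:
            continue
        kept.append(m)
    return kept


def call_presence(
    query: LocusQuery,
    matches: Sequence[GenomeMatch],
    genome: dict[str, str],
    species: str = "",
    hypothetical_window: tuple[int, int] = (-100, 200),
    rescue_identity: float = 0.70,
    rescue_min_frac: float = 0.60,
    min_overlap: int = 10,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> PresenceCall:
    """Classify a paralog locus in one genome from its scan matches.

    The highest-scoring match overlapping the query's pre-miRNA span by at
    least ``min_overlap`` nt gives ``present`` (a chance extension of a
    flank hit one or two bases into the pre-miRNA is not evidence of the
    pre-miRNA).  Failing that, a flank-only match anchors the hypothetical
    location of the pre-miRNA (100 nt upstream to 200 nt downstream of its
    expected start on the target); the pre-miRNA is aligned into that
    region and rescued as ``present`` only at >= ``rescue_identity`` over
    >= ``rescue_min_frac`` of its length, otherwise the call is
    ``absent_flanks_conserved``.  No matches at all gives ``not_found``.
    """
    pa, pb = query.premirna_span
    ordered = sorted(matches, key=lambda m: (-m.score, m.contig, m.target_span))
    overlapping = [
        m
        for m in ordered
        if min(m.query_span[1], pb) - max(m.query_span[0], pa) >= min_overlap
    ]
    if overlapping:
        return PresenceCall(
            species=species,
            paralog_id=query.paralog_id,
            status="present",
            best_match=overlapping[0],
            note="match overlaps pre-miRNA",
        )
    if not ordered:
        return PresenceCall(species, query.paralog_id, "not_found", None)
    flank = ordered[0]
    # map the expected pre-miRNA start onto the target via the flank match
    offset = flank.target_span[0] - flank.query_span[0]
    expected_start = pa + offset
    lo = max(0, expected_start + hypothetical_window[0])
    hi = min(len(genome[flank.contig]), expected_start + hypothetical_window[1])
    region = genome[flank.contig][lo:hi]
    if region:
        hit = local_align(query.premirna, region, scoring)
        if (
            hit.identity >= rescue_identity
            and hit.aligned_length >= rescue_min_frac * len(query.premirna)
        ):
            return PresenceCall(
                species,
                query.paralog_id,
                "present",
                flank,
                note="rescued at hypothetical location",
            )
    return PresenceCall(
        species,
        query.paralog_id,
        "absent_flanks_conserved",
        flank,
        note="flank match only; pre-miRNA missing at hypothetical location",
    )
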