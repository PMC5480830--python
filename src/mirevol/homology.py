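"""All-versus-all matching of mature miRNAs and clustering into homolog /
ortholog groups.

The search step an external blastn would perform is done by a local
(Smith-Waterman) aligner; the operative thresholds are the identity/length
filter (default 70% identity over >= 18 aligned columns for homolog
clustering, 100% over >= 18 for confirming predicted miRNAs).  Identity is
matched columns divided by aligned columns, counting gap columns as
mismatches — the stricter of the common conventions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .align import (
    DEFAULT_SCORING,
    ScoringScheme,
    center_star_msa,
    global_identity,
    identity_from_rows,
    longest_common_substring,
    make_aligner,
)
from .core_io import MatureRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchFilter:
    """Retention filter for pairwise hits."""

    min_identity: float = 0.70
    min_length: int = 18

    def __post_init__(self):
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")

    def accepts(self, identity: float, aligned_length: int) -> bool:
        return identity >= self.min_identity and aligned_length >= self.min_length


@dataclass(frozen=True)
class MatchResult:
    query: str
    subject: str
    identity: float
    aligned_length: int
    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


@dataclass
class HomologyGroup:
    """A connected component of the filtered match graph (single linkage)."""

    id: str
    members: list[str]


@dataclass
class OrthologGroup:
    """One particular miRNA: at most one member per species, aligned."""

    id: str
    parent: str
    members: list[MatureRecord]
    alignment: dict[str, str]  # member id -> gapped row

    @property
    def species(self) -> list[str]:
        return [m.species for m in self.members]


def local_align(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> MatchResult:
    """Optimal local alignment of two sequences under the scoring scheme.

    Returns the best-scoring hit; identity counts gap columns as mismatch.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aligner = make_aligner("local", scoring)
    alns = aligner.align(a, b)
    if len(alns) == 0:
        return MatchResult("", "", 0.0, 0, 0.0, (0, 0), (0, 0))
    aln = alns[0]
    blocks = aln.aligned
    if float(aln.score) <= 0 or len(blocks[0]) == 0:
        return MatchResult("", "", 0.0, 0, 0.0, (0, 0), (0, 0))
    row_a, row_b = str(aln[0]), str(aln[1])
    matched, columns = identity_from_rows(row_a, row_b)
    qspan = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
    sspan = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
    return MatchResult(
        query="",
        subject="",
        identity=matched / columns if columns else 0.0,
        aligned_length=columns,
        score=float(aln.score),
        query_span=qspan,
        subject_span=sspan,
    )


def all_vs_all(
    matures: Sequence[MatureRecord],
    filt: MatchFilter = MatchFilter(),
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[MatchResult]:
    """Filtered all-versus-all local search; one hit per retained unordered
    pair (symmetric by construction, self-hits excluded)."""
    by_id = {m.id: m for m in matures}
    if len(by_id) != len(matures):
        raise ValueError("duplicate mature record ids")
    hits = []
    for ra, rb in itertools.combinations(sorted(matures, key=lambda m: m.id), 2):
        res = local_align(ra.sequence, rb.sequence, scoring)
        if res.aligned_length and filt.accepts(res.identity, res.aligned_length):
            hits.append(
                MatchResult(
                    query=ra.id,
                    subject=rb.id,
                    identity=res.identity,
                    aligned_length=res.aligned_length,
                    score=res.score,
                    query_span=res.query_span,
                    subject_span=res.subject_span,
                )
            )
    return hits


def cluster_homologs(
    matches: Iterable[MatchResult], ids: Iterable[str]
) -> tuple[list[HomologyGroup], list[str]]:
    """Single-linkage clustering: connected components of the match graph.

    Returns (groups, singletons); group ids are the lexicographically
    smallest member id, groups sorted by id.  Singletons are sequences with
    no retained hits ("no known homologs within the dataset").
    """
    g = nx.Graph()
    g.add_nodes_from(ids)
    for m in matches:
        g.add_edge(m.query, m.subject)
    groups = []
    singletons = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) == 1:
            singletons.append(members[0])
        else:
            groups.append(HomologyGroup(id=members[0], members=members))
    groups.sort(key=lambda gr: gr.id)
    singletons.sort()
    return groups, singletons


def subdivide_orthologs(
    group: HomologyGroup,
    records: dict[str, MatureRecord],
    high_identity: float = 0.85,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_species: int = 3,
) -> list[OrthologGroup]:
    """Split a homology group into ortholog groups (one miRNA per group).

    Members are re-clustered at a high global-identity threshold
    (connected components at identity >= ``high_identity``); within a
    component each species keeps its single best representative (highest
    mean identity to the component, ties by read depth then id); components
    represented in fewer than ``min_species`` species are dropped.  Kept
    members are multiply aligned (center-star).
    """
    members = [records[i] for i in group.members]
    ident: dict[tuple[str, str], float] = {}
    g = nx.Graph()
    g.add_nodes_from(m.id for m in members)
    for ra, rb in itertools.combinations(members, 2):
        d = global_identity(ra.sequence, rb.sequence, scoring)
        ident[(ra.id, rb.id)] = ident[(rb.id, ra.id)] = d
        if d >= high_identity:
            g.add_edge(ra.id, rb.id)
    out = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        by_species: dict[str, list[str]] = {}
        for mid in comp:
            by_species.setdefault(records[mid].species, []).append(mid)
        kept = []
        for species, mids in by_species.items():
            if len(mids) == 1:
                kept.append(mids[0])
                continue

            def rank(mid):
                others = [ident[(mid, o)] for o in comp if o != mid]
                mean_ident = sum(others) / len(others) if others else 1.0
                return (-mean_ident, -records[mid].read_depth, mid)

            kept.append(min(mids, key=rank))
        species = {records[m].species for m in kept}
        if len(species) < min_species:
            continue
        kept.sort()
        aln = center_star_msa({m: records[m].sequence for m in kept}, scoring)
        out.append(
            OrthologGroup(
                id=kept[0],
                parent=group.id,
                members=[records[m] for m in kept],
                alignment=aln,
            )
        )
    out.sort(key=lambda o: o.id)
    return out


@dataclass(frozen=True)
class PredictedMature:
    """A homology-predicted miRNA awaiting experimental confirmation."""

    id: str
    family: str
    score: float
    sequence: str


@dataclass
class Confirmation:
    family: str
    representative: str
    score: float
    n_species: int
    species: list[str]


def confirm_predictions(
    validated: Sequence[MatureRecord],
    predicted: Sequence[PredictedMature],
    min_length: int = 18,
) -> list[Confirmation]:
    """Confirm predicted miRNAs against experimentally validated matures.

    A prediction is confirmed in species S iff some validated mature from S
    shares an exact (100% identity) block of at least ``min_length`` nt.
    Exact blocks are found by longest-common-substring search, so a perfect
    18-mer is never masked by a higher-scoring gapped alignment.  Paralogs
    (same family label) are collapsed to the single highest-scoring
    representative; per prediction the number of confirming species is
    reported.
    """
    per_prediction: dict[str, set[str]] = {}
    for p in predicted:
        confirming = set()
        for v in validated:
            if longest_common_substring(p.sequence, v.sequence) >= min_length:
                confirming.add(v.species)
        per_prediction[p.id] = confirming

    out = []
    by_family: dict[str, list[PredictedMature]] = {}
    for p in predicted:
        by_family.setdefault(p.family, []).append(p)
    for family in sorted(by_family):
        best = max(by_family[family], key=lambda p: (p.score, p.id))
        species = sorted(per_prediction[best.id])
        out.append(
            Confirmation(
                family=family,
                representative=best.id,
                score=best.score,
                n_species=len(species),
                species=species,
            )
        )
    return out
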