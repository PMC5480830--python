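"""Variant detection within the mature region of ortholog groups.

A variant is a column of the mature alignment where a minority base
differs from the majority (reference) base; it is reported with its
1-based position on the consensus mature sequence and classified into the
functional region it falls in (seed 1-8, central 9-12, supplementary
13-16, tail 17+).  Indel columns are collected separately: the mature
variant table proper contains substitutions only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import GAP, center_star_msa
from .core_io import RegionScheme
from .homology import OrthologGroup

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Variant:
    mirna: str
    position: int  # 1-based on the mature consensus
    ref_base: str
    alt_base: str
    species: tuple[str, ...]
    region: str

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt are identical")
        if not self.species:
            raise ValueError("species list empty")
        if self.position < 1:
            raise ValueError("position must be 1-based")


@dataclass(frozen=True)
class IndelColumn:
    mirna: str
    column: int
    species: tuple[str, ...]  # rows gapped at a base-majority column


@dataclass
class VariantCalls:
    variants: list[Variant]
    indels: list[IndelColumn]
    consensus: str


@dataclass
class VariantSummary:
    n_variants: int
    n_pairs: int  # variant-species pairs
    n_mirnas: int  # distinct miRNAs with >= 1 variant
    region_counts: dict[str, int]
    position_counts: dict[int, int]
    lineage_pair_counts: dict[str, int]


def align_group_matures(group: OrthologGroup) -> dict[str, str]:
    """Gapped alignment of the group's matures, keyed by species.

    Mature miRNA orthologs are near-identical, so the center-star
    progressive alignment yields gap-free columns mapping 1:1 to mature
    positions except at rare terminal extensions.
    """
    if len(group.members) < 3:
        raise ValueError("variant analysis needs >= 3 sequences")
    seqs = {m.species: m.sequence for m in group.members}
    return center_star_msa(seqs)


def call_variants(
    alignment: dict[str, str],
    region_scheme: RegionScheme = RegionScheme(),
    reference_species: Optional[str] = None,
    mirna: str = "",
) -> VariantCalls:
    """Call substitution variants from a gapped mature alignment.

    Per column the reference base is the majority base (ties broken by the
    designated reference species' base if present among the tied bases,
    else alphabetically).  Each minority base yields one Variant listing
    every species carrying it.  Positions count reference-base columns on
    the consensus.  Columns with more than two states are emitted as
    multiple variants with a warning; gap states become IndelColumn
    records, not substitutions.
    """
    species = list(alignment)
    rows = [alignment[s] for s in species]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    ncol = len(rows[0])
    variants: list[Variant] = []
    indels: list[IndelColumn] = []
    consensus = []
    position = 0
    for col in range(ncol):
        states = [r[col] for r in rows]
        base_counts = Counter(s for s in states if s != GAP)
        if not base_counts:
            continue
        top = max(base_counts.values())
        tied = sorted(b for b, c in base_counts.items() if c == top)
        ref = tied[0]
        if len(tied) > 1 and reference_species in alignment:
            ref_state = alignment[reference_species][col]
            if ref_state in tied:
                ref = ref_state
        if top < len(states):
            gapped = tuple(
                sp for sp, st in zip(species, states) if st == GAP
            )
            if gapped:
                indels.append(IndelColumn(mirna=mirna, column=col, species=gapped))
        # majority-gap columns are pure indel context, not mature positions
        n_gaps = len(states) - sum(base_counts.values())
        if n_gaps > max(base_counts.values()):
            continue
        position += 1
        consensus.append(ref)
        alts = sorted(b for b in base_counts if b != ref)
        if len(alts) > 1:
            logger.warning(
                "%s column %d has >2 states; emitting %d variants", mirna, col, len(alts)
            )
        for alt in alts:
            carriers = tuple(sp for sp, st in zip(species, states) if st == alt)
            variants.append(
                Variant(
                    mirna=mirna,
                    position=position,
                    ref_base=ref,
                    alt_base=alt,
                    species=carriers,
                    region=region_scheme.classify(position),
                )
            )
    return VariantCalls(variants=variants, indels=indels, consensus="".join(consensus))


def summarize_variants(
    variants: Sequence[Variant], clade_map: dict[str, str]
) -> VariantSummary:
    """Count variants per region/position and variant-species pairs per
    lineage (a variant carried by 3 species contributes 3 pairs)."""
    region_counts: dict[str, int] = {r: 0 for r in RegionScheme.REGIONS}
    position_counts: dict[int, int] = {}
    lineage_pair_counts: dict[str, int] = {}
    mirnas = set()
    n_pairs = 0
    for v in variants:
        region_counts[v.region] += 1
        position_counts[v.position] = position_counts.get(v.position, 0) + 1
        mirnas.add(v.mirna)
        for sp in v.species:
            if sp not in clade_map:
                raise ValueError(f"species {sp!r} missing from clade map")
            lineage = clade_map[sp]
            lineage_pair_counts[lineage] = lineage_pair_counts.get(lineage, 0) + 1
            n_pairs += 1
    return VariantSummary(
        n_variants=len(variants),
        n_pairs=n_pairs,
        n_mirnas=len(mirnas),
        region_counts=region_counts,
        position_counts=dict(sorted(position_counts.items())),
        lineage_pair_counts=lineage_pair_counts,
    )
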