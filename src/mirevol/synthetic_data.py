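"""Synthetic miRNA families evolved along a primate-like tree.

Every pipeline stage is testable against known ground truth: the
generator builds perfect-stem ancestral hairpins embedded in random
genomic windows and evolves them along a fixed 13-taxon tree with
region-specific substitution rates (seed most conserved), compensatory
stem substitutions, and lineage-specific duplication / deletion /
mature-register-shift events.

The substitution model is deliberately simple: per site, substitution
counts are Poisson with mean = region rate x branch length, and the
replacement base is uniform among the three alternatives (Jukes-Cantor
flavour).  A substitution at a paired stem site is accompanied, with
probability ``compensatory_prob``, by the pairing-restoring change at its
partner site.  There are no indels within loci; deletions act on whole
pre-miRNAs (flanks are kept), duplications insert a copy of the
pre-miRNA into fresh random flanking sequence (a dispersed duplication).
"""

from __future__ import annotations

import hashlib
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np

from .core_io import (
    HairpinRecord,
    MatureRecord,
    RegionScheme,
    revcomp,
    write_fasta,
    write_tsv,
)

#: 13 primate-like taxa; topology mirrors the ape / Old World monkey /
#: New World monkey / Strepsirrhine split structure; branch lengths are
#: invented (substitutions per site per unit rate).
DEFAULT_TREE = (
    "(((((((human:0.05,(chimpanzee:0.02,bonobo:0.02)pan:0.03)homininae:0.02,"
    "gorilla:0.06)africanape:0.03,orangutan:0.09)greatape:0.03,gibbon:0.11)ape:0.05,"
    "(macaque:0.06,baboon:0.06)owm:0.10)catarrhini:0.05,"
    "(marmoset:0.10,squirrel_monkey:0.10)nwm:0.12)simiiformes:0.08,"
    "((mouse_lemur:0.12,aye_aye:0.12)lemuriformes:0.05,galago:0.16)strepsirrhini:0.10)"
    "primates;"
)

APE_SPECIES = ("human", "chimpanzee", "bonobo", "gorilla", "orangutan", "gibbon")
OWM_SPECIES = ("macaque", "baboon")
NWM_SPECIES = ("marmoset", "squirrel_monkey")
STREPSIRRHINE_SPECIES = ("mouse_lemur", "aye_aye", "galago")

DEFAULT_CLADE_MAP = {
    **{s: "ape" for s in APE_SPECIES},
    **{s: "Old World monkey" for s in OWM_SPECIES},
    **{s: "New World monkey" for s in NWM_SPECIES},
    **{s: "Strepsirrhine" for s in STREPSIRRHINE_SPECIES},
}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = "ACGT"


@dataclass(frozen=True)
class RegionRates:
    """Substitutions per site per unit branch length, by functional region.

    Central and tail share one rate (both are the weakly constrained
    mature positions); the seed is the most conserved.
    """

    seed: float = 0.01
    supplementary: float = 0.05
    central_tail: float = 0.15
    loop: float = 0.35
    flank: float = 0.35

    def __post_init__(self):
        for r in (self.seed, self.supplementary, self.central_tail, self.loop, self.flank):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class SimParams:
    tree: str = DEFAULT_TREE
    rates: RegionRates = RegionRates()
    compensatory_prob: float = 0.5
    n_families: int = 20
    stem_len: int = 36
    loop_len: int = 11
    mature_len: int = 22
    flank_len: int = 400
    excised_flank: int = 20
    #: (branch label, paralog id) -- copy the paralog into a fresh locus
    duplications: tuple[tuple[str, str], ...] = ()
    #: (branch label, paralog id) -- delete the pre-miRNA, keep flanks
    deletions: tuple[tuple[str, str], ...] = ()
    #: (branch label, paralog id, offset) -- shift the mature register
    seed_shifts: tuple[tuple[str, str, int], ...] = ()
    #: enforce local-similarity separation between family ancestors; only
    #: needed when the clustering stage will run on the output
    separate_families: bool = True
    rng_seed: int = 42

    def __post_init__(self):
        if not (0 <= self.compensatory_prob <= 1):
            raise ValueError("compensatory_prob must be in [0, 1]")
        if self.stem_len < 18 or self.loop_len < 4:
            raise ValueError("stem_len >= 18 and loop_len >= 4 required")
        if self.mature_len > self.stem_len:
            raise ValueError("mature cannot be longer than the stem arm")


@dataclass(frozen=True)
class TrueVariant:
    family: str
    paralog: str
    position: int  # 1-based on the mature
    ref_base: str
    alt_base: str
    species: tuple[str, ...]
    region: str


@dataclass
class LocusOutput:
    window: str
    premirna_span: tuple[int, int]
    mature_offset: int  # register shift within the pre-miRNA
    mature: str
    hairpin: Optional[HairpinRecord]
    score: float
    read_depth: int


@dataclass
class GroundTruth:
    params: SimParams
    species: list[str]
    families: dict[str, list[str]]  # family -> paralog ids
    loci: dict[tuple[str, str], LocusOutput]  # (paralog, species) -> output
    presence: dict[tuple[str, str], str]  # (paralog, species) -> status
    variants: list[TrueVariant]
    mature_offsets: dict[tuple[str, str], int]

    def mature_records(self) -> list[MatureRecord]:
        out = []
        for (paralog, species), loc in sorted(self.loci.items()):
            if loc.hairpin is None:
                continue
            out.append(
                MatureRecord(
                    id=f"{paralog}_{species}",
                    species=species,
                    sequence=loc.mature,
                    read_depth=loc.read_depth,
                )
            )
        return out

    def true_family_labels(self) -> dict[str, str]:
        """mature record id -> family label (clustering ground truth)."""
        lab = {}
        for family, paralogs in self.families.items():
            for p in paralogs:
                for sp in self.species:
                    if (p, sp) in self.loci and self.loci[(p, sp)].hairpin is not None:
                        lab[f"{p}_{sp}"] = family
        return lab


@dataclass
class _Locus:
    paralog: str
    family: str
    seq: list[str]  # full window
    pre_span: tuple[int, int]
    pairing: dict[int, int]  # window position -> paired window position
    rates: np.ndarray  # per-site rate for the whole window
    mature_offset: int = 0
    deleted: bool = False


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_ancestral_hairpin(
    rng: np.random.Generator,
    stem_len: int = 36,
    loop_len: int = 11,
    mature_len: int = 22,
    flank: int = 20,
    species: str = "ancestor",
    hairpin_id: str = "anc",
) -> HairpinRecord:
    """A perfect-complement hairpin with the mature on the 5' arm,
    flanked by ``flank`` nt on each side (the excision product shape)."""
    if stem_len < 18 or loop_len < 4:
        raise ValueError("stem_len >= 18 and loop_len >= 4 required")
    mature_len = min(mature_len, stem_len)
    arm5 = _random_seq(rng, stem_len)
    loop = _random_seq(rng, loop_len)
    pre = arm5 + loop + revcomp(arm5)
    seq = _random_seq(rng, flank) + pre + _random_seq(rng, flank)
    pre_len = len(pre)
    mature_span = (flank, flank + mature_len)
    star_span = (flank + pre_len - mature_len, flank + pre_len)
    loop_span = (mature_span[1], star_span[0])
    return HairpinRecord(
        id=hairpin_id,
        species=species,
        sequence=seq,
        mature_span=mature_span,
        loop_span=loop_span,
        star_span=star_span,
    )


def _site_rates(params: SimParams, scheme: RegionScheme = RegionScheme()) -> np.ndarray:
    """Per-site rates for one locus window (flank + pre + flank)."""
    r = params.rates
    pre_len = 2 * params.stem_len + params.loop_len
    rates = np.full(2 * params.flank_len + pre_len, r.flank)
    pre0 = params.flank_len
    # 5' arm: mature region rates, then central_tail for the rest of the arm
    arm_rates = np.full(params.stem_len, r.central_tail)
    for p in range(params.mature_len):
        region = scheme.classify(p + 1)
        arm_rates[p] = {
            "seed": r.seed,
            "central": r.central_tail,
            "supplementary": r.supplementary,
            "tail": r.central_tail,
        }[region]
    rates[pre0 : pre0 + params.stem_len] = arm_rates
    rates[pre0 + params.stem_len : pre0 + params.stem_len + params.loop_len] = r.loop
    # 3' arm mirrors its paired partner's constraint
    rates[pre0 + params.stem_len + params.loop_len : pre0 + pre_len] = arm_rates[::-1]
    return rates


def _ancestral_locus(
    rng: np.random.Generator,
    params: SimParams,
    family: str,
    paralog: str,
    mature: Optional[str] = None,
) -> _Locus:
    pre_len = 2 * params.stem_len + params.loop_len
    if mature is None:
        arm5 = _random_seq(rng, params.stem_len)
    else:
        arm5 = mature + _random_seq(rng, params.stem_len - len(mature))
    loop = _random_seq(rng, params.loop_len)
    pre = arm5 + loop + revcomp(arm5)
    window = _random_seq(rng, params.flank_len) + pre + _random_seq(rng, params.flank_len)
    pre0 = params.flank_len
    pairing = {}
    for p in range(params.stem_len):
        i = pre0 + p
        j = pre0 + pre_len - 1 - p
        pairing[i] = j
        pairing[j] = i
    return _Locus(
        paralog=paralog,
        family=family,
        seq=list(window),
        pre_span=(pre0, pre0 + pre_len),
        pairing=pairing,
        rates=_site_rates(params),
    )


def _evolve_branch(
    rng: np.random.Generator,
    locus: _Locus,
    branch_length: float,
    c: float,
    flank_rate: float,
) -> None:
    if branch_length <= 0:
        return
    if locus.deleted:
        # only flanks remain; they evolve at the flank rate
        rates = np.full(len(locus.seq), flank_rate)
    else:
        rates = locus.rates
    counts = rng.poisson(rates * branch_length)
    for site in np.nonzero(counts)[0]:
        for _ in range(counts[site]):
            old = locus.seq[site]
            new = str(rng.choice([b for b in BASES if b != old]))
            locus.seq[site] = new
            partner = locus.pairing.get(site)
            if partner is not None and rng.random() < c:
                locus.seq[partner] = COMPLEMENT[new]


def _copy_locus(locus: _Locus) -> _Locus:
    return _Locus(
        paralog=locus.paralog,
        family=locus.family,
        seq=list(locus.seq),
        pre_span=locus.pre_span,
        pairing=dict(locus.pairing),
        rates=locus.rates,
        mature_offset=locus.mature_offset,
        deleted=locus.deleted,
    )


def _apply_events(
    rng: np.random.Generator,
    params: SimParams,
    branch_label: Optional[str],
    state: dict[str, _Locus],
    next_letter: dict[str, int],
    families: dict[str, list[str]],
) -> None:
    if branch_label is None:
        return
    for label, paralog in params.duplications:
        if label != branch_label or paralog not in state:
            continue
        src = state[paralog]
        family = src.family
        letter = string.ascii_lowercase[next_letter[family]]
        next_letter[family] += 1
        new_id = f"{family}{letter}"
        families[family].append(new_id)
        pre = src.seq[src.pre_span[0] : src.pre_span[1]]
        window = (
            list(_random_seq(rng, params.flank_len))
            + pre
            + list(_random_seq(rng, params.flank_len))
        )
        dup = _copy_locus(src)
        dup.paralog = new_id
        dup.seq = window
        state[new_id] = dup
    for label, paralog in params.deletions:
        if label != branch_label or paralog not in state:
            continue
        loc = state[paralog]
        if loc.deleted:
            continue
        a, b = loc.pre_span
        loc.seq = loc.seq[:a] + loc.seq[b:]
        loc.deleted = True
        loc.pairing = {}
    for label, paralog, offset in params.seed_shifts:
        if label != branch_label or paralog not in state:
            continue
        state[paralog].mature_offset += offset


def _diag_windows(xa: np.ndarray, xb: np.ndarray, min_len: int, min_density: float):
    """High-density ungapped windows on every diagonal.

    Returns an array of rows (offset, start_in_a, length, matches) for
    windows with matches/length >= min_density and length >= min_len.
    """
    out = []
    for off in range(-(len(xa) - min_len), len(xb) - min_len + 1):
        lo = max(0, -off)
        hi = min(len(xa), len(xb) - off)
        if hi - lo < min_len:
            continue
        eq = (xa[lo:hi] == xb[lo + off : hi + off]).astype(np.int32)
        c = np.concatenate([[0], np.cumsum(eq)])
        span = hi - lo
        for w in range(min_len, span + 1):
            m = c[w:] - c[:-w]
            for s in np.nonzero(m / w >= min_density)[0]:
                out.append((off, lo + int(s), w, int(m[s])))
    if not out:
        return np.empty((0, 4), dtype=np.int32)
    return np.array(out, dtype=np.int32)


def _offending_window(
    a: str, b: str, max_identity: float = 0.65, min_window: int = 13
) -> Optional[list[int]]:
    """Local-similarity guard between ancestral matures of different
    families.

    Flags any ungapped window of >= ``min_window`` columns at
    >= ``max_identity``, and any combination of two high-density diagonal
    pieces bridged by up to 3 gap columns reaching ``max_identity`` over
    >= ``min_window`` columns (the shape a gapped local alignment takes on
    sequences this short).  Stricter than the clustering filter (70% over
    18 columns), leaving margin for subsequent drift.  Returns the matched
    positions in ``a`` of the worst offender, or None if the pair is clean.
    """
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)

    def matched_positions(off, start, length):
        return [
            i for i in range(start, start + length) if a[i] == b[i + off]
        ]

    singles = _diag_windows(xa, xb, min_window, max_identity)
    if len(singles):
        off, start, length, _ = max(singles, key=lambda r: r[3] / r[2])
        return matched_positions(int(off), int(start), int(length))
    p = _diag_windows(xa, xb, 4, 0.55)
    if len(p) < 2:
        return None
    off, start, length, matches = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    end_a = start + length
    end_b = start + off + length
    g = np.abs(off[None, :] - off[:, None])
    ordered = (start[None, :] >= end_a[:, None]) & (
        (start + off)[None, :] >= end_b[:, None]
    )
    # l1+l2+g underestimates the column count when the pieces are not
    # adjacent, which only makes the guard stricter
    cols = length[:, None] + length[None, :] + g
    ident = (matches[:, None] + matches[None, :]) / cols
    hit = ordered & (g >= 1) & (g <= 3) & (cols >= min_window) & (ident >= max_identity)
    if not hit.any():
        return None
    i, j = np.unravel_index(int(np.where(hit, ident, -1).argmax()), hit.shape)
    return matched_positions(int(off[i]), int(start[i]), int(length[i])) + (
        matched_positions(int(off[j]), int(start[j]), int(length[j]))
    )


def _too_similar(a: str, b: str, max_identity: float = 0.65, min_window: int = 13) -> bool:
    return _offending_window(a, b, max_identity, min_window) is not None


def _separated_mature(
    rng: np.random.Generator,
    length: int,
    accepted: list[str],
    max_identity: float = 0.65,
    min_window: int = 13,
    max_repairs: int = 150,
    max_restarts: int = 500,
) -> str:
    """Sample a mature sequence locally dissimilar from all accepted ones.

    Starts from a random draw and repairs offending similarity windows by
    mutating a matched position inside the worst offender (WalkSAT-style
    local search); walks that fail to converge are restarted from a fresh
    draw.  Far faster than plain rejection sampling.
    """
    for _ in range(max_restarts):
        m = list(_random_seq(rng, length))
        repairs = 0
        stuck = False
        while not stuck:
            dirty = False
            for other in accepted:
                while True:
                    offender = _offending_window(
                        "".join(m), other, max_identity, min_window
                    )
                    if offender is None:
                        break
                    dirty = True
                    repairs += 1
                    if repairs > max_repairs:
                        stuck = True
                        break
                    pos = offender[rng.integers(len(offender))]
                    choices = [c for c in BASES if c != m[pos]]
                    m[pos] = choices[rng.integers(len(choices))]
                if stuck:
                    break
            if not dirty:
                return "".join(m)
    raise RuntimeError("could not separate ancestral matures")  # pragma: no cover


def evolve_along_tree(params: SimParams = SimParams()) -> GroundTruth:
    """Simulate all families along the tree and record complete ground truth."""
    rng = np.random.default_rng(params.rng_seed)
    tree = dendropy.Tree.get(data=params.tree, schema="newick", preserve_underscores=True)
    pre_len = 2 * params.stem_len + params.loop_len

    families: dict[str, list[str]] = {}
    root_state: dict[str, _Locus] = {}
    next_letter: dict[str, int] = {}
    prev_matures: list[str] = []
    for f in range(params.n_families):
        family = f"fam{f:02d}"
        paralog = f"{family}a"
        families[family] = [paralog]
        next_letter[family] = 1
        # sample the ancestral mature so families stay dissimilar: any
        # chance local similarity to an earlier family's mature would put
        # single-linkage clustering at the mercy of one spurious hit
        if params.separate_families:
            mature = _separated_mature(rng, params.mature_len, prev_matures)
            prev_matures.append(mature)
        else:
            mature = None
        locus = _ancestral_locus(rng, params, family, paralog, mature=mature)
        root_state[paralog] = locus

    loci: dict[tuple[str, str], LocusOutput] = {}
    presence: dict[tuple[str, str], str] = {}
    offsets: dict[tuple[str, str], int] = {}
    species: list[str] = []

    def node_label(node) -> Optional[str]:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def walk(node, state: dict[str, _Locus]):
        label = node_label(node)
        if node.parent_node is not None:
            _apply_events(rng, params, label, state, next_letter, families)
            bl = node.edge.length or 0.0
            for pid in sorted(state):
                _evolve_branch(
                    rng, state[pid], bl, params.compensatory_prob, params.rates.flank
                )
        if node.is_leaf():
            sp = label
            species.append(sp)
            for pid in sorted(state):
                loc = state[pid]
                if loc.deleted:
                    presence[(pid, sp)] = "absent_flanks_conserved"
                    loci[(pid, sp)] = LocusOutput(
                        window="".join(loc.seq),
                        premirna_span=(loc.pre_span[0], loc.pre_span[0]),
                        mature_offset=loc.mature_offset,
                        mature="",
                        hairpin=None,
                        score=0.0,
                        read_depth=0,
                    )
                    continue
                presence[(pid, sp)] = "present"
                window = "".join(loc.seq)
                a, b = loc.pre_span
                off = loc.mature_offset
                mature = window[a + off : a + off + params.mature_len]
                ef = params.excised_flank
                ex_a, ex_b = a - ef, b + ef
                excised = window[ex_a:ex_b]
                m_span = (ef + off, ef + off + params.mature_len)
                s_span = (ef + pre_len - params.mature_len - off, ef + pre_len - off)
                score = float(np.round(rng.uniform(0, 10), 2))
                depth = int(rng.integers(3, 500))
                hairpin = HairpinRecord(
                    id=f"{pid}_{sp}",
                    species=sp,
                    sequence=excised,
                    mature_span=m_span,
                    loop_span=(m_span[1], s_span[0]),
                    star_span=s_span,
                    score=score,
                    read_depth=depth,
                )
                offsets[(pid, sp)] = off
                loci[(pid, sp)] = LocusOutput(
                    window=window,
                    premirna_span=(a, b),
                    mature_offset=off,
                    mature=mature,
                    hairpin=hairpin,
                    score=score,
                    read_depth=depth,
                )
            return
        for child in node.child_nodes():
            walk(child, {pid: _copy_locus(l) for pid, l in state.items()})

    walk(tree.seed_node, root_state)

    # fill not_found for species never reached by a duplicated paralog
    all_paralogs = [p for f in sorted(families) for p in families[f]]
    for pid in all_paralogs:
        for sp in species:
            presence.setdefault((pid, sp), "not_found")

    truth = GroundTruth(
        params=params,
        species=species,
        families=families,
        loci=loci,
        presence=presence,
        variants=[],
        mature_offsets=offsets,
    )
    truth.variants = _true_variants(truth)
    return truth


def _true_variants(truth: GroundTruth, scheme: RegionScheme = RegionScheme()) -> list[TrueVariant]:
    """Majority-rule variant truth per paralog (>= 3 species present).

    Uses the same reference convention as the variant caller: majority
    base, ties broken alphabetically.
    """
    out = []
    for family in sorted(truth.families):
        for paralog in truth.families[family]:
            matures = {
                sp: truth.loci[(paralog, sp)].mature
                for sp in truth.species
                if truth.presence[(paralog, sp)] == "present"
            }
            if len(matures) < 3:
                continue
            length = len(next(iter(matures.values())))
            for pos in range(length):
                counts: dict[str, list[str]] = {}
                for sp, seq in sorted(matures.items()):
                    counts.setdefault(seq[pos], []).append(sp)
                if len(counts) == 1:
                    continue
                top = max(len(v) for v in counts.values())
                ref = sorted(b for b, v in counts.items() if len(v) == top)[0]
                for alt in sorted(counts):
                    if alt == ref:
                        continue
                    out.append(
                        TrueVariant(
                            family=family,
                            paralog=paralog,
                            position=pos + 1,
                            ref_base=ref,
                            alt_base=alt,
                            species=tuple(counts[alt]),
                            region=scheme.classify(pos + 1),
                        )
                    )
    return out


def write_study_bundle(truth: GroundTruth, out_dir) -> dict[str, str]:
    """Write the bundle the pipeline consumes; returns {path: sha256}."""
    out = Path(out_dir)
    (out / "matures").mkdir(parents=True, exist_ok=True)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def record(path: Path):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest[str(path.relative_to(out))] = digest

    for sp in truth.species:
        recs = [
            (f"{pid}_{s}", loc.mature)
            for (pid, s), loc in sorted(truth.loci.items())
            if s == sp and loc.hairpin is not None
        ]
        path = out / "matures" / f"{sp}.fasta"
        write_fasta(path, recs)
        record(path)

        contigs = [
            (f"{pid}_locus", loc.window)
            for (pid, s), loc in sorted(truth.loci.items())
            if s == sp and loc.window
        ]
        path = out / "genomes" / f"{sp}.fasta"
        write_fasta(path, contigs)
        record(path)

    rows = []
    for (pid, sp), loc in sorted(truth.loci.items()):
        h = loc.hairpin
        if h is None:
            continue
        rows.append(
            [h.id, sp, f"{h.score:g}", h.read_depth, h.mature, h.star, h.sequence]
        )
    path = out / "predictions.tsv"
    write_tsv(path, ["id", "species", "score", "depth", "mature", "star", "hairpin"], rows)
    record(path)

    path = out / "tree.nwk"
    path.write_text(truth.params.tree + "\n")
    record(path)

    path = out / "truth_families.tsv"
    write_tsv(
        path,
        ["family", "paralog"],
        [[f, p] for f in sorted(truth.families) for p in truth.families[f]],
    )
    record(path)

    path = out / "truth_variants.tsv"
    write_tsv(
        path,
        ["family", "paralog", "position", "ref", "alt", "species", "region"],
        [
            [v.family, v.paralog, v.position, v.ref_base, v.alt_base,
             ",".join(v.species), v.region]
            for v in truth.variants
        ],
    )
    record(path)

    path = out / "truth_presence.tsv"
    write_tsv(
        path,
        ["paralog", "species", "status"],
        [[p, s, st] for (p, s), st in sorted(truth.presence.items())],
    )
    record(path)

    path = out / "truth_offsets.tsv"
    write_tsv(
        path,
        ["paralog", "species", "offset"],
        [[p, s, o] for (p, s), o in sorted(truth.mature_offsets.items())],
    )
    record(path)

    path = out / "manifest.tsv"
    write_tsv(path, ["file", "sha256"], sorted(manifest.items()))
    return manifest
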