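"""RNA secondary-structure engine and structural-conservation statistics.

The energy model is a weighted Nussinov scheme: each canonical base pair
contributes a fixed negative score (GC -3, AU -2, GU -1 by default, on the
internal DNA alphabet AT and GT stand for AU and GU) and structures are
constrained to be nested with a minimum hairpin loop of 3 unpaired bases.
The "minimum free energy" (MFE) of a sequence is the minimum total pairing
score.  This model is deliberately simple: it is brute-force verifiable,
and the conservation statistics built on it (z-score, Structure
Conservation Index, covariance contribution) are defined relative to
whatever energy model is used.

Statistics
----------
z-score
    Number of standard deviations between a sequence's MFE and the MFE of
    shuffled sequences of the same length and composition.  The null here
    is a Monte-Carlo dinucleotide-preserving (Altschul-Erickson) shuffle.
    Scores below -3 indicate very stable structures.
SCI
    Consensus MFE of an alignment divided by the mean MFE of its
    individual sequences; close to 1 indicates structural conservation.
covariance contribution
    The part of the consensus MFE contributed by the covariance term,
    which rewards compensatory/consistent substitutions in paired columns
    and penalizes pair-breaking ones; negative values indicate
    compensatory evolution.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import GAP, center_star_msa, column_of_position, ungap
from .core_io import HairpinRecord

logger = logging.getLogger(__name__)

_INF = float("inf")


@dataclass(frozen=True)
class FoldParams:
    """Pairing scores (negative) and minimum hairpin loop length."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    min_loop: int = 3

    def __post_init__(self):
        if self.gc >= 0 or self.au >= 0 or self.gu >= 0:
            raise ValueError("pair scores must be negative")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")

    def pair_score(self, x: str, y: str) -> float:
        """Score of pairing bases x and y; +inf if not canonical."""
        p = x + y
        if p in ("GC", "CG"):
            return self.gc
        if p in ("AT", "TA"):
            return self.au
        if p in ("GT", "TG"):
            return self.gu
        return _INF


DEFAULT_FOLD = FoldParams()


@dataclass(frozen=True)
class FoldResult:
    structure: str
    energy: float
    pairs: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class StabilityResult:
    z: float
    n_shuffles: int
    shuffle_mean: float
    shuffle_sd: float
    energy: float
    rng_seed: int
    degenerate: bool = False


@dataclass(frozen=True)
class ConservationResult:
    sci: Optional[float]
    consensus_energy: float
    thermo_part: float
    covariance_contribution: float
    mean_pairwise_identity: float
    consensus_structure: str
    mean_individual_energy: float
    defined: bool = True


@dataclass(frozen=True)
class CovParams:
    """Covariance scoring for consensus folding.

    For a candidate column pair, with t distinct canonical pair types
    among pairable rows and m rows not pairable there:
    cov = -b*(t-1) + q*m.  A column pair is allowed only if more than
    ``min_pairable_frac`` of rows are pairable.
    """

    b: float = 1.0
    q: float = 1.0
    min_pairable_frac: float = 0.5


DEFAULT_COV = CovParams()


def _nussinov(score: np.ndarray, min_loop: int) -> tuple[float, list[tuple[int, int]]]:
    """Minimize total pairing score over nested structures.

    ``score[i, j]`` is the cost of pairing positions i < j (+inf if
    disallowed).  Deterministic traceback: prefer leaving i unpaired, then
    pairing i with the smallest admissible k.
    """
    n = score.shape[0]
    if n == 0:
        return 0.0, []
    W = np.zeros((n + 1, n + 1))
    ml = min_loop
    for span in range(ml + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j]
            # i paired with k in [i+ml+1, j]
            cand = score[i, i + ml + 1 : j + 1] + W[i + 1, i + ml : j] + W[i + ml + 2 : j + 2, j]
            m = cand.min()
            if m < best:
                best = m
            W[i, j] = best
    energy = float(W[0, n - 1]) if n > 1 else 0.0
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    tol = 1e-9
    while stack:
        i, j = stack.pop()
        if j - i <= ml:
            continue
        target = W[i, j]
        if target >= -tol:
            continue
        if abs(W[i + 1, j] - target) <= tol:
            stack.append((i + 1, j))
            continue
        for k in range(i + ml + 1, j + 1):
            s = score[i, k]
            if s == _INF:
                continue
            right = W[k + 1, j] if k + 1 <= j else 0.0
            if abs(s + W[i + 1, k - 1] + right - target) <= tol:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - would indicate a DP bookkeeping bug
            raise AssertionError("traceback failed")
    pairs.sort()
    return energy, pairs


def _structure_string(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i] = "("
        s[j] = ")"
    return "".join(s)


def _sequence_score_matrix(seq: str, params: FoldParams) -> np.ndarray:
    n = len(seq)
    codes = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    table = np.full((5, 5), _INF)
    for x in "ACGT":
        for y in "ACGT":
            sc = params.pair_score(x, y)
            table[codes[x], codes[y]] = sc
    idx = np.array([codes[c] for c in seq])
    return table[idx[:, None], idx[None, :]]


def fold_mfe(seq: str, params: FoldParams = DEFAULT_FOLD) -> FoldResult:
    """Minimum-energy nested structure of a sequence (dynamic program)."""
    if not seq:
        raise ValueError("cannot fold empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in sequence")
    score = _sequence_score_matrix(seq, params)
    energy, pairs = _nussinov(score, params.min_loop)
    return FoldResult(_structure_string(len(seq), pairs), energy, tuple(pairs))


def brute_force_fold(seq: str, params: FoldParams = DEFAULT_FOLD) -> FoldResult:
    """Exhaustive enumeration of nested canonical structures (test oracle).

    Refuses sequences longer than 14 nt.
    """
    if len(seq) > 14:
        raise ValueError("brute_force_fold only accepts length <= 14")
    score = _sequence_score_matrix(seq, params)
    ml = params.min_loop
    n = len(seq)

    def enumerate_all(avail: tuple[int, ...]):
        if not avail:
            return [(0.0, ())]
        i = avail[0]
        out = []
        for e, p in enumerate_all(avail[1:]):
            out.append((e, p))
        for idx in range(1, len(avail)):
            j = avail[idx]
            if j - i <= ml or score[i, j] == _INF:
                continue
            inside = tuple(avail[1:idx])
            outside = tuple(avail[idx + 1 :])
            for e_in, p_in in enumerate_all(inside):
                for e_out, p_out in enumerate_all(outside):
                    out.append((score[i, j] + e_in + e_out, ((i, j),) + p_in + p_out))
        return out

    best_energy = 0.0
    best_pairs: tuple = ()
    for e, p in enumerate_all(tuple(range(n))):
        if e < best_energy:
            best_energy, best_pairs = e, p
    pairs = tuple(sorted(best_pairs))
    return FoldResult(_structure_string(n, pairs), best_energy, pairs)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson dinucleotide-preserving shuffle.

    Preserves the exact multiset of dinucleotides (hence mononucleotide
    composition) and the first and last residues.
    """
    n = len(seq)
    if n <= 2:
        return seq
    # multigraph of dinucleotide edges
    edges: dict[str, list[str]] = {}
    for x, y in zip(seq, seq[1:]):
        edges.setdefault(x, []).append(y)
    vertices = sorted(edges.keys() | {seq[-1]})
    if len(vertices) == 1:
        return seq
    last = seq[-1]

    # choose a random "last edge" per non-terminal vertex such that the
    # last-edge graph connects every vertex to the terminal one
    for _ in range(10000):
        last_edge = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            outs = edges.get(v, [])
            if not outs:
                ok = False
                break
            last_edge[v] = outs[rng.integers(len(outs))]
        if not ok:
            continue
        # connectivity check: follow last edges toward `last`
        def reaches(v):
            seen = set()
            while v != last:
                if v in seen or v not in last_edge:
                    return False
                seen.add(v)
                v = last_edge[v]
            return True

        if all(reaches(v) for v in vertices if v != last):
            break
    else:  # pragma: no cover
        return seq

    shuffled_edges = {}
    for v in vertices:
        outs = list(edges.get(v, []))
        if v != last:
            outs.remove(last_edge[v])
        perm = rng.permutation(len(outs))
        outs = [outs[i] for i in perm]
        if v != last:
            outs.append(last_edge[v])
        shuffled_edges[v] = outs

    # Eulerian walk from the first residue
    result = [seq[0]]
    ptr = {v: 0 for v in vertices}
    v = seq[0]
    for _ in range(n - 1):
        nxt = shuffled_edges[v][ptr[v]]
        ptr[v] += 1
        result.append(nxt)
        v = nxt
    return "".join(result)


def z_score(
    seq: str,
    n_shuffles: int = 50,
    rng_seed: int = 0,
    params: FoldParams = DEFAULT_FOLD,
) -> StabilityResult:
    """Monte-Carlo z-score of a sequence's fold energy against its
    dinucleotide-shuffle null.  sd below 1e-9 (e.g. homopolymers) gives
    z = 0 with the degeneracy flag set."""
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = np.random.default_rng(rng_seed)
    e_obs = fold_mfe(seq, params).energy
    energies = np.array(
        [fold_mfe(dinucleotide_shuffle(seq, rng), params).energy for _ in range(n_shuffles)]
    )
    mean = float(energies.mean())
    sd = float(energies.std(ddof=1))
    if sd < 1e-9:
        return StabilityResult(0.0, n_shuffles, mean, sd, e_obs, rng_seed, degenerate=True)
    return StabilityResult((e_obs - mean) / sd, n_shuffles, mean, sd, e_obs, rng_seed)


def _consensus_matrices(
    rows: Sequence[str], params: FoldParams, cov: CovParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(total score, thermo part, cov part) per column pair; +inf where the
    pairable-fraction gate fails or no canonical pair exists."""
    n_rows = len(rows)
    n = len(rows[0])
    thermo = np.zeros((n, n))
    covm = np.zeros((n, n))
    total = np.full((n, n), _INF)
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            types = set()
            t_sum = 0.0
            m = 0
            for r in rows:
                x, y = r[i], r[j]
                if x == GAP or y == GAP:
                    m += 1
                    continue
                s = params.pair_score(x, y)
                if s == _INF:
                    m += 1
                else:
                    types.add(x + y)
                    t_sum += s
            pairable = n_rows - m
            if pairable / n_rows <= cov.min_pairable_frac:
                continue
            thermo[i, j] = t_sum / n_rows
            covm[i, j] = -cov.b * (len(types) - 1) + cov.q * m
            total[i, j] = thermo[i, j] + covm[i, j]
    return total, thermo, covm


def consensus_fold(
    alignment: Sequence[str],
    params: FoldParams = DEFAULT_FOLD,
    cov_params: CovParams = DEFAULT_COV,
) -> tuple[str, float, float, float]:
    """Consensus structure of a gapped alignment.

    Column-pair score = mean over rows of the row's pair score (0 for
    rows not pairable there) plus the covariance term; a column pair is
    admissible only if more than half the rows are pairable.  Returns
    (consensus dot-bracket, consensus energy, thermodynamic part,
    covariance contribution).
    """
    rows = list(alignment)
    if len(rows) < 2:
        raise ValueError("consensus_fold needs >= 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    total, thermo, covm = _consensus_matrices(rows, params, cov_params)
    energy, pairs = _nussinov(total, params.min_loop)
    thermo_part = float(sum(thermo[i, j] for i, j in pairs))
    cov_part = float(sum(covm[i, j] for i, j in pairs))
    return _structure_string(len(rows[0]), pairs), energy, thermo_part, cov_part


def mean_pairwise_identity(alignment: Sequence[str]) -> float:
    """Mean over row pairs of identical non-gap columns / columns where at
    least one row is non-gap (gap-vs-base mismatches, gap-vs-gap excluded)."""
    rows = list(alignment)
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    idents = []
    for a_i in range(len(rows)):
        for b_i in range(a_i + 1, len(rows)):
            a, b = rows[a_i], rows[b_i]
            match = 0
            comparable = 0
            for x, y in zip(a, b):
                if x == GAP and y == GAP:
                    continue
                comparable += 1
                if x == y:
                    match += 1
            if comparable == 0:
                raise ValueError("row pair with no comparable columns")
            idents.append(match / comparable)
    return float(np.mean(idents))


def sci(
    alignment: Sequence[str],
    params: FoldParams = DEFAULT_FOLD,
    cov_params: CovParams = DEFAULT_COV,
) -> ConservationResult:
    """Structure Conservation Index of a gapped alignment.

    sci = consensus energy / mean individual (ungapped) fold energy; the
    ratio is undefined (flagged) when the mean individual energy is ~0,
    e.g. for unfoldable sequences.
    """
    rows = list(alignment)
    if len(rows) < 2:
        raise ValueError("sci needs >= 2 rows")
    if any(not ungap(r) for r in rows):
        raise ValueError("all-gap row in alignment")
    structure, consensus_energy, thermo_part, cov_part = consensus_fold(
        rows, params, cov_params
    )
    individual = [fold_mfe(ungap(r), params).energy for r in rows]
    mean_e = float(np.mean(individual))
    mpi = mean_pairwise_identity(rows)
    if abs(mean_e) < 1e-9:
        return ConservationResult(
            None, consensus_energy, thermo_part, cov_part, mpi, structure, mean_e,
            defined=False,
        )
    return ConservationResult(
        consensus_energy / mean_e, consensus_energy, thermo_part, cov_part, mpi,
        structure, mean_e,
    )


@dataclass(frozen=True)
class ExcisedWindow:
    sequence: str
    span: tuple[int, int]
    truncated: bool


def excise_hairpin_window(
    genome: str, stack_span: tuple[int, int], near: int = 20, far: int = 70
) -> tuple[ExcisedWindow, ExcisedWindow]:
    """The two candidate excision windows around a read stack.

    One window has ``near`` nt upstream and ``far`` nt downstream flank,
    the other the reverse — the two registers in which a read stack can sit
    on the 5' or 3' arm of a hairpin.  Windows are truncated (and flagged)
    at contig edges.
    """
    start, end = stack_span
    if not (0 <= start <= end <= len(genome)):
        raise ValueError(f"stack span {stack_span} outside genome bounds")

    def cut(a, b):
        ca, cb = max(0, a), min(len(genome), b)
        return ExcisedWindow(genome[ca:cb], (ca, cb), truncated=(ca != a or cb != b))

    return cut(start - near, end + far), cut(start - far, end + near)


@dataclass
class SeedShiftReport:
    shifts: dict[str, int]  # species -> signed column offset from the mode
    modal_column: int
    start_columns: dict[str, int]

    def partition(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sp, sh in sorted(self.shifts.items()):
            out.setdefault(sh, []).append(sp)
        return out


def detect_seed_shift(hairpins: Sequence[HairpinRecord]) -> SeedShiftReport:
    """Detect shifts of the mature excision register across species.

    Hairpin sequences are multiply aligned; each species' mature start is
    mapped to an alignment column; the shift is the signed offset of that
    column from the modal start column.  Working in column space makes the
    report robust to indels upstream of the mature.
    """
    if len(hairpins) < 3:
        raise ValueError("seed-shift detection needs >= 3 species")
    for h in hairpins:
        if not (0 <= h.mature_span[0] < h.mature_span[1] <= len(h.sequence)):
            raise ValueError(f"mature span outside hairpin for {h.id}")
    seqs = {h.species: h.sequence for h in hairpins}
    if len(seqs) != len(hairpins):
        raise ValueError("duplicate species among hairpins")
    msa = center_star_msa(seqs)
    start_cols = {
        h.species: column_of_position(msa[h.species], h.mature_span[0]) for h in hairpins
    }
    counts = Counter(start_cols.values())
    top = max(counts.values())
    modal = min(c for c, k in counts.items() if k == top)
    shifts = {sp: col - modal for sp, col in start_cols.items()}
    return SeedShiftReport(shifts=shifts, modal_column=modal, start_columns=start_cols)
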