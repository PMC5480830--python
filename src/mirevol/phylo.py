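"""Distance-based phylogenetics: p-distance matrices and neighbor-joining.

Trees here serve the same purpose the study's likelihood trees served —
visual grouping of homologs — so the deterministic, assumption-light
neighbor-joining algorithm on p-distances is used.  NJ recovers the
generating tree exactly whenever the input matrix is additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import GAP

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, values in [0, 1] for p-distances

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("nonzero diagonal")
        self.matrix = m


def p_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """p-distances (1 - pairwise identity) from a gapped alignment.

    The pair rule matches mean_pairwise_identity: gap-vs-base counts as a
    difference, gap-vs-gap columns are excluded.
    """
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("need >= 2 rows")
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment[taxa[i]], alignment[taxa[j]]
            match = comparable = 0
            for x, y in zip(a, b):
                if x == GAP and y == GAP:
                    continue
                comparable += 1
                if x == y:
                    match += 1
            if comparable == 0:
                raise ValueError(f"no comparable columns between {taxa[i]} and {taxa[j]}")
            m[i, j] = m[j, i] = 1 - match / comparable
    return DistanceMatrix(taxa=taxa, matrix=m)


class _Node:
    __slots__ = ("label", "children", "min_leaf")

    def __init__(self, label=None, children=(), min_leaf=None):
        self.label = label
        self.children = list(children)  # (child, branch length)
        self.min_leaf = min_leaf if min_leaf is not None else label

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class NJResult:
    newick: str
    negative_clamped: bool

    def __str__(self) -> str:
        return self.newick


def nj_tree(dm: DistanceMatrix) -> NJResult:
    """Canonical neighbor-joining with a deterministic tie-break.

    When several pairs minimize the Q criterion, the pair whose canonical
    labels (smallest leaf label of each subtree) sort lexicographically
    smallest is joined.  Negative branch lengths are clamped to 0 and
    flagged.  Returns an unrooted tree as Newick (trifurcating root).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    nodes = [_Node(label=t) for t in dm.taxa]
    D = dm.matrix.copy()
    active = list(range(n))
    clamped = False
    tol = 1e-12

    def clamp(x):
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (k - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [
            (ai, aj)
            for ai in range(k)
            for aj in range(ai + 1, k)
            if Q[ai, aj] <= qmin + tol
        ]
        ai, aj = min(
            cands,
            key=lambda p: tuple(
                sorted((nodes[active[p[0]]].min_leaf, nodes[active[p[1]]].min_leaf))
            ),
        )
        i, j = active[ai], active[aj]
        dij = D[i, j]
        bi = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (k - 2))
        bj = dij - bi
        new = _Node(
            children=[(nodes[i], clamp(bi)), (nodes[j], clamp(bj))],
            min_leaf=min(nodes[i].min_leaf, nodes[j].min_leaf),
        )
        # distances from the new node to the remaining active nodes
        new_row = np.zeros(D.shape[0] + 1)
        for am in range(k):
            m = active[am]
            if m in (i, j):
                continue
            new_row[m] = 0.5 * (D[i, m] + D[j, m] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [m for m in active if m not in (i, j)] + [len(nodes) - 1]

    # final trifurcation: three-point formulas
    i, j, m = active
    dij, dim, djm = D[i, j], D[i, m], D[j, m]
    bi = clamp(0.5 * (dij + dim - djm))
    bj = clamp(0.5 * (dij + djm - dim))
    bm = clamp(0.5 * (dim + djm - dij))
    order = sorted(
        [(nodes[i], bi), (nodes[j], bj), (nodes[m], bm)], key=lambda t: t[0].min_leaf
    )
    inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in order)
    if clamped:
        logger.warning("negative NJ branch length(s) clamped to 0")
    return NJResult(newick=f"({inner});", negative_clamped=clamped)
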