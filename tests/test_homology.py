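"""Homolog search, single-linkage clustering and ortholog subdivision."""

import itertools

import numpy as np
import pytest

from mirevol.align import global_identity
from mirevol.core_io import MatureRecord
from mirevol.homology import (
    Confirmation,
    MatchFilter,
    MatchResult,
    PredictedMature,
    all_vs_all,
    cluster_homologs,
    confirm_predictions,
    local_align,
    subdivide_orthologs,
)

from conftest import random_dna


class UnionFind:
    """Independent oracle for connected components."""

    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)

    def components(self):
        comps = {}
        for i in self.parent:
            comps.setdefault(self.find(i), set()).add(i)
        return sorted(frozenset(c) for c in comps.values())


def mk(i, seq, species="human", depth=0):
    return MatureRecord(id=i, species=species, sequence=seq, read_depth=depth)


SEQ = "ACGTACGGTCACGTAGCTGCAT"  # 22-mer


class TestLocalAlign:
    def test_identical_sequences_align_full_length(self):
        res = local_align(SEQ, SEQ)
        assert res.identity == 1.0
        assert res.aligned_length == 22

    def test_disjoint_alphabets_give_no_usable_match(self):
        res = local_align("A" * 22, "C" * 22)
        assert not MatchFilter(0.70, 18).accepts(res.identity, res.aligned_length)

    def test_four_scattered_mismatches_keep_full_alignment(self):
        a = SEQ
        b = list(SEQ)
        # scattered interior substitutions at positions 3, 8, 13, 18
        for pos in (3, 8, 13, 18):
            b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[pos]]
        b = "".join(b)
        res = local_align(a, b)
        assert res.aligned_length == 22
        assert res.identity == pytest.approx(18 / 22)
        assert MatchFilter(0.70, 18).accepts(res.identity, res.aligned_length)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", SEQ)


class TestAllVsAll:
    def test_identical_pair_yields_one_undirected_hit(self):
        hits = all_vs_all([mk("a", SEQ), mk("b", SEQ)])
        assert len(hits) == 1
        assert {hits[0].query, hits[0].subject} == {"a", "b"}

    def test_single_record_yields_nothing(self):
        assert all_vs_all([mk("a", SEQ)]) == []

    def test_two_constructed_families_give_within_family_pairs(self, rng):
        # two families; within-family >= 0.90 identity by construction,
        # cross-family sequences are disjoint-composition
        f1 = "ACGTACGGTCACGTAGCTGCAT"
        f2 = "TTGGAAGGTTTGACTTCCAATG"
        records = []
        for fam, base in (("x", f1), ("y", f2)):
            for k in range(5):
                s = list(base)
                pos = int(rng.integers(0, 22))
                s[pos] = "ACGT"[(("ACGT".index(s[pos])) + 1) % 4]
                records.append(mk(f"{fam}{k}", "".join(s)))
        hits = all_vs_all(records, MatchFilter(0.70, 18))
        expected = {
            frozenset((a.id, b.id))
            for a, b in itertools.combinations(records, 2)
            if a.id[0] == b.id[0]
        }
        got = {frozenset((h.query, h.subject)) for h in hits}
        assert got == expected


class TestClusterHomologs:
    def test_no_matches_all_singletons(self):
        groups, singles = cluster_homologs([], ["a", "b", "c"])
        assert groups == []
        assert singles == ["a", "b", "c"]

    def test_transitive_chain_is_one_group(self):
        hit = lambda q, s: MatchResult(q, s, 0.8, 20, 10, (0, 20), (0, 20))
        groups, singles = cluster_homologs([hit("A", "B"), hit("B", "C")], "ABC")
        assert len(groups) == 1
        assert groups[0].members == ["A", "B", "C"]
        assert groups[0].id == "A"

    def test_matches_union_find_oracle(self, rng):
        ids = [f"s{i}" for i in range(30)]
        edges = set()
        while len(edges) < 25:
            a, b = rng.choice(30, size=2, replace=False)
            edges.add((f"s{min(a, b)}", f"s{max(a, b)}"))
        hits = [MatchResult(q, s, 0.9, 20, 10, (0, 20), (0, 20)) for q, s in edges]
        groups, singles = cluster_homologs(hits, ids)
        uf = UnionFind(ids)
        for q, s in edges:
            uf.union(q, s)
        oracle = {c for c in uf.components() if len(c) > 1}
        assert {frozenset(g.members) for g in groups} == oracle
        assert set(singles) == set().union(
            *(c for c in uf.components() if len(c) == 1), set()
        )

    def test_invariant_to_input_order(self, rng):
        records = [mk(f"r{i}", random_dna(rng, 22)) for i in range(12)]
        hits = all_vs_all(records, MatchFilter(0.5, 10))
        base, base_s = cluster_homologs(hits, [r.id for r in records])
        perm = list(hits)
        rng.shuffle(perm)
        shuf, shuf_s = cluster_homologs(perm, [r.id for r in reversed(records)])
        assert [g.members for g in base] == [g.members for g in shuf]
        assert base_s == shuf_s


class TestSubdivideOrthologs:
    def test_identical_orthologs_one_group(self):
        recs = {f"m{i}": mk(f"m{i}", SEQ, species=f"sp{i}") for i in range(5)}
        from mirevol.homology import HomologyGroup

        g = HomologyGroup(id="m0", members=sorted(recs))
        out = subdivide_orthologs(g, recs)
        assert len(out) == 1
        assert len(out[0].members) == 5

    def test_two_paralog_subfamilies_split(self):
        # subfamily A and B differ at 6 of 22 positions (~73% identity);
        # within each subfamily a single substitution (~95%)
        a = "ACGTACGGTCACGTAGCTGCAT"
        b = "ACGTAATGTCACGTACCTTGAT"
        recs = {}
        for name, base in (("a", a), ("b", b)):
            for k in range(3):
                s = list(base)
                s[2 + k] = {"G": "C", "C": "G", "A": "T", "T": "A"}[s[2 + k]]
                rid = f"{name}{k}"
                recs[rid] = mk(rid, "".join(s), species=f"sp{k}")
        from mirevol.homology import HomologyGroup

        g = HomologyGroup(id="a0", members=sorted(recs))
        out = subdivide_orthologs(g, recs, high_identity=0.85)
        assert len(out) == 2
        assert {frozenset(m.id for m in og.members) for og in out} == {
            frozenset({"a0", "a1", "a2"}),
            frozenset({"b0", "b1", "b2"}),
        }

    def test_fewer_than_three_species_dropped(self):
        recs = {f"m{i}": mk(f"m{i}", SEQ, species=f"sp{i % 2}") for i in range(4)}
        from mirevol.homology import HomologyGroup

        g = HomologyGroup(id="m0", members=sorted(recs))
        assert subdivide_orthologs(g, recs) == []

    def test_one_representative_per_species(self):
        recs = {
            "hi": mk("hi", SEQ, species="human", depth=100),
            "lo": mk("lo", SEQ, species="human", depth=5),
            "b": mk("b", SEQ, species="bonobo"),
            "c": mk("c", SEQ, species="chimp"),
        }
        from mirevol.homology import HomologyGroup

        g = HomologyGroup(id="b", members=sorted(recs))
        (og,) = subdivide_orthologs(g, recs)
        ids = {m.id for m in og.members}
        assert "hi" in ids and "lo" not in ids  # higher depth wins the tie


class TestConfirmPredictions:
    def test_exact_22mer_confirmed(self):
        validated = [mk("v", SEQ, species="gorilla")]
        predicted = [PredictedMature("p", "famA", 10.0, SEQ)]
        (c,) = confirm_predictions(validated, predicted)
        assert c.n_species == 1 and c.species == ["gorilla"]

    def test_17nt_block_not_confirmed(self):
        block = SEQ[:17]
        validated = [mk("v", block + "GGGGG", species="gorilla")]
        predicted = [PredictedMature("p", "famA", 10.0, "TT" + block + "AAA")]
        (c,) = confirm_predictions(validated, predicted)
        assert c.n_species == 0

    def test_perfect_18mer_not_masked_by_longer_imperfect_alignment(self):
        # 18 exact nt followed by divergence: a score-optimal aligner would
        # extend past the mismatch, but the 100%-identity criterion must
        # still see the perfect block
        v = SEQ[:18] + "GGGG"
        p = SEQ[:18] + "CCCC"
        (c,) = confirm_predictions([mk("v", v, species="x")],
                                   [PredictedMature("p", "f", 1.0, p)])
        assert c.n_species == 1

    def test_paralog_family_collapsed_to_best_score(self):
        validated = [mk("v", SEQ, species="x")]
        predicted = [
            PredictedMature("p1", "fam", 20.0, SEQ),
            PredictedMature("p2", "fam", 22.0, SEQ),
            PredictedMature("p3", "fam", 19.0, SEQ),
        ]
        (c,) = confirm_predictions(validated, predicted)
        assert c.representative == "p2" and c.score == 22.0
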