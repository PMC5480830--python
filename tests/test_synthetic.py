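"""Ground-truthed simulation: hairpin construction, evolution, events,
bundle determinism."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from mirevol.core_io import revcomp
from mirevol.structure import fold_mfe
from mirevol.synthetic_data import (
    DEFAULT_TREE,
    GroundTruth,
    RegionRates,
    SimParams,
    evolve_along_tree,
    make_ancestral_hairpin,
    write_study_bundle,
)


class TestAncestralHairpin:
    def test_geometry_and_deep_stem(self, rng):
        h = make_ancestral_hairpin(rng, stem_len=30, loop_len=10, flank=0)
        assert len(h.sequence) == 70
        r = fold_mfe(h.sequence)
        assert len(r.pairs) >= 25  # construction guarantees a deep stem
        assert r.energy <= -2 * 30

    def test_minimal_geometry(self, rng):
        h = make_ancestral_hairpin(rng, stem_len=18, loop_len=4, flank=0)
        assert len(h.sequence) == 40
        assert h.mature_span == (0, 18)
        assert h.star_span == (22, 40)

    def test_star_is_reverse_complement_of_mature_arm(self, rng):
        h = make_ancestral_hairpin(rng, stem_len=22, loop_len=6, flank=0)
        assert h.star == revcomp(h.mature)

    def test_deterministic_under_seed(self):
        a = make_ancestral_hairpin(np.random.default_rng(7))
        b = make_ancestral_hairpin(np.random.default_rng(7))
        assert a.sequence == b.sequence

    def test_rejects_tiny_geometry(self, rng):
        with pytest.raises(ValueError):
            make_ancestral_hairpin(rng, stem_len=10, loop_len=4)


ZERO = RegionRates(0, 0, 0, 0, 0)


class TestEvolveAlongTree:
    def test_zero_rates_all_species_identical(self):
        truth = evolve_along_tree(SimParams(n_families=2, rates=ZERO, rng_seed=1))
        for fam, paralogs in truth.families.items():
            for p in paralogs:
                seqs = {truth.loci[(p, sp)].mature for sp in truth.species}
                assert len(seqs) == 1
        assert truth.variants == []

    def test_seed_rate_zero_keeps_seed_invariant(self):
        rates = RegionRates(seed=0.0, supplementary=0.1, central_tail=0.3,
                            loop=0.3, flank=0.3)
        truth = evolve_along_tree(
            SimParams(n_families=6, rates=rates, compensatory_prob=0, rng_seed=2)
        )
        assert truth.variants, "expect some variation outside the seed"
        assert all(v.position >= 9 for v in truth.variants)

    def test_deletion_event_marks_exact_clade(self):
        truth = evolve_along_tree(
            SimParams(n_families=2, rng_seed=3,
                      deletions=(("strepsirrhini", "fam00a"),))
        )
        absent = {sp for (p, sp), st in truth.presence.items()
                  if p == "fam00a" and st == "absent_flanks_conserved"}
        assert absent == {"mouse_lemur", "aye_aye", "galago"}
        # flanks are retained in the genomic window, pre-miRNA is gone
        out = truth.loci[("fam00a", "galago")]
        assert out.hairpin is None
        assert len(out.window) == 800

    def test_duplication_confined_to_descendants(self):
        truth = evolve_along_tree(
            SimParams(n_families=2, rng_seed=4,
                      duplications=(("catarrhini", "fam01a"),))
        )
        assert truth.families["fam01"] == ["fam01a", "fam01b"]
        present = {sp for (p, sp), st in truth.presence.items()
                   if p == "fam01b" and st == "present"}
        catarrhines = {"human", "chimpanzee", "bonobo", "gorilla", "orangutan",
                       "gibbon", "macaque", "baboon"}
        assert present == catarrhines
        rest = {sp for (p, sp), st in truth.presence.items()
                if p == "fam01b" and st == "not_found"}
        assert rest == set(truth.species) - catarrhines

    def test_seed_shift_recorded_in_truth(self):
        truth = evolve_along_tree(
            SimParams(n_families=1, rates=ZERO, rng_seed=5,
                      seed_shifts=(("ape", "fam00a", 1),))
        )
        apes = {"human", "chimpanzee", "bonobo", "gorilla", "orangutan", "gibbon"}
        for sp in truth.species:
            want = 1 if sp in apes else 0
            assert truth.mature_offsets[("fam00a", sp)] == want
        # the shifted mature really is displaced by 1 nt in the hairpin
        h_ape = truth.loci[("fam00a", "human")].hairpin
        h_out = truth.loci[("fam00a", "galago")].hairpin
        assert h_ape.mature_span[0] == h_out.mature_span[0] + 1

    def test_variant_truth_positions_match_sequences(self):
        truth = evolve_along_tree(SimParams(n_families=4, rng_seed=6,
                                            compensatory_prob=0))
        for v in truth.variants:
            for sp in v.species:
                seq = truth.loci[(v.paralog, sp)].mature
                assert seq[v.position - 1] == v.alt_base

    def test_determinism(self):
        p = SimParams(n_families=2, rng_seed=8)
        a = evolve_along_tree(p)
        b = evolve_along_tree(p)
        assert a.loci.keys() == b.loci.keys()
        assert all(a.loci[k].window == b.loci[k].window for k in a.loci)
        assert a.variants == b.variants


class TestStudyBundle:
    def test_bundle_files_and_checksum_determinism(self, tmp_path):
        p = SimParams(n_families=2, rng_seed=10)
        truth = evolve_along_tree(p)
        m1 = write_study_bundle(truth, tmp_path / "a")
        m2 = write_study_bundle(evolve_along_tree(p), tmp_path / "b")
        assert m1 == m2
        assert (tmp_path / "a" / "predictions.tsv").exists()
        assert len(list((tmp_path / "a" / "matures").glob("*.fasta"))) == 13

    def test_bundle_round_trips_through_parser(self, tmp_path):
        from mirevol.core_io import PredictionFilter, parse_prediction_table

        truth = evolve_along_tree(SimParams(n_families=2, rng_seed=10))
        write_study_bundle(truth, tmp_path)
        recs = parse_prediction_table(tmp_path / "predictions.tsv",
                                      PredictionFilter(min_score=0, min_depth=3))
        assert len(recs) == len([1 for loc in truth.loci.values()
                                 if loc.hairpin is not None
                                 and loc.score >= 0 and loc.read_depth >= 3])
        for r in recs:
            assert r.mature in r.sequence

    def test_zero_families_valid_empty_bundle(self, tmp_path):
        truth = evolve_along_tree(SimParams(n_families=0, rng_seed=1))
        manifest = write_study_bundle(truth, tmp_path)
        assert "predictions.tsv" in manifest
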