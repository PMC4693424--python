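"""Greedy tiling, modulation, and local branch-and-bound refinement."""

import random

import pytest

from monomerizer.evalkit import generate_polymer
from monomerizer.isosearch import MatchSet
from monomerizer.markov_index import FrequencyModel, build_index
from monomerizer.molgraph import parse_smiles, to_line_graph
from monomerizer.residues import build_family
from monomerizer.tiler import (
    Tile,
    Tiling,
    greedy_tile,
    make_tile,
    modulate,
    rank_key,
    rank_tiles,
    refine_local,
)

from oracles import best_tiling_exhaustive


def fake_tile(polymer, atoms, name="M", n_att=1, prio=1.0, level=1):
    """A Tile with a synthetic residue-free match (metadata supplied directly)."""
    m = MatchSet(residue=None, polymer=polymer, atom_map=tuple((i, a) for i, a in
                 enumerate(sorted(atoms))), covered_atoms=frozenset(atoms), mode="strict")
    return Tile(match=m, size=len(atoms), n_attachments=n_att, bond_priority=prio)


@pytest.fixture
def decane():
    return parse_smiles("C" * 10)


class TestRanking:
    def test_larger_first(self, decane):
        small = fake_tile(decane, range(8))
        big = fake_tile(decane, range(10))
        assert rank_tiles([small, big])[0] is big

    def test_fewer_attachments_first_on_equal_size(self, decane):
        one = fake_tile(decane, range(5), n_att=1)
        two = fake_tile(decane, range(5), n_att=2)
        assert rank_tiles([two, one])[0] is one

    def test_higher_bond_priority_first_on_remaining_tie(self, decane):
        peptide = fake_tile(decane, range(5), n_att=1, prio=10.0)
        glyco = fake_tile(decane, range(5), n_att=1, prio=1.0)
        assert rank_tiles([glyco, peptide])[0] is peptide

    def test_rank_is_total_and_deterministic(self, decane):
        tiles = [fake_tile(decane, {i, i + 1}) for i in range(8)]
        r1 = [rank_key(t) for t in rank_tiles(tiles)]
        assert r1 == sorted(r1)


class TestGreedy:
    def test_full_cover_single_tile(self, decane):
        tiling = greedy_tile([fake_tile(decane, range(10))], decane)
        assert tiling.coverage_rate == 1.0

    def test_overlapping_equal_tiles_keep_rank_first(self, decane):
        a = fake_tile(decane, range(5), n_att=1)
        b = fake_tile(decane, range(4, 9), n_att=2)
        tiling = greedy_tile([b, a], decane)
        assert tiling.selected == (a,)

    def test_disjointness_enforced(self, decane):
        with pytest.raises(ValueError):
            Tiling((fake_tile(decane, range(5)), fake_tile(decane, range(4, 7))), decane)

    def test_recovers_synthetic_tetrapeptide(self, monomers, rules, peptide_pairing):
        sub = {k: monomers[k] for k in ("Glycine", "Alanine", "Serine", "Leucine")}
        gt = generate_polymer(sub, rules, 4, "linear", seed=9, pairings=peptide_pairing)
        fm = FrequencyModel.uniform()
        tiles = []
        from monomerizer.isosearch import search_family

        plg = to_line_graph(gt.graph)
        for name, g in sub.items():
            fam = build_family(g, rules, name)
            tiles += [make_tile(m) for m in
                      search_family(fam, build_index(fam.root, fm), plg, "strict")]
        tiling = greedy_tile(tiles, gt.graph)
        assert tiling.coverage_rate == 1.0
        got = {(t.monomer_name, t.covered_atoms) for t in tiling.selected}
        assert got == set(gt.truth_tiles)


class TestModulate:
    def test_fully_covered_is_noop(self, decane):
        tiling = greedy_tile([fake_tile(decane, range(10))], decane)
        assert modulate(tiling, [], decane) is tiling

    def test_blocking_tile_replaced(self, monomers, rules, peptide_pairing):
        """A small random match blocking the true residue is removed and the
        light local re-search restores full coverage."""
        gt = generate_polymer({"Serine": monomers["Serine"]}, rules, 3, "linear",
                              seed=2, pairings=peptide_pairing)
        fams = {k: build_family(monomers[k], rules, k) for k in ("Serine", "Glycine")}
        from monomerizer.isosearch import search_family

        plg = to_line_graph(gt.graph)
        tiles = [make_tile(m) for m in search_family(fams["Glycine"], None, plg, "light")]
        partial = greedy_tile(tiles, gt.graph)
        assert partial.coverage_rate < 1.0
        repaired = modulate(partial, list(fams.values()), gt.graph)
        assert repaired.coverage_rate == 1.0
        assert repaired.uncovered == frozenset()

    def test_unfillable_gap_keeps_coverage(self, monomers, rules, peptide_pairing):
        gt = generate_polymer({"Tryptophan": monomers["Tryptophan"]}, rules, 2, "linear",
                              seed=4, pairings=peptide_pairing)
        fam = build_family(monomers["Glycine"], rules, "Glycine")
        tiling = greedy_tile([], gt.graph)
        out = modulate(tiling, [fam], gt.graph)
        assert out.coverage_rate >= tiling.coverage_rate

    def test_coverage_never_decreases(self, monomers, rules, peptide_pairing):
        rng = random.Random(31)
        fams = [build_family(g, rules, k) for k, g in monomers.items()]
        sub = {k: monomers[k] for k in ("Alanine", "Valine", "Serine", "Lysine")}
        for _ in range(5):
            gt = generate_polymer(sub, rules, rng.randint(2, 5), "linear",
                                  seed=rng.randrange(2**31), pairings=peptide_pairing)
            # deliberately weak start: only glycine matches available
            gly = next(f for f in fams if f.monomer_name == "Glycine")
            from monomerizer.isosearch import search_family

            plg = to_line_graph(gt.graph)
            tiles = [make_tile(m) for m in search_family(gly, None, plg, "light")]
            t0 = greedy_tile(tiles, gt.graph)
            t1 = modulate(t0, fams, gt.graph)
            assert t1.coverage_rate >= t0.coverage_rate


class TestRefineLocal:
    def test_greedy_optimal_region_unchanged(self, decane):
        a = fake_tile(decane, range(5))
        b = fake_tile(decane, range(5, 10))
        tiling = greedy_tile([a, b], decane)
        out = refine_local(tiling, [a, b], frozenset(range(10)))
        assert out.covered == tiling.covered

    def test_two_small_beat_one_blocking_large(self, decane):
        big = fake_tile(decane, range(6))            # 6 atoms, blocks both
        left = fake_tile(decane, range(5))           # 5 atoms
        right = fake_tile(decane, range(5, 10))      # 5 atoms
        tiling = greedy_tile([big, left, right], decane)
        assert tiling.covered == frozenset(range(6))
        out = refine_local(tiling, [big, left, right], frozenset(range(10)))
        assert out.covered == frozenset(range(10))
        assert {t.covered_atoms for t in out.selected} == {
            frozenset(range(5)), frozenset(range(5, 10))
        }

    def test_matches_exhaustive_enumeration(self, decane):
        """On ≤15 candidate tiles the refinement equals brute-force subset max."""
        rng = random.Random(41)
        for trial in range(20):
            tiles = []
            for _ in range(rng.randint(3, 12)):
                start = rng.randrange(9)
                size = rng.randint(1, 10 - start)
                tiles.append(fake_tile(decane, range(start, start + size),
                                       n_att=rng.randint(1, 3)))
            tiling = greedy_tile(tiles, decane)
            out = refine_local(tiling, tiles, frozenset(range(10)))
            best_cov, best_key = best_tiling_exhaustive(tiles, rank_key)
            assert len(out.covered) == best_cov, trial
            assert tuple(sorted(rank_key(t) for t in out.selected)) == best_key, trial

    def test_never_below_greedy(self, decane):
        rng = random.Random(43)
        for _ in range(15):
            tiles = [fake_tile(decane, range(s, s + rng.randint(1, 4)))
                     for s in rng.sample(range(7), rng.randint(2, 6))]
            tiling = greedy_tile(tiles, decane)
            out = refine_local(tiling, tiles, frozenset(range(10)))
            assert len(out.covered) >= len(tiling.covered)

    def test_budget_truncation_warns_and_keeps_valid_tiling(self, decane):
        tiles = [fake_tile(decane, {i, (i + 1) % 10}) for i in range(10)]
        tiling = greedy_tile([], decane)
        with pytest.warns(UserWarning):
            out = refine_local(tiling, tiles, frozenset(range(10)), budget=5)
        seen = set()
        for t in out.selected:
            assert not (seen & t.covered_atoms)
            seen |= t.covered_atoms
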