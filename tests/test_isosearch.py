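"""Completeness and pruning of the branch-and-bound residue search."""

import random

import pytest

from monomerizer.evalkit import generate_polymer
from monomerizer.isosearch import search_family, search_local, search_root, _bfs_index
from monomerizer.markov_index import FrequencyModel, build_index
from monomerizer.molgraph import parse_smiles, to_line_graph
from monomerizer.residues import build_family

from oracles import naive_matches, random_connected_query, random_molecule


def atom_sets(matches):
    return {m.covered_atoms for m in matches}


class TestSearchRoot:
    def test_identity_embedding(self, cysteine):
        idx = build_index(cysteine, FrequencyModel.uniform())
        found = search_root(idx, to_line_graph(cysteine), "strict")
        assert frozenset(range(cysteine.n_atoms)) in atom_sets(found)

    def test_triglycine_has_three_backbone_occurrences(self, monomers, rules, peptide_pairing):
        gt = generate_polymer({"Glycine": monomers["Glycine"]}, rules, 3, "linear",
                              seed=1, pairings=peptide_pairing)
        fam = build_family(monomers["Glycine"], rules, "Glycine")
        idx = build_index(fam.root, FrequencyModel.uniform())
        found = search_root(idx, to_line_graph(gt.graph), "strict", residue=fam.root)
        assert len(found) == 3
        assert atom_sets(found) == naive_matches(fam.root.graph, gt.graph, "strict")

    def test_absent_residue_returns_empty(self, monomers, rules):
        fam = build_family(monomers["Tryptophan"], rules, "Tryptophan")
        idx = build_index(fam.root, FrequencyModel.uniform())
        target = parse_smiles("CCO")
        assert search_root(idx, to_line_graph(target), "strict") == []

    def test_strict_subset_of_light(self):
        rng = random.Random(11)
        for _ in range(25):
            target = random_molecule(rng, rng.randint(5, 18))
            query = random_connected_query(rng, target, rng.randint(2, 5))
            idx = _bfs_index(query)
            plg = to_line_graph(target)
            strict = atom_sets(search_root(idx, plg, "strict"))
            light = atom_sets(search_root(idx, plg, "light"))
            assert strict <= light

    def test_results_equal_oracle_both_modes(self):
        rng = random.Random(13)
        for _ in range(30):
            target = random_molecule(rng, rng.randint(4, 20))
            query = random_connected_query(rng, target, rng.randint(2, 6))
            idx = _bfs_index(query)
            plg = to_line_graph(target)
            for mode in ("strict", "light"):
                assert atom_sets(search_root(idx, plg, mode)) == naive_matches(
                    query, target, mode
                )

    def test_order_independence(self):
        """Any valid connected order yields identical results (index affects
        speed only)."""
        rng = random.Random(17)
        target = random_molecule(rng, 16)
        query = random_connected_query(rng, target, 5)
        plg = to_line_graph(target)
        reference = atom_sets(search_root(_bfs_index(query), plg, "strict"))
        lg = to_line_graph(query)
        for trial in range(10):
            r = random.Random(trial)
            # random connected order
            nodes = [n.node_id for n in lg.nodes]
            order = [r.choice(nodes)]
            while len(order) < len(nodes):
                frontier = [v for v in nodes if v not in order
                            and any(v in lg.adjacency[u] for u in order)]
                if not frontier:
                    frontier = [v for v in nodes if v not in order]
                order.append(r.choice(frontier))
            from monomerizer.markov_index import MarkovIndex

            conn = tuple(
                tuple(j for j in range(k) if order[j] in lg.adjacency[node])
                for k, node in enumerate(order)
            )
            idx = MarkovIndex(graph=query, line_graph=lg, order=tuple(order),
                              connectivity=conn, expected_cost=0.0)
            assert atom_sets(search_root(idx, plg, "strict")) == reference

    def test_single_atom_query_matched_on_atoms(self):
        # bond-free queries bypass the line graph and match atom labels directly
        target = parse_smiles("OCC=O")  # hydroxyl O (1H), carbonyl O (0H)
        hydroxyl = atom_sets(search_root(_bfs_index(parse_smiles("[OH]")),
                                         to_line_graph(target), "strict"))
        assert hydroxyl == {frozenset({0})}
        any_oxygen = atom_sets(search_root(_bfs_index(parse_smiles("[OH]")),
                                           to_line_graph(target), "light"))
        assert any_oxygen == {frozenset({0}), frozenset({3})}


class TestSearchFamily:
    def test_dicysteine_family_occurrences(self, monomers, rules, peptide_pairing):
        gt = generate_polymer({"Cysteine": monomers["Cysteine"]}, rules, 2, "linear",
                              seed=3, pairings=peptide_pairing)
        fam = build_family(monomers["Cysteine"], rules, "Cysteine")
        idx = build_index(fam.root, FrequencyModel.uniform())
        found = search_family(fam, idx, to_line_graph(gt.graph), "strict")
        # every residue's occurrences must equal an independent full search
        by_res = {}
        for m in found:
            by_res.setdefault(m.residue.residue_id, set()).add(m.covered_atoms)
        for r in fam.residues:
            expected = naive_matches(r.graph, gt.graph, "strict")
            assert by_res.get(r.residue_id, set()) == expected
        # the two singly-truncated level-1 residues each occur
        for r in fam.levels()[1]:
            assert by_res.get(r.residue_id)

    def test_root_absent_prunes_everything(self, monomers, rules):
        fam = build_family(monomers["Tryptophan"], rules, "Tryptophan")
        idx = build_index(fam.root, FrequencyModel.uniform())
        target = parse_smiles("CCCCO")
        assert search_family(fam, idx, to_line_graph(target), "strict") == []

    def test_equals_independent_search_of_every_residue(self, monomers, rules,
                                                        peptide_pairing):
        rng = random.Random(23)
        sub = {k: monomers[k] for k in ("Glycine", "Alanine", "Serine", "Cysteine")}
        fams = {k: build_family(g, rules, k) for k, g in sub.items()}
        fm = FrequencyModel.uniform()
        for trial in range(8):
            gt = generate_polymer(sub, rules, rng.randint(2, 4), "linear",
                                  seed=rng.randrange(2**31), pairings=peptide_pairing)
            plg = to_line_graph(gt.graph)
            for name, fam in fams.items():
                found = search_family(fam, build_index(fam.root, fm), plg, "strict")
                by_res = {}
                for m in found:
                    by_res.setdefault(m.residue.residue_id, set()).add(m.covered_atoms)
                for r in fam.residues:
                    assert by_res.get(r.residue_id, set()) == naive_matches(
                        r.graph, gt.graph, "strict"
                    ), (name, r.residue_id, trial)


class TestSearchLocal:
    def test_full_region_equals_family_search(self, monomers, rules, peptide_pairing):
        gt = generate_polymer({"Glycine": monomers["Glycine"]}, rules, 3, "linear",
                              seed=5, pairings=peptide_pairing)
        fam = build_family(monomers["Glycine"], rules, "Glycine")
        plg = to_line_graph(gt.graph)
        full = search_family(fam, None, plg, "strict")
        local = search_local(fam, plg, frozenset(range(gt.graph.n_atoms)), "strict")
        assert atom_sets(full) == atom_sets(local)

    def test_region_excluding_occurrences_is_empty(self, monomers, rules, peptide_pairing):
        gt = generate_polymer({"Glycine": monomers["Glycine"]}, rules, 3, "linear",
                              seed=5, pairings=peptide_pairing)
        fam = build_family(monomers["Glycine"], rules, "Glycine")
        plg = to_line_graph(gt.graph)
        region = frozenset({0})
        assert search_local(fam, plg, region, "strict") == []

    def test_empty_region_rejected(self, monomers, rules):
        fam = build_family(monomers["Glycine"], rules, "Glycine")
        plg = to_line_graph(parse_smiles("CC"))
        with pytest.raises(ValueError):
            search_local(fam, plg, frozenset(), "strict")
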