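"""Molecular graphs, atom mapping (isomorphism/MCS) and descriptors."""

import numpy as np
import pytest
from oracles import mcs_size_oracle

from ligandrmsd.molgraph import (
    UnmappableLigandsError,
    build_graph,
    enumerate_mappings,
    graph_from_elements,
    map_ligand_atoms,
    match_atoms,
    molecular_weight,
    parse_formula,
    rotatable_bonds,
)
from ligandrmsd.pdb_io import Atom, LigandInstance
from ligandrmsd.superpose import kabsch
from ligandrmsd.synth_fixtures import (
    chain_ligand_spec,
    random_ligand_spec,
    ring_tail_ligand_spec,
    spec_to_instance,
)


def _graph(elements, bonds):
    return graph_from_elements(elements, bonds)


RING6 = _graph(["C"] * 6, [(i, (i + 1) % 6) for i in range(6)])
BUTANE = _graph(["C"] * 4, [(0, 1), (1, 2), (2, 3)])
BIPHENYL = _graph(
    ["C"] * 12,
    [(i, (i + 1) % 6) for i in range(6)]
    + [(6 + i, 6 + (i + 1) % 6) for i in range(6)]
    + [(0, 6)],
)


class TestBuildGraph:
    def test_ring_all_edges_cyclic(self):
        assert RING6.n_atoms == 6 and RING6.n_bonds == 6
        assert all(RING6.is_ring_edge(u, v) for u, v in RING6.graph.edges)

    def test_chain_no_ring_edges(self):
        assert BUTANE.n_bonds == 3
        assert not any(BUTANE.is_ring_edge(u, v) for u, v in BUTANE.graph.edges)

    def test_disconnected_fragments_allowed(self):
        g = _graph(["C", "C", "O", "O"], [(0, 1), (2, 3)])
        import networkx as nx

        assert nx.number_connected_components(g.graph) == 2

    def test_from_ligand(self, chain_instance):
        g = build_graph(chain_instance)
        assert g.n_atoms == chain_instance.n_heavy_atoms
        assert g.n_bonds == len(chain_instance.bonds)


class TestMatchAtoms:
    def test_identity_name_match(self, chain_instance):
        m = map_ligand_atoms(chain_instance, chain_instance)
        assert m.source == "name-match"
        assert m.size == chain_instance.n_heavy_atoms
        assert all(a == b for a, b in m.pairs)

    def test_ring_relabel_recovers_best_automorphism(self):
        """All automorphisms are tried; the RMSD-optimal one is returned."""
        spec = ring_tail_ligand_spec()
        lig_a = spec_to_instance(spec, "RNGA")
        # rename atoms (breaks name matching) and flip the ring labels
        lig_b = spec_to_instance(spec, "RNGB")
        for a in lig_b.atoms:
            a.name = "Q" + a.name
        lig_b.chem_comp_id = "BZX"
        m = match_atoms(
            build_graph(lig_a), build_graph(lig_b), lig_a.coords, lig_b.coords
        )
        assert m.source == "isomorphism"
        assert m.size == 9
        # the best automorphism on identical coordinates is the identity
        sup = kabsch(lig_a.coords, lig_b.coords, m)
        assert sup.rmsd < 1e-9

    def test_automorphism_choice_matches_exhaustive_min(self, rng):
        """The returned mapping attains the exhaustive minimum over mappings."""
        spec = ring_tail_ligand_spec()
        coords_b = spec.coords + rng.normal(scale=0.3, size=spec.coords.shape)
        lig_a = spec_to_instance(spec, "RNGA")
        lig_b = spec_to_instance(spec, "RNGB", coords=coords_b)
        lig_b.chem_comp_id = "BZX"  # force the isomorphism route
        gA, gB = build_graph(lig_a), build_graph(lig_b)
        candidates, _src = enumerate_mappings(gA, gB)
        brute = min(kabsch(lig_a.coords, coords_b, c).rmsd for c in candidates)
        m = match_atoms(gA, gB, lig_a.coords, coords_b)
        assert kabsch(lig_a.coords, coords_b, m).rmsd == pytest.approx(brute, abs=1e-12)

    def test_ring_vs_ring_plus_tail_mcs(self):
        tail = _graph(["C"] * 7, [(i, (i + 1) % 6) for i in range(6)] + [(0, 6)])
        coords_ring = _hexagon()
        coords_tail = np.vstack([_hexagon(), [[3.0, 0.0, 0.0]]])
        m = match_atoms(RING6, tail, coords_ring, coords_tail)
        assert m.source == "mcs"
        assert m.size == 6
        assert m.size == mcs_size_oracle(
            ["C"] * 6, list(RING6.graph.edges), ["C"] * 7, list(tail.graph.edges)
        )

    def test_mapping_size_symmetric(self, rng):
        for seed in range(5):
            a = random_ligand_spec(np.random.default_rng(seed), 7)
            b = random_ligand_spec(np.random.default_rng(seed + 100), 7)
            ga, gb = _graph(a.elements, a.bonds), _graph(b.elements, b.bonds)
            try:
                m_ab = match_atoms(ga, gb, a.coords, b.coords)
                m_ba = match_atoms(gb, ga, b.coords, a.coords)
            except UnmappableLigandsError:
                continue
            assert m_ab.size == m_ba.size

    def test_mcs_size_equals_exhaustive_oracle(self):
        """Spot check; the full 200-pair sweep runs in the acceptance suite."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            a = random_ligand_spec(rng, int(rng.integers(4, 9)))
            b = random_ligand_spec(rng, int(rng.integers(4, 9)))
            expected = mcs_size_oracle(a.elements, a.bonds, b.elements, b.bonds)
            ga, gb = _graph(a.elements, a.bonds), _graph(b.elements, b.bonds)
            if expected < 3:
                with pytest.raises(UnmappableLigandsError):
                    enumerate_mappings(ga, gb)
            else:
                candidates, _src = enumerate_mappings(ga, gb)
                assert len(candidates[0]) == expected, f"seed {seed}"

    def test_too_small_common_subgraph_unmappable(self):
        a = _graph(["C", "N", "O"], [(0, 1), (1, 2)])
        b = _graph(["S", "S", "S"], [(0, 1), (1, 2)])
        with pytest.raises(UnmappableLigandsError):
            enumerate_mappings(a, b)

    def test_collinear_mapping_unmappable(self):
        g = _graph(["C", "C", "C", "C"], [(0, 1), (1, 2), (2, 3)])
        line = np.array([[float(i), 0.0, 0.0] for i in range(4)])
        with pytest.raises(UnmappableLigandsError):
            match_atoms(g, g, line, line)


class TestRotatableBonds:
    def test_butane_central_bond_only(self):
        assert rotatable_bonds(BUTANE) == (1, pytest.approx(1 / 3))

    def test_ring_bonds_never_rotatable(self):
        assert rotatable_bonds(RING6)[0] == 0

    def test_biphenyl_linker(self):
        # oracle: per-bond manual rule — only the inter-ring bond qualifies
        assert rotatable_bonds(BIPHENYL)[0] == 1

    def test_ratio_in_unit_interval(self):
        for seed in range(20):
            spec = random_ligand_spec(np.random.default_rng(seed))
            _abs, rel = rotatable_bonds(_graph(spec.elements, spec.bonds))
            assert 0.0 <= rel <= 1.0

    def test_adding_ring_edge_never_increases_count(self):
        before, _ = rotatable_bonds(_graph(["C"] * 5, [(i, i + 1) for i in range(4)]))
        after, _ = rotatable_bonds(
            _graph(["C"] * 5, [(i, i + 1) for i in range(4)] + [(0, 4)])
        )
        assert after <= before


class TestMolecularWeight:
    def _single_carbon(self):
        return LigandInstance(
            "X", "LIG", "A", 1, [Atom(1, "C1", "C", np.zeros(3))]
        )

    def test_single_carbon(self):
        assert molecular_weight(self._single_carbon()) == pytest.approx(12.011, abs=1e-3)

    def test_formula_override_benzamidine(self):
        # hand sum of standard atomic masses for C7H8N2
        assert molecular_weight(self._single_carbon(), "C7H8N2") == pytest.approx(
            120.15, abs=0.01
        )

    def test_empty_override_falls_back_to_atoms(self):
        assert molecular_weight(self._single_carbon(), {}) == pytest.approx(
            12.011, abs=1e-3
        )

    def test_unknown_element_errors(self):
        with pytest.raises(ValueError, match="unknown element"):
            molecular_weight(self._single_carbon(), {"Qq": 1})

    def test_parse_formula(self):
        assert parse_formula("C7H8N2") == {"C": 7, "H": 8, "N": 2}
        with pytest.raises(ValueError):
            parse_formula("7CH")


def _hexagon():
    r = 1.52 / (2 * np.sin(np.pi / 6))
    return np.array(
        [[r * np.cos(np.pi / 3 * i), r * np.sin(np.pi / 3 * i), 0.0] for i in range(6)]
    )
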