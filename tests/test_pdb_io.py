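"""Structure parsing, ligand extraction, bond inference and blacklisting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligandrmsd.pdb_io import (
    Atom,
    BlacklistConfig,
    LigandInstance,
    PDBParseError,
    extract_ligands,
    infer_bonds,
    is_blacklisted,
    ligand_inventory,
    parse_structure,
    write_ligand_pdb,
)
from ligandrmsd.synth_fixtures import chain_ligand_spec, format_structure, spec_to_instance, _helix_backbone


def _pdb_line(record, serial, name, altloc, resname, chain, resnum, xyz, occ, element):
    return (
        "%-6s%5d %s%1s%3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
        % (record, serial, f" {name:<3}" if len(name) < 4 else name, altloc,
           resname, chain, resnum, xyz[0], xyz[1], xyz[2], occ, 0.0, element)
    )


def _toy_structure():
    """10-residue chain plus one 9-heavy-atom HET residue plus a water."""
    spec = chain_ligand_spec(9, comp_id="BEN", seed=4)
    lig = spec_to_instance(spec, "TOY1", "A", 200, serial_start=41)
    return format_structure("TOY1", "A", "ACDEFGHIKL", _helix_backbone(10), lig)


class TestParseStructure:
    def test_chain_and_ligand_extracted(self):
        chains, ligands = extract_ligands(_toy_structure(), "TOY1")
        assert len(chains) == 1
        assert chains[0].sequence == "ACDEFGHIKL"
        assert len(chains[0].residues) == 10
        assert len(ligands) == 1
        lig = ligands[0]
        assert lig.chem_comp_id == "BEN"
        assert lig.n_heavy_atoms == 9
        assert len(lig.bonds) == 8  # unbranched chain topology from CONECT

    def test_water_only_yields_no_ligands(self):
        text = "\n".join(
            _pdb_line("HETATM", i + 1, "O", " ", "HOH", "A", 100 + i,
                      (float(i), 0.0, 0.0), 1.0, "O")
            for i in range(3)
        ) + "\nEND\n"
        _chains, ligands, _conect = parse_structure(text, "WAT1")
        assert ligands == []

    def test_altloc_highest_occupancy_wins(self):
        lines = [
            _pdb_line("HETATM", 1, "C1", "A", "LIG", "A", 90, (1.0, 2.0, 3.0), 0.6, "C"),
            _pdb_line("HETATM", 2, "C1", "B", "LIG", "A", 90, (9.0, 9.0, 9.0), 0.4, "C"),
            _pdb_line("HETATM", 3, "C2", " ", "LIG", "A", 90, (2.5, 2.0, 3.0), 1.0, "C"),
            _pdb_line("HETATM", 4, "C3", " ", "LIG", "A", 90, (4.0, 2.0, 3.0), 1.0, "C"),
            "END",
        ]
        _c, ligands, _m = parse_structure("\n".join(lines), "ALT1")
        (lig,) = ligands
        c1 = next(a for a in lig.atoms if a.name == "C1")
        np.testing.assert_allclose(c1.coords, [1.0, 2.0, 3.0])
        assert c1.altloc == "A"

    def test_altloc_tie_prefers_a(self):
        lines = [
            _pdb_line("HETATM", 1, "C1", "B", "LIG", "A", 90, (9.0, 9.0, 9.0), 0.5, "C"),
            _pdb_line("HETATM", 2, "C1", "A", "LIG", "A", 90, (1.0, 2.0, 3.0), 0.5, "C"),
            "END",
        ]
        _c, ligands, _m = parse_structure("\n".join(lines), "ALT2")
        np.testing.assert_allclose(ligands[0].atoms[0].coords, [1.0, 2.0, 3.0])

    def test_hydrogens_dropped(self):
        lines = [
            _pdb_line("HETATM", 1, "C1", " ", "LIG", "A", 90, (0.0, 0.0, 0.0), 1.0, "C"),
            _pdb_line("HETATM", 2, "H1", " ", "LIG", "A", 90, (1.0, 0.0, 0.0), 1.0, "H"),
            _pdb_line("HETATM", 3, "O1", " ", "LIG", "A", 90, (2.0, 0.0, 0.0), 1.0, "O"),
            "END",
        ]
        _c, ligands, _m = parse_structure("\n".join(lines), "HYD1")
        assert [a.element for a in ligands[0].atoms] == ["C", "O"]

    def test_malformed_coordinate_names_line(self):
        bad = _toy_structure().splitlines()
        bad[3] = bad[3][:33] + "x.xxx" + bad[3][38:]
        with pytest.raises(PDBParseError, match="line 4"):
            parse_structure("\n".join(bad), "BAD1")

    def test_empty_input_errors(self):
        with pytest.raises(PDBParseError):
            parse_structure("HEADER    EMPTY\nEND\n", "EMP1")

    def test_modified_residue_in_chain_is_not_ligand(self):
        # MSE (selenomethionine) peptide-linked between two ALA residues
        lines = [
            _pdb_line("ATOM", 1, "N", " ", "ALA", "A", 1, (0.0, 0.0, 0.0), 1.0, "N"),
            _pdb_line("ATOM", 2, "CA", " ", "ALA", "A", 1, (1.4, 0.0, 0.0), 1.0, "C"),
            _pdb_line("ATOM", 3, "C", " ", "ALA", "A", 1, (2.0, 1.2, 0.0), 1.0, "C"),
            _pdb_line("HETATM", 4, "N", " ", "MSE", "A", 2, (2.2, 2.4, 0.0), 1.0, "N"),
            _pdb_line("HETATM", 5, "CA", " ", "MSE", "A", 2, (3.6, 2.6, 0.0), 1.0, "C"),
            _pdb_line("HETATM", 6, "C", " ", "MSE", "A", 2, (4.2, 3.8, 0.0), 1.0, "C"),
            _pdb_line("ATOM", 7, "N", " ", "ALA", "A", 3, (4.4, 5.0, 0.0), 1.0, "N"),
            _pdb_line("ATOM", 8, "CA", " ", "ALA", "A", 3, (5.8, 5.2, 0.0), 1.0, "C"),
            _pdb_line("ATOM", 9, "C", " ", "ALA", "A", 3, (6.4, 6.4, 0.0), 1.0, "C"),
            "END",
        ]
        chains, ligands, _m = parse_structure("\n".join(lines), "MOD1")
        assert ligands == []
        assert len(chains[0].residues) == 3

    def test_roundtrip_preserves_names_elements_coords(self, chain_instance):
        text = write_ligand_pdb(chain_instance)
        _c, ligands, conect = parse_structure(text, chain_instance.pdb_id)
        (lig,) = ligands
        lig.bonds = infer_bonds(lig, conect)
        assert [a.name for a in lig.atoms] == [a.name for a in chain_instance.atoms]
        assert lig.elements == chain_instance.elements
        np.testing.assert_allclose(lig.coords, chain_instance.coords, atol=5e-4)
        assert lig.bonds == sorted(tuple(sorted(b)) for b in chain_instance.bonds)


class TestInferBonds:
    def _two_carbons(self, dist):
        atoms = [
            Atom(1, "C1", "C", np.array([0.0, 0.0, 0.0])),
            Atom(2, "C2", "C", np.array([dist, 0.0, 0.0])),
        ]
        return LigandInstance("X", "LIG", "A", 1, atoms)

    def test_bond_within_covalent_threshold(self):
        assert infer_bonds(self._two_carbons(1.52)) == [(0, 1)]

    def test_no_bond_beyond_threshold(self):
        assert infer_bonds(self._two_carbons(3.0)) == []

    def test_conect_deduplicated_and_symmetric(self):
        lig = self._two_carbons(3.0)  # geometry would give no bond
        conect = {1: {2}, 2: {1}}
        assert infer_bonds(lig, conect) == [(0, 1)]

    def test_no_self_bonds(self):
        lig = self._two_carbons(1.5)
        assert all(i != j for i, j in infer_bonds(lig, {1: {1}}))


class TestBlacklist:
    def _lig(self, n, comp="XYZ"):
        atoms = [
            Atom(i + 1, f"C{i+1}", "C", np.array([1.6 * i, 0.0, 0.0]))
            for i in range(n)
        ]
        return LigandInstance("X", comp, "A", 1, atoms)

    def test_five_heavy_atoms_blacklisted(self):
        assert is_blacklisted(self._lig(5), BlacklistConfig())

    def test_six_heavy_atoms_pass(self):
        assert not is_blacklisted(self._lig(6), BlacklistConfig())

    def test_excluded_component(self):
        cfg = BlacklistConfig(excluded_comp_ids={"GOL", "EDO"})
        assert is_blacklisted(self._lig(6, "GOL"), cfg)
        # benzamidine-sized drug is not on the solvent list
        assert not is_blacklisted(self._lig(9, "BEN"), cfg)

    def test_default_config_loads(self):
        cfg = BlacklistConfig.default()
        assert cfg.max_heavy_atoms == 5
        assert "GOL" in cfg.excluded_comp_ids

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        extra=st.sets(st.sampled_from(["AAA", "BBB", "CCC", "XYZ"])),
        n=st.integers(min_value=1, max_value=12),
    )
    def test_enlarging_exclusions_is_monotone(self, extra, n):
        lig = self._lig(n)
        base = BlacklistConfig(excluded_comp_ids=set())
        bigger = BlacklistConfig(excluded_comp_ids=extra)
        if is_blacklisted(lig, base):
            assert is_blacklisted(lig, bigger)

    def test_inventory_schema(self):
        df = ligand_inventory([self._lig(4), self._lig(9, "BEN")])
        assert list(df["blacklisted"]) == [True, False]
        assert list(df["n_heavy_atoms"]) == [4, 9]
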