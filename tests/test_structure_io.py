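import gzip

import numpy as np
import pytest

from molshots.errors import (
    EmptyStructureError,
    MalformedCIFError,
    NoCoordinatesError,
    UnknownAssemblyError,
    UnsupportedFormatError,
)
from molshots.model import AssemblyDef, Structure
from molshots.structure_io import (
    expand_assembly,
    parse_oper_expression,
    read_structure,
    select_deposited,
    to_mmcif_text,
)

from conftest import assert_structures_equal, point_structure

THREE_ATOM_CIF = """data_MINI
_entry.id MINI
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N  . ALA A 1 1 0.0 0.0 0.0 1.00 10.0 1 A 1
ATOM 2 C CA . ALA A 1 1 1.5 0.0 0.0 1.00 11.0 1 A 1
ATOM 3 C C  . ALA A 1 1 2.5 1.0 0.0 1.00 12.0 1 A 1
"""


class TestReadStructure:
    def test_three_atom_fixture(self, tmp_path):
        path = tmp_path / "mini.cif"
        path.write_text(THREE_ATOM_CIF)
        s = read_structure(path)
        assert len(s.models) == 1
        assert len(s.models[0][1]) == 1
        assert s.atom_count() == 3
        assert s.entry_id == "mini"

    def test_gzip_detected_by_magic_bytes(self, tmp_path):
        plain = tmp_path / "mini.cif"
        plain.write_text(THREE_ATOM_CIF)
        # Deliberately plain .cif extension: magic bytes, not suffix, decide.
        gz = tmp_path / "minigz.cif"
        gz.write_bytes(gzip.compress(THREE_ATOM_CIF.encode()))
        assert_structures_equal(read_structure(plain), read_structure(gz))

    def test_gzip_extension_roundtrip(self, tmp_path, pdb_fixture):
        cif_path, _ = pdb_fixture
        gz = tmp_path / "1tst.cif.gz"
        gz.write_bytes(gzip.compress(cif_path.read_bytes()))
        assert_structures_equal(read_structure(cif_path), read_structure(gz))

    def test_no_atom_site_is_no_coordinates_error(self, tmp_path):
        path = tmp_path / "empty.cif"
        path.write_text("data_X\n_entry.id X\n")
        with pytest.raises(NoCoordinatesError):
            read_structure(path)

    def test_bcif_rejected(self, tmp_path):
        path = tmp_path / "x.bcif"
        path.write_bytes(b"\x00\x01binary")
        with pytest.raises(UnsupportedFormatError):
            read_structure(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "absent.cif")

    @pytest.mark.parametrize(
        "text",
        [
            "data_x\nloop_\n_atom_site.id\n_atom_site.Cartn_x\n1 2 3\n",
            "this is not cif at all { ] )\n",
        ],
    )
    def test_malformed_cif(self, tmp_path, text):
        path = tmp_path / "bad.cif"
        path.write_text(text)
        with pytest.raises(MalformedCIFError):
            read_structure(path)

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        rows = (
            "ATOM 1 C CA A ALA A 1 1 0.0 0.0 0.0 0.40 10.0 1 A 1\n"
            "ATOM 2 C CA B ALA A 1 1 9.0 0.0 0.0 0.60 10.0 1 A 1\n"
        )
        path = tmp_path / "alt.cif"
        path.write_text(THREE_ATOM_CIF.rsplit("ATOM", 3)[0] + rows)
        s = read_structure(path)
        assert s.atom_count() == 1
        (atom,) = [a for _, _, _, a in s.iter_atoms()]
        assert atom.pos[0] == pytest.approx(9.0)

    def test_altloc_tie_prefers_lexicographic(self, tmp_path):
        rows = (
            "ATOM 1 C CA B ALA A 1 1 9.0 0.0 0.0 0.50 10.0 1 A 1\n"
            "ATOM 2 C CA A ALA A 1 1 0.0 0.0 0.0 0.50 10.0 1 A 1\n"
        )
        path = tmp_path / "alt.cif"
        path.write_text(THREE_ATOM_CIF.rsplit("ATOM", 3)[0] + rows)
        s = read_structure(path)
        (atom,) = [a for _, _, _, a in s.iter_atoms()]
        assert atom.pos[0] == pytest.approx(0.0)

    def test_roundtrip_parse_serialize_parse(self, structure):
        text = to_mmcif_text(structure)
        reparsed = read_structure_from_text(text, structure.entry_id)
        assert_structures_equal(structure, reparsed)
        # Second round is byte-stable.
        assert to_mmcif_text(reparsed) == text


def read_structure_from_text(text, entry_id, tmpdir=None):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / f"{entry_id}.cif"
        path.write_text(text)
        return read_structure(path)


class TestOperExpression:
    def test_comma_list(self):
        assert parse_oper_expression("1,2") == [("1",), ("2",)]

    def test_range(self):
        assert parse_oper_expression("(1-3)") == [("1",), ("2",), ("3",)]

    def test_cartesian_product(self):
        assert parse_oper_expression("(1,2)(3)") == [("1", "3"), ("2", "3")]


class TestExpandAssembly:
    def test_identity_operator_keeps_coordinates(self, structure):
        expanded = expand_assembly(structure, "1")
        src = {c.label_asym_id: c for c in structure.models[0][1]}
        for chain in expanded.models[0][1]:
            base, idx = chain.label_asym_id.rsplit("-", 1)
            if idx == "1":  # operator 1 is the identity
                orig = src[base]
                for ra, rb in zip(orig.residues, chain.residues):
                    for aa, ab in zip(ra.atoms, rb.atoms):
                        np.testing.assert_allclose(aa.pos, ab.pos, atol=1e-9)

    def test_atom_count_exactness(self, structure):
        expanded = expand_assembly(structure, "1")
        asm = structure.assembly("1")
        expected = 0
        by_label = {c.label_asym_id: c for c in structure.models[0][1]}
        for chain_set, sequences in asm.operator_expressions:
            for label in chain_set:
                expected += len(sequences) * by_label[label].atom_count()
        assert expanded.atom_count() == expected

    def test_two_operators_double_a_chain(self):
        s = point_structure(np.random.default_rng(0).normal(size=(10, 3)))
        asm = AssemblyDef(
            assembly_id="1",
            operator_expressions=[(("A",), [("1",), ("2",)])],
            operators={
                "1": (np.eye(3), np.zeros(3)),
                "2": (np.diag([-1.0, -1.0, 1.0]), np.array([5.0, 0, 0])),
            },
        )
        s.assemblies.append(asm)
        assert expand_assembly(s, "1").atom_count() == 20

    def test_composed_expression_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        s = point_structure(pts)
        r1 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        t1 = np.array([1.0, 2.0, 3.0])
        r2 = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        t2 = np.array([-4.0, 0.5, 0.0])
        s.assemblies.append(
            AssemblyDef(
                assembly_id="1",
                operator_expressions=[(("A",), [("2", "1")])],
                operators={"1": (r1, t1), "2": (r2, t2)},
            )
        )
        expanded = expand_assembly(s, "1")
        got = expanded.coords()
        # Brute-force oracle: sequence (2, 1) means op1 acts first, then op2.
        expected = np.array([r2 @ (r1 @ p + t1) + t2 for p in pts])
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_unknown_assembly(self, structure):
        with pytest.raises(UnknownAssemblyError):
            expand_assembly(structure, "999")

    def test_parsed_operators_orthogonal(self, structure):
        for asm in structure.assemblies:
            for rot, _ in asm.operators.values():
                np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-6)


class TestSelectDeposited:
    def test_all_models_retained(self):
        s1 = point_structure(np.random.default_rng(2).normal(size=(4, 3)))
        s = Structure(
            entry_id="nmr",
            models=[(1, s1.models[0][1]), (2, s1.models[0][1])],
            entities=s1.entities,
        )
        out = select_deposited(s)
        assert len(out.models) == 2
        assert out.view_label == "deposited"

    def test_single_model_unchanged(self, structure):
        out = select_deposited(structure)
        assert out.models is structure.models

    def test_empty_models_error(self):
        with pytest.raises(EmptyStructureError):
            Structure(entry_id="x", models=[], entities=[])
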