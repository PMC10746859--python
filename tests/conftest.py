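import numpy as np
import pytest

from molshots.annotations import load_annotations
from molshots.fixtures import FixtureSpec, make_fixture
from molshots.model import Atom, Chain, Entity, Residue, Structure
from molshots.scenes import SceneSpec
from molshots.structure_io import read_structure


@pytest.fixture(scope="session")
def pdb_fixture(tmp_path_factory):
    """(cif_path, annotations_path) for the full-featured pdb fixture."""
    outdir = tmp_path_factory.mktemp("fixture_pdb")
    return make_fixture(FixtureSpec(entry_id="1tst"), outdir)


@pytest.fixture(scope="session")
def structure(pdb_fixture):
    return read_structure(pdb_fixture[0])


@pytest.fixture(scope="session")
def annotations(pdb_fixture):
    return load_annotations(pdb_fixture[1])


@pytest.fixture(scope="session")
def af_fixture(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_af")
    spec = FixtureSpec(
        n_chains=1, mode="alphafold", entry_id="af1",
        with_ligand=False, with_modres=False, with_assembly=False,
        with_outliers=False, with_waters=False,
    )
    return make_fixture(spec, outdir)


@pytest.fixture(scope="session")
def af_structure(af_fixture):
    return read_structure(af_fixture[0])


def point_structure(points, b_factors=None, entry_id="test", exptl_method=""):
    """Structure with one chain, one single-atom residue per point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if b_factors is None:
        b_factors = [0.0] * len(points)
    residues = [
        Residue(
            comp_id="ALA", auth_seq=i + 1, label_seq=i + 1,
            atoms=[Atom(name="CA", element="C", pos=p, b_factor=float(b))],
        )
        for i, (p, b) in enumerate(zip(points, b_factors))
    ]
    chain = Chain(label_asym_id="A", auth_asym_id="A", entity_id="1", residues=residues)
    return Structure(
        entry_id=entry_id, models=[(1, [chain])],
        entities=[Entity("1", "polymer")], exptl_method=exptl_method,
    )


def simple_scene(points, colors, radii, visible=None, camera=None, scene_type="entry"):
    """SceneSpec over a point structure with an explicit camera (default identity)."""
    structure = point_structure(points)
    n = len(structure.coords())
    visible = tuple(range(n)) if visible is None else tuple(visible)
    return SceneSpec(
        scene_type=scene_type, qualifier="", structure=structure,
        visible_atoms=visible,
        atom_colors={i: tuple(colors[i]) for i in visible},
        atom_radii={i: float(radii[i]) for i in visible},
        highlight=frozenset(),
        camera_front=np.eye(3) if camera is None else np.asarray(camera, dtype=float),
        views=("front",), caption="test scene",
    )


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a random Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def assert_structures_equal(a: Structure, b: Structure, tol=1e-6):
    assert a.entry_id == b.entry_id
    assert a.exptl_method == b.exptl_method
    assert len(a.models) == len(b.models)
    assert {e.entity_id: (e.entity_type, e.description) for e in a.entities} == {
        e.entity_id: (e.entity_type, e.description) for e in b.entities
    }
    assert [x.assembly_id for x in a.assemblies] == [x.assembly_id for x in b.assemblies]
    for asm_a, asm_b in zip(a.assemblies, b.assemblies):
        assert asm_a.operator_expressions == asm_b.operator_expressions
        assert set(asm_a.operators) == set(asm_b.operators)
        for op in asm_a.operators:
            np.testing.assert_allclose(asm_a.operators[op][0], asm_b.operators[op][0], atol=tol)
            np.testing.assert_allclose(asm_a.operators[op][1], asm_b.operators[op][1], atol=tol)
    for (num_a, chains_a), (num_b, chains_b) in zip(a.models, b.models):
        assert num_a == num_b
        assert len(chains_a) == len(chains_b)
        for ca, cb in zip(chains_a, chains_b):
            assert (ca.label_asym_id, ca.auth_asym_id, ca.entity_id) == (
                cb.label_asym_id, cb.auth_asym_id, cb.entity_id,
            )
            assert len(ca.residues) == len(cb.residues)
            for ra, rb in zip(ca.residues, cb.residues):
                assert (ra.comp_id, ra.auth_seq, ra.label_seq, ra.ins_code) == (
                    rb.comp_id, rb.auth_seq, rb.label_seq, rb.ins_code,
                )
                assert len(ra.atoms) == len(rb.atoms)
                for aa, ab in zip(ra.atoms, rb.atoms):
                    assert (aa.name, aa.element, aa.is_hetero) == (
                        ab.name, ab.element, ab.is_hetero,
                    )
                    np.testing.assert_allclose(aa.pos, ab.pos, atol=tol)
                    assert abs(aa.b_factor - ab.b_factor) <= tol
                    assert abs(aa.occupancy - ab.occupancy) <= tol
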