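import numpy as np
import pytest

from molshots.annotations import AnnotationSet, DomainSegment
from molshots.errors import PLDDTRangeError, SceneTypeError
from molshots.model import Atom, Chain, Entity, Residue, Structure
from molshots.scenes import (
    ALL_TYPES,
    ALPHAFOLD_TYPES,
    MODE_TYPES,
    PALETTE,
    PDB_TYPES,
    PLDDT_COLORS,
    PUTTY_HIGH,
    PUTTY_LOW,
    NEUTRAL_GRAY,
    VALIDATION_COLORS,
    build_bfactor,
    build_domain,
    build_entity,
    build_entry,
    build_ligand,
    build_modres,
    build_plddt,
    build_validation,
    chain_palette,
    generate_scenes,
    plddt_band,
)

from conftest import point_structure


class TestGenerateScenes:
    def test_full_pdb_fixture_yields_12_scenes(self, structure, annotations):
        scenes = generate_scenes(structure, annotations, "pdb")
        # 1 entry + 1 assembly + 3 entity + 3 domain + 1 ligand + 1 modres
        # + 1 bfactor + 1 validation
        assert len(scenes) == 12
        by_type = {}
        for s in scenes:
            by_type.setdefault(s.scene_type, []).append(s)
        assert {t: len(v) for t, v in by_type.items()} == {
            "entry": 1, "assembly": 1, "entity": 3, "domain": 3,
            "ligand": 1, "modres": 1, "bfactor": 1, "validation": 1,
        }

    def test_order_is_catalogue_then_qualifier(self, structure, annotations):
        scenes = generate_scenes(structure, annotations, "pdb")
        types = [s.scene_type for s in scenes]
        assert types == sorted(types, key=PDB_TYPES.index)
        for t in set(types):
            quals = [s.qualifier for s in scenes if s.scene_type == t]
            assert quals == sorted(quals)

    def test_alphafold_mode_single_plddt_scene(self, af_structure):
        scenes = generate_scenes(af_structure, AnnotationSet(), "alphafold")
        assert [s.scene_type for s in scenes] == ["plddt"]

    def test_requested_entry_only(self, structure, annotations):
        scenes = generate_scenes(structure, annotations, "pdb", requested_types={"entry"})
        assert len(scenes) == 1 and scenes[0].scene_type == "entry"

    def test_type_not_applicable_to_mode(self, structure, annotations):
        with pytest.raises(SceneTypeError):
            generate_scenes(structure, annotations, "pdb", requested_types={"plddt"})

    def test_unknown_type_rejected(self, structure, annotations):
        with pytest.raises(SceneTypeError):
            generate_scenes(structure, annotations, "pdb", requested_types={"ribbon"})

    def test_catalogue_is_nine_types(self):
        assert len(ALL_TYPES) == 9
        assert len(PDB_TYPES) == 8
        assert len(ALPHAFOLD_TYPES) == 1
        assert set(MODE_TYPES) == {"pdb", "alphafold"}

    def test_deterministic(self, structure, annotations):
        a = generate_scenes(structure, annotations, "pdb")
        b = generate_scenes(structure, annotations, "pdb")
        assert len(a) == len(b)
        assert all(x.equals(y) for x, y in zip(a, b))

    def test_every_scene_satisfies_invariants(self, structure, annotations):
        for scene in generate_scenes(structure, annotations, "pdb"):
            visible = set(scene.visible_atoms)
            assert scene.highlight <= visible
            assert set(scene.atom_colors) >= visible
            assert set(scene.atom_radii) >= visible


class TestEntry:
    def test_chains_get_distinct_colors(self, structure):
        scene = build_entry(structure)
        flat = scene.flat
        colors_by_chain = {}
        for i in scene.visible_atoms:
            colors_by_chain.setdefault(flat.label_asym_id[i], set()).add(
                scene.atom_colors[i]
            )
        assert all(len(c) == 1 for c in colors_by_chain.values())
        assert colors_by_chain["A"] != colors_by_chain["B"]

    def test_ensemble_shows_all_models(self):
        base = point_structure(np.random.default_rng(0).normal(size=(5, 3)))
        ensemble = Structure(
            entry_id="nmr",
            models=[(m, base.models[0][1]) for m in (1, 2, 3)],
            entities=base.entities,
        )
        scene = build_entry(ensemble)
        assert len(scene.visible_atoms) == 3 * 5

    def test_single_atom_structure(self):
        scene = build_entry(point_structure([[0.0, 0.0, 0.0]]))
        assert scene.visible_atoms == (0,)


class TestEntity:
    def test_water_entity_rejected(self, structure, annotations):
        water = next(e for e in structure.entities if e.entity_type == "water")
        with pytest.raises(SceneTypeError):
            build_entity(structure, annotations, water.entity_id)

    def test_highlight_is_entity_atoms_in_preferred_assembly(self, structure, annotations):
        scene = build_entity(structure, annotations, "1")
        assert scene.structure.view_label == "assembly-1"
        assert scene.highlight
        assert scene.highlight <= set(scene.visible_atoms)
        assert all(scene.flat.entity_id[i] == "1" for i in scene.highlight)

    def test_non_highlight_faded(self, structure, annotations):
        scene = build_entity(structure, annotations, "1")
        other = next(i for i in scene.visible_atoms if i not in scene.highlight)
        inside = next(iter(scene.highlight))
        # Faded colors drift toward light gray: lower saturation.
        assert max(scene.atom_colors[other]) - min(scene.atom_colors[other]) < max(
            scene.atom_colors[inside]
        ) - min(scene.atom_colors[inside])


class TestDomain:
    def test_one_scene_per_family(self, structure, annotations):
        scenes = build_domain(structure, annotations)
        assert len(scenes) == 3
        assert [s.qualifier for s in scenes] == sorted(s.qualifier for s in scenes)

    def test_empty_mappings(self, structure):
        assert build_domain(structure, AnnotationSet()) == []

    def test_inclusive_range(self):
        s = point_structure(np.arange(30).reshape(10, 3).astype(float))
        ann = AnnotationSet(domains=[DomainSegment("CATH", "fam", "A", 5, 7)])
        (scene,) = build_domain(s, ann)
        highlighted_seqs = {int(scene.flat.auth_seq[i]) for i in scene.highlight}
        assert highlighted_seqs == {5, 6, 7}

    def test_missing_chain_segment_skipped(self, structure, annotations, caplog):
        ann = AnnotationSet(domains=[DomainSegment("SCOP", "sf1", "Z", 1, 5)])
        (scene,) = build_domain(structure, ann)
        assert scene.highlight == frozenset()


def ligand_test_structure():
    """Ligand atom at origin; two polymer residues at 4 and 6 Angstrom."""
    chain_a = Chain(
        label_asym_id="A", auth_asym_id="A", entity_id="1",
        residues=[
            Residue(comp_id="ALA", auth_seq=1, label_seq=1,
                    atoms=[Atom("CA", "C", [4.0, 0.0, 0.0])]),
            Residue(comp_id="GLY", auth_seq=2, label_seq=2,
                    atoms=[Atom("CA", "C", [6.0, 0.0, 0.0])]),
        ],
    )
    chain_l = Chain(
        label_asym_id="L", auth_asym_id="L", entity_id="2",
        residues=[Residue(comp_id="XYZ", auth_seq=100, label_seq=None,
                          atoms=[Atom("C1", "C", [0.0, 0.0, 0.0], is_hetero=True)])],
    )
    return Structure(
        entry_id="lig", models=[(1, [chain_a, chain_l])],
        entities=[Entity("1", "polymer"), Entity("2", "non-polymer")],
    )


class TestLigand:
    def test_environment_radius_five_angstrom(self):
        scene = build_ligand(ligand_test_structure(), AnnotationSet(), "2")
        seqs = {int(scene.flat.auth_seq[i]) for i in scene.visible_atoms}
        assert seqs == {100, 1}  # the 6 A residue stays out

    def test_polymer_entity_rejected(self):
        with pytest.raises(SceneTypeError):
            build_ligand(ligand_test_structure(), AnnotationSet(), "1")

    def test_water_not_offered_by_dispatch(self, structure, annotations):
        scenes = generate_scenes(structure, annotations, "pdb", requested_types={"ligand"})
        assert len(scenes) == 1  # only the true ligand entity, not water
        assert scenes[0].qualifier == "LIG"

    def test_all_entity_copies_visible(self, structure, annotations):
        scene = build_ligand(structure, annotations, "3")
        lig_atoms = [i for i in scene.visible_atoms if scene.flat.entity_id[i] == "3"]
        assert len(lig_atoms) == 3


class TestModres:
    def test_one_scene_two_highlighted_sites(self, structure, annotations):
        scenes = build_modres(structure, annotations)
        assert len(scenes) == 1
        scene = scenes[0]
        # Preferred assembly has 2 copies of chain A -> 2 sites x 2 copies.
        seqs = sorted(
            {(scene.flat.auth_asym_id[i], int(scene.flat.auth_seq[i])) for i in scene.highlight}
        )
        assert {s for _, s in seqs} == {3, 7}
        assert all(scene.flat.comp_id[i] == "MSE" for i in scene.highlight)

    def test_empty_modres(self, structure):
        assert build_modres(structure, AnnotationSet()) == []


class TestBfactor:
    def test_mapping_endpoints(self, structure):
        scene = build_bfactor(structure)
        radii = [scene.atom_radii[i] for i in scene.visible_atoms]
        lo, hi = min(radii), max(radii)
        assert lo == pytest.approx(0.3, abs=1e-6)
        assert hi == pytest.approx(2.5, abs=1e-6)
        lo_atom = next(i for i in scene.visible_atoms if scene.atom_radii[i] == lo)
        hi_atom = next(i for i in scene.visible_atoms if scene.atom_radii[i] == hi)
        assert scene.atom_colors[lo_atom] == PUTTY_LOW
        assert scene.atom_colors[hi_atom] == PUTTY_HIGH

    def test_constant_b_gives_unit_radius(self):
        s = point_structure(
            np.random.default_rng(1).normal(size=(6, 3)),
            b_factors=[42.0] * 6, exptl_method="X-RAY DIFFRACTION",
        )
        scene = build_bfactor(s)
        assert all(r == pytest.approx(1.0) for r in scene.atom_radii.values())

    def test_skipped_for_non_xray(self, structure, annotations):
        import dataclasses

        em = dataclasses.replace(structure, exptl_method="ELECTRON MICROSCOPY")
        scenes = generate_scenes(em, annotations, "pdb")
        assert "bfactor" not in {s.scene_type for s in scenes}


class TestValidation:
    def test_color_bands(self, structure, annotations):
        scene = build_validation(structure, annotations)
        flat = scene.flat
        lookup = annotations.outlier_lookup()
        for i in scene.visible_atoms:
            key = (flat.auth_asym_id[i], int(flat.auth_seq[i]))
            if key in lookup:
                assert scene.atom_colors[i] == VALIDATION_COLORS[min(lookup[key], 3)]
            else:
                assert scene.atom_colors[i] == NEUTRAL_GRAY

    def test_no_data_skips(self, structure):
        with pytest.raises(SceneTypeError):
            build_validation(structure, AnnotationSet())


class TestPlddt:
    def test_band_colors(self, af_structure):
        scene = build_plddt(af_structure)
        flat = scene.flat
        for i in scene.visible_atoms:
            band = plddt_band(float(flat.b_factor[i]))
            # Per-residue mean equals the atom value in the fixture
            assert scene.atom_colors[i] == PLDDT_COLORS[band]

    def test_band_boundaries_left_inclusive(self):
        assert plddt_band(49.999) == 0
        assert plddt_band(50.0) == 1
        assert plddt_band(70.0) == 2
        assert plddt_band(90.0) == 3
        assert plddt_band(95.0) == 3

    def test_out_of_range_raises(self):
        s = point_structure([[0, 0, 0], [1, 0, 0]], b_factors=[50.0, 105.0])
        with pytest.raises(PLDDTRangeError):
            build_plddt(s)


class TestChainPalette:
    def test_cyclic(self):
        assert chain_palette(0) == chain_palette(len(PALETTE))

    def test_pairwise_distinct(self):
        colors = [chain_palette(i) for i in range(len(PALETTE))]
        assert len(set(colors)) == len(PALETTE)

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            chain_palette(-1)
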