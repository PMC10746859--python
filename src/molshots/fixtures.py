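"""Deterministic synthetic test data: mmCIF files + annotation JSONs.

The generator builds idealized helical chains (rise 1.5 A, twist 100 deg,
radius 2.3 A) so the coordinate PCA spectrum is non-degenerate (strongly
elongated along z), which canonical-orientation tests rely on.  A fully
featured 'pdb' fixture exercises every scene type: two distinct polymer
entities, a 3-atom ligand, water, a modified residue (MSE at two sites), a
2-operator assembly, ramped B-factors, domain segments, and cycling
outlier counts.  An 'alphafold' fixture carries confidence values in the
B-factor field instead.

Output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import (
    AnnotationSet,
    DomainSegment,
    ModifiedResidueRecord,
    ResidueOutlierCount,
    save_annotations,
)
from .model import AssemblyDef, Atom, Chain, Entity, Residue, Structure
from .structure_io import to_mmcif_text

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = math.radians(100.0)
HELIX_RADIUS = 2.3  # A
CHAIN_SPACING = 9.0  # A along x between chains
JITTER = 0.05  # A of deterministic coordinate noise

B_RANGE_PDB = (10.0, 80.0)
B_RANGE_ALPHAFOLD = (30.0, 98.0)

MODRES_COMP = "MSE"
MODRES_POSITIONS = (3, 7)  # 1-based residue numbers on chain A

# Backbone atom template: (name, element, angle offset, z offset, radius)
_BACKBONE = (
    ("N", "N", -0.6, -0.5, 2.0),
    ("CA", "C", 0.0, 0.0, HELIX_RADIUS),
    ("C", "C", 0.6, 0.5, 2.0),
    ("O", "O", 0.6, 1.1, 2.6),
)


@dataclass
class FixtureSpec:
    n_chains: int = 2
    residues_per_chain: int = 10
    with_ligand: bool = True
    with_modres: bool = True
    with_assembly: bool = True
    with_outliers: bool = True
    with_waters: bool = True
    mode: str = "pdb"
    seed: int = 0
    entry_id: str = "1tst"

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.residues_per_chain < 1:
            raise ValueError("n_chains and residues_per_chain must be >= 1")
        if self.mode not in ("pdb", "alphafold"):
            raise ValueError(f"mode must be 'pdb' or 'alphafold', got {self.mode!r}")
        if not self.entry_id:
            raise ValueError("entry_id must be non-empty")


def build_structure(spec: FixtureSpec) -> Structure:
    """Construct the fixture Structure in memory."""
    rng = np.random.default_rng(spec.seed)
    b_lo, b_hi = B_RANGE_ALPHAFOLD if spec.mode == "alphafold" else B_RANGE_PDB
    n_res = spec.residues_per_chain
    chains: list[Chain] = []
    entities: list[Entity] = [Entity("1", "polymer", "Alpha helix protein 1")]
    if spec.n_chains > 1:
        entities.append(Entity("2", "polymer", "Alpha helix protein 2"))
    for c in range(spec.n_chains):
        label = chr(ord("A") + c)
        entity_id = "1" if c == 0 else "2"
        residues = []
        for j in range(n_res):
            seq = j + 1
            comp = "ALA" if c == 0 else "GLY"
            if (
                spec.mode == "pdb" and spec.with_modres and c == 0
                and seq in MODRES_POSITIONS
            ):
                comp = MODRES_COMP
            b = b_lo if n_res == 1 else b_lo + (b_hi - b_lo) * j / (n_res - 1)
            atoms = []
            for name, element, dtheta, dz, radius in _BACKBONE:
                theta = HELIX_TWIST * j + dtheta
                pos = np.array(
                    [
                        radius * math.cos(theta) + CHAIN_SPACING * c,
                        radius * math.sin(theta),
                        HELIX_RISE * j + dz,
                    ]
                )
                pos = pos + rng.normal(0.0, JITTER, size=3)
                atoms.append(Atom(name=name, element=element, pos=pos, b_factor=round(b, 2)))
            residues.append(Residue(comp_id=comp, auth_seq=seq, label_seq=seq, atoms=atoms))
        chains.append(
            Chain(label_asym_id=label, auth_asym_id=label, entity_id=entity_id,
                  residues=residues)
        )
    polymer_labels = tuple(ch.label_asym_id for ch in chains)

    if spec.mode == "pdb" and spec.with_ligand:
        lig_entity = str(len(entities) + 1)
        entities.append(Entity(lig_entity, "non-polymer", "Synthetic ligand"))
        z_mid = HELIX_RISE * (n_res - 1) / 2.0
        base = np.array([4.0, 0.0, z_mid])
        lig_atoms = [
            Atom(name=name, element=el, pos=base + off, b_factor=30.0, is_hetero=True)
            for name, el, off in (
                ("C1", "C", np.zeros(3)),
                ("O1", "O", np.array([0.8, 0.0, 0.0])),
                ("N1", "N", np.array([0.0, 0.8, 0.0])),
            )
        ]
        chains.append(
            Chain(
                label_asym_id="L", auth_asym_id="L", entity_id=lig_entity,
                residues=[Residue(comp_id="LIG", auth_seq=201, label_seq=None,
                                  atoms=lig_atoms)],
            )
        )
    if spec.mode == "pdb" and spec.with_waters:
        wat_entity = str(len(entities) + 1)
        entities.append(Entity(wat_entity, "water", "water"))
        waters = [
            Residue(
                comp_id="HOH", auth_seq=301 + k, label_seq=None,
                atoms=[Atom(name="O", element="O",
                            pos=np.array([-6.0, -6.0, 3.0 * k]),
                            b_factor=30.0, is_hetero=True)],
            )
            for k in range(2)
        ]
        chains.append(
            Chain(label_asym_id="W", auth_asym_id="W", entity_id=wat_entity,
                  residues=waters)
        )

    assemblies = []
    if spec.with_assembly:
        rot180z = np.diag([-1.0, -1.0, 1.0])
        assemblies.append(
            AssemblyDef(
                assembly_id="1",
                operator_expressions=[(polymer_labels, [("1",), ("2",)])],
                operators={
                    "1": (np.eye(3), np.zeros(3)),
                    "2": (rot180z, np.array([24.0, 0.0, 0.0])),
                },
            )
        )
    return Structure(
        entry_id=spec.entry_id,
        models=[(1, chains)],
        entities=entities,
        assemblies=assemblies,
        exptl_method="X-RAY DIFFRACTION" if spec.mode == "pdb" else "",
        view_label="deposited",
    )


def build_annotations(spec: FixtureSpec) -> AnnotationSet:
    """Annotation content matching :func:`build_structure` output."""
    ann = AnnotationSet()
    if spec.mode != "pdb":
        return ann
    ann.entity_names = {"1": "Alpha helix protein 1"}
    if spec.n_chains > 1:
        ann.entity_names["2"] = "Alpha helix protein 2"
    if spec.with_assembly:
        ann.preferred_assembly_id = "1"
    n = spec.residues_per_chain
    if n >= 2:
        half = max(n // 2, 1)
        ann.domains = [
            DomainSegment("CATH", "1.10.8.10", "A", 1, half),
            DomainSegment("CATH", "2.40.50.140", "A", min(half + 1, n), n),
            DomainSegment("Pfam", "PF00001", "A", 1, n),
        ]
    if spec.with_modres:
        sites = tuple(("A", seq) for seq in MODRES_POSITIONS if seq <= n)
        if sites:
            ann.modres = [ModifiedResidueRecord(comp_id=MODRES_COMP, sites=sites)]
    if spec.with_outliers:
        ann.outliers = [
            ResidueOutlierCount(chain=chr(ord("A") + c), auth_seq=j + 1,
                                outlier_count=j % 4)
            for c in range(spec.n_chains)
            for j in range(n)
        ]
    return ann


def make_fixture(spec: FixtureSpec, outdir) -> tuple[Path, Path]:
    """Write the fixture mmCIF and annotation JSON; returns both paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = build_structure(spec)
    cif_path = outdir / f"{spec.entry_id}.cif"
    cif_path.write_text(to_mmcif_text(structure))
    ann_path = outdir / f"{spec.entry_id}_annotations.json"
    save_annotations(build_annotations(spec), ann_path, entry_id=spec.entry_id)
    return cif_path, ann_path
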