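"""Internal structure model.

A deliberately small hierarchy: ``Structure`` -> models -> ``Chain`` ->
``Residue`` -> ``Atom``, plus ``Entity`` descriptions and biological
``AssemblyDef`` operator lists.  Coordinates are float64 numpy vectors in
Angstrom.  The model is value-oriented: helpers return new objects rather
than mutating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .errors import EmptyStructureError

ENTITY_TYPES = ("polymer", "non-polymer", "branched", "water")


@dataclass
class Atom:
    """A single atom site (one altloc conformer already selected)."""

    name: str
    element: str
    pos: np.ndarray  # shape (3,), Angstrom
    b_factor: float = 0.0  # also carries pLDDT for predicted models
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.pos!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    comp_id: str
    auth_seq: int
    label_seq: Optional[int] = None
    ins_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.comp_id} {self.auth_seq} has no atoms")

    def mean_b(self) -> float:
        return float(np.mean([a.b_factor for a in self.atoms]))


@dataclass
class Chain:
    label_asym_id: str
    auth_asym_id: str
    entity_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [
            r.label_seq if r.label_seq is not None else r.auth_seq for r in self.residues
        ]
        if keys != sorted(keys):
            self.residues = [r for _, r in sorted(zip(keys, self.residues), key=lambda p: p[0])]

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass
class Entity:
    entity_id: str
    entity_type: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(
                f"entity_type must be one of {ENTITY_TYPES}, got {self.entity_type!r}"
            )


@dataclass
class AssemblyDef:
    """One biological assembly: operator expressions over chain sets.

    ``operator_expressions`` pairs a tuple of label_asym_ids with the list
    of operator-id sequences to apply; each sequence composes left-to-right
    as a matrix product acting on coordinates.  ``operators`` maps operator
    id to ``(rotation 3x3, translation 3-vector)``.
    """

    assembly_id: str
    operator_expressions: list[tuple[tuple[str, ...], list[tuple[str, ...]]]]
    operators: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for _, sequences in self.operator_expressions:
            for seq in sequences:
                for op_id in seq:
                    if op_id not in self.operators:
                        raise ValueError(
                            f"assembly {self.assembly_id}: operator {op_id!r} "
                            "referenced but not defined"
                        )
        for op_id, (rot, _) in self.operators.items():
            det = abs(np.linalg.det(np.asarray(rot, dtype=float)))
            if abs(det - 1.0) > 1e-6:
                raise ValueError(
                    f"operator {op_id}: |det| = {det:.8f}, expected 1 within 1e-6"
                )


@dataclass
class Structure:
    entry_id: str
    models: list[tuple[int, list[Chain]]]
    entities: list[Entity] = field(default_factory=list)
    assemblies: list[AssemblyDef] = field(default_factory=list)
    exptl_method: str = ""
    view_label: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise EmptyStructureError(f"structure {self.entry_id!r} has no models")
        known = {e.entity_id for e in self.entities}
        for _, chains in self.models:
            for chain in chains:
                if chain.entity_id not in known:
                    raise ValueError(
                        f"chain {chain.label_asym_id}: entity {chain.entity_id!r} "
                        "does not resolve to an entity"
                    )

    # -- convenience accessors ------------------------------------------------

    def entity(self, entity_id: str) -> Entity:
        for ent in self.entities:
            if ent.entity_id == entity_id:
                return ent
        raise KeyError(entity_id)

    def assembly(self, assembly_id: str) -> AssemblyDef:
        for asm in self.assemblies:
            if asm.assembly_id == assembly_id:
                return asm
        raise KeyError(assembly_id)

    def iter_atoms(self) -> Iterator[tuple[int, Chain, Residue, Atom]]:
        """Yield (model_number, chain, residue, atom) in stable order."""
        for model_num, chains in self.models:
            for chain in chains:
                for residue in chain.residues:
                    for atom in residue.atoms:
                        yield model_num, chain, residue, atom

    def atom_count(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        """All atom coordinates over all models, shape (N, 3)."""
        pts = [a.pos for _, _, _, a in self.iter_atoms()]
        if not pts:
            return np.empty((0, 3))
        return np.stack(pts)

    def with_view_label(self, label: str) -> "Structure":
        return replace(self, view_label=label)


@dataclass(frozen=True)
class FlatAtoms:
    """Column-oriented view of a Structure used by scene building/rendering.

    Index ``i`` in every array refers to the same atom; iteration order
    matches :meth:`Structure.iter_atoms`.
    """

    coords: np.ndarray  # (N, 3) float
    b_factor: np.ndarray  # (N,) float
    model_num: np.ndarray  # (N,) int
    label_asym_id: np.ndarray  # (N,) object
    auth_asym_id: np.ndarray  # (N,) object
    entity_id: np.ndarray  # (N,) object
    comp_id: np.ndarray  # (N,) object
    auth_seq: np.ndarray  # (N,) int
    atom_name: np.ndarray  # (N,) object
    element: np.ndarray  # (N,) object
    is_hetero: np.ndarray  # (N,) bool

    def __len__(self) -> int:
        return len(self.coords)


def flatten(structure: Structure) -> FlatAtoms:
    rows = list(structure.iter_atoms())
    if not rows:
        raise EmptyStructureError(f"structure {structure.entry_id!r} has no atoms")
    return FlatAtoms(
        coords=np.stack([a.pos for _, _, _, a in rows]),
        b_factor=np.array([a.b_factor for _, _, _, a in rows]),
        model_num=np.array([m for m, _, _, _ in rows]),
        label_asym_id=np.array([c.label_asym_id for _, c, _, _ in rows], dtype=object),
        auth_asym_id=np.array([c.auth_asym_id for _, c, _, _ in rows], dtype=object),
        entity_id=np.array([c.entity_id for _, c, _, _ in rows], dtype=object),
        comp_id=np.array([r.comp_id for _, _, r, _ in rows], dtype=object),
        auth_seq=np.array([r.auth_seq for _, _, r, _ in rows]),
        atom_name=np.array([a.name for _, _, _, a in rows], dtype=object),
        element=np.array([a.element for _, _, _, a in rows], dtype=object),
        is_hetero=np.array([a.is_hetero for _, _, _, a in rows], dtype=bool),
    )
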