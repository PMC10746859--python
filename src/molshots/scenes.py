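"""Scene construction: the nine predefined view types.

A :class:`SceneSpec` is a fully resolved description of one view family —
which atoms are visible, their colors and radii, which subset is
highlighted, the canonical front camera, and which derived views (front/
side/top) to render.  Builders never touch pixels; rendering happens in
:mod:`molshots.render`.

Scene types and modes:

========== ========== =====================================================
mode       type       content
========== ========== =====================================================
pdb        entry      complete deposited structure, colored by chain
pdb        assembly   each listed assembly, expanded and colored by chain
pdb        entity     preferred assembly with one entity highlighted
pdb        domain     one scene per (source, family) domain mapping
pdb        ligand     each non-polymer entity with its 5 A environment
pdb        modres     preferred assembly with one modified-residue type
pdb        bfactor    deposited structure, putty sized/colored by B
pdb        validation deposited structure colored by outlier counts
alphafold  plddt      predicted structure colored by confidence bands
========== ========== =====================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet
from .errors import PLDDTRangeError, SceneTypeError
from .model import FlatAtoms, Structure, flatten
from .orientation import canonical_rotation
from .structure_io import expand_assembly, select_deposited

logger = logging.getLogger(__name__)

Color = tuple[int, int, int]

MODES = ("pdb", "alphafold")

#: Output order of scene types (pdb mode rows first, catalogue order).
PDB_TYPES = ("entry", "assembly", "entity", "domain", "ligand", "modres",
             "bfactor", "validation")
ALPHAFOLD_TYPES = ("plddt",)
MODE_TYPES = {"pdb": PDB_TYPES, "alphafold": ALPHAFOLD_TYPES}
ALL_TYPES = PDB_TYPES + ALPHAFOLD_TYPES

#: Types rendered in front+side+top; the rest render front only.
MULTI_VIEW_TYPES = frozenset({"entry", "assembly", "bfactor", "validation", "plddt"})

# 12-color cyclic chain palette (visually distinct, fixed for determinism).
PALETTE: tuple[Color, ...] = (
    (27, 158, 119), (217, 95, 2), (117, 112, 179), (231, 41, 138),
    (102, 166, 30), (230, 171, 2), (166, 118, 29), (102, 102, 102),
    (31, 120, 180), (178, 34, 34), (106, 61, 154), (255, 127, 0),
)

FADE_TARGET: Color = (208, 208, 208)
FADE_FRACTION = 0.65  # blend weight toward FADE_TARGET for non-highlighted atoms
NEUTRAL_GRAY: Color = (160, 160, 160)

DEFAULT_RADIUS = 1.6  # overview impostor sphere radius, Angstrom
LIGAND_BALL_RADIUS = 0.5
ENVIRONMENT_RADIUS = 0.3  # thinner spheres for binding-site environment
ENVIRONMENT_SHELL = 5.0  # Angstrom; whole-residue inclusion

PUTTY_R_MIN, PUTTY_R_MAX = 0.3, 2.5  # r = 0.3 + 2.2 * t
PUTTY_LOW: Color = (40, 60, 220)
PUTTY_HIGH: Color = (220, 30, 30)

VALIDATION_COLORS: tuple[Color, ...] = (
    (0, 170, 68),    # 0 outliers
    (255, 210, 0),   # 1
    (255, 140, 0),   # 2
    (220, 30, 30),   # >= 3
)

PLDDT_COLORS: tuple[Color, ...] = (
    (255, 125, 69),   # very low  (< 50)
    (255, 219, 87),   # low       [50, 70)
    (101, 203, 243),  # confident [70, 90)
    (0, 83, 214),     # very high [90, 100]
)
PLDDT_THRESHOLDS = (50.0, 70.0, 90.0)

_TRACE_ATOM_NAMES = ("CA", "C4'", "P")

CAPTIONS = {
    "entry": "{id}: complete deposited structure, colored by chain.",
    "assembly": "{id}: biological assembly {qualifier}, colored by chain.",
    "entity": "{id}: entity {qualifier} ({name}) highlighted in the preferred assembly.",
    "domain": "{id}: {qualifier} domain segments highlighted.",
    "ligand": "{id}: ligand {qualifier} and its surroundings within 5 A.",
    "modres": "{id}: all instances of modified residue {qualifier} highlighted.",
    "bfactor": "{id}: deposited structure in putty representation, colored by B-factor.",
    "validation": "{id}: deposited structure colored by per-residue quality outliers.",
    "plddt": "{id}: predicted structure colored by per-residue confidence (pLDDT).",
}


@dataclass
class SceneSpec:
    scene_type: str
    qualifier: str
    structure: Structure
    visible_atoms: tuple[int, ...]
    atom_colors: dict[int, Color]
    atom_radii: dict[int, float]
    highlight: frozenset[int]
    camera_front: np.ndarray
    views: tuple[str, ...]
    caption: str
    flat: FlatAtoms = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.scene_type not in ALL_TYPES:
            raise SceneTypeError(f"unknown scene type {self.scene_type!r}")
        if self.flat is None:
            self.flat = flatten(self.structure)
        vis = set(self.visible_atoms)
        if not self.highlight <= vis:
            raise ValueError("highlight set must be a subset of visible atoms")
        missing_c = vis - set(self.atom_colors)
        missing_r = vis - set(self.atom_radii)
        if missing_c or missing_r:
            raise ValueError(
                f"visible atoms lack color ({len(missing_c)}) or radius ({len(missing_r)})"
            )

    def equals(self, other: "SceneSpec", atol: float = 1e-9) -> bool:
        return (
            self.scene_type == other.scene_type
            and self.qualifier == other.qualifier
            and self.visible_atoms == other.visible_atoms
            and self.atom_colors == other.atom_colors
            and self.highlight == other.highlight
            and self.views == other.views
            and self.caption == other.caption
            and set(self.atom_radii) == set(other.atom_radii)
            and all(
                abs(self.atom_radii[i] - other.atom_radii[i]) <= atol
                for i in self.atom_radii
            )
            and np.allclose(self.camera_front, other.camera_front, atol=atol)
        )


# ---------------------------------------------------------------------------
# Small helpers


def chain_palette(index: int) -> Color:
    """Deterministic cyclic chain color palette."""
    if index < 0:
        raise ValueError(f"palette index must be non-negative, got {index}")
    return PALETTE[index % len(PALETTE)]


def faded(color: Color) -> Color:
    """Blend a color 65% toward light gray (non-highlight rendering)."""
    return tuple(
        int(round((1 - FADE_FRACTION) * c + FADE_FRACTION * t))
        for c, t in zip(color, FADE_TARGET)
    )


def _lerp_color(lo: Color, hi: Color, t: float) -> Color:
    t = min(max(t, 0.0), 1.0)
    return tuple(int(round(l + (h - l) * t)) for l, h in zip(lo, hi))


def _chain_color_map(flat: FlatAtoms) -> dict[str, Color]:
    order: list[str] = []
    for label in flat.label_asym_id:
        if label not in order:
            order.append(label)
    return {label: chain_palette(i) for i, label in enumerate(order)}


def _camera(flat: FlatAtoms, visible: tuple[int, ...]) -> np.ndarray:
    return canonical_rotation(flat.coords[list(visible)])


def _views_for(scene_type: str) -> tuple[str, ...]:
    return ("front", "side", "top") if scene_type in MULTI_VIEW_TYPES else ("front",)


def _auth_base(auth_asym_id: str) -> str:
    """Strip the '-{copy}' suffix that assembly expansion appends."""
    return auth_asym_id.split("-", 1)[0]


def preferred_context(structure: Structure, annotations: AnnotationSet) -> Structure:
    """The preferred assembly; falls back to the first listed assembly, then
    to the deposited structure."""
    asm_id = annotations.preferred_assembly_id
    if asm_id is not None and any(a.assembly_id == asm_id for a in structure.assemblies):
        return expand_assembly(structure, asm_id)
    if structure.assemblies:
        return expand_assembly(structure, structure.assemblies[0].assembly_id)
    return select_deposited(structure)


def plddt_band(value: float) -> int:
    """Band index 0..3 for a confidence value; bands are left-inclusive."""
    if not 0.0 <= value <= 100.0:
        raise PLDDTRangeError(f"pLDDT value {value} outside [0, 100]")
    for i, threshold in enumerate(PLDDT_THRESHOLDS):
        if value < threshold:
            return i
    return 3


def outlier_color(count) -> Color:
    if count is None:
        return NEUTRAL_GRAY
    return VALIDATION_COLORS[min(int(count), 3)]


def putty_radius(b: float, b_min: float, b_max: float) -> float:
    if b_max <= b_min:
        return 1.0
    t = min(max((b - b_min) / (b_max - b_min), 0.0), 1.0)
    return PUTTY_R_MIN + (PUTTY_R_MAX - PUTTY_R_MIN) * t


def _residue_keys(flat: FlatAtoms) -> np.ndarray:
    """Per-atom residue key array (model, chain, auth_seq) as object tuples."""
    return np.array(
        [
            (m, c, s)
            for m, c, s in zip(flat.model_num, flat.label_asym_id, flat.auth_seq)
        ],
        dtype=object,
    )


# ---------------------------------------------------------------------------
# Per-type builders


def build_entry(structure: Structure) -> SceneSpec:
    """All atoms of all models, colored by chain."""
    context = select_deposited(structure)
    flat = flatten(context)
    visible = tuple(range(len(flat)))
    cmap = _chain_color_map(flat)
    colors = {i: cmap[flat.label_asym_id[i]] for i in visible}
    radii = {i: DEFAULT_RADIUS for i in visible}
    return SceneSpec(
        scene_type="entry", qualifier="", structure=context, flat=flat,
        visible_atoms=visible, atom_colors=colors, atom_radii=radii,
        highlight=frozenset(), camera_front=_camera(flat, visible),
        views=_views_for("entry"),
        caption=CAPTIONS["entry"].format(id=structure.entry_id),
    )


def build_assembly(structure: Structure, assembly_id: str) -> SceneSpec:
    context = expand_assembly(structure, assembly_id)
    flat = flatten(context)
    visible = tuple(range(len(flat)))
    cmap = _chain_color_map(flat)
    colors = {i: cmap[flat.label_asym_id[i]] for i in visible}
    radii = {i: DEFAULT_RADIUS for i in visible}
    return SceneSpec(
        scene_type="assembly", qualifier=assembly_id, structure=context, flat=flat,
        visible_atoms=visible, atom_colors=colors, atom_radii=radii,
        highlight=frozenset(), camera_front=_camera(flat, visible),
        views=_views_for("assembly"),
        caption=CAPTIONS["assembly"].format(id=structure.entry_id, qualifier=assembly_id),
    )


def build_entity(structure: Structure, annotations: AnnotationSet, entity_id: str) -> SceneSpec:
    entity = structure.entity(entity_id)
    if entity.entity_type == "water":
        raise SceneTypeError("entity scenes exclude the water entity")
    context = preferred_context(structure, annotations)
    flat = flatten(context)
    visible = tuple(range(len(flat)))
    cmap = _chain_color_map(flat)
    highlight = frozenset(i for i in visible if flat.entity_id[i] == entity_id)
    colors = {
        i: (cmap[flat.label_asym_id[i]] if i in highlight else faded(cmap[flat.label_asym_id[i]]))
        for i in visible
    }
    radii = {i: DEFAULT_RADIUS for i in visible}
    name = annotations.entity_names.get(entity_id) or entity.description or "unnamed"
    return SceneSpec(
        scene_type="entity", qualifier=entity_id, structure=context, flat=flat,
        visible_atoms=visible, atom_colors=colors, atom_radii=radii,
        highlight=highlight, camera_front=_camera(flat, visible),
        views=_views_for("entity"),
        caption=CAPTIONS["entity"].format(id=structure.entry_id, qualifier=entity_id, name=name),
    )


def build_domain(structure: Structure, annotations: AnnotationSet) -> list[SceneSpec]:
    """One scene per (source, family) pair; segments get distinct shades."""
    if not annotations.domains:
        return []
    context = select_deposited(structure)
    flat = flatten(context)
    visible = tuple(range(len(flat)))
    cmap = _chain_color_map(flat)
    families: dict[tuple[str, str], list] = {}
    for seg in annotations.domains:
        families.setdefault((seg.source, seg.family_id), []).append(seg)
    scenes = []
    for (source, family_id), segments in sorted(families.items()):
        highlight: set[int] = set()
        colors = {i: faded(cmap[flat.label_asym_id[i]]) for i in visible}
        base = chain_palette(len(PALETTE) - 1)  # family base hue
        for k, seg in enumerate(segments):
            mask = [
                i for i in visible
                if _auth_base(flat.auth_asym_id[i]) == seg.chain
                and seg.start_seq <= flat.auth_seq[i] <= seg.end_seq
                and not flat.is_hetero[i]
            ]
            if not mask:
                logger.warning(
                    "domain %s/%s: segment %s %d-%d matches no residues; skipped",
                    source, family_id, seg.chain, seg.start_seq, seg.end_seq,
                )
                continue
            shade = _lerp_color(base, (255, 255, 255), 0.25 * (k % 3))
            for i in mask:
                highlight.add(i)
                colors[i] = shade
        qualifier = f"{source}_{family_id}"
        scenes.append(
            SceneSpec(
                scene_type="domain", qualifier=qualifier, structure=context, flat=flat,
                visible_atoms=visible, atom_colors=colors,
                atom_radii={i: DEFAULT_RADIUS for i in visible},
                highlight=frozenset(highlight), camera_front=_camera(flat, visible),
                views=_views_for("domain"),
                caption=CAPTIONS["domain"].format(
                    id=structure.entry_id, qualifier=f"{source} {family_id}"
                ),
            )
        )
    scenes.sort(key=lambda s: s.qualifier)
    return scenes


def build_ligand(structure: Structure, annotations: AnnotationSet, entity_id: str) -> SceneSpec:
    """A non-polymer entity plus whole residues within the 5 A shell."""
    entity = structure.entity(entity_id)
    if entity.entity_type != "non-polymer":
        raise SceneTypeError(
            f"entity {entity_id} is {entity.entity_type}, not a non-polymer ligand"
        )
    context = select_deposited(structure)
    flat = flatten(context)
    ligand_idx = np.flatnonzero(flat.entity_id == entity_id)
    if len(ligand_idx) == 0:
        raise SceneTypeError(f"no atoms found for ligand entity {entity_id}")
    dists = np.linalg.norm(
        flat.coords[:, None, :] - flat.coords[None, ligand_idx, :], axis=2
    ).min(axis=1)
    res_keys = _residue_keys(flat)
    env_residues = {
        tuple(res_keys[i])
        for i in np.flatnonzero(dists <= ENVIRONMENT_SHELL)
        if flat.entity_id[i] != entity_id
    }
    env_idx = [i for i in range(len(flat)) if tuple(res_keys[i]) in env_residues]
    visible = tuple(sorted(set(ligand_idx.tolist()) | set(env_idx)))
    cmap = _chain_color_map(flat)
    ligand_set = frozenset(ligand_idx.tolist())
    colors, radii = {}, {}
    for i in visible:
        if i in ligand_set:
            colors[i] = cmap[flat.label_asym_id[i]]
            radii[i] = LIGAND_BALL_RADIUS
        else:
            colors[i] = faded(cmap[flat.label_asym_id[i]])
            radii[i] = ENVIRONMENT_RADIUS
    comp = flat.comp_id[ligand_idx[0]]
    return SceneSpec(
        scene_type="ligand", qualifier=str(comp), structure=context, flat=flat,
        visible_atoms=visible, atom_colors=colors, atom_radii=radii,
        highlight=ligand_set, camera_front=_camera(flat, visible),
        views=_views_for("ligand"),
        caption=CAPTIONS["ligand"].format(id=structure.entry_id, qualifier=comp),
    )


def build_modres(structure: Structure, annotations: AnnotationSet) -> list[SceneSpec]:
    if not annotations.modres:
        return []
    context = preferred_context(structure, annotations)
    flat = flatten(context)
    visible = tuple(range(len(flat)))
    cmap = _chain_color_map(flat)
    scenes = []
    for record in sorted(annotations.modres, key=lambda r: r.comp_id):
        highlight: set[int] = set()
        for chain, seq in record.sites:
            hits = [
                i for i in visible
                if _auth_base(flat.auth_asym_id[i]) == chain
                and flat.auth_seq[i] == seq
                and flat.comp_id[i] == record.comp_id
            ]
            if not hits:
                logger.warning(
                    "modres %s: site %s %d not resolvable; skipped",
                    record.comp_id, chain, seq,
                )
            highlight.update(hits)
        colors = {
            i: ((230, 60, 60) if i in highlight else faded(cmap[flat.label_asym_id[i]]))
            for i in visible
        }
        scenes.append(
            SceneSpec(
                scene_type="modres", qualifier=record.comp_id, structure=context,
                flat=flat, visible_atoms=visible, atom_colors=colors,
                atom_radii={i: DEFAULT_RADIUS for i in visible},
                highlight=frozenset(highlight), camera_front=_camera(flat, visible),
                views=_views_for("modres"),
                caption=CAPTIONS["modres"].format(
                    id=structure.entry_id, qualifier=record.comp_id
                ),
            )
        )
    return scenes


def bfactor_applicable(structure: Structure) -> bool:
    """Putty only applies to X-ray structures; without a recorded method,
    fall back to requiring non-constant B-factors."""
    method = structure.exptl_method.upper()
    if method:
        return "X-RAY" in method
    flat = flatten(structure)
    return float(np.var(flat.b_factor)) > 0.0


def _polymer_trace(structure: Structure, flat: FlatAtoms) -> tuple[list[int], dict]:
    """Backbone trace atom indices for polymer chains plus residue grouping."""
    polymer_entities = {e.entity_id for e in structure.entities if e.entity_type == "polymer"}
    res_keys = _residue_keys(flat)
    groups: dict[tuple, list[int]] = {}
    for i in range(len(flat)):
        if flat.entity_id[i] in polymer_entities:
            groups.setdefault(tuple(res_keys[i]), []).append(i)
    trace = []
    for key, members in groups.items():
        pick = None
        for name in _TRACE_ATOM_NAMES:
            for i in members:
                if flat.atom_name[i] == name:
                    pick = i
                    break
            if pick is not None:
                break
        trace.append(pick if pick is not None else members[0])
    trace.sort()
    return trace, groups


def build_bfactor(structure: Structure) -> SceneSpec:
    context = select_deposited(structure)
    flat = flatten(context)
    trace, groups = _polymer_trace(context, flat)
    if not trace:
        raise SceneTypeError("no polymer residues for putty representation")
    res_keys = _residue_keys(flat)
    mean_b = {key: float(np.mean(flat.b_factor[members])) for key, members in groups.items()}
    values = list(mean_b.values())
    b_min, b_max = min(values), max(values)
    colors, radii = {}, {}
    for i in trace:
        b = mean_b[tuple(res_keys[i])]
        if b_max > b_min:
            t = (b - b_min) / (b_max - b_min)
        else:
            t = 0.5
        colors[i] = _lerp_color(PUTTY_LOW, PUTTY_HIGH, t)
        radii[i] = putty_radius(b, b_min, b_max)
    visible = tuple(trace)
    return SceneSpec(
        scene_type="bfactor", qualifier="", structure=context, flat=flat,
        visible_atoms=visible, atom_colors=colors, atom_radii=radii,
        highlight=frozenset(), camera_front=_camera(flat, visible),
        views=_views_for("bfactor"),
        caption=CAPTIONS["bfactor"].format(id=structure.entry_id),
    )


def build_validation(structure: Structure, annotations: AnnotationSet) -> SceneSpec:
    if not annotations.outliers:
        raise SceneTypeError("no residue-wise outlier data; validation scene skipped")
    context = select_deposited(structure)
    flat = flatten(context)
    visible = tuple(range(len(flat)))
    lookup = annotations.outlier_lookup()
    colors = {
        i: outlier_color(lookup.get((_auth_base(flat.auth_asym_id[i]), int(flat.auth_seq[i]))))
        for i in visible
    }
    return SceneSpec(
        scene_type="validation", qualifier="", structure=context, flat=flat,
        visible_atoms=visible, atom_colors=colors,
        atom_radii={i: DEFAULT_RADIUS for i in visible},
        highlight=frozenset(), camera_front=_camera(flat, visible),
        views=_views_for("validation"),
        caption=CAPTIONS["validation"].format(id=structure.entry_id),
    )


def build_plddt(structure: Structure) -> SceneSpec:
    context = select_deposited(structure)
    flat = flatten(context)
    visible = tuple(range(len(flat)))
    res_keys = _residue_keys(flat)
    groups: dict[tuple, list[int]] = {}
    for i in visible:
        groups.setdefault(tuple(res_keys[i]), []).append(i)
    colors = {}
    for key, members in groups.items():
        value = float(np.mean(flat.b_factor[members]))
        band = plddt_band(value)
        for i in members:
            colors[i] = PLDDT_COLORS[band]
    return SceneSpec(
        scene_type="plddt", qualifier="", structure=context, flat=flat,
        visible_atoms=visible, atom_colors=colors,
        atom_radii={i: DEFAULT_RADIUS for i in visible},
        highlight=frozenset(), camera_front=_camera(flat, visible),
        views=_views_for("plddt"),
        caption=CAPTIONS["plddt"].format(id=structure.entry_id),
    )


# ---------------------------------------------------------------------------
# Dispatch


def generate_scenes(
    structure: Structure,
    annotations: AnnotationSet,
    mode: str = "pdb",
    requested_types="all",
) -> list[SceneSpec]:
    """Build all applicable scenes for ``mode`` in deterministic order.

    Inapplicable types are silently skipped with a logged reason unless
    explicitly requested, in which case a :class:`SceneTypeError` is
    raised for types outside the mode's catalogue.
    """
    if mode not in MODES:
        raise SceneTypeError(f"unknown mode {mode!r}; expected one of {MODES}")
    applicable = MODE_TYPES[mode]
    if requested_types == "all":
        selected = applicable
    else:
        requested = set(requested_types)
        unknown = requested - set(ALL_TYPES)
        if unknown:
            raise SceneTypeError(f"unknown scene types: {sorted(unknown)}")
        outside = requested - set(applicable)
        if outside:
            raise SceneTypeError(
                f"scene types {sorted(outside)} not applicable to mode {mode!r}"
            )
        selected = tuple(t for t in applicable if t in requested)

    scenes: list[SceneSpec] = []
    for scene_type in selected:
        try:
            scenes.extend(_build_type(structure, annotations, scene_type))
        except SceneTypeError as exc:
            if requested_types != "all":
                raise
            logger.info("skipping %s: %s", scene_type, exc)
    return scenes


def _build_type(structure, annotations, scene_type) -> list[SceneSpec]:
    if scene_type == "entry":
        return [build_entry(structure)]
    if scene_type == "assembly":
        return [
            build_assembly(structure, asm.assembly_id)
            for asm in sorted(structure.assemblies, key=lambda a: a.assembly_id)
        ]
    if scene_type == "entity":
        eligible = sorted(
            (e for e in structure.entities if e.entity_type != "water"),
            key=lambda e: e.entity_id,
        )
        return [build_entity(structure, annotations, e.entity_id) for e in eligible]
    if scene_type == "domain":
        return build_domain(structure, annotations)
    if scene_type == "ligand":
        eligible = sorted(
            (e for e in structure.entities if e.entity_type == "non-polymer"),
            key=lambda e: e.entity_id,
        )
        return [build_ligand(structure, annotations, e.entity_id) for e in eligible]
    if scene_type == "modres":
        return build_modres(structure, annotations)
    if scene_type == "bfactor":
        if not bfactor_applicable(structure):
            raise SceneTypeError(
                "B-factor putty only applies to X-ray structures with usable B-factors"
            )
        return [build_bfactor(structure)]
    if scene_type == "validation":
        return [build_validation(structure, annotations)]
    if scene_type == "plddt":
        return [build_plddt(structure)]
    raise SceneTypeError(f"unknown scene type {scene_type!r}")
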