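"""Output artifacts: PNG files, caption JSON, state files, and summaries.

Filename grammar::

    {stem}_image-{width}x{height}.png
    stem = {id}_{type}[_{qualifier}][_{view}]

The qualifier appears only for multi-instance types (assembly id, entity
id, domain family, ligand/modres component code) and the view token only
for non-front views, so singleton front-view names match the published
``{id}_{type}_image-{W}x{H}.png`` shape exactly.  Qualifiers are
lower-cased with non-alphanumerics replaced by ``-``.

Alongside every rendered view two JSON files are written: a caption file
(``{stem}.caption.json``) and a state file (``{stem}.molj.json``).  The
state file uses this package's own documented schema (``schema_version``
1) sufficient to re-create the SceneSpec; it is *not* claimed to be
loadable by external viewers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .model import Structure
from .render import ImageBuffer
from .scenes import ALL_TYPES, SceneSpec

SCHEMA_VERSION = 1

_FILENAME_RE = re.compile(r"^(?P<stem>.+)_image-(?P<w>\d+)x(?P<h>\d+)\.png$")


@dataclass
class ImageRecord:
    stem: str
    scene_type: str
    qualifier: str
    view: str
    caption: str
    sizes: list[tuple[int, int]] = field(default_factory=list)
    files: list[str] = field(default_factory=list)


def sanitize_token(token: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", token.lower()).strip("-")


def image_stem(entry_id: str, scene_type: str, qualifier: str = "", view: str = "front") -> str:
    parts = [sanitize_token(entry_id), sanitize_token(scene_type)]
    if qualifier:
        parts.append(sanitize_token(qualifier))
    if view != "front":
        parts.append(sanitize_token(view))
    return "_".join(parts)


def image_filename(stem: str, width: int, height: int) -> str:
    """``("1tqn_bfactor", 800, 800)`` -> ``"1tqn_bfactor_image-800x800.png"``."""
    if not stem:
        raise ValueError("image filename stem must be non-empty")
    if width <= 0 or height <= 0:
        raise ValueError(f"image dimensions must be positive, got {width}x{height}")
    return f"{stem}_image-{width}x{height}.png"


def parse_image_filename(name: str) -> tuple[str, int, int]:
    m = _FILENAME_RE.match(name)
    if not m:
        raise ValueError(f"filename {name!r} does not match the image grammar")
    return m.group("stem"), int(m.group("w")), int(m.group("h"))


# ---------------------------------------------------------------------------
# State (scene) serialization


def scene_to_state(scene: SceneSpec, view: str = "front", source: str | None = None) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "entry_id": scene.structure.entry_id,
        "source": source,
        "view_label": scene.structure.view_label,
        "scene_type": scene.scene_type,
        "qualifier": scene.qualifier,
        "view": view,
        "views": list(scene.views),
        "caption": scene.caption,
        "camera_front": [[float(v) for v in row] for row in np.asarray(scene.camera_front)],
        "visible_atoms": list(scene.visible_atoms),
        "atom_colors": {str(i): list(c) for i, c in scene.atom_colors.items()},
        "atom_radii": {str(i): float(r) for i, r in scene.atom_radii.items()},
        "highlight": sorted(scene.highlight),
    }


def scene_from_state(state: dict, structure: Structure) -> SceneSpec:
    """Re-create a SceneSpec from a state dict plus its context structure."""
    if state.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported state schema_version {state.get('schema_version')!r}")
    return SceneSpec(
        scene_type=state["scene_type"],
        qualifier=state["qualifier"],
        structure=structure,
        visible_atoms=tuple(state["visible_atoms"]),
        atom_colors={int(i): tuple(c) for i, c in state["atom_colors"].items()},
        atom_radii={int(i): float(r) for i, r in state["atom_radii"].items()},
        highlight=frozenset(state["highlight"]),
        camera_front=np.array(state["camera_front"], dtype=float),
        views=tuple(state["views"]),
        caption=state["caption"],
    )


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Per-image artifact writing


def write_image_set(
    record: ImageRecord,
    images: list[ImageBuffer],
    scene: SceneSpec,
    outdir,
    source: str | None = None,
) -> ImageRecord:
    """Write PNGs (one per size), the caption JSON, and the state file.

    Returns a copy of ``record`` with ``files`` and ``sizes`` populated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    sizes: list[tuple[int, int]] = []
    for buf in images:
        name = image_filename(record.stem, buf.width, buf.height)
        buf.save_png(outdir / name)
        files.append(name)
        sizes.append((buf.width, buf.height))
    caption_name = f"{record.stem}.caption.json"
    _write_json(
        outdir / caption_name,
        {
            "schema_version": SCHEMA_VERSION,
            "caption": record.caption,
            "entry_id": scene.structure.entry_id,
            "scene_type": record.scene_type,
            "qualifier": record.qualifier,
            "view": record.view,
        },
    )
    files.append(caption_name)
    state_name = f"{record.stem}.molj.json"
    _write_json(outdir / state_name, scene_to_state(scene, view=record.view, source=source))
    files.append(state_name)
    return replace(record, files=files, sizes=sizes)


def write_summaries(entry_id: str, records: list[ImageRecord], outdir) -> tuple[Path, Path]:
    """Write ``{id}_filelist`` (stems, generation order) and ``{id}.json``.

    The JSON summary has one section per scene type (all types present,
    empty lists when unused), each entry carrying stem, qualifier, view,
    caption, and available sizes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eid = sanitize_token(entry_id)
    filelist_path = outdir / f"{eid}_filelist"
    filelist_path.write_text("".join(r.stem + "\n" for r in records))
    sections: dict[str, list] = {t: [] for t in ALL_TYPES}
    for r in records:
        sections[r.scene_type].append(
            {
                "stem": r.stem,
                "qualifier": r.qualifier,
                "view": r.view,
                "caption": r.caption,
                "sizes": [list(s) for s in r.sizes],
            }
        )
    json_path = outdir / f"{eid}.json"
    _write_json(
        json_path,
        {"schema_version": SCHEMA_VERSION, "entry_id": eid, "sections": sections},
    )
    return filelist_path, json_path
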