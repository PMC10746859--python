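"""mmCIF reading, minimal writing, and biological assembly expansion.

Only the categories needed downstream are read: ``atom_site``, ``entity``,
``pdbx_struct_assembly_gen``, ``pdbx_struct_oper_list``, plus ``entry`` and
``exptl`` for the header.  Everything else in the file is ignored.  Binary
CIF is rejected outright rather than mis-parsed.

Alternate locations are collapsed to a single conformer per atom name:
highest occupancy wins, ties broken by lexicographically smallest altloc id.
"""

from __future__ import annotations

import gzip
import io
import itertools
import re
from pathlib import Path

import numpy as np
from biotite.structure.io.pdbx import CIFFile

from .errors import (
    EmptyStructureError,
    MalformedCIFError,
    NoCoordinatesError,
    UnknownAssemblyError,
    UnsupportedFormatError,
)
from .model import AssemblyDef, Atom, Chain, Entity, Residue, Structure

GZIP_MAGIC = b"\x1f\x8b"

_ATOM_SITE_COLUMNS = [
    "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
    "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
    "pdbx_PDB_ins_code", "Cartn_x", "Cartn_y", "Cartn_z", "occupancy",
    "B_iso_or_equiv", "auth_seq_id", "auth_asym_id", "pdbx_PDB_model_num",
]


def read_structure(path) -> Structure:
    """Parse an mmCIF file (``.cif`` or ``.cif.gz``) into a :class:`Structure`.

    GZIP is detected by magic bytes, not the extension.  ``.bcif`` input
    raises :class:`UnsupportedFormatError`; files without an ``atom_site``
    category raise :class:`NoCoordinatesError`; unparsable text raises
    :class:`MalformedCIFError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    suffixes = [s.lower() for s in path.suffixes]
    if ".bcif" in suffixes:
        raise UnsupportedFormatError(
            f"{path.name}: binary CIF (.bcif) is an unsupported format; "
            "convert to .cif first"
        )
    raw = path.read_bytes()
    if raw[:2] == GZIP_MAGIC:
        raw = gzip.decompress(raw)
    if raw[:2] == b"BC" or b"\x00" in raw[:256]:
        raise UnsupportedFormatError(f"{path.name}: binary content is not mmCIF text")
    try:
        text = raw.decode("utf-8")
        cif = CIFFile.read(io.StringIO(text))
        block = cif.block
        categories = {name: block[name] for name in block.keys()}
    except Exception as exc:
        raise MalformedCIFError(f"{path.name}: malformed CIF syntax: {exc}") from exc
    if "atom_site" not in categories:
        raise NoCoordinatesError(f"{path.name}: no atom_site category (no coordinates)")
    return _build_structure(path, categories)


def _col(category, name, n, default=None):
    """Fetch a column as a list of strings; masked values become ''."""
    if name not in category:
        return [default] * n
    return [str(v) for v in category[name].as_array(str, masked_value="")]


def _build_structure(path: Path, categories: dict) -> Structure:
    atom_site = categories["atom_site"]
    n = atom_site.row_count
    group = _col(atom_site, "group_PDB", n, "ATOM")
    element = _col(atom_site, "type_symbol", n, "C")
    atom_name = _col(atom_site, "label_atom_id", n, "")
    alt_id = _col(atom_site, "label_alt_id", n, "")
    comp_id = _col(atom_site, "label_comp_id", n, "UNK")
    label_asym = _col(atom_site, "label_asym_id", n, "A")
    entity_id = _col(atom_site, "label_entity_id", n, "1")
    label_seq = _col(atom_site, "label_seq_id", n, "")
    ins_code = _col(atom_site, "pdbx_PDB_ins_code", n, "")
    occupancy = _col(atom_site, "occupancy", n, "1.0")
    b_iso = _col(atom_site, "B_iso_or_equiv", n, "0.0")
    auth_seq = _col(atom_site, "auth_seq_id", n, "")
    auth_asym = _col(atom_site, "auth_asym_id", n, "")
    model_num = _col(atom_site, "pdbx_PDB_model_num", n, "1")
    try:
        x = atom_site["Cartn_x"].as_array(float)
        y = atom_site["Cartn_y"].as_array(float)
        z = atom_site["Cartn_z"].as_array(float)
    except KeyError as exc:
        raise NoCoordinatesError(f"{path.name}: atom_site lacks Cartn_* columns") from exc
    except Exception as exc:
        raise MalformedCIFError(f"{path.name}: non-numeric coordinates: {exc}") from exc

    # Group rows by model -> chain -> residue, resolving altlocs as we go.
    # models[model][chain_key] -> {"meta": ..., "residues": ordered dict}
    models: dict[int, dict] = {}
    for i in range(n):
        mnum = int(model_num[i] or 1)
        chains = models.setdefault(mnum, {})
        ckey = label_asym[i] or "A"
        chain = chains.setdefault(
            ckey,
            {
                "auth_asym_id": auth_asym[i] or ckey,
                "entity_id": entity_id[i] or "1",
                "residues": {},
            },
        )
        lseq = int(label_seq[i]) if label_seq[i] not in ("", ".", "?") else None
        aseq_raw = auth_seq[i]
        aseq = int(aseq_raw) if aseq_raw not in ("", ".", "?") else (lseq or 0)
        rkey = (lseq if lseq is not None else aseq, aseq, ins_code[i] or "")
        residue = chain["residues"].setdefault(
            rkey,
            {"comp_id": comp_id[i], "label_seq": lseq, "auth_seq": aseq,
             "ins_code": ins_code[i] or "", "atoms": {}},
        )
        occ = float(occupancy[i]) if occupancy[i] not in ("", ".", "?") else 1.0
        alt = alt_id[i] if alt_id[i] not in (".", "?") else ""
        atom = Atom(
            name=atom_name[i],
            element=element[i],
            pos=np.array([x[i], y[i], z[i]]),
            b_factor=float(b_iso[i]) if b_iso[i] not in ("", ".", "?") else 0.0,
            occupancy=min(max(occ, 0.0), 1.0),
            is_hetero=(group[i] == "HETATM"),
        )
        existing = residue["atoms"].get(atom_name[i])
        if existing is None:
            residue["atoms"][atom_name[i]] = (atom, alt)
        else:
            prev_atom, prev_alt = existing
            if (atom.occupancy, _alt_rank(alt)) > (prev_atom.occupancy, _alt_rank(prev_alt)):
                residue["atoms"][atom_name[i]] = (atom, alt)

    model_list = []
    for mnum in sorted(models):
        chain_objs = []
        for ckey, cdata in models[mnum].items():
            residues = [
                Residue(
                    comp_id=r["comp_id"], auth_seq=r["auth_seq"],
                    label_seq=r["label_seq"], ins_code=r["ins_code"],
                    atoms=[atom for atom, _ in r["atoms"].values()],
                )
                for r in cdata["residues"].values()
            ]
            chain_objs.append(
                Chain(
                    label_asym_id=ckey,
                    auth_asym_id=cdata["auth_asym_id"],
                    entity_id=cdata["entity_id"],
                    residues=residues,
                )
            )
        model_list.append((mnum, chain_objs))

    entities = _parse_entities(categories, model_list)
    assemblies = _parse_assemblies(categories)
    entry_id = path.name.split(".")[0]
    if "entry" in categories and "id" in categories["entry"]:
        entry_id = str(categories["entry"]["id"].as_array(str)[0]).lower()
    exptl_method = ""
    if "exptl" in categories and "method" in categories["exptl"]:
        exptl_method = str(categories["exptl"]["method"].as_array(str)[0])
    return Structure(
        entry_id=entry_id,
        models=model_list,
        entities=entities,
        assemblies=assemblies,
        exptl_method=exptl_method,
        view_label="deposited",
    )


def _alt_rank(alt: str):
    # Higher rank wins; lexicographically *smaller* altloc wins ties, so
    # invert the ordering via a negative-codepoint tuple.
    return tuple(-ord(c) for c in alt) if alt else (1,)


def _parse_entities(categories, model_list) -> list[Entity]:
    entities = []
    if "entity" in categories:
        cat = categories["entity"]
        n = cat.row_count
        ids = _col(cat, "id", n)
        types = _col(cat, "type", n, "polymer")
        descs = _col(cat, "pdbx_description", n, "")
        for eid, etype, desc in zip(ids, types, descs):
            etype = etype if etype in ("polymer", "non-polymer", "branched", "water") else "polymer"
            entities.append(Entity(entity_id=eid, entity_type=etype, description=desc or ""))
    known = {e.entity_id for e in entities}
    # Synthesize entities for chains referencing undeclared entity ids.
    for _, chains in model_list:
        for chain in chains:
            if chain.entity_id in known:
                continue
            comps = {r.comp_id for r in chain.residues}
            if comps <= {"HOH", "DOD", "WAT"}:
                etype = "water"
            elif all(a.is_hetero for r in chain.residues for a in r.atoms):
                etype = "non-polymer"
            else:
                etype = "polymer"
            entities.append(Entity(entity_id=chain.entity_id, entity_type=etype))
            known.add(chain.entity_id)
    return entities


def _expand_ids(token_list: str) -> list[str]:
    """Expand '1,3,5-7' to ['1', '3', '5', '6', '7']."""
    out: list[str] = []
    for tok in token_list.split(","):
        tok = tok.strip()
        if not tok:
            continue
        m = re.fullmatch(r"(\d+)-(\d+)", tok)
        if m:
            out.extend(str(i) for i in range(int(m.group(1)), int(m.group(2)) + 1))
        else:
            out.append(tok)
    return out


def parse_oper_expression(expr: str) -> list[tuple[str, ...]]:
    """Parse a pdbx oper_expression into operator-id sequences.

    ``'1,2'`` -> ``[('1',), ('2',)]``; ``'(1-2)(3)'`` -> the cartesian
    product ``[('1','3'), ('2','3')]`` where each sequence composes
    left-to-right as a matrix product.
    """
    expr = expr.strip().strip("'\"")
    if expr.startswith("("):
        groups = [_expand_ids(m) for m in re.findall(r"\(([^()]*)\)", expr)]
    else:
        groups = [_expand_ids(expr)]
    return [tuple(combo) for combo in itertools.product(*groups)]


def _parse_assemblies(categories) -> list[AssemblyDef]:
    if "pdbx_struct_assembly_gen" not in categories or "pdbx_struct_oper_list" not in categories:
        return []
    oper_cat = categories["pdbx_struct_oper_list"]
    n_op = oper_cat.row_count
    op_ids = _col(oper_cat, "id", n_op)
    operators: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(n_op):
        rot = np.array(
            [
                [float(_col(oper_cat, f"matrix[{r}][{c}]", n_op, "0")[i] or 0)
                 for c in (1, 2, 3)]
                for r in (1, 2, 3)
            ]
        )
        trans = np.array(
            [float(_col(oper_cat, f"vector[{r}]", n_op, "0")[i] or 0) for r in (1, 2, 3)]
        )
        operators[op_ids[i]] = (rot, trans)

    gen_cat = categories["pdbx_struct_assembly_gen"]
    n_gen = gen_cat.row_count
    asm_ids = _col(gen_cat, "assembly_id", n_gen)
    exprs = _col(gen_cat, "oper_expression", n_gen)
    asym_lists = _col(gen_cat, "asym_id_list", n_gen)
    grouped: dict[str, list] = {}
    for aid, expr, asyms in zip(asm_ids, exprs, asym_lists):
        chain_set = tuple(s.strip() for s in asyms.split(",") if s.strip())
        grouped.setdefault(aid, []).append((chain_set, parse_oper_expression(expr)))
    return [
        AssemblyDef(assembly_id=aid, operator_expressions=expr_list, operators=operators)
        for aid, expr_list in grouped.items()
    ]


# ---------------------------------------------------------------------------
# Assembly expansion


def _compose(operators, sequence) -> tuple[np.ndarray, np.ndarray]:
    """Compose an operator-id sequence left-to-right into (R, t)."""
    mat = np.eye(4)
    for op_id in sequence:
        rot, trans = operators[op_id]
        m = np.eye(4)
        m[:3, :3] = rot
        m[:3, 3] = trans
        mat = mat @ m
    return mat[:3, :3], mat[:3, 3]


def expand_assembly(structure: Structure, assembly_id: str) -> Structure:
    """Return a new Structure with the assembly's operator-transformed chains.

    Only model 1 is expanded (ensembles and assemblies are not combined);
    chain copies are renamed ``{label_asym_id}-{i}`` with a 1-based operator
    chain index.
    """
    try:
        assembly = structure.assembly(assembly_id)
    except KeyError:
        known = [a.assembly_id for a in structure.assemblies]
        raise UnknownAssemblyError(
            f"unknown assembly {assembly_id!r}; structure defines {known}"
        ) from None
    model_num, chains = structure.models[0]
    by_label = {c.label_asym_id: c for c in chains}
    new_chains: list[Chain] = []
    for chain_set, sequences in assembly.operator_expressions:
        for label in chain_set:
            source = by_label.get(label)
            if source is None:
                continue
            for idx, seq in enumerate(sequences, start=1):
                rot, trans = _compose(assembly.operators, seq)
                new_chains.append(_transform_chain(source, rot, trans, idx))
    return Structure(
        entry_id=structure.entry_id,
        models=[(model_num, new_chains)],
        entities=structure.entities,
        assemblies=structure.assemblies,
        exptl_method=structure.exptl_method,
        view_label=f"assembly-{assembly_id}",
    )


def _transform_chain(chain: Chain, rot: np.ndarray, trans: np.ndarray, copy_index: int) -> Chain:
    residues = [
        Residue(
            comp_id=r.comp_id, auth_seq=r.auth_seq, label_seq=r.label_seq,
            ins_code=r.ins_code,
            atoms=[
                Atom(
                    name=a.name, element=a.element, pos=rot @ a.pos + trans,
                    b_factor=a.b_factor, occupancy=a.occupancy, is_hetero=a.is_hetero,
                )
                for a in r.atoms
            ],
        )
        for r in chain.residues
    ]
    return Chain(
        label_asym_id=f"{chain.label_asym_id}-{copy_index}",
        auth_asym_id=f"{chain.auth_asym_id}-{copy_index}",
        entity_id=chain.entity_id,
        residues=residues,
    )


def select_deposited(structure: Structure) -> Structure:
    """Identity passthrough that labels the view 'deposited'; keeps all models."""
    if not structure.models:
        raise EmptyStructureError(f"structure {structure.entry_id!r} has no models")
    return structure.with_view_label("deposited")


# ---------------------------------------------------------------------------
# Minimal mmCIF writer — supports the fixture generator and round-trip tests.


def to_mmcif_text(structure: Structure) -> str:
    """Serialize a Structure into mmCIF text covering the categories we read."""
    lines = [f"data_{structure.entry_id.upper()}", "#"]
    lines.append(f"_entry.id {structure.entry_id.upper()}")
    if structure.exptl_method:
        lines.append(f"_exptl.method '{structure.exptl_method}'")
    lines.append("#")
    if structure.entities:
        lines += ["loop_", "_entity.id", "_entity.type", "_entity.pdbx_description"]
        for ent in structure.entities:
            desc = ent.description or "?"
            if " " in desc:
                desc = f"'{desc}'"
            lines.append(f"{ent.entity_id} {ent.entity_type} {desc}")
        lines.append("#")
    for asm in structure.assemblies:
        lines += [
            "loop_",
            "_pdbx_struct_assembly_gen.assembly_id",
            "_pdbx_struct_assembly_gen.oper_expression",
            "_pdbx_struct_assembly_gen.asym_id_list",
        ]
        for chain_set, sequences in asm.operator_expressions:
            expr = _format_oper_expression(sequences)
            lines.append(f"{asm.assembly_id} '{expr}' {','.join(chain_set)}")
        lines.append("#")
    if structure.assemblies:
        operators = structure.assemblies[0].operators
        header = ["loop_", "_pdbx_struct_oper_list.id"]
        header += [f"_pdbx_struct_oper_list.matrix[{r}][{c}]" for r in (1, 2, 3) for c in (1, 2, 3)]
        header += [f"_pdbx_struct_oper_list.vector[{r}]" for r in (1, 2, 3)]
        lines += header
        for op_id, (rot, trans) in operators.items():
            vals = [f"{v:.6f}" for v in rot.ravel()] + [f"{v:.6f}" for v in trans]
            lines.append(" ".join([op_id] + vals))
        lines.append("#")
    lines += ["loop_"] + [f"_atom_site.{c}" for c in _ATOM_SITE_COLUMNS]
    serial = 0
    for model_num, chains in structure.models:
        for chain in chains:
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    lines.append(" ".join([
                        "HETATM" if atom.is_hetero else "ATOM",
                        str(serial), atom.element, atom.name, ".",
                        res.comp_id, chain.label_asym_id, chain.entity_id,
                        str(res.label_seq) if res.label_seq is not None else ".",
                        res.ins_code or "?",
                        f"{atom.pos[0]:.3f}", f"{atom.pos[1]:.3f}", f"{atom.pos[2]:.3f}",
                        f"{atom.occupancy:.2f}", f"{atom.b_factor:.2f}",
                        str(res.auth_seq), chain.auth_asym_id, str(model_num),
                    ]))
    lines.append("#")
    return "\n".join(lines) + "\n"


def _format_oper_expression(sequences: list[tuple[str, ...]]) -> str:
    if all(len(s) == 1 for s in sequences):
        return ",".join(s[0] for s in sequences)
    lengths = {len(s) for s in sequences}
    if len(lengths) == 1:
        k = lengths.pop()
        groups = []
        for pos in range(k):
            seen: list[str] = []
            for s in sequences:
                if s[pos] not in seen:
                    seen.append(s[pos])
            groups.append(seen)
        if list(itertools.product(*groups)) == [tuple(s) for s in sequences]:
            return "".join("(" + ",".join(g) + ")" for g in groups)
    raise ValueError("cannot serialize irregular operator expression")
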