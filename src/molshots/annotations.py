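"""Optional per-entry annotation data.

Annotations add names, the preferred assembly, modified-residue sites,
domain segments, and per-residue quality outlier counts on top of the
coordinates.  They are loaded from a single offline JSON file whose
sections mirror the public API payload shapes (see
``schema/annotations.schema.json``), or optionally fetched live by the
network adapter.  Loading is lenient by design: unknown keys are ignored
and missing sections yield empty collections.
"""

from __future__ import annotations

import json
import logging
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .errors import AnnotationError

logger = logging.getLogger(__name__)

DOMAIN_SOURCES = ("CATH", "SCOP", "Pfam", "Rfam")

SECTION_KEYS = ("molecules", "summary", "modified_residues", "mappings", "validation")

# Endpoint path templates, relative to the API base URL.
ENDPOINTS = {
    "molecules": ["/pdb/entry/molecules/{id}"],
    "summary": ["/pdb/entry/summary/{id}"],
    "modified_residues": ["/pdb/entry/modified_AA_or_NA/{id}"],
    "mappings": ["/mappings/{id}", "/nucleic_mappings/{id}"],
    "validation": ["/validation/residuewise_outlier_summary/entry/{id}"],
}


@dataclass(frozen=True)
class DomainSegment:
    source: str  # CATH | SCOP | Pfam | Rfam
    family_id: str
    chain: str  # auth_asym_id
    start_seq: int
    end_seq: int  # inclusive

    def __post_init__(self) -> None:
        if self.source not in DOMAIN_SOURCES:
            raise ValueError(f"domain source must be one of {DOMAIN_SOURCES}")
        if self.start_seq > self.end_seq:
            raise ValueError(f"segment start {self.start_seq} > end {self.end_seq}")


@dataclass(frozen=True)
class ModifiedResidueRecord:
    comp_id: str
    sites: tuple[tuple[str, int], ...]  # (auth chain, auth_seq)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError(f"modified residue {self.comp_id} has no sites")


@dataclass(frozen=True)
class ResidueOutlierCount:
    chain: str
    auth_seq: int
    outlier_count: int

    def __post_init__(self) -> None:
        if self.outlier_count < 0:
            raise ValueError("outlier_count must be >= 0")


@dataclass
class AnnotationSet:
    entity_names: dict[str, str] = field(default_factory=dict)
    preferred_assembly_id: Optional[str] = None
    domains: list[DomainSegment] = field(default_factory=list)
    modres: list[ModifiedResidueRecord] = field(default_factory=list)
    outliers: list[ResidueOutlierCount] = field(default_factory=list)

    def outlier_lookup(self) -> dict[tuple[str, int], int]:
        return {(o.chain, o.auth_seq): o.outlier_count for o in self.outliers}


# ---------------------------------------------------------------------------
# Section parsers.  Each accepts the raw (already entry-unwrapped) payload
# and never fails on partial data.


_NO_UNWRAP_KEYS = set(DOMAIN_SOURCES) | {"molecules", "assemblies", "chains", "models", "residues"}


def _unwrap(payload, entry_id: Optional[str] = None):
    """Strip the '{entry id: ...}' wrapper the API puts around payloads."""
    if isinstance(payload, dict) and len(payload) == 1:
        (key,), (value,) = zip(*payload.items())
        if key in _NO_UNWRAP_KEYS:
            return payload
        if entry_id is None or key.lower() == entry_id.lower():
            if isinstance(value, (dict, list)):
                return value
    return payload


def _parse_molecules(payload) -> dict[str, str]:
    names: dict[str, str] = {}
    if not isinstance(payload, list):
        return names
    for mol in payload:
        if not isinstance(mol, dict) or "entity_id" not in mol:
            continue
        name = mol.get("molecule_name") or []
        if isinstance(name, list):
            name = name[0] if name else ""
        names[str(mol["entity_id"])] = str(name)
    return names


def _parse_summary(payload) -> Optional[str]:
    if not isinstance(payload, list):
        return None
    for record in payload:
        for asm in record.get("assemblies", []) if isinstance(record, dict) else []:
            if asm.get("preferred") and "assembly_id" in asm:
                return str(asm["assembly_id"])
    return None


def _parse_modified_residues(payload) -> list[ModifiedResidueRecord]:
    if not isinstance(payload, list):
        return []
    sites: dict[str, list[tuple[str, int]]] = {}
    for rec in payload:
        if not isinstance(rec, dict):
            continue
        comp = rec.get("chem_comp_id")
        chain = rec.get("auth_asym_id") or rec.get("chain_id")
        seq = rec.get("author_residue_number")
        if comp is None or chain is None or seq is None:
            continue
        site = (str(chain), int(seq))
        if site not in sites.setdefault(str(comp), []):
            sites[str(comp)].append(site)
    return [
        ModifiedResidueRecord(comp_id=comp, sites=tuple(site_list))
        for comp, site_list in sorted(sites.items())
    ]


def _parse_mappings(payload) -> list[DomainSegment]:
    segments: list[DomainSegment] = []
    if not isinstance(payload, dict):
        return segments
    for source in DOMAIN_SOURCES:
        families = payload.get(source) or {}
        if not isinstance(families, dict):
            continue
        for family_id in sorted(families):
            body = families[family_id]
            mappings = body.get("mappings", []) if isinstance(body, dict) else []
            for seg in mappings:
                if not isinstance(seg, dict):
                    continue
                chain = seg.get("chain_id") or seg.get("struct_asym_id")
                start = (seg.get("start") or {}).get("author_residue_number")
                end = (seg.get("end") or {}).get("author_residue_number")
                if chain is None or start is None or end is None:
                    continue
                try:
                    segments.append(
                        DomainSegment(
                            source=source, family_id=str(family_id), chain=str(chain),
                            start_seq=int(start), end_seq=int(end),
                        )
                    )
                except ValueError as exc:
                    logger.warning("skipping invalid domain segment %s: %s", seg, exc)
    return segments


def _parse_validation(payload) -> list[ResidueOutlierCount]:
    out: list[ResidueOutlierCount] = []
    if not isinstance(payload, dict):
        return out
    for mol in payload.get("molecules", []):
        for chain in mol.get("chains", []) if isinstance(mol, dict) else []:
            chain_id = chain.get("chain_id")
            if chain_id is None:
                continue
            for model in chain.get("models", []):
                for res in model.get("residues", []) if isinstance(model, dict) else []:
                    seq = res.get("author_residue_number")
                    count = res.get("outlier_count", res.get("outlier_types_count"))
                    if seq is None or count is None:
                        continue
                    out.append(
                        ResidueOutlierCount(
                            chain=str(chain_id), auth_seq=int(seq),
                            outlier_count=int(count),
                        )
                    )
    return out


def _parse_sections(sections: dict, entry_id: Optional[str] = None) -> AnnotationSet:
    ann = AnnotationSet()
    ann.entity_names = _parse_molecules(_unwrap(sections.get("molecules", []), entry_id))
    ann.preferred_assembly_id = _parse_summary(_unwrap(sections.get("summary", []), entry_id))
    ann.modres = _parse_modified_residues(
        _unwrap(sections.get("modified_residues", []), entry_id)
    )
    ann.domains = _parse_mappings(_unwrap(sections.get("mappings", {}), entry_id))
    ann.outliers = _parse_validation(_unwrap(sections.get("validation", {}), entry_id))
    return ann


def load_annotations(path) -> AnnotationSet:
    """Load the offline annotation JSON file.

    The file is one JSON object with optional keys ``molecules``,
    ``summary``, ``modified_residues``, ``mappings``, ``validation``, each
    holding the corresponding API-shaped payload.  Unknown keys are
    ignored; missing sections yield empty collections.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise AnnotationError(f"cannot read annotation file {path}: {exc}") from exc
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise AnnotationError(f"{path}: top-level annotation value must be an object")
    return _parse_sections(data)


def save_annotations(ann: AnnotationSet, path, entry_id: str = "entry") -> Path:
    """Write an AnnotationSet back into the offline JSON schema."""
    eid = entry_id.lower()
    families: dict[str, dict] = {}
    for seg in ann.domains:
        fam = families.setdefault(seg.source, {}).setdefault(seg.family_id, {"mappings": []})
        fam["mappings"].append(
            {
                "chain_id": seg.chain,
                "start": {"author_residue_number": seg.start_seq},
                "end": {"author_residue_number": seg.end_seq},
            }
        )
    by_chain: dict[str, list] = {}
    for o in ann.outliers:
        by_chain.setdefault(o.chain, []).append(
            {"author_residue_number": o.auth_seq, "outlier_count": o.outlier_count}
        )
    payload = {
        "molecules": {
            eid: [
                {"entity_id": entity_id, "molecule_name": [name]}
                for entity_id, name in ann.entity_names.items()
            ]
        },
        "summary": {
            eid: [
                {
                    "assemblies": (
                        [{"assembly_id": ann.preferred_assembly_id, "preferred": True}]
                        if ann.preferred_assembly_id is not None
                        else []
                    )
                }
            ]
        },
        "modified_residues": {
            eid: [
                {
                    "chem_comp_id": rec.comp_id,
                    "auth_asym_id": chain,
                    "chain_id": chain,
                    "author_residue_number": seq,
                }
                for rec in ann.modres
                for chain, seq in rec.sites
            ]
        },
        "mappings": {eid: families},
        "validation": {
            eid: {
                "molecules": [
                    {
                        "chains": [
                            {"chain_id": chain, "models": [{"model_id": 1, "residues": residues}]}
                            for chain, residues in sorted(by_chain.items())
                        ]
                    }
                ]
            }
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Live network adapter (optional; disabled by default, untested in CI).


def _default_opener(url: str):
    with urllib.request.urlopen(url, timeout=30) as resp:
        return json.loads(resp.read().decode("utf-8"))


def fetch_annotations(
    api_base_url: str,
    entry_id: str,
    enabled: bool = False,
    opener: Optional[Callable[[str], object]] = None,
) -> AnnotationSet:
    """Fetch the five annotation sections from an API base URL.

    Disabled by default (mirrors ``--no-api``): returns an empty
    AnnotationSet without any network activity.  A failed endpoint degrades
    to an empty section with a logged warning; only total connection
    failure (every endpoint unreachable) raises.
    """
    if not enabled:
        return AnnotationSet()
    opener = opener or _default_opener
    sections: dict[str, object] = {}
    attempts = 0
    connection_failures = 0
    base = api_base_url.rstrip("/")
    for section, paths in ENDPOINTS.items():
        merged: dict = {}
        for path in paths:
            url = base + path.format(id=entry_id.lower())
            attempts += 1
            try:
                payload = _unwrap(opener(url), entry_id)
                if isinstance(payload, dict):
                    merged.update(payload)
                elif isinstance(payload, list):
                    merged = payload  # list payloads are not merged across paths
            except (urllib.error.URLError, ConnectionError, OSError) as exc:
                connection_failures += 1
                logger.warning("endpoint %s unreachable: %s", url, exc)
            except Exception as exc:
                logger.warning("endpoint %s failed: %s", url, exc)
        sections[section] = {entry_id.lower(): merged}
    if attempts > 0 and connection_failures == attempts:
        raise ConnectionError(f"all annotation endpoints unreachable under {api_base_url}")
    return _parse_sections(sections, entry_id)
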