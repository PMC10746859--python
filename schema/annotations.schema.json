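{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "molshots/annotations.schema.json",
  "title": "molshots offline annotation file",
  "description": "One JSON object bundling the five optional annotation sections. Each section holds the corresponding public-API-shaped payload, optionally wrapped in a single '{entry id: ...}' key as the live API returns it. Unknown keys anywhere are ignored; missing sections yield empty collections.",
  "type": "object",
  "properties": {
    "molecules": {
      "description": "Entity names. Payload: list of {entity_id, molecule_name: [string]}.",
      "type": ["object", "array"]
    },
    "summary": {
      "description": "Preferred assembly. Payload: list of {assemblies: [{assembly_id, preferred: bool}]}.",
      "type": ["object", "array"]
    },
    "modified_residues": {
      "description": "Modified residue sites. Payload: list of {chem_comp_id, auth_asym_id|chain_id, author_residue_number}.",
      "type": ["object", "array"]
    },
    "mappings": {
      "description": "Domain segments. Payload: {CATH|SCOP|Pfam|Rfam: {family_id: {mappings: [{chain_id, start: {author_residue_number}, end: {author_residue_number}}]}}}.",
      "type": "object"
    },
    "validation": {
      "description": "Per-residue outlier counts. Payload: {molecules: [{chains: [{chain_id, models: [{residues: [{author_residue_number, outlier_count}]}]}]}]}.",
      "type": "object"
    }
  },
  "additionalProperties": true
}
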