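# molshots

Browserless, fully offline generation of standardized macromolecular
structure images from mmCIF files. For a given entry the tool builds up to
nine predefined scene types across two modes, orients each scene with a
deterministic PCA-based canonical camera ("laying the structure flat
against the screen"), rasterizes it with a built-in z-buffered software
renderer, and writes for every image a PNG ladder, a caption JSON, and a
reloadable state file, plus two per-entry summary files.

| mode      | type       | content |
|-----------|------------|---------|
| pdb       | entry      | complete deposited structure, colored by chain/entity (all models for ensembles) |
| pdb       | assembly   | each assembly listed in the mmCIF, expanded and colored by chain |
| pdb       | entity     | preferred assembly with one entity highlighted (water excluded) |
| pdb       | domain     | CATH/SCOP/Pfam/Rfam domain segments highlighted |
| pdb       | ligand     | each non-polymer entity and its 5 Å surroundings |
| pdb       | modres     | preferred assembly with all instances of one modified-residue type |
| pdb       | bfactor    | putty representation sized/colored by B-factor (X-ray only) |
| pdb       | validation | per-residue quality-outlier coloring |
| alphafold | plddt      | per-residue confidence (pLDDT) band coloring |

Everything runs offline: no network access is ever required. A synthetic
fixture generator produces mmCIF + annotation inputs that exercise every
scene type. Live retrieval of coordinates and annotations exists as an
optional adapter (`--api`) but is disabled by default.

## CLI

```sh
# Generate synthetic inputs (no downloads needed):
molshots make-fixture --outdir work --entry-id 1tqn

# Render every applicable image type:
molshots render 1tqn --input work/1tqn.cif --annotations work/1tqn_annotations.json \
    --no-api --outdir work/out

# Select types/views, custom sizes, no axis arrows:
molshots render 1tqn --input work/1tqn.cif --no-api --type entry,bfactor \
    --view front --no-axes --size 800x800 --size 200x200 --outdir work/out
```

Key flags: `--input` (local `.cif`/`.cif.gz`; GZIP is detected by magic
bytes), `--annotations` (offline JSON, schema in
`schema/annotations.schema.json`), `--type`, `--view front|side|top|all`,
`--no-axes`, `--no-api`/`--api` + `--api-url`, `--size WxH` (repeatable,
largest first; default ladder 1600/800/200/100), `--mode pdb|alphafold`,
`--outdir`. Binary CIF (`.bcif`) is rejected with a clear error.

## Outputs

For each rendered view `{id}_{type}[_{qualifier}][_{view}]`:

* `{stem}_image-{W}x{H}.png` — one per size; smaller sizes are
  box-downsampled from the largest render;
* `{stem}.caption.json` — caption text and scene metadata;
* `{stem}.molj.json` — a versioned state file (own documented schema)
  sufficient to re-create the scene via `molshots.outputs.scene_from_state`.

Per entry: `{id}_filelist` (stems, generation order) and `{id}.json`
(records grouped into sections by image type). Identical inputs produce
byte-identical outputs.

## Library

```python
from molshots import (read_structure, load_annotations, generate_scenes,
                      rasterize, RenderSettings)

structure = read_structure("1tqn.cif")
annotations = load_annotations("1tqn_annotations.json")
scenes = generate_scenes(structure, annotations, mode="pdb")
image = rasterize(scenes[0], "front", RenderSettings())
image.save_png("entry.png")
```

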