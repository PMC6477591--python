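"""Render one imaging animal per arm to TIFF tiles plus a manifest.

Writes results/tiles/ with two 16-bit TIFFs per subsection and a JSON
manifest carrying the planted ground truth for later comparison.
"""

import json
from pathlib import Path

from nephroshield.synthetic_data import TileSpec, default_design, generate_study_images
from nephroshield.tiles import write_tile

SEED = 20240
OUT = Path(__file__).resolve().parents[1] / "results" / "tiles"


def main() -> None:
    design = default_design(SEED)
    design.image_n_per_arm = 1
    manifest = []
    for animal_id, arm, tiles in generate_study_images(design, TileSpec()):
        for tile, truth in tiles:
            dapi, gh2ax = write_tile(tile, OUT)
            manifest.append(
                {
                    "animal_id": animal_id,
                    "arm": arm,
                    "dapi": dapi.name,
                    "gh2ax": gh2ax.name,
                    "compartment": tile.compartment,
                    "structure": tile.structure,
                    "n_nuclei": len(truth.nuclei),
                    "n_positive": truth.n_positive,
                }
            )
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"wrote {len(manifest)} tiles to {OUT}")


if __name__ == "__main__":
    main()
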