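"""Quantify percent-positive nuclei for the tiles written by 01.

Reads results/tiles/, applies the subsection gate, and writes per-
subsection summaries plus per-animal compartment means to results/foci/.
"""

import json
from pathlib import Path

import pandas as pd

from nephroshield.foci_quant import SubsectionGateError, ThresholdConfig, quantify_tile
from nephroshield.tiles import read_tile

RESULTS = Path(__file__).resolve().parents[1] / "results"
TILES = RESULTS / "tiles"
OUT = RESULTS / "foci"


def main() -> None:
    cfg = ThresholdConfig()
    manifest = json.loads((TILES / "manifest.json").read_text())
    rows = []
    for entry in manifest:
        tile = read_tile(
            TILES / entry["dapi"],
            TILES / entry["gh2ax"],
            compartment=entry["compartment"],
            structure=entry["structure"],
            animal_id=entry["animal_id"],
        )
        try:
            s = quantify_tile(tile, cfg)
        except SubsectionGateError as err:
            print(f"skipped: {err}")
            continue
        rows.append(
            {
                "animal_id": entry["animal_id"],
                "arm": entry["arm"],
                "compartment": s.compartment,
                "structure": s.structure,
                "n_nuclei": s.n_nuclei,
                "n_positive": s.n_positive,
                "percent_positive": s.percent_positive,
                "planted_positive": entry["n_positive"],
            }
        )
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "subsections.csv", index=False)
    means = (
        df.groupby(["animal_id", "arm", "compartment"])["percent_positive"]
        .mean()
        .reset_index()
    )
    means.to_csv(OUT / "animal_means.csv", index=False)
    print(means.to_string(index=False))


if __name__ == "__main__":
    main()
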