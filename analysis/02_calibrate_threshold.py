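"""Calibrate the foci intensity threshold against manual-style counts.

Simulates six calibration tiles with jittered focus intensities, counts
them at a known reference threshold (standing in for a manual count),
and grid-searches the threshold that best reproduces those counts.
Writes results/calibration.json.
"""

from pathlib import Path

import numpy as np

from nephroshield.foci_quant import (
    ThresholdConfig,
    calibrate_threshold,
    classify_positive,
    detect_foci,
    segment_nuclei,
)
from nephroshield.synthetic_data import TileSpec, generate_tile

SEED = 20241
OUT = Path(__file__).resolve().parents[1] / "results" / "calibration.json"


def main() -> None:
    spec = TileSpec(
        width=256, height=256, n_nuclei=60, positive_fraction=0.25,
        focus_intensity=0.5, focus_intensity_jitter=0.4,
    )
    reference = ThresholdConfig(foci_intensity_threshold=0.45, min_subsection_nuclei=1)
    tiles, counts = [], []
    for s in range(6):
        tile, _ = generate_tile(spec, seed=SEED + s)
        nuclei = segment_nuclei(tile, reference)
        foci = detect_foci(tile, nuclei, reference)
        counts.append(
            (len(nuclei), sum(classify_positive(r, foci, reference) for r in nuclei))
        )
        tiles.append(tile)
    grid = [round(x, 2) for x in np.arange(0.20, 0.71, 0.05)]
    cfg, report = calibrate_threshold(tiles, counts, grid)
    report.to_json(OUT)
    print(f"calibrated T = {cfg.foci_intensity_threshold}; report at {OUT}")


if __name__ == "__main__":
    main()
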