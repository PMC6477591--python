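"""The two-channel image tile and its TIFF round trip.

A tile is one subsection's field of view with a nuclear-counterstain
channel (DAPI) and a DNA-damage-marker channel (gamma-H2AX), both held in
memory as float arrays normalised to [0, 1].  On disk each channel is a
single-channel 16-bit grayscale TIFF; intensities are rescaled by the
dtype maximum on read, so thresholds are always expressed in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageTile", "write_tile", "read_tile", "tile_basename"]

COMPARTMENTS = ("cortex", "medulla")
STRUCTURES = ("glomerular", "tubular")


@dataclass
class ImageTile:
    dapi: np.ndarray
    gh2ax: np.ndarray
    pixel_size_um: float = 0.5
    compartment: str = "cortex"
    structure: str = "tubular"
    animal_id: str = ""
    section_id: int = 0
    index: int = 0

    def __post_init__(self) -> None:
        self.dapi = np.asarray(self.dapi, dtype=float)
        self.gh2ax = np.asarray(self.gh2ax, dtype=float)
        if self.dapi.ndim != 2 or self.dapi.size == 0:
            raise ValueError("channels must be non-empty 2-D arrays")
        if self.dapi.shape != self.gh2ax.shape:
            raise ValueError("channel shapes differ")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"bad compartment: {self.compartment!r}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"bad structure: {self.structure!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape


def tile_basename(tile: ImageTile) -> str:
    return f"{tile.animal_id}_{tile.section_id}_{tile.compartment}_{tile.index}"


def write_tile(tile: ImageTile, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the two channels as 16-bit grayscale TIFFs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = tile_basename(tile)
    paths = []
    for name, chan in (("dapi", tile.dapi), ("gh2ax", tile.gh2ax)):
        arr = np.clip(chan, 0.0, 1.0)
        path = out_dir / f"{base}_{name}.tif"
        tifffile.imwrite(path, (arr * np.iinfo(np.uint16).max).round().astype(np.uint16))
        paths.append(path)
    return paths[0], paths[1]


def _read_channel(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def read_tile(
    dapi_path: str | Path,
    gh2ax_path: str | Path,
    pixel_size_um: float = 0.5,
    compartment: str = "cortex",
    structure: str = "tubular",
    animal_id: str = "",
    section_id: int = 0,
    index: int = 0,
) -> ImageTile:
    return ImageTile(
        dapi=_read_channel(Path(dapi_path)),
        gh2ax=_read_channel(Path(gh2ax_path)),
        pixel_size_um=pixel_size_um,
        compartment=compartment,
        structure=structure,
        animal_id=animal_id,
        section_id=section_id,
        index=index,
    )
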