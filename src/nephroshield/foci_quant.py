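"""Per-nucleus quantification of gamma-H2AX foci in fluorescence tiles.

The damage readout of the study: nuclei are segmented from the DAPI
channel, the stained area of individual and clustered gamma-H2AX foci is
measured inside each nucleus, and a subsection is summarised as the
percentage of nuclei exhibiting staining above the calibrated thresholds
(P) together with the total stained area.  Thresholds are calibrated
against manual counts on a small set of tiles and then frozen for all
quantification.

Coordinates are 0-based row-major ``(row, col)``; areas are in pixels; all
intensities are normalised to [0, 1] (see :mod:`nephroshield.tiles`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .tiles import ImageTile

__all__ = [
    "ThresholdConfig",
    "NucleusRecord",
    "FocusRecord",
    "NucleusCollection",
    "SubsectionSummary",
    "SubsectionGateError",
    "segment_nuclei",
    "detect_foci",
    "classify_positive",
    "summarize_subsection",
    "quantify_tile",
    "aggregate_compartment",
    "calibrate_threshold",
]

# 8-connectivity for foci components: "individual and clustered" foci are
# measured as single connected areas
_CONN8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ThresholdConfig:
    """Pixel-classification thresholds and gates for the counting pipeline.

    ``foci_intensity_threshold`` is the calibrated foci threshold T;
    ``min_subsection_nuclei`` is the acceptance gate requiring at least 103
    counterstained nuclei per subsection.  ``positivity_metric`` selects
    how a nucleus is called positive: ``"focus"`` (at least one focus of
    area >= ``min_focus_area``, the default) or ``"total_area"`` (total
    stained area >= ``min_focus_area``).
    """

    nucleus_channel_threshold: float = 0.35
    foci_intensity_threshold: float = 0.40
    min_nucleus_area: int = 20
    min_focus_area: int = 4
    min_subsection_nuclei: int = 103
    watershed_min_distance: int = 7
    positivity_metric: str = "focus"

    def __post_init__(self) -> None:
        for name in ("nucleus_channel_threshold", "foci_intensity_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_nucleus_area < 1 or self.min_focus_area < 1:
            raise ValueError("minimum areas must be >= 1 px")
        if self.min_subsection_nuclei < 1:
            raise ValueError("min_subsection_nuclei must be >= 1")
        if self.positivity_metric not in ("focus", "total_area"):
            raise ValueError(f"bad positivity_metric: {self.positivity_metric!r}")


@dataclass(frozen=True)
class NucleusRecord:
    id: int
    centroid: tuple[float, float]  # (row, col)
    area: int
    compartment: str = "cortex"
    structure: str = "tubular"


@dataclass(frozen=True)
class FocusRecord:
    nucleus_id: int
    component_id: int
    area: int


@dataclass
class NucleusCollection:
    """Segmentation result: records plus the labelled mask they index into.

    ``labels`` assigns every pixel its nucleus id (0 = background); label
    masks are pairwise disjoint by construction.
    """

    records: list[NucleusRecord]
    labels: np.ndarray

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


class SubsectionGateError(ValueError):
    """A subsection failed the minimum-nucleus-count gate."""


@dataclass(frozen=True)
class SubsectionSummary:
    n_nuclei: int
    n_positive: int
    percent_positive: float
    total_foci_area: int
    compartment: str
    structure: str
    animal_id: str = ""
    section_id: int = 0
    index: int = 0


# ---------------------------------------------------------------------------
# Segmentation and detection
# ---------------------------------------------------------------------------

def segment_nuclei(tile: ImageTile, cfg: ThresholdConfig) -> NucleusCollection:
    """Detect counterstained nuclei in the DAPI channel.

    Binarise at the nucleus threshold, fill holes, split touching nuclei
    by a distance-transform watershed seeded at distance maxima, and
    discard components below ``min_nucleus_area``.
    """
    chan = tile.dapi
    if chan.ndim != 2 or chan.size == 0:
        raise ValueError("nucleus channel must be a non-empty 2-D array")
    binary = chan >= cfg.nucleus_channel_threshold
    if not binary.any():
        return NucleusCollection([], np.zeros(chan.shape, dtype=np.int32))
    filled = ndi.binary_fill_holes(binary)
    dist = ndi.distance_transform_edt(filled)
    peaks = peak_local_max(
        dist, min_distance=cfg.watershed_min_distance, labels=filled, exclude_border=False
    )
    markers = np.zeros(chan.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=filled)

    # drop small components, relabel sequentially
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= cfg.min_nucleus_area]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[labels]

    records = []
    if len(keep):
        centroids = ndi.center_of_mass(
            np.ones_like(labels), labels, index=np.arange(1, len(keep) + 1)
        )
        areas = np.bincount(labels.ravel())[1:]
        for i, (cen, area) in enumerate(zip(centroids, areas), start=1):
            records.append(
                NucleusRecord(
                    id=i,
                    centroid=(float(cen[0]), float(cen[1])),
                    area=int(area),
                    compartment=tile.compartment,
                    structure=tile.structure,
                )
            )
    return NucleusCollection(records, labels)


def detect_foci(
    tile: ImageTile, nuclei: NucleusCollection, cfg: ThresholdConfig
) -> list[FocusRecord]:
    """Measure stained foci areas inside each segmented nucleus.

    Pixels of the damage channel at or above the foci threshold T form
    8-connected components *within each nucleus mask only*; components
    with at least ``min_focus_area`` pixels become focus records.  Signal
    outside every nucleus is ignored.
    """
    if tile.gh2ax.shape != nuclei.labels.shape:
        raise ValueError("foci channel shape does not match segmentation")
    supra = tile.gh2ax >= cfg.foci_intensity_threshold
    out: list[FocusRecord] = []
    slices = ndi.find_objects(nuclei.labels)
    comp_counter = 0
    for rec in nuclei.records:
        sl = slices[rec.id - 1]
        if sl is None:
            continue
        inside = supra[sl] & (nuclei.labels[sl] == rec.id)
        comp, n_comp = ndi.label(inside, structure=_CONN8)
        if n_comp == 0:
            continue
        areas = np.bincount(comp.ravel())[1:]
        for a in areas:
            comp_counter += 1
            if a >= cfg.min_focus_area:
                out.append(FocusRecord(nucleus_id=rec.id, component_id=comp_counter, area=int(a)))
    return out


def classify_positive(
    nucleus: NucleusRecord, foci: list[FocusRecord], cfg: ThresholdConfig
) -> bool:
    """Decide whether one nucleus exhibits staining within the thresholds."""
    mine = [f for f in foci if f.nucleus_id == nucleus.id]
    if cfg.positivity_metric == "total_area":
        return sum(f.area for f in mine) >= cfg.min_focus_area
    return any(f.area >= cfg.min_focus_area for f in mine)


def summarize_subsection(
    nuclei: NucleusCollection,
    foci: list[FocusRecord],
    cfg: ThresholdConfig,
    compartment: str = "cortex",
    structure: str = "tubular",
    animal_id: str = "",
    section_id: int = 0,
    index: int = 0,
) -> SubsectionSummary:
    """Summarise one subsection as P = 100 * n_positive / n_nuclei.

    Subsections with fewer than ``min_subsection_nuclei`` detected nuclei
    are rejected with a gate error naming the subsection.
    """
    n = len(nuclei)
    if n < cfg.min_subsection_nuclei:
        raise SubsectionGateError(
            f"subsection {animal_id}/{section_id}/{compartment}/{index}: "
            f"{n} nuclei < required {cfg.min_subsection_nuclei}"
        )
    n_pos = sum(classify_positive(rec, foci, cfg) for rec in nuclei)
    return SubsectionSummary(
        n_nuclei=n,
        n_positive=n_pos,
        percent_positive=100.0 * n_pos / n,
        total_foci_area=int(sum(f.area for f in foci)),
        compartment=compartment,
        structure=structure,
        animal_id=animal_id,
        section_id=section_id,
        index=index,
    )


def quantify_tile(tile: ImageTile, cfg: ThresholdConfig) -> SubsectionSummary:
    """Full pipeline for one tile: segment, detect, summarise."""
    nuclei = segment_nuclei(tile, cfg)
    foci = detect_foci(tile, nuclei, cfg)
    return summarize_subsection(
        nuclei,
        foci,
        cfg,
        compartment=tile.compartment,
        structure=tile.structure,
        animal_id=tile.animal_id,
        section_id=tile.section_id,
        index=tile.index,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_compartment(
    summaries: list[SubsectionSummary], level: str
) -> pd.DataFrame:
    """Per-animal mean P and total foci area at a tissue level.

    ``level`` is one of ``cortex``/``medulla`` (tile compartment) or
    ``glomerular``/``tubular`` (structure within the tile).  Subsection P
    values are averaged per animal without weighting (every accepted
    subsection already passed the nucleus-count gate); the animal is the
    statistical unit downstream.
    """
    if level in ("cortex", "medulla"):
        selected = [s for s in summaries if s.compartment == level]
    elif level in ("glomerular", "tubular"):
        selected = [s for s in summaries if s.structure == level]
    else:
        raise ValueError(f"unknown level: {level!r}")
    if not selected:
        raise ValueError(f"no accepted subsections at level {level!r}")
    df = pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in selected],
            "percent_positive": [s.percent_positive for s in selected],
            "total_foci_area": [s.total_foci_area for s in selected],
        }
    )
    out = (
        df.groupby("animal_id")
        .agg(
            mean_percent_positive=("percent_positive", "mean"),
            total_foci_area=("total_foci_area", "sum"),
            n_subsections=("percent_positive", "count"),
        )
        .reset_index()
    )
    out["level"] = level
    return out


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    config: ThresholdConfig
    foci_threshold_loss: dict[float, int]
    nucleus_threshold_loss: dict[float, int] | None = None
    validation_error: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "foci_intensity_threshold": self.config.foci_intensity_threshold,
            "nucleus_channel_threshold": self.config.nucleus_channel_threshold,
            "foci_threshold_loss": {str(k): v for k, v in self.foci_threshold_loss.items()},
            "nucleus_threshold_loss": (
                None
                if self.nucleus_threshold_loss is None
                else {str(k): v for k, v in self.nucleus_threshold_loss.items()}
            ),
            "validation_error": self.validation_error,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _positive_counts(
    tiles: list[ImageTile], cfg: ThresholdConfig
) -> tuple[list[int], list[int]]:
    n_nuc, n_pos = [], []
    for tile in tiles:
        nuclei = segment_nuclei(tile, cfg)
        foci = detect_foci(tile, nuclei, cfg)
        n_nuc.append(len(nuclei))
        n_pos.append(sum(classify_positive(rec, foci, cfg) for rec in nuclei))
    return n_nuc, n_pos


def calibrate_threshold(
    tiles: list[ImageTile],
    manual_counts: list[tuple[int, int]],
    grid: list[float],
    base_cfg: ThresholdConfig | None = None,
    nucleus_grid: list[float] | None = None,
    validation: tuple[list[ImageTile], list[tuple[int, int]]] | None = None,
) -> tuple[ThresholdConfig, CalibrationReport]:
    """Derive thresholds by matching the software to manual counts.

    Emulates the iterative manual/automated comparison used to fix the
    pixel thresholds: for every candidate foci threshold T in ``grid`` the
    detector is run on the calibration tiles and the value minimising
    ``sum |software n_positive - manual n_positive|`` is chosen, ties
    broken toward the lower threshold.  If ``nucleus_grid`` is given, the
    nucleus threshold is first chosen by the secondary criterion
    ``sum |software n_nuclei - manual n_nuclei|``.  When a held-out
    ``validation`` set is supplied, its residual count error at the chosen
    thresholds is reported.
    """
    if not tiles or not manual_counts or len(tiles) != len(manual_counts):
        raise ValueError("need matching non-empty tile and manual-count lists")
    if not grid:
        raise ValueError("empty foci-threshold grid")
    if sorted(grid) != list(grid):
        raise ValueError("grid must be sorted ascending")
    cfg = base_cfg or ThresholdConfig()

    nucleus_loss: dict[float, int] | None = None
    if nucleus_grid:
        nucleus_loss = {}
        for thr in nucleus_grid:
            trial = replace(cfg, nucleus_channel_threshold=thr)
            n_nuc, _ = _positive_counts(tiles, trial)
            nucleus_loss[thr] = int(
                sum(abs(a - m[0]) for a, m in zip(n_nuc, manual_counts))
            )
        best_nuc = min(nucleus_grid, key=lambda thr: (nucleus_loss[thr], thr))
        cfg = replace(cfg, nucleus_channel_threshold=best_nuc)

    # nuclei segmentation does not depend on T: segment once, sweep T
    segmented = [segment_nuclei(tile, cfg) for tile in tiles]
    foci_loss: dict[float, int] = {}
    for t in grid:
        trial = replace(cfg, foci_intensity_threshold=t)
        loss = 0
        for tile, nuclei, (_, manual_pos) in zip(tiles, segmented, manual_counts):
            foci = detect_foci(tile, nuclei, trial)
            soft_pos = sum(classify_positive(rec, foci, trial) for rec in nuclei)
            loss += abs(soft_pos - manual_pos)
        foci_loss[t] = loss
    best_t = min(grid, key=lambda t: (foci_loss[t], t))
    cfg = replace(cfg, foci_intensity_threshold=best_t)

    val_err = None
    if validation is not None:
        vtiles, vcounts = validation
        _, vpos = _positive_counts(vtiles, cfg)
        val_err = float(sum(abs(a - m[1]) for a, m in zip(vpos, vcounts)))
    return cfg, CalibrationReport(cfg, foci_loss, nucleus_loss, val_err)
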