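"""Nucleus segmentation, within-nucleus foci detection, subsection
summaries and threshold calibration, checked against planted ground truth."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from conftest import match_nuclei_to_truth
from oracles import disk_pixel_count

from nephroshield.foci_quant import (
    FocusRecord,
    NucleusCollection,
    NucleusRecord,
    SubsectionGateError,
    SubsectionSummary,
    ThresholdConfig,
    aggregate_compartment,
    calibrate_threshold,
    classify_positive,
    detect_foci,
    segment_nuclei,
    summarize_subsection,
)
from nephroshield.synthetic_data import TileSpec, generate_tile
from nephroshield.tiles import ImageTile


def _tile_from_arrays(dapi, gh2ax, **kw):
    return ImageTile(dapi=dapi, gh2ax=gh2ax, **kw)


def _disk(shape, center, radius, value=0.7):
    arr = np.zeros(shape)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    arr[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = value
    return arr


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def test_blank_channel_yields_no_nuclei(loose_cfg):
    tile = _tile_from_arrays(np.zeros((64, 64)), np.zeros((64, 64)))
    assert len(segment_nuclei(tile, loose_cfg)) == 0


def test_single_disk_area_matches_brute_force(loose_cfg):
    center, radius = (40.3, 50.7), 10.0
    tile = _tile_from_arrays(_disk((96, 96), center, radius), np.zeros((96, 96)))
    nuclei = segment_nuclei(tile, loose_cfg)
    assert len(nuclei) == 1
    expected = disk_pixel_count(center, radius)
    assert abs(nuclei.records[0].area - expected) <= 0.05 * expected


def test_segmentation_matches_ground_truth(loose_cfg):
    spec = TileSpec(width=512, height=512, n_nuclei=150, positive_fraction=0.2)
    tile, truth = generate_tile(spec, seed=21)
    nuclei = segment_nuclei(tile, loose_cfg)
    matched = set()
    for rec in nuclei.records:
        for nuc in truth.nuclei:
            d = math.hypot(rec.centroid[0] - nuc.center[0], rec.centroid[1] - nuc.center[1])
            if d <= nuc.radius and nuc.id not in matched:
                matched.add(nuc.id)
                break
    assert len(matched) >= 0.95 * len(truth.nuclei)
    assert len(nuclei) <= 1.05 * len(truth.nuclei)


def test_non_2d_channel_rejected(loose_cfg):
    with pytest.raises(ValueError):
        ImageTile(dapi=np.zeros((4, 4, 3)), gh2ax=np.zeros((4, 4, 3)))


# ---------------------------------------------------------------------------
# Foci detection
# ---------------------------------------------------------------------------

def test_subthreshold_channel_gives_no_foci(loose_cfg):
    dapi = _disk((64, 64), (32, 32), 10)
    tile = _tile_from_arrays(dapi, np.full((64, 64), 0.2))
    nuclei = segment_nuclei(tile, loose_cfg)
    assert detect_foci(tile, nuclei, loose_cfg) == []


def test_square_focus_inside_nucleus_has_area_nine(loose_cfg):
    dapi = _disk((64, 64), (32, 32), 12)
    gh2ax = np.zeros((64, 64))
    gh2ax[30:33, 30:33] = 0.9
    tile = _tile_from_arrays(dapi, gh2ax)
    nuclei = segment_nuclei(tile, loose_cfg)
    foci = detect_foci(tile, nuclei, loose_cfg)
    assert len(foci) == 1 and foci[0].area == 9


def test_signal_outside_nuclei_is_ignored(loose_cfg):
    dapi = _disk((64, 64), (20, 20), 8)
    gh2ax = np.zeros((64, 64))
    gh2ax[50:56, 50:56] = 0.9  # far from the nucleus
    tile = _tile_from_arrays(dapi, gh2ax)
    nuclei = segment_nuclei(tile, loose_cfg)
    assert detect_foci(tile, nuclei, loose_cfg) == []


def test_shape_mismatch_rejected(loose_cfg):
    dapi = _disk((64, 64), (32, 32), 8)
    tile = _tile_from_arrays(dapi, np.zeros((64, 64)))
    nuclei = segment_nuclei(tile, loose_cfg)
    other = _tile_from_arrays(np.zeros((32, 32)), np.zeros((32, 32)))
    with pytest.raises(ValueError):
        detect_foci(other, nuclei, loose_cfg)


# ---------------------------------------------------------------------------
# Positivity and summaries
# ---------------------------------------------------------------------------

def _nucleus(i=1):
    return NucleusRecord(id=i, centroid=(0.0, 0.0), area=100)


@pytest.mark.parametrize(
    "areas,expected",
    [([], False), ([4], True), ([3], False), ([2, 3], False), ([3, 7], True)],
)
def test_positivity_boundary(areas, expected, loose_cfg):
    foci = [FocusRecord(nucleus_id=1, component_id=k, area=a) for k, a in enumerate(areas)]
    assert classify_positive(_nucleus(), foci, loose_cfg) is expected


def test_total_area_positivity_rule():
    cfg = ThresholdConfig(min_subsection_nuclei=1, positivity_metric="total_area")
    foci = [FocusRecord(1, 1, 2), FocusRecord(1, 2, 2)]
    assert classify_positive(_nucleus(), foci, cfg) is True


def _collection(n):
    return NucleusCollection([_nucleus(i) for i in range(1, n + 1)], np.zeros((4, 4), np.int32))


def test_subsection_gate_boundary():
    cfg = ThresholdConfig()
    with pytest.raises(SubsectionGateError, match="102 nuclei"):
        summarize_subsection(_collection(102), [], cfg, animal_id="m1")
    summary = summarize_subsection(_collection(103), [], cfg)
    assert summary.n_nuclei == 103 and summary.percent_positive == 0.0


def test_subsection_percentage():
    cfg = ThresholdConfig()
    foci = [FocusRecord(nucleus_id=i, component_id=i, area=5) for i in range(1, 32)]
    summary = summarize_subsection(_collection(103), foci, cfg)
    assert summary.n_positive == 31
    assert summary.percent_positive == pytest.approx(100 * 31 / 103)
    assert summary.total_foci_area == 31 * 5


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _summary(p, animal="m1", comp="cortex", struct="tubular", area=0):
    return SubsectionSummary(
        n_nuclei=103, n_positive=0, percent_positive=p, total_foci_area=area,
        compartment=comp, structure=struct, animal_id=animal,
    )


def test_aggregate_mean_of_subsections():
    out = aggregate_compartment([_summary(p) for p in (10.0, 20.0, 30.0)], "cortex")
    assert out["mean_percent_positive"].tolist() == [20.0]
    single = aggregate_compartment([_summary(12.5)], "cortex")
    assert single["mean_percent_positive"].tolist() == [12.5]


def test_aggregate_levels_and_errors():
    summaries = [_summary(10.0, comp="cortex", struct="glomerular"), _summary(30.0, comp="medulla")]
    assert aggregate_compartment(summaries, "glomerular")["mean_percent_positive"].tolist() == [10.0]
    with pytest.raises(ValueError):
        aggregate_compartment(summaries, "papilla")
    with pytest.raises(ValueError):
        aggregate_compartment([_summary(5.0, comp="cortex")], "medulla")


# ---------------------------------------------------------------------------
# Monotonicity and correlation properties
# ---------------------------------------------------------------------------

def test_raising_threshold_never_increases_counts(noisy_tile, loose_cfg):
    tile, _ = noisy_tile
    nuclei = segment_nuclei(tile, loose_cfg)
    prev_pos, prev_area = math.inf, math.inf
    for t in (0.2, 0.35, 0.5, 0.65, 0.8):
        cfg = replace(loose_cfg, foci_intensity_threshold=t)
        foci = detect_foci(tile, nuclei, cfg)
        n_pos = sum(classify_positive(r, foci, cfg) for r in nuclei)
        area = sum(f.area for f in foci)
        assert n_pos <= prev_pos and area <= prev_area
        prev_pos, prev_area = n_pos, area


def test_noise_free_detection_equals_planted_truth(noise_free_spec, loose_cfg):
    tile, truth = generate_tile(noise_free_spec, seed=31)
    nuclei = segment_nuclei(tile, loose_cfg)
    foci = detect_foci(tile, nuclei, loose_cfg)
    assert len(nuclei) == len(truth.nuclei)
    for rec, planted in match_nuclei_to_truth(nuclei, truth):
        assert planted is not None
        detected = sorted(f.area for f in foci if f.nucleus_id == rec.id)
        assert detected == sorted(f.area_px for f in planted.foci)
        assert classify_positive(rec, foci, loose_cfg) == planted.is_positive


def test_percent_positive_and_total_area_correlate(loose_cfg):
    """Across a simulated dose gradient the two readouts move together."""
    ps, areas = [], []
    for i, frac in enumerate((0.01, 0.05, 0.1, 0.2, 0.3, 0.4)):
        spec = TileSpec(width=256, height=256, n_nuclei=60, positive_fraction=frac)
        tile, _ = generate_tile(spec, seed=40 + i)
        nuclei = segment_nuclei(tile, loose_cfg)
        foci = detect_foci(tile, nuclei, loose_cfg)
        ps.append(100 * sum(classify_positive(r, foci, loose_cfg) for r in nuclei) / len(nuclei))
        areas.append(sum(f.area for f in foci))
    rho, _ = stats.spearmanr(ps, areas)
    assert rho > 0


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _calibration_tiles(n=4, t_star=0.45):
    spec = TileSpec(
        width=256, height=256, n_nuclei=60, positive_fraction=0.25,
        focus_intensity=0.5, focus_intensity_jitter=0.4,
    )
    cfg_star = ThresholdConfig(foci_intensity_threshold=t_star, min_subsection_nuclei=1)
    tiles, counts = [], []
    for s in range(n):
        tile, _ = generate_tile(spec, seed=100 + s)
        nuclei = segment_nuclei(tile, cfg_star)
        foci = detect_foci(tile, nuclei, cfg_star)
        counts.append((len(nuclei), sum(classify_positive(r, foci, cfg_star) for r in nuclei)))
        tiles.append(tile)
    return tiles, counts


def test_calibration_recovers_generating_threshold():
    tiles, counts = _calibration_tiles()
    grid = [round(x, 2) for x in np.arange(0.20, 0.71, 0.05)]
    cfg, report = calibrate_threshold(tiles, counts, grid)
    assert cfg.foci_intensity_threshold == 0.45
    assert report.foci_threshold_loss[0.45] == 0


def test_calibration_tie_resolves_to_lower_value():
    tiles, counts = _calibration_tiles(n=2)
    # a two-point grid far above every focus intensity: both detect nothing,
    # identical loss, so the lower value must win
    cfg, report = calibrate_threshold(tiles, counts, [0.95, 0.99])
    assert report.foci_threshold_loss[0.95] == report.foci_threshold_loss[0.99]
    assert cfg.foci_intensity_threshold == 0.95


def test_calibration_validation_and_errors():
    tiles, counts = _calibration_tiles(n=3)
    with pytest.raises(ValueError):
        calibrate_threshold(tiles, counts, [])
    with pytest.raises(ValueError):
        calibrate_threshold([], [], [0.5])
    with pytest.raises(ValueError):
        calibrate_threshold(tiles, counts, [0.6, 0.4])
    cfg, report = calibrate_threshold(
        tiles[:2], counts[:2], [0.40, 0.45, 0.50], validation=(tiles[2:], counts[2:])
    )
    assert report.validation_error is not None and report.validation_error >= 0
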