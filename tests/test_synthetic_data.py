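"""The generators are pure functions of (spec, seed) and their cohorts
recover the design parameters."""

import math
from dataclasses import replace

import numpy as np
import pytest

from nephroshield.dosimetry import TimeActivityCurve, cumulated_activity
from nephroshield.histopath import LESIONS, total_lesion_score
from nephroshield.survival import classify_outcome, km_estimate
from nephroshield.synthetic_data import (
    ArmEffects,
    KineticsSpec,
    StudyDesign,
    TilePlacementError,
    TileSpec,
    default_design,
    generate_biomarkers,
    generate_scoresheets,
    generate_study_images,
    generate_survival,
    generate_tile,
    generate_time_activity,
    round_half_away,
    study_truth_summaries,
)


# ---------------------------------------------------------------------------
# Tiles
# ---------------------------------------------------------------------------

def test_empty_tile_is_pure_noise():
    spec = TileSpec(width=64, height=64, n_nuclei=0)
    tile, truth = generate_tile(spec, seed=1)
    assert truth.nuclei == []
    assert truth.labels.max() == 0
    assert truth.percent_positive == 0.0
    assert tile.dapi.shape == (64, 64)


def test_same_seed_bit_identical():
    spec = TileSpec(width=128, height=128, n_nuclei=20, positive_fraction=0.5)
    t1, g1 = generate_tile(spec, seed=11)
    t2, g2 = generate_tile(spec, seed=11)
    assert np.array_equal(t1.dapi, t2.dapi)
    assert np.array_equal(t1.gh2ax, t2.gh2ax)
    assert np.array_equal(g1.labels, g2.labels)
    t3, _ = generate_tile(spec, seed=12)
    assert not np.array_equal(t1.dapi, t3.dapi)


@pytest.mark.parametrize(
    "n,fraction,expected",
    [(150, 0.30, 45), (103, 0.005, 1), (7, 0.5, 4), (10, 0.25, 3), (10, 0.0, 0)],
)
def test_positive_count_rounds_half_away_from_zero(n, fraction, expected):
    assert round_half_away(fraction * n) == expected
    spec = TileSpec(width=512, height=512, n_nuclei=n, positive_fraction=fraction)
    _, truth = generate_tile(spec, seed=2)
    assert truth.n_positive == expected


def test_ground_truth_consistency():
    """Planted foci stay inside their nucleus mask; masks are disjoint;
    the positive flag is exactly 'has at least one planted focus'."""
    spec = TileSpec(width=256, height=256, n_nuclei=50, positive_fraction=0.4)
    _, truth = generate_tile(spec, seed=3)
    areas = np.bincount(truth.labels.ravel())[1:]
    assert len(areas) == 50  # every nucleus rasterised with its own label
    for nuc in truth.nuclei:
        assert areas[nuc.id - 1] == nuc.area_px
        assert nuc.is_positive == (len(nuc.foci) > 0)
        for focus in nuc.foci:
            rr = np.arange(truth.labels.shape[0])[:, None]
            cc = np.arange(truth.labels.shape[1])[None, :]
            inside = (rr - focus.center[0]) ** 2 + (cc - focus.center[1]) ** 2 <= focus.radius**2
            assert np.all(truth.labels[inside] == nuc.id)
            assert focus.area_px == int(inside.sum())


def test_infeasible_placement_raises():
    spec = TileSpec(width=64, height=64, n_nuclei=300)
    with pytest.raises(TilePlacementError):
        generate_tile(spec, seed=0)


def test_spec_validation():
    with pytest.raises(ValueError):
        TileSpec(positive_fraction=1.5)
    with pytest.raises(ValueError):
        TileSpec(n_nuclei=-1)
    with pytest.raises(ValueError):
        TileSpec(nucleus_radius_range=(5.0, 3.0))
    with pytest.raises(ValueError):
        TileSpec(focus_intensity=1.4)


# ---------------------------------------------------------------------------
# Study images
# ---------------------------------------------------------------------------

def _tiny_template():
    return TileSpec(width=96, height=96, n_nuclei=8)


def test_each_animal_gets_18_tiles():
    design = default_design(seed=4)
    design.image_n_per_arm = 1
    animal_id, arm, tiles = next(generate_study_images(design, _tiny_template()))
    assert len(tiles) == 18  # 2 sections x (6 cortex + 3 medulla)
    comps = [t.compartment for t, _ in tiles]
    assert comps.count("cortex") == 12 and comps.count("medulla") == 6
    structs = [t.structure for t, _ in tiles]
    assert structs.count("glomerular") == 4


def test_null_fractions_give_zero_positives():
    design = default_design(seed=5)
    for arm in design.arms.values():
        arm.positive_fraction = {"cortex": 0.0, "medulla": 0.0}
    df = study_truth_summaries(design, _tiny_template())
    assert (df["n_positive"] == 0).all()


def test_arm_fraction_recovery():
    """Cohort mean planted fraction matches the arm nominal within
    sampling error (Gamma animal-effect oracle)."""
    template = TileSpec(width=512, height=512, n_nuclei=150)
    nominal = {"control": 0.005, "lu": 0.06}
    reps = 40
    samples = {a: [] for a in nominal}
    for r in range(reps):
        design = default_design(seed=1000 + r)
        design.image_n_per_arm = 2
        df = study_truth_summaries(design, template)
        for arm in nominal:
            sel = df[(df["arm"] == arm) & (df["compartment"] == "cortex")]
            samples[arm].extend(sel["percent_positive"] / 100.0)
    for arm, frac in nominal.items():
        vals = np.asarray(samples[arm])
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        # rounding to integer positives per 150-nucleus tile biases <= 1/300
        assert abs(vals.mean() - frac) <= 3 * se + 1 / 300


# ---------------------------------------------------------------------------
# Score sheets
# ---------------------------------------------------------------------------

def test_degenerate_grade_distributions():
    design = default_design(seed=6)
    for arm in design.arms.values():
        arm.lesion_grade_probs = (1.0, 0.0, 0.0, 0.0, 0.0)
    assert all(total_lesion_score(s) == 0 for s in generate_scoresheets(design))
    for arm in design.arms.values():
        arm.lesion_grade_probs = (0.0, 0.0, 0.0, 0.0, 1.0)
    assert all(total_lesion_score(s) == 32 for s in generate_scoresheets(design))


def test_glomerulus_poisson_recovery():
    design = default_design(seed=7)
    means = {"control": [], "lu": []}
    for r in range(60):
        design.seed = 7000 + r
        for s in generate_scoresheets(design):
            if s.arm in means:
                means[s.arm].append(s.glomerulus_count)
    for arm, nominal in (("control", 60.0), ("lu", 30.0)):
        vals = np.asarray(means[arm], dtype=float)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - nominal) <= 3 * se


# ---------------------------------------------------------------------------
# Biomarkers & expression
# ---------------------------------------------------------------------------

def test_null_fold_change_gives_zero_ddct():
    ddcts = []
    for r in range(30):
        design = default_design(seed=2000 + r)
        for arm in design.arms.values():
            arm.fold_changes = {g: 1.0 for g in arm.fold_changes}
        _, ct = generate_biomarkers(design)
        ref = ct[ct["gene"] == "B2m"].set_index("sample_id")["ct"]
        tgt = ct[ct["gene"] == "Bax"]
        dct = tgt["ct"].to_numpy() - ref.loc[tgt["sample_id"]].to_numpy()
        ddcts.append(dct.mean() - dct[(tgt["arm"] == "control").to_numpy()].mean())
    assert abs(np.mean(ddcts)) < 0.05


def test_zero_sd_gives_identical_samples():
    design = default_design(seed=8)
    for arm in design.arms.values():
        arm.biomarkers = {"bun_mmol_l": (8.0, 0.0)}
    bio, _ = generate_biomarkers(design)
    ctrl = bio[(bio["arm"] == "control") & (bio["analyte"] == "bun_mmol_l")]["value"]
    assert np.allclose(ctrl, 8.0)


def test_planted_outlier_is_displaced():
    design = default_design(seed=9)
    bio_clean, _ = generate_biomarkers(design)
    bio_out, _ = generate_biomarkers(design, outlier_offset_sd=10.0, outliers_per_analyte=1)
    sel = lambda df: df[(df["arm"] == "lu") & (df["analyte"] == "bun_mmol_l")]["value"].to_numpy()
    diff = sel(bio_out) - sel(bio_clean)
    assert diff[0] == pytest.approx(10.0 * 1.8)  # 10 x design SD
    assert np.all(diff[1:] == 0)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def test_zero_hazard_all_censored_km_is_one():
    design = default_design(seed=10)
    for arm in design.arms.values():
        arm.hazard_per_week = 0.0
        arm.censor_hazard_per_week = 0.0
    records = generate_survival(design)
    assert all(r.status == "censored" for r in records)
    curve = km_estimate(records)
    assert curve.survival_at(24) == 1.0


def test_event_fraction_matches_exponential_closed_form():
    lam, t_end = 0.05, 24
    events = total = 0
    for r in range(25):
        design = default_design(seed=3000 + r)
        for arm in design.arms.values():
            arm.hazard_per_week = lam
            arm.censor_hazard_per_week = 0.0
        recs = [x for x in generate_survival(design) if x.arm == "lu"]
        events += sum(x.status == "event" for x in recs)
        total += len(recs)
    # records pool the 6/12/24-week groups; expectation is the size-weighted
    # mean of the closed-form event fractions 1 - exp(-lambda * T)
    sizes = {6: 9, 12: 7, t_end: 10}
    expected = sum(n * (1 - math.exp(-lam * t)) for t, n in sizes.items()) / sum(sizes.values())
    sd = math.sqrt(expected * (1 - expected) / total)
    assert abs(events / total - expected) <= 3 * sd


def test_findings_reproduce_labels_and_are_deterministic():
    design = default_design(seed=11)
    r1 = generate_survival(design)
    r2 = generate_survival(design)
    assert r1 == r2
    for rec in r1:
        status, _ = classify_outcome(rec.findings, rec.context)
        assert status == rec.status


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def test_time_activity_basics():
    spec = KineticsSpec(amplitudes_mbq=(5.0,), lambda_bio_per_h=(0.02,), sampling_times_h=(0.0, 1.0))
    curve = generate_time_activity(spec)
    assert curve.activities_mbq[0] == pytest.approx(5.0)
    zero = generate_time_activity(replace(spec, amplitudes_mbq=(0.0,)))
    assert np.all(zero.activities_mbq == 0)


def test_time_activity_integrates_to_closed_form():
    spec = KineticsSpec(
        amplitudes_mbq=(5.0,),
        lambda_bio_per_h=(0.02,),
        sampling_times_h=tuple(np.linspace(0, 10 / 0.0243, 6000)),
    )
    lam = spec.effective_lambdas_per_h[0]
    curve = generate_time_activity(spec)
    curve = TimeActivityCurve(
        curve.times_h, curve.activities_mbq, tail="mono-exponential", lambda_eff_per_h=lam
    )
    assert cumulated_activity(curve) == pytest.approx(5.0 / lam, rel=1e-6)


def test_kinetics_validation():
    with pytest.raises(ValueError):
        KineticsSpec(sampling_times_h=(0.0, 2.0, 1.0))
    with pytest.raises(ValueError):
        KineticsSpec(lambda_bio_per_h=(0.0,))
    with pytest.raises(ValueError):
        KineticsSpec(amplitudes_mbq=(-1.0,))


# ---------------------------------------------------------------------------
# Design validation
# ---------------------------------------------------------------------------

def test_design_requires_exact_arm_names():
    with pytest.raises(ValueError):
        StudyDesign(arms={"control": ArmEffects()}, group_sizes={("control", 6): 5})
    with pytest.raises(ValueError):
        d = default_design()
        StudyDesign(arms=d.arms, group_sizes={("control", 6): 0})
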