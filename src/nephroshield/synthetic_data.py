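"""Synthetic study generator: every input the pipeline consumes, with
known ground truth.

The animal data behind the original study are not public, so the pipeline
is exercised on simulated inputs that emulate its study design: four
treatment arms (control, radioligand, radioligand + alpha-1-microglobulin,
protein alone), fluorescence tiles with planted nuclei and damage foci at
controlled positive fractions per renal compartment, ordinal lesion
grades, Gaussian biomarker panels, qPCR Ct values with nominal fold
changes, exponential survival with censoring, and multi-exponential
time-activity curves.

Every generator is a pure function of its parameters and a seed.
Per-animal streams are derived from ``numpy.random.SeedSequence`` with the
entropy tuple ``(master seed, stage tag, arm index, animal index)``, so
cohorts are reproducible piecewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .biomarker_stats import ARMS
from .dosimetry import TimeActivityCurve, days_to_hours
from .histopath import LESIONS, LesionScoreSheet
from .survival import HUMANE_FINDINGS, RADIATION_FINDINGS, SurvivalRecord, classify_outcome
from .tiles import ImageTile

__all__ = [
    "TileSpec",
    "PlantedFocus",
    "PlantedNucleus",
    "GroundTruth",
    "ArmEffects",
    "StudyDesign",
    "KineticsSpec",
    "TilePlacementError",
    "default_design",
    "generate_tile",
    "generate_study_images",
    "study_truth_summaries",
    "generate_scoresheets",
    "generate_biomarkers",
    "generate_survival",
    "generate_time_activity",
]

# stage tags for deriving independent seed streams from the master seed
_TAG_TILES, _TAG_SCORES, _TAG_BIOMARKERS, _TAG_SURVIVAL = 1, 2, 3, 4


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


class TilePlacementError(RuntimeError):
    """Hard-core nucleus placement exceeded its attempt budget."""


# ---------------------------------------------------------------------------
# Tiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TileSpec:
    """Parameters of one simulated subsection field of view.

    The image model is deliberately minimal: flat disks for nuclei and
    foci, a Gaussian point-spread function, additive Gaussian background
    and optional Poisson shot noise — the simplest model that exercises
    thresholding and segmentation realistically.
    """

    width: int = 512
    height: int = 512
    pixel_size_um: float = 0.5
    n_nuclei: int = 150
    nucleus_radius_range: tuple[float, float] = (6.0, 9.0)
    positive_fraction: float = 0.0
    foci_per_positive_nucleus: float = 3.0
    focus_radius_range: tuple[float, float] = (1.5, 2.5)
    focus_intensity: float = 0.8
    focus_intensity_jitter: float = 0.0
    nucleus_intensity: float = 0.7
    background_mean: float = 0.08
    background_sd: float = 0.02
    psf_sigma: float = 1.0
    shot_noise: bool = False
    shot_noise_photons: float = 500.0
    compartment: str = "cortex"
    structure: str = "tubular"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("tile dimensions must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        for lo, hi in (self.nucleus_radius_range, self.focus_radius_range):
            if lo <= 0 or hi < lo:
                raise ValueError("radius ranges must be positive and ordered")
        for name in ("focus_intensity", "nucleus_intensity", "background_mean"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.background_sd < 0 or self.psf_sigma < 0:
            raise ValueError("background_sd and psf_sigma must be >= 0")
        if self.focus_intensity_jitter < 0:
            raise ValueError("focus_intensity_jitter must be >= 0")


@dataclass(frozen=True)
class PlantedFocus:
    center: tuple[float, float]  # (row, col)
    radius: float
    area_px: int
    intensity: float = 0.8


@dataclass
class PlantedNucleus:
    id: int
    center: tuple[float, float]
    radius: float
    area_px: int
    compartment: str
    structure: str
    is_positive: bool
    foci: list[PlantedFocus] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Planted truth for one tile; the oracle for the counting pipeline.

    ``labels`` assigns every pixel its planted nucleus id (0 background);
    planted foci pixels always lie inside their nucleus mask.
    """

    nuclei: list[PlantedNucleus]
    labels: np.ndarray

    @property
    def n_positive(self) -> int:
        return sum(n.is_positive for n in self.nuclei)

    @property
    def percent_positive(self) -> float:
        if not self.nuclei:
            return 0.0
        return 100.0 * self.n_positive / len(self.nuclei)


def _rasterize_disk(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates (rows, cols) with centre distance <= radius."""
    r0 = max(0, int(math.floor(center[0] - radius)))
    r1 = min(shape[0] - 1, int(math.ceil(center[0] + radius)))
    c0 = max(0, int(math.floor(center[1] - radius)))
    c1 = min(shape[1] - 1, int(math.ceil(center[1] + radius)))
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[inside], cc[inside]


_PLACEMENT_ATTEMPTS = 10_000  # per nucleus; exceeding it is an error


def generate_tile(spec: TileSpec, seed: int) -> tuple[ImageTile, GroundTruth]:
    """Render one two-channel tile and its planted ground truth.

    Nuclei are placed by a hard-core process (centre distance at least the
    two radii plus a 2 px gap, so masks are disjoint and never 8-adjacent).
    Exactly ``round_half_away(positive_fraction * n_nuclei)`` nuclei carry
    foci; foci are wholly inside their nucleus and never touch each other,
    so on a noise-free tile the detected component areas equal the planted
    rasterised areas exactly.  Identical (spec, seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    shape = (spec.height, spec.width)
    nuclei: list[PlantedNucleus] = []
    labels = np.zeros(shape, dtype=np.int32)

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for i in range(spec.n_nuclei):
        rad = rng.uniform(*spec.nucleus_radius_range)
        placed = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            cy = rng.uniform(rad, spec.height - 1 - rad)
            cx = rng.uniform(rad, spec.width - 1 - rad)
            ok = all(
                (cy - y) ** 2 + (cx - x) ** 2 >= (rad + r + 2.0) ** 2
                for (y, x), r in zip(centers, radii)
            )
            if ok:
                placed = True
                break
        if not placed:
            raise TilePlacementError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} "
                f"within {_PLACEMENT_ATTEMPTS} attempts"
            )
        centers.append((cy, cx))
        radii.append(rad)

    n_pos = round_half_away(spec.positive_fraction * spec.n_nuclei)
    positive_idx = set(
        rng.choice(spec.n_nuclei, size=n_pos, replace=False).tolist()
    ) if spec.n_nuclei else set()

    dapi = np.zeros(shape, dtype=float)
    gh2ax = np.zeros(shape, dtype=float)
    for i, ((cy, cx), rad) in enumerate(zip(centers, radii)):
        rr, cc = _rasterize_disk(shape, (cy, cx), rad)
        labels[rr, cc] = i + 1
        dapi[rr, cc] = spec.nucleus_intensity
        nuc = PlantedNucleus(
            id=i + 1,
            center=(cy, cx),
            radius=rad,
            area_px=len(rr),
            compartment=spec.compartment,
            structure=spec.structure,
            is_positive=i in positive_idx,
        )
        if nuc.is_positive:
            n_foci = max(1, int(rng.poisson(spec.foci_per_positive_nucleus)))
            placed_foci: list[tuple[tuple[float, float], float]] = []
            for _ in range(n_foci):
                frad = min(rng.uniform(*spec.focus_radius_range), rad - 1.0)
                if frad <= 0:
                    continue
                max_off = rad - frad
                for _ in range(200):
                    ang = rng.uniform(0, 2 * math.pi)
                    off = max_off * math.sqrt(rng.uniform())
                    fy, fx = cy + off * math.sin(ang), cx + off * math.cos(ang)
                    # foci within a nucleus keep a 2 px gap so 8-connected
                    # components map one-to-one onto planted foci
                    if all(
                        (fy - py) ** 2 + (fx - px) ** 2 >= (frad + pr + 2.0) ** 2
                        for (py, px), pr in placed_foci
                    ):
                        placed_foci.append(((fy, fx), frad))
                        break
            if not placed_foci:
                # guaranteed placeable: dead centre with the smallest radius
                frad = min(spec.focus_radius_range[0], rad - 1.0)
                placed_foci.append(((cy, cx), frad))
            for (fy, fx), frad in placed_foci:
                fr_r, fr_c = _rasterize_disk(shape, (fy, fx), frad)
                intensity = spec.focus_intensity
                if spec.focus_intensity_jitter > 0:
                    intensity = float(
                        np.clip(
                            intensity
                            + rng.uniform(
                                -spec.focus_intensity_jitter, spec.focus_intensity_jitter
                            ),
                            0.05,
                            1.0,
                        )
                    )
                gh2ax[fr_r, fr_c] = intensity
                nuc.foci.append(PlantedFocus((fy, fx), frad, len(fr_r), intensity))
        nuclei.append(nuc)

    if spec.psf_sigma > 0:
        dapi = ndi.gaussian_filter(dapi, spec.psf_sigma)
        gh2ax = ndi.gaussian_filter(gh2ax, spec.psf_sigma)
    if spec.background_mean > 0 or spec.background_sd > 0:
        dapi = dapi + rng.normal(spec.background_mean, spec.background_sd, shape)
        gh2ax = gh2ax + rng.normal(spec.background_mean, spec.background_sd, shape)
    if spec.shot_noise:
        scale = spec.shot_noise_photons
        dapi = rng.poisson(np.clip(dapi, 0, None) * scale) / scale
        gh2ax = rng.poisson(np.clip(gh2ax, 0, None) * scale) / scale
    dapi = np.clip(dapi, 0.0, 1.0)
    gh2ax = np.clip(gh2ax, 0.0, 1.0)

    tile = ImageTile(
        dapi=dapi,
        gh2ax=gh2ax,
        pixel_size_um=spec.pixel_size_um,
        compartment=spec.compartment,
        structure=spec.structure,
    )
    return tile, GroundTruth(nuclei, labels)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass
class ArmEffects:
    """Effect parameters of one treatment arm.

    ``positive_fraction`` maps compartment (cortex/medulla) to the arm's
    mean fraction of damage-positive nuclei; per-animal fractions are
    drawn from a Gamma distribution with this mean and shape
    ``animal_fraction_shape`` (CV = shape**-0.5), which keeps the mean
    exact while staying positive.  ``lesion_grade_probs`` is one
    categorical distribution over grades 0-4 applied to all eight lesions.
    Hazards are per week.
    """

    positive_fraction: dict[str, float] = field(
        default_factory=lambda: {"cortex": 0.005, "medulla": 0.005}
    )
    animal_fraction_shape: float = 16.0
    lesion_grade_probs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)
    glomerulus_mean: float = 60.0
    biomarkers: dict[str, tuple[float, float]] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    hazard_per_week: float = 0.0
    censor_hazard_per_week: float = 0.0

    def __post_init__(self) -> None:
        for comp, f in self.positive_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"positive fraction for {comp} outside [0, 1]")
        probs = np.asarray(self.lesion_grade_probs, dtype=float)
        if len(probs) != 5 or np.any(probs < 0) or not math.isclose(probs.sum(), 1.0):
            raise ValueError("lesion_grade_probs must be 5 probabilities summing to 1")
        if self.hazard_per_week < 0 or self.censor_hazard_per_week < 0:
            raise ValueError("hazards must be >= 0")
        if self.glomerulus_mean < 0:
            raise ValueError("glomerulus mean must be >= 0")


@dataclass
class StudyDesign:
    """Four-arm study layout with per-arm effect parameters and seed."""

    arms: dict[str, ArmEffects]
    group_sizes: dict[tuple[str, int], int]  # (arm, endpoint weeks) -> n
    time_points_days: tuple[int, ...] = (1, 4, 8)
    time_points_weeks: tuple[int, ...] = (6, 12, 24)
    image_n_per_arm: int = 9
    ct_reference_mean: float = 20.0
    ct_target_offset: float = 5.0
    ct_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.arms) != set(ARMS):
            raise ValueError(f"arm names must be exactly {ARMS}")
        for key, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {key} must be positive")
        if self.image_n_per_arm <= 0:
            raise ValueError("image_n_per_arm must be positive")

    def animals(self, arm: str, endpoint_weeks: int) -> list[str]:
        n = self.group_sizes[(arm, endpoint_weeks)]
        return [f"{arm}-{endpoint_weeks}w-{i:02d}" for i in range(1, n + 1)]


def default_design(seed: int = 0) -> StudyDesign:
    """The default study conditions.

    Group sizes follow the long-term design (n = 9 per arm, except the
    radioligand arm with n = 7 at 12 weeks and n = 10 at 24 weeks, and
    controls n = 7/8/9 at 6/12/24 weeks).  Effect sizes emulate the
    reported pattern: strong damage in the radioligand arm, intermediate
    in the protected arm, background in control and protein-alone arms.
    """
    analytes = {
        "control": {
            "cystatin_c_ng_ml": (220.0, 30.0),
            "bun_mmol_l": (8.0, 1.2),
            "urine_albumin_ug_ml": (20.0, 6.0),
        },
        "lu": {
            "cystatin_c_ng_ml": (320.0, 45.0),
            "bun_mmol_l": (11.5, 1.8),
            "urine_albumin_ug_ml": (60.0, 18.0),
        },
        "lu_a1m": {
            "cystatin_c_ng_ml": (255.0, 35.0),
            "bun_mmol_l": (9.0, 1.4),
            "urine_albumin_ug_ml": (32.0, 10.0),
        },
        "a1m": {
            "cystatin_c_ng_ml": (220.0, 30.0),
            "bun_mmol_l": (8.0, 1.2),
            "urine_albumin_ug_ml": (20.0, 6.0),
        },
    }
    fold = {
        "control": {"Bax": 1.0, "Gadd45a": 1.0, "Tnfrsf10b": 1.0, "NGAL": 1.0},
        "lu": {"Bax": 2.6, "Gadd45a": 3.5, "Tnfrsf10b": 2.2, "NGAL": 6.0},
        "lu_a1m": {"Bax": 1.6, "Gadd45a": 2.0, "Tnfrsf10b": 1.4, "NGAL": 2.5},
        "a1m": {"Bax": 1.0, "Gadd45a": 1.0, "Tnfrsf10b": 1.0, "NGAL": 1.0},
    }
    arms = {
        "control": ArmEffects(
            positive_fraction={"cortex": 0.005, "medulla": 0.005},
            lesion_grade_probs=(0.8, 0.2, 0.0, 0.0, 0.0),
            glomerulus_mean=60.0,
            biomarkers=analytes["control"],
            fold_changes=fold["control"],
            hazard_per_week=0.0,
            censor_hazard_per_week=0.003,
        ),
        "lu": ArmEffects(
            positive_fraction={"cortex": 0.06, "medulla": 0.04},
            lesion_grade_probs=(0.05, 0.10, 0.25, 0.35, 0.25),
            glomerulus_mean=30.0,
            biomarkers=analytes["lu"],
            fold_changes=fold["lu"],
            hazard_per_week=0.0234,  # ~57% survival at 24 weeks
            censor_hazard_per_week=0.003,
        ),
        "lu_a1m": ArmEffects(
            positive_fraction={"cortex": 0.025, "medulla": 0.018},
            lesion_grade_probs=(0.30, 0.35, 0.25, 0.08, 0.02),
            glomerulus_mean=45.0,
            biomarkers=analytes["lu_a1m"],
            fold_changes=fold["lu_a1m"],
            hazard_per_week=0.00486,  # ~89% survival at 24 weeks
            censor_hazard_per_week=0.003,
        ),
        "a1m": ArmEffects(
            positive_fraction={"cortex": 0.005, "medulla": 0.005},
            lesion_grade_probs=(0.8, 0.2, 0.0, 0.0, 0.0),
            glomerulus_mean=60.0,
            biomarkers=analytes["a1m"],
            fold_changes=fold["a1m"],
            hazard_per_week=0.0,
            censor_hazard_per_week=0.003,
        ),
    }
    sizes: dict[tuple[str, int], int] = {}
    for arm in ARMS:
        for tp in (6, 12, 24):
            sizes[(arm, tp)] = 9
    sizes[("control", 6)], sizes[("control", 12)], sizes[("control", 24)] = 7, 8, 9
    sizes[("lu", 12)], sizes[("lu", 24)] = 7, 10
    return StudyDesign(arms=arms, group_sizes=sizes, seed=seed)


def _stream(design_seed: int, tag: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(design_seed), int(tag), *map(int, indices)])
    )


# ---------------------------------------------------------------------------
# Study-level image generation
# ---------------------------------------------------------------------------

#: fixed tile layout per section: six cortex subsections (the last two
#: centred on glomeruli) and three medulla subsections
_SECTION_LAYOUT = [("cortex", "tubular")] * 4 + [("cortex", "glomerular")] * 2 + [
    ("medulla", "tubular")
] * 3


def _animal_tile_plan(
    design: StudyDesign, arm: str, arm_idx: int, animal_idx: int, template: TileSpec
) -> list[tuple[TileSpec, int, str, int, int]]:
    """Per-animal tile specs and seeds: 2 sections x (6 cortex + 3 medulla).

    Returns tuples ``(spec, seed, animal_id, section, index)``.  The
    animal's per-compartment positive fractions are Gamma draws around the
    arm means.
    """
    effects = design.arms[arm]
    rng = _stream(design.seed, _TAG_TILES, arm_idx, animal_idx)
    animal_id = f"{arm}-img-{animal_idx:02d}"
    fractions = {}
    for comp, mean in effects.positive_fraction.items():
        if mean == 0:
            fractions[comp] = 0.0
        else:
            shape = effects.animal_fraction_shape
            fractions[comp] = min(1.0, rng.gamma(shape, mean / shape))
    plan = []
    for section in (1, 2):
        for idx, (comp, structure) in enumerate(_SECTION_LAYOUT):
            spec = replace(
                template,
                compartment=comp,
                structure=structure,
                positive_fraction=fractions[comp],
            )
            tile_seed = int(rng.integers(0, 2**31 - 1))
            plan.append((spec, tile_seed, animal_id, section, idx))
    return plan


def generate_study_images(design: StudyDesign, tile_template: TileSpec):
    """Yield ``(animal_id, arm, [(ImageTile, GroundTruth), ...])`` per animal.

    Each animal contributes 2 sections x (6 cortex + 3 medulla) = 18 tiles.
    """
    for arm_idx, arm in enumerate(ARMS):
        for animal_idx in range(1, design.image_n_per_arm + 1):
            plan = _animal_tile_plan(design, arm, arm_idx, animal_idx, tile_template)
            tiles = []
            for spec, tile_seed, animal_id, section, idx in plan:
                tile, truth = generate_tile(spec, tile_seed)
                tile.animal_id = animal_id
                tile.section_id = section
                tile.index = idx
                tiles.append((tile, truth))
            yield plan[0][2], arm, tiles


def study_truth_summaries(design: StudyDesign, tile_template: TileSpec) -> pd.DataFrame:
    """Planted per-subsection summaries without rasterising any pixels.

    The planted positive count per tile is ``round_half_away(f * n)`` — by
    construction identical to what :func:`generate_tile` would plant for
    the same plan — so cohort-level statistics can be exercised at scale.
    """
    rows = []
    for arm_idx, arm in enumerate(ARMS):
        for animal_idx in range(1, design.image_n_per_arm + 1):
            plan = _animal_tile_plan(design, arm, arm_idx, animal_idx, tile_template)
            for spec, _seed, animal_id, section, idx in plan:
                n_pos = round_half_away(spec.positive_fraction * spec.n_nuclei)
                rows.append(
                    {
                        "animal_id": animal_id,
                        "arm": arm,
                        "section_id": section,
                        "index": idx,
                        "compartment": spec.compartment,
                        "structure": spec.structure,
                        "n_nuclei": spec.n_nuclei,
                        "n_positive": n_pos,
                        "percent_positive": 100.0 * n_pos / spec.n_nuclei
                        if spec.n_nuclei
                        else 0.0,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Score sheets, biomarkers, survival, kinetics
# ---------------------------------------------------------------------------

def generate_scoresheets(
    design: StudyDesign, time_point_weeks: int = 24
) -> list[LesionScoreSheet]:
    """Per-animal ordinal lesion grades and glomerulus counts.

    Each of the eight lesions draws independently from the arm's
    categorical grade distribution; the glomerulus count is Poisson with
    the arm's mean.
    """
    sheets = []
    for arm_idx, arm in enumerate(ARMS):
        effects = design.arms[arm]
        for animal_idx, animal_id in enumerate(
            design.animals(arm, time_point_weeks), start=1
        ):
            rng = _stream(design.seed, _TAG_SCORES, time_point_weeks, arm_idx, animal_idx)
            grades = {
                lesion: int(rng.choice(5, p=effects.lesion_grade_probs))
                for lesion in LESIONS
            }
            sheets.append(
                LesionScoreSheet(
                    animal_id=animal_id,
                    arm=arm,
                    time_point_weeks=time_point_weeks,
                    grades=grades,
                    glomerulus_count=int(rng.poisson(effects.glomerulus_mean)),
                )
            )
    return sheets


def generate_biomarkers(
    design: StudyDesign,
    time_point_weeks: int = 24,
    outlier_offset_sd: float = 0.0,
    outliers_per_analyte: int = 0,
    reference_gene: str = "B2m",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gaussian analyte panel and a long-format qPCR Ct table.

    Analytes draw ``Normal(mean, sd)`` per the arm's parameters; if
    requested, the first ``outliers_per_analyte`` samples of the
    radioligand arm are displaced by ``outlier_offset_sd`` arm SDs.  Ct
    values are constructed so the implied fold change versus control
    equals the arm's nominal fold change in (geometric) expectation:
    ``dct = offset - log2(FC) + noise`` and ``ct_target = ct_ref + dct``.
    """
    bio_rows = []
    ct_rows = []
    genes = sorted(design.arms["control"].fold_changes)
    for arm_idx, arm in enumerate(ARMS):
        effects = design.arms[arm]
        for animal_idx, animal_id in enumerate(
            design.animals(arm, time_point_weeks), start=1
        ):
            rng = _stream(
                design.seed, _TAG_BIOMARKERS, time_point_weeks, arm_idx, animal_idx
            )
            for analyte, (mean, sd) in sorted(effects.biomarkers.items()):
                value = rng.normal(mean, sd)
                if (
                    arm == "lu"
                    and outliers_per_analyte > 0
                    and animal_idx <= outliers_per_analyte
                ):
                    value += outlier_offset_sd * sd
                bio_rows.append(
                    {"animal_id": animal_id, "arm": arm, "analyte": analyte, "value": value}
                )
            ct_ref = rng.normal(design.ct_reference_mean, design.ct_sd)
            ct_rows.append(
                {"sample_id": animal_id, "arm": arm, "gene": reference_gene, "ct": ct_ref}
            )
            for gene in genes:
                fc = effects.fold_changes.get(gene, 1.0)
                dct = design.ct_target_offset - math.log2(fc) + rng.normal(0, design.ct_sd)
                ct_rows.append(
                    {"sample_id": animal_id, "arm": arm, "gene": gene, "ct": ct_ref + dct}
                )
    return pd.DataFrame(bio_rows), pd.DataFrame(ct_rows)


def generate_survival(design: StudyDesign) -> list[SurvivalRecord]:
    """Exponential event and censoring times, rounded to whole weeks.

    Radiation-related deaths draw their necropsy findings from the
    radiation list, humane-endpoint removals from the humane list, and
    scheduled sacrifices carry no findings — so re-running the outcome
    classifier on the findings reproduces the generated labels.
    """
    records = []
    rad_terms = sorted(RADIATION_FINDINGS)
    hum_terms = sorted(HUMANE_FINDINGS)
    for arm_idx, arm in enumerate(ARMS):
        effects = design.arms[arm]
        for tp in design.time_points_weeks:
            if (arm, tp) not in design.group_sizes:
                continue
            for animal_idx, animal_id in enumerate(design.animals(arm, tp), start=1):
                rng = _stream(design.seed, _TAG_SURVIVAL, tp, arm_idx, animal_idx)
                t_event = (
                    rng.exponential(1.0 / effects.hazard_per_week)
                    if effects.hazard_per_week > 0
                    else math.inf
                )
                t_cens = (
                    rng.exponential(1.0 / effects.censor_hazard_per_week)
                    if effects.censor_hazard_per_week > 0
                    else math.inf
                )
                if t_event < tp and t_event <= t_cens:
                    context = "died"
                    findings = frozenset(
                        rng.choice(rad_terms, size=int(rng.integers(1, 3)), replace=False)
                    )
                    week = round_half_away(t_event)
                elif t_cens < tp:
                    context = "terminated_humane_endpoint"
                    findings = frozenset([str(rng.choice(hum_terms))])
                    week = round_half_away(t_cens)
                else:
                    context = "scheduled_sacrifice"
                    findings = frozenset()
                    week = tp
                status, reason = classify_outcome(findings, context)
                records.append(
                    SurvivalRecord(
                        animal_id=animal_id,
                        arm=arm,
                        time_weeks=week,
                        status=status,
                        findings=findings,
                        context=context,
                        censor_reason=reason,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsSpec:
    """Multi-exponential kidney kinetics: amplitudes with biological
    clearance constants, combined with physical decay."""

    amplitudes_mbq: tuple[float, ...] = (5.0,)
    lambda_bio_per_h: tuple[float, ...] = (0.02,)
    physical_half_life_days: float = 6.73
    sampling_times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 169, 4))
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.amplitudes_mbq) != len(self.lambda_bio_per_h):
            raise ValueError("amplitudes and decay constants must pair up")
        if any(a < 0 for a in self.amplitudes_mbq):
            raise ValueError("amplitudes must be >= 0")
        if any(l <= 0 for l in self.lambda_bio_per_h):
            raise ValueError("biological decay constants must be > 0")
        t = np.asarray(self.sampling_times_h)
        if len(t) and t[0] < 0:
            raise ValueError("first sampling time must be >= 0")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must be strictly increasing")

    @property
    def lambda_phys_per_h(self) -> float:
        return math.log(2.0) / days_to_hours(self.physical_half_life_days)

    @property
    def effective_lambdas_per_h(self) -> tuple[float, ...]:
        return tuple(l + self.lambda_phys_per_h for l in self.lambda_bio_per_h)


def generate_time_activity(spec: KineticsSpec, seed: int = 0) -> TimeActivityCurve:
    """Evaluate the multi-exponential activity at the sampling times.

    Noise is off by default; with ``noise_sd > 0`` multiplicative Gaussian
    noise is applied and clipped at zero.
    """
    t = np.asarray(spec.sampling_times_h, dtype=float)
    a = np.zeros_like(t)
    for amp, lam in zip(spec.amplitudes_mbq, spec.effective_lambdas_per_h):
        a += amp * np.exp(-lam * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
        a = np.clip(a * (1.0 + rng.normal(0, spec.noise_sd, a.shape)), 0.0, None)
    return TimeActivityCurve(times_h=t, activities_mbq=a)
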