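"""Histopathology scoring: eight kidney lesions graded 0-4, plus the count
of morphologically normal glomeruli in one central sagittal section.

Grading is pathologist data entry, not image computation; this module
enforces structure, computes per-animal totals and group summaries, and
hands the totals to the ordinal statistics (Kruskal-Wallis + Dunn) and the
glomerulus counts to ANOVA + Tukey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarker_stats import (
    RESTRICTED_PAIRS,
    ComparisonReport,
    kruskal_dunn,
    tukey_hsd,
)

__all__ = [
    "LESIONS",
    "GRADE_LABELS",
    "ScoreSheetError",
    "LesionScoreSheet",
    "validate_scoresheet",
    "total_lesion_score",
    "group_lesion_summary",
    "glomerulus_comparison",
    "scoresheets_to_frame",
    "frame_to_scoresheets",
]

#: The eight scored lesions: cortical atrophy, medullary atrophy, cortical
#: and medullary interstitial fibrosis, glomerular findings, cortical
#: tubular findings, cortical inflammatory findings, and collecting-duct
#: findings in the medulla.
LESIONS = (
    "cortex_atrophy",
    "medulla_atrophy",
    "cortex_fibrosis",
    "medulla_fibrosis",
    "glomerular_findings",
    "tubular_findings_cortex",
    "inflammatory_findings_cortex",
    "collecting_duct_findings",
)

GRADE_LABELS = {0: "normal", 1: "minimal", 2: "mild", 3: "moderate", 4: "marked"}


class ScoreSheetError(ValueError):
    pass


@dataclass
class LesionScoreSheet:
    animal_id: str
    arm: str
    time_point_weeks: int
    grades: dict[str, int] = field(default_factory=dict)
    glomerulus_count: int | None = None


def validate_scoresheet(sheet: LesionScoreSheet) -> LesionScoreSheet:
    """Check that all eight lesions are present with integer grades 0-4."""
    keys = set(sheet.grades)
    missing = set(LESIONS) - keys
    extra = keys - set(LESIONS)
    if missing:
        raise ScoreSheetError(f"{sheet.animal_id}: missing lesion(s) {sorted(missing)}")
    if extra:
        raise ScoreSheetError(f"{sheet.animal_id}: unknown lesion(s) {sorted(extra)}")
    for lesion, grade in sheet.grades.items():
        if not isinstance(grade, (int, np.integer)) or not 0 <= int(grade) <= 4:
            raise ScoreSheetError(
                f"{sheet.animal_id}: grade {grade!r} for {lesion} outside 0-4"
            )
    if sheet.glomerulus_count is not None and (
        sheet.glomerulus_count < 0 or int(sheet.glomerulus_count) != sheet.glomerulus_count
    ):
        raise ScoreSheetError(f"{sheet.animal_id}: glomerulus count must be a non-negative integer")
    return sheet


def total_lesion_score(sheet: LesionScoreSheet) -> int:
    """Sum of the eight grades; bounded [0, 32]."""
    validate_scoresheet(sheet)
    return int(sum(sheet.grades[k] for k in LESIONS))


def group_lesion_summary(
    sheets: list[LesionScoreSheet],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray]]:
    """Per-arm mean total score, per-lesion mean grade, and the per-arm
    totals ready for Kruskal-Wallis/Dunn.

    Returns ``(arm_summary, lesion_means, totals_by_arm)``.
    """
    if not sheets:
        raise ScoreSheetError("no score sheets")
    rows = []
    for s in sheets:
        validate_scoresheet(s)
        row = {"animal_id": s.animal_id, "arm": s.arm, "total": total_lesion_score(s)}
        row.update({k: s.grades[k] for k in LESIONS})
        rows.append(row)
    df = pd.DataFrame(rows)
    arm_summary = (
        df.groupby("arm")["total"].agg(mean_total="mean", n="count").reset_index()
    )
    lesion_means = df.groupby("arm")[list(LESIONS)].mean().reset_index()
    totals_by_arm = {
        arm: sub["total"].to_numpy(dtype=float) for arm, sub in df.groupby("arm")
    }
    return arm_summary, lesion_means, totals_by_arm


def lesion_score_comparison(
    sheets: list[LesionScoreSheet],
    restricted_pairs=RESTRICTED_PAIRS,
) -> ComparisonReport:
    """Kruskal-Wallis + Dunn on the per-animal total lesion scores."""
    _, _, totals = group_lesion_summary(sheets)
    return kruskal_dunn(totals, restricted_pairs, analyte="total_lesion_score")


def glomerulus_comparison(
    sheets: list[LesionScoreSheet],
    restricted_pairs=RESTRICTED_PAIRS,
) -> ComparisonReport:
    """ANOVA + Tukey on the per-animal normal-glomerulus counts."""
    counts: dict[str, list[float]] = {}
    for s in sheets:
        if s.glomerulus_count is None:
            raise ScoreSheetError(f"{s.animal_id}: no glomerulus count")
        counts.setdefault(s.arm, []).append(float(s.glomerulus_count))
    return tukey_hsd(
        {a: np.asarray(v) for a, v in counts.items()},
        restricted_pairs,
        analyte="glomerulus_count",
    )


# -- CSV round trip ---------------------------------------------------------

def scoresheets_to_frame(sheets: list[LesionScoreSheet]) -> pd.DataFrame:
    rows = []
    for s in sheets:
        validate_scoresheet(s)
        row = {
            "animal_id": s.animal_id,
            "arm": s.arm,
            "time_point_weeks": s.time_point_weeks,
            "glomerulus_count": s.glomerulus_count,
        }
        row.update({k: s.grades[k] for k in LESIONS})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_scoresheets(df: pd.DataFrame) -> list[LesionScoreSheet]:
    sheets = []
    for _, row in df.iterrows():
        gc = row.get("glomerulus_count")
        sheets.append(
            validate_scoresheet(
                LesionScoreSheet(
                    animal_id=str(row["animal_id"]),
                    arm=str(row["arm"]),
                    time_point_weeks=int(row["time_point_weeks"]),
                    grades={k: int(row[k]) for k in LESIONS},
                    glomerulus_count=None if pd.isna(gc) else int(gc),
                )
            )
        )
    return sheets
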