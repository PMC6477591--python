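"""Lesion scoring: simulate score sheets and compare arms.

Writes results/histopath/ with arm summaries, per-lesion means, the
lesion-score comparisons (Kruskal-Wallis + Dunn on the restricted pair
set) and the glomerulus-count comparisons (ANOVA + Tukey).
"""

from pathlib import Path

from nephroshield.histopath import (
    glomerulus_comparison,
    group_lesion_summary,
    lesion_score_comparison,
    scoresheets_to_frame,
)
from nephroshield.synthetic_data import default_design, generate_scoresheets

SEED = 20242
OUT = Path(__file__).resolve().parents[1] / "results" / "histopath"


def main() -> None:
    sheets = generate_scoresheets(default_design(SEED))
    OUT.mkdir(parents=True, exist_ok=True)
    scoresheets_to_frame(sheets).to_csv(OUT / "score_sheets.csv", index=False)
    arm_summary, lesion_means, _ = group_lesion_summary(sheets)
    arm_summary.to_csv(OUT / "arm_summary.csv", index=False)
    lesion_means.to_csv(OUT / "lesion_means.csv", index=False)
    lesion_score_comparison(sheets).as_frame().to_csv(
        OUT / "lesion_comparisons.csv", index=False
    )
    glomerulus_comparison(sheets).as_frame().to_csv(
        OUT / "glomerulus_comparisons.csv", index=False
    )
    print(arm_summary.to_string(index=False))


if __name__ == "__main__":
    main()
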