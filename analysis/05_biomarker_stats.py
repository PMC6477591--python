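"""Biomarkers and gene expression: outlier removal, group comparisons,
relative expression and the colour-binned heat map table.

Writes results/biomarkers/.
"""

from pathlib import Path

import pandas as pd

from nephroshield.biomarker_stats import compare_groups, delta_delta_ct, heatmap_bin
from nephroshield.synthetic_data import default_design, generate_biomarkers

SEED = 20243
REFERENCE_GENE = "B2m"
OUT = Path(__file__).resolve().parents[1] / "results" / "biomarkers"


def main() -> None:
    design = default_design(SEED)
    bio, ct = generate_biomarkers(design, outlier_offset_sd=8.0, outliers_per_analyte=1)
    OUT.mkdir(parents=True, exist_ok=True)
    bio.to_csv(OUT / "biomarkers.csv", index=False)

    frames = []
    for analyte, sel in bio.groupby("analyte"):
        groups = {arm: g["value"].to_numpy() for arm, g in sel.groupby("arm")}
        frames.append(compare_groups(groups, method="anova", analyte=analyte).as_frame())
    pd.concat(frames).to_csv(OUT / "biomarker_comparisons.csv", index=False)

    expr = delta_delta_ct(ct, reference_gene=REFERENCE_GENE)
    expr.to_csv(OUT / "expression.csv", index=False)
    heat = (
        expr[expr["gene"] != REFERENCE_GENE]
        .groupby(["arm", "gene"])["fold_change"]
        .mean()
        .reset_index()
    )
    heat["bin"] = heat["fold_change"].map(heatmap_bin)
    heat.to_csv(OUT / "expression_heatmap.csv", index=False)
    print(heat.to_string(index=False))


if __name__ == "__main__":
    main()
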