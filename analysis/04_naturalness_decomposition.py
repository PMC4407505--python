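"""Decompose perceived naturalness into modeled and non-modeled parts.

Regresses the per-image mean naturalness rating on the 10 features; the
fitted value is the bottom-up, feature-modeled component and the residual
the non-modeled component. Color-only and structure-only sub-models give
the two modeled sub-components. Writes results/split.csv and
results/naturalness_fit.json.
"""

import argparse
from pathlib import Path

import pandas as pd

from scenestats import io
from scenestats.naturalness import decompose_naturalness

parser = argparse.ArgumentParser()
parser.add_argument("--results-dir", type=Path, default=Path("results"))
args = parser.parse_args()

features = io.read_feature_table(args.results_dir / "features.csv")
summary = pd.read_csv(args.results_dir / "image_summary.csv")
merged = features.merge(summary, on="image_id")

split = decompose_naturalness(merged, merged["mean_naturalness"])
split.table.to_csv(args.results_dir / "split.csv", index=False)
io.write_json(
    {
        "full": split.full_fit.to_dict(),
        "color_only": split.color_fit.to_dict(),
        "structure_only": split.structure_fit.to_dict(),
    },
    args.results_dir / "naturalness_fit.json",
)

for name, fit in (
    ("10 features", split.full_fit),
    ("color only ", split.color_fit),
    ("structure  ", split.structure_fit),
):
    print(
        f"naturalness ~ {name}: R2 = {fit.r2:.3f} (adj {fit.adj_r2:.3f}), "
        f"F({fit.df_model},{fit.df_resid}) = {fit.f_stat:.2f}"
    )
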