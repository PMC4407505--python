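"""Preference regressions: features, naturalness components, RT moderation.

Fits the standardized preference-on-features model, the simple
preference-on-naturalness regression, the two RT-moderation models (does
the link between a naturalness component and preference depend on how fast
the preference judgment was made?), their simple slopes at fast / mean /
slow RT, and the color x structure decomposition model. Writes
results/preference_report.json.
"""

import argparse
from pathlib import Path

import pandas as pd

from scenestats import io
from scenestats.preference import (
    color_structure_model,
    preference_on_features,
    preference_on_naturalness,
    rt_interaction_model,
    simple_slopes,
)

parser = argparse.ArgumentParser()
parser.add_argument("--results-dir", type=Path, default=Path("results"))
args = parser.parse_args()

features = io.read_feature_table(args.results_dir / "features.csv")
summary = pd.read_csv(args.results_dir / "image_summary.csv")
split = pd.read_csv(args.results_dir / "split.csv")
merged = features.merge(summary, on="image_id").merge(split, on="image_id")
pref = merged["mean_preference"]

report = {}
fit = preference_on_features(merged, pref)
report["preference_on_features"] = fit.to_dict()
print(f"preference ~ features (standardized): adj R2 = {fit.adj_r2:.3f}")

nat_fit = preference_on_naturalness(merged["mean_naturalness"], pref)
report["preference_on_naturalness"] = nat_fit.to_dict()
print(
    f"preference ~ naturalness: slope = {nat_fit.params['naturalness']:.3f}, "
    f"R2 = {nat_fit.r2:.3f}"
)

for label in ("modeled", "non_modeled"):
    inter = rt_interaction_model(pref, merged[label], merged["mean_z_rt"], label)
    ss = simple_slopes(inter)
    report[f"rt_x_{label}"] = inter.fit.to_dict()
    report[f"simple_slopes_{label}"] = ss.as_dict()
    print(
        f"preference ~ {label} x RT: main {inter.b_component:+.3f}, "
        f"interaction {inter.b_interaction:+.3f}; slopes fast/mean/slow = "
        + "/".join(f"{s:+.3f}" for s in ss.slopes)
    )

class _SplitView:
    table = merged

cs = color_structure_model(pref, _SplitView())
report["color_structure"] = cs.to_dict()
print(
    "preference ~ color + structure + non-modeled + color x structure: "
    + ", ".join(f"{k} {v:+.3f}" for k, v in cs.params.items())
)
io.write_json(report, args.results_dir / "preference_report.json")
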