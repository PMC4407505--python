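"""Quadratic-discriminant classification of preferred vs. non-preferred.

Median-splits mean preference into high/low classes and scores pairwise
leave-one-out QD accuracy for five predictor sets: the 7-feature subset,
modeled naturalness alone, non-modeled naturalness alone, both naturalness
components, and features plus non-modeled naturalness. Optionally re-runs
backward feature elimination from all 10 features. Writes
results/qd_report.json.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from scenestats import io
from scenestats.classify import backward_elimination, loo_pairwise_accuracy, median_split
from scenestats.image_features import FEATURE_NAMES
from scenestats.reference import QD_FEATURE_SUBSET

parser = argparse.ArgumentParser()
parser.add_argument("--results-dir", type=Path, default=Path("results"))
parser.add_argument("--eliminate", action="store_true", help="re-run backward elimination")
args = parser.parse_args()

features = io.read_feature_table(args.results_dir / "features.csv")
summary = pd.read_csv(args.results_dir / "image_summary.csv")
split = pd.read_csv(args.results_dir / "split.csv")
merged = features.merge(summary, on="image_id").merge(split, on="image_id")

labels = median_split(merged["mean_preference"].to_numpy())
subset = list(QD_FEATURE_SUBSET)
predictor_sets = {
    "features": merged[subset].to_numpy(),
    "modeled": merged[["modeled"]].to_numpy(),
    "non_modeled": merged[["non_modeled"]].to_numpy(),
    "modeled+non_modeled": merged[["modeled", "non_modeled"]].to_numpy(),
    "features+non_modeled": np.column_stack(
        [merged[subset].to_numpy(), merged["non_modeled"].to_numpy()]
    ),
}
report = {
    "subset": subset,
    "class_sizes": {c: int((labels == c).sum()) for c in ("high", "low")},
    "accuracy": {},
}
print(f"median split: {report['class_sizes']} (chance = 50%)")
for name, X in predictor_sets.items():
    acc = loo_pairwise_accuracy(X, labels).accuracy
    report["accuracy"][name] = acc
    print(f"  {name:22s} pairwise-LOO accuracy {acc:6.1%}")

if args.eliminate:
    best, trace = backward_elimination(
        merged[list(FEATURE_NAMES)].to_numpy(), labels, FEATURE_NAMES
    )
    report["backward_elimination"] = {
        "best_subset": list(best),
        "trace": [{"subset": list(s), "accuracy": a} for s, a in trace],
    }
    print(f"backward elimination kept {list(best)} at {trace[-1][1]:.1%}")

io.write_json(report, args.results_dir / "qd_report.json")
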