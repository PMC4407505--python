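"""Generate the synthetic stimulus set and extract its image features.

Renders scenes along a natural-to-built gradient (curved green textured
fields at one end, desaturated straight-line grids at the other), computes
the 10 low-level features per image, and writes results/features.csv.
"""

import argparse
from pathlib import Path

import numpy as np

from scenestats import io
from scenestats.pipeline import RunConfig, extract_feature_table, simulate_images

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-images", type=int, default=80)
parser.add_argument("--results-dir", type=Path, default=Path("results"))
args = parser.parse_args()

config = RunConfig(seed=args.seed, n_images=args.n_images)
images, ids = simulate_images(config)
features = extract_feature_table(images, ids, config.edge, config.straight)
features = features.dropna().reset_index(drop=True)

args.results_dir.mkdir(exist_ok=True)
io.write_feature_table(features, args.results_dir / "features.csv")

print(f"generated {len(features)} scenes ({config.image_height}x{config.image_width})")
for col in ("ed", "sed", "der", "hue", "sat", "entropy"):
    print(f"  {col:8s} mean {features[col].mean():.3f}  sd {features[col].std():.3f}")
print(
    "straight-edge density and disorganized-edge ratio anticorrelate: "
    f"r = {np.corrcoef(features['sed'], features['der'])[0, 1]:.2f}"
)
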