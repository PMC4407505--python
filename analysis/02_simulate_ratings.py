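"""Simulate participant ratings for the generated stimulus set.

Each simulated participant rates every image for naturalness (generated
from the reference 10-feature linear model plus rating noise) and
preference (from the standardized reference betas), with reaction times
that shorten as the image's feature-modeled naturalness rises. Writes
results/ratings.csv.
"""

import argparse
from pathlib import Path

from scenestats import io
from scenestats.synthetic import RatingSimSpec, simulate_ratings

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-participants", type=int, default=20)
parser.add_argument("--results-dir", type=Path, default=Path("results"))
args = parser.parse_args()

features = io.read_feature_table(args.results_dir / "features.csv")
spec = RatingSimSpec(n_participants=args.n_participants, seed=args.seed + 1)
ratings = simulate_ratings(features, spec)
io.write_ratings(ratings, args.results_dir / "ratings.csv")

print(
    f"simulated {spec.n_participants} participants x {features.shape[0]} images "
    f"({len(ratings)} rating rows)"
)
print(
    "  naturalness range "
    f"[{ratings['naturalness'].min():.2f}, {ratings['naturalness'].max():.2f}], "
    f"mean RT {ratings['rt'].mean():.2f} s"
)
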