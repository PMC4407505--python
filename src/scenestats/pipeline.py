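"""End-to-end orchestration: simulate/extract -> aggregate -> decompose ->
preference models -> classification, with a JSON-serializable run config
and a manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, reference
from .classify import backward_elimination, loo_pairwise_accuracy, median_split
from .image_features import (
    FEATURE_NAMES,
    EdgeConfig,
    StraightConfig,
    extract_features,
)
from .naturalness import decompose_naturalness
from .preference import (
    color_structure_model,
    preference_on_features,
    preference_on_naturalness,
    rt_interaction_model,
    simple_slopes,
)
from .ratings import aggregate_means, order_effect_test, zscore_rt
from .synthetic import RatingSimSpec, SceneSpec, generate_scene, simulate_ratings

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (JSON round-trippable)."""

    seed: int = 0
    n_images: int = 80
    n_participants: int = 20
    image_height: int = 96
    image_width: int = 128
    images_dir: str | None = None  # extract from files instead of simulating
    ratings_csv: str | None = None  # load ratings instead of simulating
    simulate: bool = True
    save_images: bool = False
    naturalness_noise_sd: float = 0.9
    preference_noise_sd: float = 0.8
    qd_subset: tuple[str, ...] = reference.QD_FEATURE_SUBSET
    run_backward_elimination: bool = False
    edge: EdgeConfig = field(default_factory=EdgeConfig)
    straight: StraightConfig = field(default_factory=StraightConfig)
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "edge" in data:
            data["edge"] = EdgeConfig(**data["edge"])
        if "straight" in data:
            data["straight"] = StraightConfig(**data["straight"])
        if "qd_subset" in data:
            data["qd_subset"] = tuple(data["qd_subset"])
        return cls(**data)


def random_scene_spec(
    rng: np.random.Generator, naturalness: float, size: tuple[int, int], seed: int
) -> SceneSpec:
    """A scene spec along a naturalness gradient u in [0, 1].

    u = 0 is grid-like and desaturated (built), u = 1 is curved, green and
    saturation-graded (natural); primitive counts and color parameters
    interpolate in between.
    """
    u = float(naturalness)
    return SceneSpec(
        size=size,
        n_straight_lines=int(round(10 * (1 - u))),
        n_curves=int(round(6 * u)),
        # natural end: yellow-green, desaturated but saturation-diverse;
        # built end: bluish-gray, uniformly saturated
        base_hue=0.55 - 0.25 * u,
        hue_jitter=0.01 + 0.05 * u,
        base_sat=0.55 - 0.25 * u,
        sat_gradient_amplitude=0.05 + 0.25 * u,
        texture_noise_sd=0.02 * u,
        orientation_mode="cardinal" if u < 0.5 else "canonical",
        seed=seed,
    )


def simulate_images(config: RunConfig) -> tuple[list[np.ndarray], list[str]]:
    rng = np.random.default_rng(config.seed)
    size = (config.image_height, config.image_width)
    images, ids = [], []
    for i in range(config.n_images):
        u = rng.uniform()
        seed = int(rng.integers(0, 2**31 - 1))
        scene = generate_scene(random_scene_spec(rng, u, size, seed))
        images.append(scene.pixels)
        ids.append(f"img{i:04d}")
    return images, ids


def extract_feature_table(
    images: list[np.ndarray],
    image_ids: list[str],
    edge: EdgeConfig | None = None,
    straight: StraightConfig | None = None,
) -> pd.DataFrame:
    rows = []
    for img, image_id in zip(images, image_ids):
        feats = extract_features(img, edge, straight)
        rows.append({"image_id": image_id, **feats})
    return pd.DataFrame(rows, columns=["image_id", *FEATURE_NAMES])


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@_stage("features")
def _features_stage(config: RunConfig, out: Path) -> pd.DataFrame:
    if config.images_dir:
        paths = io.iter_image_paths(config.images_dir)
        if not paths:
            raise ValueError(f"no images found in {config.images_dir}")
        images = [io.read_image(p) for p in paths]
        ids = [p.stem for p in paths]
    else:
        images, ids = simulate_images(config)
        if config.save_images:
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            for img, image_id in zip(images, ids):
                io.save_scene(img, img_dir / f"{image_id}.png")
    features = extract_feature_table(images, ids, config.edge, config.straight)
    if features[list(FEATURE_NAMES)].isna().any().any():
        # edgeless images have undefined DER; drop them from the analysis set
        bad = features[features[list(FEATURE_NAMES)].isna().any(axis=1)]
        logger.warning("dropping %d images with undefined features", len(bad))
        features = features.dropna().reset_index(drop=True)
    io.write_feature_table(features, out / "features.csv")
    return features


@_stage("ratings")
def _ratings_stage(config: RunConfig, features: pd.DataFrame, out: Path) -> pd.DataFrame:
    if config.ratings_csv:
        ratings = io.read_ratings(config.ratings_csv)
    elif config.simulate:
        spec = RatingSimSpec(
            n_participants=config.n_participants,
            naturalness_noise_sd=config.naturalness_noise_sd,
            preference_noise_sd=config.preference_noise_sd,
            seed=config.seed + 1,
        )
        ratings = simulate_ratings(features, spec)
    else:
        raise ValueError("no ratings source: set ratings_csv or simulate=true")
    io.write_ratings(ratings, out / "ratings.csv")
    return ratings


@_stage("aggregate")
def _aggregate_stage(ratings: pd.DataFrame, out: Path) -> tuple[pd.DataFrame, dict]:
    ratings = zscore_rt(ratings)
    summary = aggregate_means(ratings)
    _, order = order_effect_test(ratings, "preference")
    _, order_nat = order_effect_test(ratings, "naturalness")
    summary.to_csv(out / "image_summary.csv", index=False)
    report = {"preference": order, "naturalness": order_nat}
    io.write_json(report, out / "order_effect.json")
    return summary, report


@_stage("decompose")
def _decompose_stage(features: pd.DataFrame, summary: pd.DataFrame, out: Path):
    merged = features.merge(summary, on="image_id")
    split = decompose_naturalness(merged, merged["mean_naturalness"])
    split.table.to_csv(out / "split.csv", index=False)
    io.write_json(
        {
            "full": split.full_fit.to_dict(),
            "color_only": split.color_fit.to_dict(),
            "structure_only": split.structure_fit.to_dict(),
        },
        out / "naturalness_fit.json",
    )
    return split, merged


@_stage("preference")
def _preference_stage(merged: pd.DataFrame, split, out: Path) -> dict:
    pref = merged["mean_preference"]
    report = {
        "preference_on_features": preference_on_features(merged, pref).to_dict(),
        "preference_on_naturalness": preference_on_naturalness(
            merged["mean_naturalness"], pref
        ).to_dict(),
    }
    for label, comp in (
        ("modeled", split.table["modeled"]),
        ("non_modeled", split.table["non_modeled"]),
    ):
        inter = rt_interaction_model(pref, comp, merged["mean_z_rt"], label)
        report[f"rt_x_{label}"] = inter.fit.to_dict()
        report[f"simple_slopes_{label}"] = simple_slopes(inter).as_dict()
    report["color_structure"] = color_structure_model(pref, split).to_dict()
    io.write_json(report, out / "preference_report.json")
    return report


@_stage("classify")
def _classify_stage(
    config: RunConfig, merged: pd.DataFrame, split, out: Path
) -> dict:
    labels = median_split(merged["mean_preference"].to_numpy())
    subset = list(config.qd_subset)
    predictor_sets = {
        "features": merged[subset].to_numpy(),
        "modeled": split.table[["modeled"]].to_numpy(),
        "non_modeled": split.table[["non_modeled"]].to_numpy(),
        "modeled+non_modeled": split.table[["modeled", "non_modeled"]].to_numpy(),
        "features+non_modeled": np.column_stack(
            [merged[subset].to_numpy(), split.table["non_modeled"].to_numpy()]
        ),
    }
    report: dict = {"subset": subset, "class_sizes": {
        "high": int((labels == "high").sum()),
        "low": int((labels == "low").sum()),
    }}
    report["accuracy"] = {
        name: loo_pairwise_accuracy(X, labels).accuracy
        for name, X in predictor_sets.items()
    }
    if config.run_backward_elimination:
        best, trace = backward_elimination(
            merged[list(FEATURE_NAMES)].to_numpy(), labels, FEATURE_NAMES
        )
        report["backward_elimination"] = {
            "best_subset": list(best),
            "trace": [{"subset": list(s), "accuracy": a} for s, a in trace],
        }
    io.write_json(report, out / "qd_report.json")
    return report


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write outputs plus a manifest into ``out_dir``.

    Identical config + seed produce byte-identical CSV/JSON outputs; the
    manifest records the config, the seed and a SHA-256 per output file.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = _features_stage(config, out)
    ratings = _ratings_stage(config, features, out)
    summary, _ = _aggregate_stage(ratings, out)
    split, merged = _decompose_stage(features, summary, out)
    _preference_stage(merged, split, out)
    _classify_stage(config, merged, split, out)

    outputs = sorted(
        p for p in out.iterdir() if p.suffix in {".csv", ".json"} and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    io.write_json(manifest, out / "manifest.json")
    return out
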