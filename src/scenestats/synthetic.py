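"""Synthetic scenes and simulated rating data.

Two families of generators:

* parametric scene images with controllable straight/curved edge content
  and HSV color composition, standing in for photographs of natural and
  built environments;
* simulated participant ratings (naturalness, preference, reaction times)
  whose generating equations are the reference regression models, so that
  every downstream analysis stage can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import circle_perimeter, line

from . import reference
from .image_features import FEATURE_NAMES


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    The base field is an HSV canvas: per-pixel hue jittered uniformly around
    ``base_hue``, a vertical saturation gradient of amplitude
    ``sat_gradient_amplitude`` around ``base_sat``, and Gaussian brightness
    texture of SD ``texture_noise_sd`` around ``base_bright``. On top of it,
    ``n_straight_lines`` straight segments (length >= min_line_length px) and
    ``n_curves`` circular contours are drawn at a brightness contrast of
    ``primitive_contrast``.

    ``orientation_mode`` controls line angles: ``canonical`` (default) draws
    at 0/45/90/135 degrees, where rasterized segments are exactly collinear
    and the straightness criterion certifies them at any length;
    ``cardinal`` restricts to horizontal/vertical (a grid-like built
    scene); ``free`` draws arbitrary angles, whose raster staircase only
    passes the strict straightness criterion for long segments
    (roughly > 100 px).
    """

    size: tuple[int, int] = (96, 128)
    n_straight_lines: int = 0
    n_curves: int = 0
    base_hue: float = 0.33
    hue_jitter: float = 0.03
    base_sat: float = 0.45
    sat_gradient_amplitude: float = 0.2
    base_bright: float = 0.6
    texture_noise_sd: float = 0.0
    primitive_contrast: float = 0.35
    min_line_length: int = 40
    line_thickness: int = 3
    orientation_mode: str = "canonical"  # canonical | cardinal | free
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_straight_lines < 0 or self.n_curves < 0:
            raise ValueError("primitive counts must be >= 0")
        for name in ("base_hue", "hue_jitter", "base_sat", "base_bright"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.orientation_mode not in ("canonical", "cardinal", "free"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")
        H, W = self.size
        if min(H, W) < self.min_line_length + 8:
            raise ValueError(
                "image too small for the requested minimum line length"
            )


@dataclass
class SceneImage:
    """A generated scene: 8-bit RGB pixels plus generation bookkeeping."""

    pixels: np.ndarray  # H x W x 3 uint8
    n_straight_lines: int
    n_curves: int
    line_pixel_counts: list[int] = field(default_factory=list)
    expected_line_lengths: list[int] = field(default_factory=list)


def _draw_line(
    rng: np.random.Generator, spec: SceneSpec, bright: np.ndarray
) -> tuple[int, int]:
    """Draw one straight segment; returns (pixels drawn, Bresenham length)."""
    H, W = spec.size
    margin = 3
    max_len = min(H, W) - 2 * margin - 1
    L = int(rng.integers(spec.min_line_length, max_len + 1))
    if spec.orientation_mode == "canonical":
        theta = rng.choice([0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4])
    elif spec.orientation_mode == "cardinal":
        theta = rng.choice([0.0, np.pi / 2])
    else:
        theta = rng.uniform(0.0, np.pi)
    dr = int(round(L * np.sin(theta)))
    dc = int(round(L * np.cos(theta)))
    r0 = int(rng.integers(margin + max(0, -dr), H - margin - max(0, dr)))
    c0 = int(rng.integers(margin + max(0, -dc), W - margin - max(0, dc)))
    value = spec.base_bright + rng.choice([-1.0, 1.0]) * spec.primitive_contrast
    value = float(np.clip(value, 0.0, 1.0))
    # perpendicular offsets give the line its thickness
    perp = np.array([np.cos(theta), -np.sin(theta)])
    n_central = 0
    for k in range(spec.line_thickness):
        off = (k - (spec.line_thickness - 1) // 2) * perp
        orr, occ = int(round(off[0])), int(round(off[1]))
        rr, cc = line(r0 + orr, c0 + occ, r0 + dr + orr, c0 + dc + occ)
        keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        bright[rr[keep], cc[keep]] = value
        if orr == 0 and occ == 0:
            n_central = int(keep.sum())
    return n_central, max(abs(dr), abs(dc)) + 1


def _draw_curve(
    rng: np.random.Generator, spec: SceneSpec, bright: np.ndarray
) -> None:
    """Draw one circular contour, fully inside the canvas."""
    H, W = spec.size
    radius = int(rng.integers(12, max(13, min(H, W) // 4)))
    r = int(rng.integers(radius + 2, H - radius - 2))
    c = int(rng.integers(radius + 2, W - radius - 2))
    value = spec.base_bright + rng.choice([-1.0, 1.0]) * spec.primitive_contrast
    value = float(np.clip(value, 0.0, 1.0))
    for dr in (-1, 0, 1):
        rr, cc = circle_perimeter(r + dr, c, radius, shape=(H, W))
        bright[rr, cc] = value


def generate_scene(spec: SceneSpec) -> SceneImage:
    """Render a synthetic scene; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    hue = np.clip(
        spec.base_hue + rng.uniform(-spec.hue_jitter, spec.hue_jitter, (H, W)),
        0.0,
        1.0,
    )
    gradient = np.linspace(-0.5, 0.5, H)[:, None] * spec.sat_gradient_amplitude
    sat = np.clip(spec.base_sat + gradient + np.zeros((H, W)), 0.0, 1.0)
    bright = spec.base_bright + spec.texture_noise_sd * rng.standard_normal((H, W))
    bright = np.clip(bright, 0.0, 1.0)

    line_counts: list[int] = []
    expected: list[int] = []
    for _ in range(spec.n_straight_lines):
        drawn, nominal = _draw_line(rng, spec, bright)
        line_counts.append(drawn)
        expected.append(nominal)
    for _ in range(spec.n_curves):
        _draw_curve(rng, spec, bright)

    hsv = np.dstack([hue, sat, np.clip(bright, 0.0, 1.0)])
    rgb = np.clip(np.rint(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return SceneImage(
        pixels=rgb,
        n_straight_lines=spec.n_straight_lines,
        n_curves=spec.n_curves,
        line_pixel_counts=line_counts,
        expected_line_lengths=expected,
    )


def nature_spec(seed: int = 0, size: tuple[int, int] = (96, 128)) -> SceneSpec:
    """A nature-like scene: curved contours, green hue, saturation gradient."""
    return SceneSpec(
        size=size,
        n_straight_lines=0,
        n_curves=6,
        base_hue=0.30,
        hue_jitter=0.06,
        base_sat=0.30,
        sat_gradient_amplitude=0.3,
        texture_noise_sd=0.02,
        seed=seed,
    )


def urban_spec(seed: int = 0, size: tuple[int, int] = (96, 128)) -> SceneSpec:
    """An urban-like scene: a grid of straight lines, low hue diversity."""
    return SceneSpec(
        size=size,
        n_straight_lines=10,
        n_curves=0,
        base_hue=0.55,
        hue_jitter=0.01,
        base_sat=0.55,
        sat_gradient_amplitude=0.05,
        texture_noise_sd=0.0,
        orientation_mode="cardinal",
        seed=seed,
    )


def sample_feature_table(
    n_images: int, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Sample a feature table from independent uniforms over plausible ranges.

    Used when simulating ratings without rendering images; ranges are the
    package's documented defaults per feature.
    """
    rng = np.random.default_rng(seed)
    data = {
        f: rng.uniform(*reference.FEATURE_RANGES[f], size=n_images)
        for f in FEATURE_NAMES
    }
    df = pd.DataFrame(data)
    df.insert(0, "image_id", [f"img{i:04d}" for i in range(n_images)])
    return df


@dataclass(frozen=True)
class RatingSimSpec:
    """Generating model for simulated participant ratings.

    Naturalness ratings follow the reference linear model on the 10 features
    plus per-rating Gaussian noise. Preference follows the standardized
    reference betas applied to z-scored features, shifted to the Likert
    midpoint. Reaction times decrease with the image's modeled naturalness
    (a negative ``rt_slope`` reproduces the faster-for-bottom-up-nature
    coupling); RT baseline and noise defaults are the package's own choices.
    """

    n_participants: int = 52
    naturalness_coeffs: tuple[float, ...] = tuple(
        reference.naturalness_coefficients()
    )
    naturalness_noise_sd: float = 0.9
    preference_betas: tuple[float, ...] = tuple(reference.preference_beta_vector())
    preference_baseline: float = 4.0
    preference_noise_sd: float = 0.8
    rt_baseline: float = 1.5
    rt_slope: float = -0.25
    rt_noise_sd: float = 0.3
    likert: bool = False
    counterbalance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.naturalness_coeffs) != 11:
            raise ValueError(
                "naturalness_coeffs must have length 11 (intercept + 10 slopes)"
            )
        if len(self.preference_betas) != 10:
            raise ValueError("preference_betas must have length 10")
        for name in ("naturalness_noise_sd", "preference_noise_sd", "rt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.counterbalance and self.n_participants % 2:
            raise ValueError("n_participants must be even when counterbalancing")


def _clip_likert(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 1, 7)


def simulate_ratings(features: pd.DataFrame, spec: RatingSimSpec) -> pd.DataFrame:
    """Simulate per-participant ratings for a feature table.

    Returns a long table with columns participant_id, image_id, preference,
    naturalness, rt, group. Deterministic under ``spec.seed``.
    """
    X = features[list(FEATURE_NAMES)].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    rng = np.random.default_rng(spec.seed)
    n_img = X.shape[0]
    n_par = spec.n_participants
    coeffs = np.asarray(spec.naturalness_coeffs)
    eta_nat = coeffs[0] + X @ coeffs[1:]
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    eta_pref = spec.preference_baseline + Xz @ np.asarray(spec.preference_betas)

    nat = eta_nat[None, :] + spec.naturalness_noise_sd * rng.standard_normal(
        (n_par, n_img)
    )
    pref = eta_pref[None, :] + spec.preference_noise_sd * rng.standard_normal(
        (n_par, n_img)
    )
    rt = (
        spec.rt_baseline
        + spec.rt_slope * (eta_nat - eta_nat.mean())[None, :]
        + spec.rt_noise_sd * rng.standard_normal((n_par, n_img))
    )
    rt = np.maximum(rt, 0.2)
    if spec.likert:
        nat, pref = _clip_likert(nat), _clip_likert(pref)

    image_ids = (
        features["image_id"].astype(str).to_numpy()
        if "image_id" in features
        else np.array([f"img{i:04d}" for i in range(n_img)])
    )
    half = n_par // 2
    groups = ["preference-first"] * half + ["naturalness-first"] * (n_par - half)
    rows = {
        "participant_id": np.repeat([f"p{i:03d}" for i in range(n_par)], n_img),
        "image_id": np.tile(image_ids, n_par),
        "preference": pref.ravel(),
        "naturalness": nat.ravel(),
        "rt": rt.ravel(),
        "group": np.repeat(groups, n_img),
    }
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InteractionSimSpec:
    """Generating model for the standardized RT-interaction dataset.

    Modeled naturalness, non-modeled naturalness and RT are drawn as
    independent standard normals; preference is a linear combination
    ``b1*mod + b2*rt + b3*rt*mod + b4*nonmod + b5*rt*nonmod`` plus Gaussian
    noise. Defaults take (b1, b2, b3) from the modeled-naturalness reference
    model and (b4, b5) from the non-modeled one.
    """

    n_images: int = 2000
    coeffs: tuple[float, float, float, float, float] = (
        reference.MODELED_RT_COEFFS[0],
        reference.MODELED_RT_COEFFS[1],
        reference.MODELED_RT_COEFFS[2],
        reference.NONMODELED_RT_COEFFS[0],
        reference.NONMODELED_RT_COEFFS[2],
    )
    noise_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.coeffs) != 5:
            raise ValueError("coeffs must have length 5")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_interaction_dataset(
    spec: InteractionSimSpec | None = None, **kwargs
) -> pd.DataFrame:
    """Draw a (preference, modeled, non_modeled, rt) table per the spec."""
    if spec is None:
        spec = InteractionSimSpec(**kwargs)
    elif kwargs:
        spec = replace(spec, **kwargs)
    rng = np.random.default_rng(spec.seed)
    mod, nonmod, rt = rng.standard_normal((3, spec.n_images))
    b1, b2, b3, b4, b5 = spec.coeffs
    pref = (
        b1 * mod
        + b2 * rt
        + b3 * rt * mod
        + b4 * nonmod
        + b5 * rt * nonmod
        + spec.noise_sd * rng.standard_normal(spec.n_images)
    )
    return pd.DataFrame(
        {"preference": pref, "modeled": mod, "non_modeled": nonmod, "rt": rt}
    )
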