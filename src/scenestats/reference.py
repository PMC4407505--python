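"""Reference coefficient values used as simulation defaults.

These are regression estimates from a study-scale dataset (307 scene
photographs spanning a natural-to-urban gradient, rated by 52 participants
on 1-7 Likert scales). They define the generating models of the synthetic
rating simulators, so that downstream fits can be checked for parameter
recovery against known ground truth.

Feature order everywhere follows :data:`scenestats.image_features.FEATURE_NAMES`.
"""

from __future__ import annotations

import numpy as np

from .image_features import FEATURE_NAMES

#: Intercept of the unstandardized naturalness-on-features regression.
NATURALNESS_INTERCEPT = 3.573

#: Unstandardized slopes of perceived naturalness on the 10 features.
NATURALNESS_SLOPES = {
    "hue": -0.249,
    "sd_hue": -0.220,
    "sat": -0.756,
    "sd_sat": 0.244,
    "bright": 0.069,
    "sd_bright": 0.059,
    "entropy": -0.021,
    "ed": 0.717,
    "sed": -0.299,
    "der": 0.582,
}

#: Standardized betas of esthetic preference on the 10 (z-scored) features.
PREFERENCE_BETAS = {
    "hue": -0.177,
    "sd_hue": -0.009,
    "sat": -0.089,
    "sd_sat": 0.214,
    "bright": 0.085,
    "sd_bright": -0.031,
    "entropy": 0.066,
    "ed": 0.008,
    "sed": -0.382,
    "der": 0.123,
}

#: Standardized (main, RT, interaction) coefficients of preference on
#: modeled naturalness, reaction time, and their product.
MODELED_RT_COEFFS = (0.453, -0.036, -0.247)

#: Same structure for the non-modeled (residual) naturalness component.
NONMODELED_RT_COEFFS = (0.482, 0.069, 0.108)

#: Standardized coefficients of preference on color-modeled naturalness,
#: structure-modeled naturalness, non-modeled naturalness, and the
#: color x structure product.
COLOR_STRUCTURE_COEFFS = (0.362, 0.533, 0.480, 0.207)

#: Seven-feature subset retained by backward elimination for the quadratic
#: discriminant classifier.
QD_FEATURE_SUBSET = ("hue", "sat", "sd_hue", "sd_sat", "entropy", "sed", "der")

#: Empirically plausible per-feature ranges used to sample feature tables
#: when no images are involved (independent uniforms).
FEATURE_RANGES = {
    "hue": (0.05, 0.60),
    "sd_hue": (0.02, 0.30),
    "sat": (0.10, 0.80),
    "sd_sat": (0.05, 0.35),
    "bright": (0.30, 0.80),
    "sd_bright": (0.05, 0.30),
    "entropy": (4.00, 7.90),
    "ed": (0.02, 0.30),
    "sed": (0.00, 0.15),
    "der": (0.20, 1.00),
}


def naturalness_coefficients() -> np.ndarray:
    """Intercept + 10 slopes in canonical feature order (length 11)."""
    return np.array(
        [NATURALNESS_INTERCEPT] + [NATURALNESS_SLOPES[f] for f in FEATURE_NAMES]
    )


def preference_beta_vector() -> np.ndarray:
    """Standardized preference betas in canonical feature order (length 10)."""
    return np.array([PREFERENCE_BETAS[f] for f in FEATURE_NAMES])
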