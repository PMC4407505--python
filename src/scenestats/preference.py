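"""Preference regressions, RT-moderation models and simple slopes.

All models here follow the standardized convention: every variable is
z-scored across images (sample SD) before fitting, product terms are formed
from the z-scored mains and not re-standardized, and the intercept — zero
by construction — is not reported. Simple slopes of preference on a
naturalness component are evaluated at RT levels of the mean and
mean ± 1.5 SD, i.e. at z-RT in {-1.5, 0, +1.5}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_features import FEATURE_NAMES
from .naturalness import LinearFit, NaturalnessSplit, fit_ols, zscore


def preference_on_features(
    features: pd.DataFrame, preference: np.ndarray | pd.Series
) -> LinearFit:
    """Standardized regression of mean preference on the 10 image features."""
    return fit_ols(features[list(FEATURE_NAMES)], preference, standardize=True)


def preference_on_naturalness(
    naturalness: np.ndarray | pd.Series, preference: np.ndarray | pd.Series
) -> LinearFit:
    """Simple (unstandardized) regression of preference on naturalness."""
    X = pd.DataFrame({"naturalness": np.asarray(naturalness, float)})
    return fit_ols(X, preference)


@dataclass
class InteractionFit:
    """A preference ~ component + RT + component x RT moderation fit."""

    fit: LinearFit
    component: str  # "modeled" | "non_modeled"

    @property
    def b_component(self) -> float:
        return float(self.fit.params.iloc[0])

    @property
    def b_rt(self) -> float:
        return float(self.fit.params.iloc[1])

    @property
    def b_interaction(self) -> float:
        return float(self.fit.params.iloc[2])


def rt_interaction_model(
    preference: np.ndarray | pd.Series,
    component: np.ndarray | pd.Series,
    rt: np.ndarray | pd.Series,
    component_label: str = "modeled",
) -> InteractionFit:
    """Moderation of the component -> preference link by reaction time.

    Preference, the naturalness component, and RT are each z-scored across
    images; the product term is computed from the z-scored mains. Reports
    the three standardized coefficients with SEs and CIs.
    """
    comp_z = zscore(component)
    rt_z = zscore(rt)
    X = pd.DataFrame(
        {
            component_label: comp_z,
            "rt": rt_z,
            f"rt_x_{component_label}": comp_z * rt_z,
        }
    )
    y = zscore(preference)
    fit = fit_ols(X, y)
    # drop the (structurally ~0) intercept row from the report
    fit = LinearFit(
        params=fit.params.iloc[1:],
        bse=fit.bse.iloc[1:],
        tvalues=fit.tvalues.iloc[1:],
        conf_int=fit.conf_int.iloc[1:],
        r2=fit.r2,
        adj_r2=fit.adj_r2,
        f_stat=fit.f_stat,
        df_model=fit.df_model,
        df_resid=fit.df_resid,
        n=fit.n,
        fitted=fit.fitted,
        residuals=fit.residuals,
        standardized=True,
    )
    return InteractionFit(fit=fit, component=component_label)


@dataclass
class SimpleSlopes:
    """Conditional slopes of preference on a component at fixed RT levels."""

    component: str
    levels: tuple[float, ...]
    slopes: tuple[float, ...]

    def as_dict(self) -> dict[str, float]:
        return {f"rt_z={lvl:+.1f}": s for lvl, s in zip(self.levels, self.slopes)}


def simple_slopes(
    interaction: InteractionFit, levels: tuple[float, ...] = (-1.5, 0.0, 1.5)
) -> SimpleSlopes:
    """Slope at RT level L is b_component + b_interaction * L (exact)."""
    slopes = tuple(
        interaction.b_component + interaction.b_interaction * lvl for lvl in levels
    )
    return SimpleSlopes(
        component=interaction.component, levels=tuple(levels), slopes=slopes
    )


def color_structure_model(
    preference: np.ndarray | pd.Series, split: NaturalnessSplit
) -> LinearFit:
    """Preference on color- and structure-modeled naturalness and residual.

    Standardized fit of preference on color-modeled naturalness,
    structure-modeled naturalness, non-modeled naturalness, and the
    color x structure product (formed after z-scoring).
    """
    col = zscore(split.table["modeled_color"])
    struct = zscore(split.table["modeled_structure"])
    nonmod = zscore(split.table["non_modeled"])
    X = pd.DataFrame(
        {
            "modeled_color": col,
            "modeled_structure": struct,
            "non_modeled": nonmod,
            "color_x_structure": col * struct,
        }
    )
    fit = fit_ols(X, zscore(preference))
    return LinearFit(
        params=fit.params.iloc[1:],
        bse=fit.bse.iloc[1:],
        tvalues=fit.tvalues.iloc[1:],
        conf_int=fit.conf_int.iloc[1:],
        r2=fit.r2,
        adj_r2=fit.adj_r2,
        f_stat=fit.f_stat,
        df_model=fit.df_model,
        df_resid=fit.df_resid,
        n=fit.n,
        fitted=fit.fitted,
        residuals=fit.residuals,
        standardized=True,
    )


def r2_from_f(f_stat: float, k: int, df2: int, n: int) -> tuple[float, float]:
    """Recover (R², adjusted R²) from an F statistic and its degrees of freedom.

    ``R² = k F / (k F + df2)`` and ``adj = 1 - (1 - R²)(n - 1)/df2``;
    requires ``df2 = n - k - 1``. Useful for consistency checks between
    printed F values and printed R² values.
    """
    if f_stat < 0:
        raise ValueError("F must be >= 0")
    if df2 <= 0 or df2 != n - k - 1:
        raise ValueError("require df2 = n - k - 1 > 0")
    r2 = k * f_stat / (k * f_stat + df2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / df2
    return float(r2), float(adj)


def plot_simple_slopes(
    interaction: InteractionFit, path: str, levels=(-1.5, 0.0, 1.5)
) -> None:
    """Plot the conditional regression lines at fast / mean / slow RT."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ss = simple_slopes(interaction, levels)
    x = np.linspace(-2.5, 2.5, 50)
    fig, ax = plt.subplots(figsize=(5, 4))
    styles = {-1.5: ("black", "fast RT"), 0.0: ("tab:blue", "mean RT"), 1.5: ("tab:red", "slow RT")}
    for lvl, slope in zip(ss.levels, ss.slopes):
        color, label = styles.get(lvl, ("gray", f"RT z={lvl:+.1f}"))
        y = slope * x + interaction.b_rt * lvl
        ax.plot(x, y, color=color, label=f"{label} (slope {slope:.3f})")
    ax.set_xlabel(f"{interaction.component} naturalness (z)")
    ax.set_ylabel("preference (z)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
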