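"""OLS fitting and the modeled / non-modeled naturalness decomposition.

Perceived naturalness is regressed on the 10 image features; the fitted
value is the "modeled" (bottom-up, feature-driven) component and the
residual is the "non-modeled" component. Sub-models on the 6 color
features and the 4 spatial features give color-modeled and
structure-modeled naturalness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .image_features import COLOR_FEATURES, FEATURE_NAMES, SPATIAL_FEATURES


class SingularityError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class LinearFit:
    """An ordinary-least-squares fit with the usual inferential summary.

    ``params`` excludes the intercept when ``standardized`` (all variables
    z-scored; the intercept is 0 by construction and carries no
    information), and includes it under the name ``intercept`` otherwise.
    Confidence intervals use the exact t(df_resid) critical value.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    r2: float
    adj_r2: float
    f_stat: float
    df_model: int
    df_resid: int
    n: int
    fitted: np.ndarray
    residuals: np.ndarray
    standardized: bool

    def to_dict(self) -> dict:
        return {
            "standardized": self.standardized,
            "n": self.n,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "f": self.f_stat,
            "df": [self.df_model, self.df_resid],
            "coefficients": {
                name: {
                    "estimate": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "t": float(self.tvalues[name]),
                    "ci": [
                        float(self.conf_int.loc[name, "lower"]),
                        float(self.conf_int.loc[name, "upper"]),
                    ],
                }
                for name in self.params.index
            },
        }


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(mat) == mat.shape[1]:
        return
    # name the offending columns: greedily keep columns that raise the rank
    kept: list[int] = []
    base = np.ones((len(X), 1))
    current = 1
    bad = []
    for j, name in enumerate(X.columns):
        trial = np.column_stack([base] + [X.iloc[:, k] for k in kept + [j]])
        if np.linalg.matrix_rank(trial) > current:
            kept.append(j)
            current += 1
        else:
            bad.append(name)
    raise SingularityError(f"design matrix is rank deficient; collinear: {bad}")


def zscore(x: np.ndarray | pd.Series) -> np.ndarray:
    """Sample-SD (ddof=1) z-score."""
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance variable")
    return (x - x.mean()) / sd


def fit_ols(
    X: pd.DataFrame, y: np.ndarray | pd.Series, standardize: bool = False
) -> LinearFit:
    """OLS of ``y`` on the columns of ``X`` with an intercept.

    With ``standardize=True`` every column of X and y is z-scored (sample
    SD) first; the intercept is still included in the design — it is exactly
    0 and keeps the residual degrees of freedom at n - k - 1 — but is not
    reported.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    if np.isnan(X.to_numpy(float)).any() or np.isnan(y).any():
        raise ValueError("missing values in the regression inputs")
    if standardize:
        X = X.apply(zscore)
        y = zscore(y)
    _check_rank(X)
    design = sm.add_constant(X.to_numpy(float), prepend=True)
    res = sm.OLS(y, design).fit()
    names = ["intercept"] + list(X.columns)
    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    tvals = pd.Series(res.tvalues, index=names)
    ci = pd.DataFrame(res.conf_int(alpha=0.05), index=names, columns=["lower", "upper"])
    if standardize:
        params, bse, tvals, ci = (
            params.iloc[1:],
            bse.iloc[1:],
            tvals.iloc[1:],
            ci.iloc[1:],
        )
    return LinearFit(
        params=params,
        bse=bse,
        tvalues=tvals,
        conf_int=ci,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n=n,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        standardized=standardize,
    )


@dataclass
class NaturalnessSplit:
    """Per-image decomposition of perceived naturalness."""

    table: pd.DataFrame  # image_id, modeled, non_modeled, modeled_color, modeled_structure
    full_fit: LinearFit
    color_fit: LinearFit
    structure_fit: LinearFit


def decompose_naturalness(
    features: pd.DataFrame, naturalness: np.ndarray | pd.Series
) -> NaturalnessSplit:
    """Split naturalness into modeled and non-modeled components.

    Fits the full 10-feature model (modeled = fitted values, non-modeled =
    residuals, so modeled + non_modeled reproduces the ratings exactly) and
    two sub-models: color-only (6 features) and structure-only (4 features).
    """
    y = np.asarray(naturalness, float)
    full = fit_ols(features[list(FEATURE_NAMES)], y)
    color = fit_ols(features[list(COLOR_FEATURES)], y)
    structure = fit_ols(features[list(SPATIAL_FEATURES)], y)
    table = pd.DataFrame(
        {
            "modeled": full.fitted,
            "non_modeled": full.residuals,
            "modeled_color": color.fitted,
            "modeled_structure": structure.fitted,
        }
    )
    if "image_id" in features:
        table.insert(0, "image_id", features["image_id"].to_numpy())
    return NaturalnessSplit(
        table=table, full_fit=full, color_fit=color, structure_fit=structure
    )
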