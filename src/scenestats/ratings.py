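"""Aggregation of per-participant ratings to per-image summaries.

Reaction times are z-scored within participants before averaging, so that
individual differences in overall response speed do not leak into the
per-image RT summary. A counterbalance-order check compares the two task
order groups image by image.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RATING_COLUMNS = ("participant_id", "image_id", "preference", "naturalness", "rt")


class ZeroVarianceError(ValueError):
    pass


def zscore_rt(ratings: pd.DataFrame) -> pd.DataFrame:
    """Add a ``z_rt`` column: RT standardized within each participant.

    Uses the sample SD (ddof=1); each participant's z-values then have mean
    0 and SD 1 exactly. A participant with fewer than two RTs or zero RT
    variance is an error (z undefined).
    """
    out = ratings.reset_index(drop=True).copy()
    z = np.empty(len(out))
    for pid, grp in out.groupby("participant_id", sort=False):
        rt = grp["rt"].to_numpy(float)
        if len(rt) < 2:
            raise ZeroVarianceError(f"participant {pid!r} has fewer than 2 RTs")
        sd = rt.std(ddof=1)
        if sd == 0:
            raise ZeroVarianceError(f"participant {pid!r} has zero RT variance")
        z[grp.index.to_numpy()] = (rt - rt.mean()) / sd
    out["z_rt"] = z
    return out


def aggregate_means(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-image means of preference, naturalness and z-scored RT.

    RT is averaged after within-participant z-scoring (``zscore_rt`` is run
    here if the column is absent). Images with no ratings at all are dropped
    with a warning.
    """
    if "z_rt" not in ratings:
        ratings = zscore_rt(ratings)
    grouped = ratings.groupby("image_id", sort=True)
    summary = grouped.agg(
        mean_preference=("preference", "mean"),
        mean_naturalness=("naturalness", "mean"),
        mean_z_rt=("z_rt", "mean"),
        n_raters=("participant_id", "count"),
    ).reset_index()
    empty = summary["n_raters"] == 0
    if empty.any():
        logger.warning("dropping %d images with no ratings", int(empty.sum()))
        summary = summary[~empty]
    return summary


def order_effect_test(
    ratings: pd.DataFrame,
    measure: str = "preference",
    equal_var: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-image two-sample t-test between the two counterbalance groups.

    For each image, compares the ``measure`` ratings of the two task-order
    groups (Welch's t by default; ``equal_var=True`` pools variances).
    Returns the per-image table (t, df, p) and a summary with the minimum p
    and its t — the "closest to significance" check that licenses pooling
    raters across orders.
    """
    groups = sorted(ratings["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 counterbalance groups, got {groups}")
    rows = []
    for image_id, grp in ratings.groupby("image_id", sort=True):
        a = grp.loc[grp["group"] == groups[0], measure].to_numpy(float)
        b = grp.loc[grp["group"] == groups[1], measure].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("image %r skipped: a group has < 2 raters", image_id)
            continue
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {"image_id": image_id, "t": res.statistic, "df": res.df, "p": res.pvalue}
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no image had enough raters in both groups")
    imin = table["p"].idxmin()
    summary = {
        "min_p": float(table.loc[imin, "p"]),
        "t_at_min_p": float(table.loc[imin, "t"]),
        "image_at_min_p": table.loc[imin, "image_id"],
        "n_images_tested": int(len(table)),
    }
    return table, summary
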