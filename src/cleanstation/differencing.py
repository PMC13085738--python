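"""Before-after-control-impact differencing of the metric table.

Two stages convert raw per-survey metrics into change scores:

1. per station and variable, the signed change from baseline at each
   post-baseline replicate, ``abs_diff = value_r - value_before``;
2. the same change expressed relative to natural drift, by subtracting
   the mean change of the unmanipulated control stations in the same
   (variable, replicate) cell:
   ``rel_to_control = abs_diff - mean(control abs_diff)``.

Control stations therefore average to exactly zero within every cell by
construction, and any additive shock shared by all stations at a
replicate cancels out of ``rel_to_control``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .metrics import RESPONSE_VARIABLES

__all__ = [
    "absolute_difference",
    "control_reference",
    "relative_to_control",
    "difference_table",
    "POST_REPLICATES",
]

log = logging.getLogger(__name__)

POST_REPLICATES = ("first", "second", "after")
BASELINE = "before"


def _long_metrics(metrics: pd.DataFrame, variables) -> pd.DataFrame:
    id_cols = ["station_id", "replicate"] + (
        ["treatment"] if "treatment" in metrics else []
    )
    return metrics.melt(
        id_vars=id_cols, value_vars=list(variables), var_name="variable", value_name="value"
    )


def absolute_difference(
    metrics: pd.DataFrame, variables=RESPONSE_VARIABLES
) -> pd.DataFrame:
    """Signed per-station change from the baseline replicate.

    Returns a long table (station_id [, treatment], variable, replicate,
    abs_diff) with one row per station, variable and post-baseline
    replicate where both the replicate value and the baseline value are
    present.  Station-variable pairs lacking a baseline are skipped with
    a log message.
    """
    long = _long_metrics(metrics, variables)
    base = long[long["replicate"] == BASELINE].set_index(["station_id", "variable"])[
        "value"
    ]
    post = long[long["replicate"].isin(POST_REPLICATES)].copy()
    idx = pd.MultiIndex.from_frame(post[["station_id", "variable"]])
    post["baseline"] = base.reindex(idx).to_numpy()
    n_missing_base = post["baseline"].isna().sum()
    if n_missing_base:
        log.warning(
            "%d station-variable-replicate rows dropped: baseline missing", n_missing_base
        )
    post["abs_diff"] = post["value"] - post["baseline"]
    out = post.dropna(subset=["abs_diff"])
    keep = ["station_id", "variable", "replicate", "abs_diff"]
    if "treatment" in out:
        keep.insert(1, "treatment")
    return out[keep].reset_index(drop=True)


def control_reference(
    abs_diffs: pd.DataFrame, treatment_map: pd.Series | None = None
) -> pd.DataFrame:
    """Mean control-station abs_diff per (variable, replicate) cell.

    ``treatment_map`` (station_id -> treatment) is only needed when the
    abs_diff table lacks a treatment column.  Cells with no control
    value are flagged (``n_control == 0``) and excluded downstream.
    """
    df = abs_diffs.copy()
    if "treatment" not in df:
        if treatment_map is None:
            raise ValueError("treatment column absent and no treatment_map given")
        df["treatment"] = df["station_id"].map(treatment_map)
    ctrl = df[df["treatment"] == "control"]
    cells = (
        df.groupby(["variable", "replicate"])
        .size()
        .rename("n_rows")
        .reset_index()[["variable", "replicate"]]
    )
    ref = (
        ctrl.groupby(["variable", "replicate"])["abs_diff"]
        .agg(control_mean="mean", n_control="size")
        .reset_index()
    )
    out = cells.merge(ref, on=["variable", "replicate"], how="left")
    out["n_control"] = out["n_control"].fillna(0).astype(int)
    empty = out[out["n_control"] == 0]
    if len(empty):
        log.warning(
            "no control values in %d (variable, replicate) cells; rows skipped", len(empty)
        )
    return out


def relative_to_control(abs_diff: float, control_mean: float) -> float:
    """Change at a station minus the mean control change for the cell."""
    return abs_diff - control_mean


def difference_table(
    metrics: pd.DataFrame,
    treatment_map: pd.Series | None = None,
    variables=RESPONSE_VARIABLES,
) -> pd.DataFrame:
    """Full long difference table: abs_diff and rel_to_control per row.

    Rows in cells where the control mean is undefined are dropped (and
    logged); within the control treatment the station mean of
    ``rel_to_control`` is 0 in every retained cell by construction.
    """
    diffs = absolute_difference(metrics, variables)
    if "treatment" not in diffs:
        if treatment_map is None:
            raise ValueError("treatment column absent and no treatment_map given")
        diffs = diffs.copy()
        diffs["treatment"] = diffs["station_id"].map(treatment_map)
    ref = control_reference(diffs)
    out = diffs.merge(ref, on=["variable", "replicate"], how="left")
    out = out[out["n_control"] > 0].copy()
    out["rel_to_control"] = out["abs_diff"] - out["control_mean"]
    cols = [
        "station_id",
        "treatment",
        "variable",
        "replicate",
        "abs_diff",
        "rel_to_control",
    ]
    return out[cols].reset_index(drop=True)
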