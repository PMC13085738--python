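"""Per-survey behavioural response variables from raw observation tables.

Each station-replicate survey yields eight responses: cleaning rate
(cleans/hr), mean clean duration (s), posing rate (poses/hr), cleaner
responsiveness (mean flight-initiation distance, cm), cleaner
selectivity (filled by :mod:`cleanstation.selectivity`), potential
client abundance (distinct individuals/hr from frame censuses),
potential client species richness, and actual client species richness
(species actually cleaned).

Surveys with no events for a metric carry a missing value (NaN) rather
than an imputation; downstream models drop those rows complete-case.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .selectivity import station_selectivity

__all__ = [
    "cleaning_rate",
    "mean_clean_duration",
    "posing_rate",
    "community_metrics",
    "actual_richness",
    "responsiveness",
    "build_metric_table",
    "RESPONSE_VARIABLES",
]

#: The eight response variables, in reporting order.
RESPONSE_VARIABLES = (
    "cleaning_rate",
    "mean_clean_duration_s",
    "posing_rate",
    "responsiveness_cm",
    "selectivity",
    "potential_client_abundance",
    "potential_richness",
    "actual_richness",
)


def _check_duration(obs_duration_min: float) -> float:
    if obs_duration_min <= 0:
        raise ValueError(f"obs_duration_min must be positive, got {obs_duration_min}")
    return obs_duration_min / 60.0


def cleaning_rate(events: pd.DataFrame, obs_duration_min: float) -> float:
    """Cleans per hour over one survey."""
    hours = _check_duration(obs_duration_min)
    return len(events) / hours


def mean_clean_duration(events: pd.DataFrame) -> float:
    """Mean clean duration in seconds; NaN when the survey has no cleans."""
    if len(events) == 0:
        return np.nan
    dur = (events["end_s"] - events["start_s"]).astype(float)
    if (dur < 0).any():
        bad = events.index[dur < 0].tolist()
        raise ValueError(f"clean events with end_s < start_s at rows {bad}")
    return float(dur.mean())


def posing_rate(poses: pd.DataFrame, obs_duration_min: float) -> float:
    """Client poses per hour over one survey."""
    hours = _check_duration(obs_duration_min)
    return len(poses) / hours


def community_metrics(frames: pd.DataFrame, obs_duration_min: float, *, tagged: bool = True):
    """Potential client abundance (fish/hr) and potential species richness.

    Abundance counts distinct ``individual_tag`` values across all frames
    of the survey, so an individual present in every frame counts once
    (the tag-based de-duplication rule).  ``tagged=False`` falls back to
    summing per-frame species counts and dividing by hours — a
    pseudoreplicated rate that is NOT equivalent and only suitable for
    untagged censuses.
    """
    hours = _check_duration(obs_duration_min)
    if len(frames) == 0:
        return 0.0, 0
    richness = int(frames["species"].nunique())
    if tagged:
        abundance = frames["individual_tag"].nunique() / hours
    else:
        abundance = len(frames) / hours
    return float(abundance), richness


def actual_richness(events: pd.DataFrame) -> int:
    """Distinct client species actually cleaned during the survey."""
    if len(events) == 0:
        return 0
    return int(events["client_species"].nunique())


def responsiveness(trials: pd.DataFrame) -> float:
    """Mean flight-initiation distance (cm); NaN when no trial succeeded."""
    if len(trials) == 0:
        return np.nan
    fid = pd.to_numeric(trials["fid_cm"], errors="coerce")
    if (fid.dropna() < 0).any():
        raise ValueError("negative fid_cm value")
    present = fid.dropna()
    if len(present) == 0:
        return np.nan
    return float(present.mean())


def build_metric_table(
    surveys: pd.DataFrame,
    clean_events: pd.DataFrame,
    pose_events: pd.DataFrame,
    frame_censuses: pd.DataFrame,
    fid_trials: pd.DataFrame,
    *,
    selectivity_grain: str = "species",
    availability_floor: float | None = 1e-6,
) -> pd.DataFrame:
    """One row per station-replicate survey with all eight responses.

    Parameters
    ----------
    surveys : DataFrame
        One row per (station_id, replicate) with ``obs_duration_min``
        and optionally ``treatment``.
    clean_events, pose_events, frame_censuses, fid_trials : DataFrame
        Event tables carrying ``station_id`` and ``replicate`` keys.
    availability_floor : float
        Availability proportion for cleaned-but-never-censused species
        passed through to the selectivity calculation; the permissive
        default keeps simulated surveys computable.
    """
    rows = []
    key = ["station_id", "replicate"]
    g_clean = dict(iter(clean_events.groupby(key))) if len(clean_events) else {}
    g_pose = dict(iter(pose_events.groupby(key))) if len(pose_events) else {}
    g_frame = dict(iter(frame_censuses.groupby(key))) if len(frame_censuses) else {}
    g_fid = dict(iter(fid_trials.groupby(key))) if len(fid_trials) else {}
    empty = pd.DataFrame()

    for _, sv in surveys.iterrows():
        k = (sv["station_id"], sv["replicate"])
        dur = float(sv["obs_duration_min"])
        cleans = g_clean.get(k, empty)
        poses = g_pose.get(k, empty)
        frames = g_frame.get(k, empty)
        fids = g_fid.get(k, empty)
        abundance, pot_rich = community_metrics(frames, dur) if len(frames) else (0.0, 0)
        sel = station_selectivity(
            cleans, frames, grain=selectivity_grain, availability_floor=availability_floor
        )
        row = {
            "station_id": sv["station_id"],
            "replicate": sv["replicate"],
            "obs_duration_min": dur,
            "cleaning_rate": cleaning_rate(cleans, dur),
            "mean_clean_duration_s": mean_clean_duration(cleans),
            "posing_rate": posing_rate(poses, dur),
            "responsiveness_cm": responsiveness(fids),
            "selectivity": sel.station_value,
            "potential_client_abundance": abundance,
            "potential_richness": pot_rich,
            "actual_richness": actual_richness(cleans),
        }
        if "treatment" in sv.index:
            row["treatment"] = sv["treatment"]
        rows.append(row)
    out = pd.DataFrame(rows)
    lead = ["station_id", "replicate"] + (["treatment"] if "treatment" in out else [])
    cols = lead + ["obs_duration_min"] + list(RESPONSE_VARIABLES)
    return out[cols]
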