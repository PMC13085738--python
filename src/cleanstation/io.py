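"""CSV readers and writers for the four observation tables.

All files are UTF-8, comma-separated with a header row, "." decimal and
empty fields for missing values.  Event-annotation exports (e.g. BORIS
aggregated event tables with subject/behaviour/start/stop columns) can
be adapted with a column-mapping dict passed to the readers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .rugosity import SurfaceProfile

CLEAN_COLUMNS = [
    "station_id", "replicate", "start_s", "end_s",
    "client_species", "client_family", "n_cleaners",
]
POSE_COLUMNS = ["station_id", "replicate", "time_s", "client_species"]
FRAME_COLUMNS = [
    "station_id", "replicate", "frame_index", "individual_tag", "species", "family",
]
FID_COLUMNS = ["station_id", "replicate", "cleaner_id", "fid_cm"]
SURVEY_COLUMNS = ["station_id", "replicate", "obs_duration_min"]


def _read(path, required, column_map=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_clean_events(path, column_map: dict | None = None) -> pd.DataFrame:
    return _read(path, CLEAN_COLUMNS[:6], column_map)


def read_pose_events(path, column_map: dict | None = None) -> pd.DataFrame:
    return _read(path, POSE_COLUMNS, column_map)


def read_frame_censuses(path, column_map: dict | None = None) -> pd.DataFrame:
    return _read(path, FRAME_COLUMNS, column_map)


def read_fid_trials(path, column_map: dict | None = None) -> pd.DataFrame:
    return _read(path, FID_COLUMNS, column_map)


def read_surveys(path, column_map: dict | None = None) -> pd.DataFrame:
    return _read(path, SURVEY_COLUMNS, column_map)


def read_stations(path) -> pd.DataFrame:
    return _read(path, ["station_id", "treatment"])


def read_profiles(path) -> dict:
    """Long profile CSV (station_id, x_cm, z_cm) -> dict of SurfaceProfile."""
    df = _read(path, ["station_id", "x_cm", "z_cm"])
    return {
        sid: SurfaceProfile(g["x_cm"].to_numpy(), g["z_cm"].to_numpy())
        for sid, g in df.groupby("station_id", sort=False)
    }


def write_table(df: pd.DataFrame, path, *, seed=None) -> None:
    """Write a CSV, optionally recording the run seed in a comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
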