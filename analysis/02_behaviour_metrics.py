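"""Extract the eight per-survey response variables from the raw tables.

Reads results/study/, computes cleaning rate, clean duration, posing
rate, responsiveness (FID), selectivity, potential client abundance and
both richness measures for each of the 80 station-replicate surveys,
and writes results/metric_table.csv.
"""

from cleanstation import io as csvio
from cleanstation.metrics import RESPONSE_VARIABLES, build_metric_table

IN, OUT = "results/study", "results/metric_table.csv"


def main() -> None:
    surveys = csvio.read_surveys(f"{IN}/surveys.csv")
    stations = csvio.read_stations(f"{IN}/stations.csv")
    if "treatment" not in surveys:
        surveys = surveys.merge(stations[["station_id", "treatment"]], on="station_id")
    table = build_metric_table(
        surveys,
        csvio.read_clean_events(f"{IN}/clean_events.csv"),
        csvio.read_pose_events(f"{IN}/pose_events.csv"),
        csvio.read_frame_censuses(f"{IN}/frame_censuses.csv"),
        csvio.read_fid_trials(f"{IN}/fid_trials.csv"),
    )
    csvio.write_table(table, OUT)
    print(f"{len(table)} survey rows -> {OUT}")
    exp = table[table["treatment"] == "experimental"]
    summary = exp.groupby("replicate")[list(RESPONSE_VARIABLES)].mean()
    summary = summary.reindex(["before", "first", "second", "after"]).round(2)
    print("experimental-station means per replicate:")
    print(summary.to_string())


if __name__ == "__main__":
    main()
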