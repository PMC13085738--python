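"""Convert raw metrics into before/after change scores and express them
relative to the natural drift measured at control stations.

Reads results/metric_table.csv and writes results/difference_table.csv
(long format: station, treatment, variable, replicate, abs_diff,
rel_to_control).  Control stations average to exactly zero within every
variable-replicate cell by construction.
"""

from cleanstation import io as csvio
from cleanstation.differencing import difference_table

IN, OUT = "results/metric_table.csv", "results/difference_table.csv"


def main() -> None:
    metrics = csvio.read_table(IN)
    diffs = difference_table(metrics)
    csvio.write_table(diffs, OUT)
    print(f"{len(diffs)} difference rows -> {OUT}")
    cell = (
        diffs[diffs["treatment"] == "experimental"]
        .groupby(["variable", "replicate"])["rel_to_control"]
        .mean()
        .unstack()
        .round(2)
    )
    print("experimental mean rel_to_control per cell:")
    print(cell.to_string())


if __name__ == "__main__":
    main()
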