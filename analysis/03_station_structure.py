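"""Chain rugosity of every station's surface profile.

Drapes a virtual 2 cm-link chain over each station transect and writes
the span-to-chain-length ratio (1 = flat, lower = more rugose) with the
station's surface area to results/station_rugosity.csv.
"""

import pandas as pd

from cleanstation import io as csvio
from cleanstation.rugosity import drape_chain, rugosity

IN, OUT = "results/study", "results/station_rugosity.csv"


def main() -> None:
    profiles = csvio.read_profiles(f"{IN}/profiles.csv")
    stations = csvio.read_stations(f"{IN}/stations.csv")
    rows = []
    for sid, prof in profiles.items():
        drape = drape_chain(prof, 2.0)
        rows.append(
            {
                "station_id": sid,
                "rugosity": rugosity(prof, 2.0),
                "n_links": drape.n_links,
                "chain_length_cm": drape.chain_length_cm,
                "span_cm": drape.span_cm,
            }
        )
    table = stations.merge(pd.DataFrame(rows), on="station_id")
    csvio.write_table(table, OUT)
    print(f"{len(table)} stations -> {OUT}")
    print(
        "rugosity range: "
        f"{table['rugosity'].min():.3f}-{table['rugosity'].max():.3f} "
        f"(mean {table['rugosity'].mean():.3f})"
    )


if __name__ == "__main__":
    main()
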