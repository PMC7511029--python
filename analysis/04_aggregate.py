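#!/usr/bin/env python
"""Roll district births-averted up to state and national level.

State BA is the sum of district BA; state PIB divides that sum by the
state's total window births (a births-weighted mean of district PIBs).
The same procedure yields the national figures.
"""

import pathlib

import pandas as pd

from avert import aggregate as agg
from avert import io_tables

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main():
    est = io_tables.read_estimates(ROOT / "results" / "district_estimates.csv")
    averted = io_tables.read_estimates(ROOT / "results" / "averted.csv")

    states = agg.aggregate(averted, est, "state")
    national = agg.aggregate(averted, est, "national")
    io_tables.write_estimates(
        pd.concat([states, national], ignore_index=True),
        ROOT / "results" / "state_aggregates.csv",
    )

    nat = national.set_index("method")
    for m in (1, 2):
        row = nat.loc[m]
        print(f"method {m}: national BA {row.ba_total:,.0f} of "
              f"{row.total_births:,.0f} births -> PIB {row.pib:.2f}%")
    print(f"{nat.loc[1, 'n_below_replacement']} districts below replacement "
          f"fertility (TFR < 2.1); {nat.loc[1, 'n_cpr_above_50']} with CPR > 50%")
    print(f"-> {ROOT / 'results' / 'state_aggregates.csv'}")


if __name__ == "__main__":
    main()
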