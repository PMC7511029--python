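#!/usr/bin/env python
"""Generate the synthetic study population.

640 districts (32 states x 20) with a planted district-level law
log TFR = 1.199 - 0.0083 CPR + eps, eps ~ N(0, 0.1), CPR uniform on
2.7-84.8% — the observed national ranges — and 500 women per district.
Microdata (large) go to scratch/, the district truth table to results/.
"""

import argparse
import pathlib

from avert import io_tables, synthetic

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2016)
    args = parser.parse_args()

    cfg = synthetic.SimConfig(women_per_district=500, seed=args.seed)
    truths, women, births = synthetic.simulate(cfg)

    out = ROOT / "scratch" / "microdata"
    io_tables.write_microdata(women, births, out)
    (ROOT / "results").mkdir(exist_ok=True)
    truths.to_csv(ROOT / "results" / "truths.csv", index=False)

    print(f"simulated {len(truths)} districts, {len(women):,} women, "
          f"{len(births):,} births in the 3-year window")
    print(f"planted TFR range: {truths.tfr_true.min():.2f}-{truths.tfr_true.max():.2f} "
          f"births/woman; CPR range: {truths.cpr_true.min():.1f}-{truths.cpr_true.max():.1f}%")
    print(f"microdata -> {out}")


if __name__ == "__main__":
    main()
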