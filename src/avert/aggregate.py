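"""State and national roll-up of district births-averted results.

District BA values are summed within the unit and divided by the unit's
total births, so the aggregate PIB is the births-weighted mean of district
PIBs:

    PIB_unit = 100 * sum_i BA_i / sum_i B_i.

District-count columns use the reporting thresholds TFR < 2.1 (replacement
level, strict) and CPR > 50 (strict) — deliberately distinct from the
Method-1 grouping thresholds, and configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AvertError

REPLACEMENT_TFR = 2.1
CPR_REPORT_THRESHOLD = 50.0

NATIONAL_ID = "national"


def aggregate(
    averted: pd.DataFrame,
    estimates: pd.DataFrame,
    level: str = "state",
    replacement_tfr: float = REPLACEMENT_TFR,
    cpr_threshold: float = CPR_REPORT_THRESHOLD,
) -> pd.DataFrame:
    """Sum district BA to state or national level and recompute PIB.

    Every district in ``averted`` must have a matching row in ``estimates``;
    an unmatched district is a consistency error, not a silent drop.
    """
    if level not in ("state", "national"):
        raise ValueError(f"level must be 'state' or 'national', got {level!r}")

    est = estimates.set_index("district_id")
    missing = set(averted["district_id"]) - set(est.index)
    if missing:
        raise AvertError(f"averted districts with no estimate: {sorted(missing)}")

    merged = averted.merge(
        estimates[["district_id", "state_id", "tfr", "cpr", "total_births_window"]],
        on="district_id",
        validate="many_to_one",
    )
    unit = merged["state_id"] if level == "state" else NATIONAL_ID
    merged = merged.assign(unit_id=unit)

    def _one(g: pd.DataFrame) -> pd.Series:
        total_births = g["total_births_window"].sum()
        ba_total = g["ba"].sum()
        return pd.Series(
            {
                "n_districts": g["district_id"].nunique(),
                "n_below_replacement": int(
                    (g.drop_duplicates("district_id")["tfr"] < replacement_tfr).sum()
                ),
                "n_cpr_above_50": int(
                    (g.drop_duplicates("district_id")["cpr"] > cpr_threshold).sum()
                ),
                "total_births": total_births,
                "ba_total": ba_total,
                "pib": 100.0 * ba_total / total_births if total_births > 0 else np.nan,
            }
        )

    out = (
        merged.groupby(["unit_id", "method"], sort=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    for col in ("n_districts", "n_below_replacement", "n_cpr_above_50"):
        out[col] = out[col].astype(int)
    return out[
        [
            "unit_id",
            "method",
            "n_districts",
            "n_below_replacement",
            "n_cpr_above_50",
            "total_births",
            "ba_total",
            "pib",
        ]
    ]
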