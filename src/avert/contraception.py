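"""Contraceptive prevalence rate (CPR) per district.

CPR is the percentage of currently married women aged 15-49 using any
contraceptive method (couple-level use is collapsed into the woman's
``using_any_method`` flag).  Unmarried women are excluded from both the
numerator and the denominator regardless of their use flag.
"""

from __future__ import annotations

import warnings

import pandas as pd


def compute_cpr(women: pd.DataFrame) -> pd.Series:
    """Weighted CPR per district, in percent.

    Districts with no currently married women have an undefined CPR and are
    returned as NaN with a warning so downstream stages can exclude them
    explicitly rather than silently.
    """
    married = women[women["currently_married"]]
    denom = married.groupby("district_id")["weight"].sum()
    numer = (
        married[married["using_any_method"]]
        .groupby("district_id")["weight"]
        .sum()
        .reindex(denom.index, fill_value=0.0)
    )
    cpr = 100.0 * numer / denom
    all_districts = pd.Index(women["district_id"].unique(), name="district_id")
    cpr = cpr.reindex(all_districts)
    if cpr.isna().any():
        missing = cpr.index[cpr.isna()].tolist()
        warnings.warn(
            f"districts with no currently married women, CPR undefined: {missing}",
            stacklevel=2,
        )
    return cpr.rename("cpr")
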