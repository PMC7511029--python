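"""Sensitivity summaries of the births-averted estimates.

Two views: the distribution of district PIB stratified by replacement-level
fertility (TFR 2.1), and the coefficient of variation of BA across
districts, comparable between the stratified and pooled methods.

Quantiles use linear interpolation between order statistics (numpy's
default, type 7).  The standard deviation uses the n-1 denominator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .aggregate import REPLACEMENT_TFR
from .errors import EstimationError


def pib_distribution(
    averted: pd.DataFrame,
    estimates: pd.DataFrame,
    split_tfr: float = REPLACEMENT_TFR,
) -> pd.DataFrame:
    """Quartile summary of district PIB per (method, TFR stratum).

    Strata are TFR > split and TFR <= split.  ``skew`` reports the
    direction implied by the mean-median comparison: "left" when
    mean < median, "right" when mean > median, "none" otherwise.
    An empty stratum is omitted with a warning.
    """
    if averted.empty:
        raise EstimationError("no averted results to summarize")
    merged = averted.merge(
        estimates[["district_id", "tfr"]], on="district_id", validate="many_to_one"
    )
    rows = []
    for method, g in merged.groupby("method", sort=True):
        for label, mask in (
            (f"tfr>{split_tfr}", g["tfr"] > split_tfr),
            (f"tfr<={split_tfr}", g["tfr"] <= split_tfr),
        ):
            vals = g.loc[mask, "pib"].to_numpy(float)
            if len(vals) == 0:
                warnings.warn(
                    f"method {method}: stratum {label} is empty, omitted",
                    stacklevel=2,
                )
                continue
            p25, med, p75 = np.percentile(vals, [25, 50, 75])
            mean = float(vals.mean())
            skew = "left" if mean < med else ("right" if mean > med else "none")
            rows.append(
                {
                    "method": method,
                    "stratum": label,
                    "n": len(vals),
                    "p25": p25,
                    "median": med,
                    "p75": p75,
                    "mean": mean,
                    "skew": skew,
                }
            )
    return pd.DataFrame(rows)


def cv_of_ba(ba_values) -> float:
    """Coefficient of variation, percent: 100 * SD(n-1) / mean."""
    vals = np.asarray(ba_values, float)
    if len(vals) < 2:
        raise EstimationError("CV needs at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise EstimationError("CV undefined for zero mean")
    return float(100.0 * vals.std(ddof=1) / mean)
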