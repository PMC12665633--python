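"""Exposure-fate summaries for the applied herbicide.

Measured water concentrations are summarized against nominal applications
(percent of nominal at 1 h), dissipation is characterized by a first-order
(log-linear) fit over uncensored timepoints, and detection status is tabulated
per treatment with explicit handling of the reporting detection limit
(censored values are stored at the limit and flagged, never dropped or zeroed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_of_nominal",
    "fit_dissipation",
    "detection_status_table",
    "DissipationFit",
]


@dataclass
class DissipationFit:
    k_per_day: float           # first-order rate (positive = declining)
    dt50_days: float           # ln 2 / k; inf when k <= 0
    r2: float
    n_used: int
    n_censored_excluded: int
    intercept_log: float


def percent_of_nominal(measured_1h: pd.Series, nominal: pd.Series) -> dict:
    """Per-tank 100 * measured / nominal, summarized (controls excluded).

    Returns mean, standard error (sd / sqrt(n)), n, min and max.
    """
    df = pd.DataFrame({"measured": measured_1h, "nominal": nominal}).dropna()
    excluded = int((df["nominal"] <= 0).sum())
    df = df[df["nominal"] > 0]
    if df.empty:
        raise ValueError("no tanks with positive nominal concentration")
    pct = 100.0 * df["measured"] / df["nominal"]
    n = len(pct)
    out = {
        "mean": float(pct.mean()),
        "se": float(pct.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "n": n,
        "min": float(pct.min()),
        "max": float(pct.max()),
    }
    if excluded:
        out["n_excluded_zero_nominal"] = excluded
    return out


def fit_dissipation(series: pd.DataFrame, tank_ids=None,
                    analyte: str = "diquat") -> DissipationFit:
    """First-order dissipation fit: least squares of ln(value) on day.

    Censored (below-detection) points are excluded, not substituted; their
    count is reported.  DT50 = ln 2 / k, flagged infinite when the estimated
    rate is non-positive.
    """
    sub = series[series["analyte"] == analyte]
    if tank_ids is not None:
        sub = sub[sub["tank_id"].isin(list(tank_ids))]
    cen = sub["below_detection"].astype(bool)
    n_cen = int(cen.sum())
    sub = sub[~cen]
    sub = sub[(sub["value"] > 0) & np.isfinite(sub["value"])]
    if len(sub) < 3 or sub["day"].nunique() < 3:
        raise ValueError(
            f"need >= 3 uncensored timepoints; have {len(sub)} rows "
            f"({n_cen} censored excluded)")
    res = stats.linregress(sub["day"].to_numpy(float), np.log(sub["value"].to_numpy(float)))
    k = -float(res.slope)
    dt50 = np.log(2.0) / k if k > 0 else np.inf
    return DissipationFit(k_per_day=k, dt50_days=float(dt50),
                          r2=float(res.rvalue ** 2), n_used=len(sub),
                          n_censored_excluded=n_cen,
                          intercept_log=float(res.intercept))


def detection_status_table(series: pd.DataFrame, day: float, treatment: pd.Series,
                           analyte: str = "diquat") -> pd.DataFrame:
    """Detected vs below-detection tank counts per treatment at one day."""
    sub = series[(series["analyte"] == analyte) & (series["day"] == day)].copy()
    if sub.empty:
        raise ValueError(f"day {day} not present in the chemistry series")
    sub["treatment"] = sub["tank_id"].map(treatment)
    tab = (sub.groupby("treatment")["below_detection"]
           .agg(n_tanks="count", n_censored="sum").reset_index())
    tab["n_detected"] = tab["n_tanks"] - tab["n_censored"]
    return tab[["treatment", "n_tanks", "n_detected", "n_censored"]]
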