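"""Simulated physical-activity questionnaire and accelerometer columns.

Questionnaire minutes are log-normal and days-per-week binomial, giving the
right-skewed MET-min/week totals typical of population questionnaires; the
default medians are calibrated so total physical activity (TPA) has a median
near 2000 MET-min/week.  A configurable fraction of subjects has no
accelerometer sub-study data, and a further fraction fails the 72-hour
calibrated-wear requirement; both have the mean acceleration vector marked
unavailable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["default_activity_params", "generate_activity"]


def default_activity_params() -> dict:
    return {
        # minutes per session: log-normal (median, sigma of log)
        "walking_min_median": 29.5,
        "walking_min_sigma": 0.80,
        "moderate_min_median": 41.5,
        "moderate_min_sigma": 0.90,
        "vigorous_min_median": 29.5,
        "vigorous_min_sigma": 0.90,
        # days per week: binomial(7, p)
        "walking_days_p": 0.75,
        "moderate_days_p": 0.50,
        "vigorous_days_p": 0.35,
        # accelerometer sub-study
        "accel_available_fraction": 0.41,
        "wear_fail_fraction": 0.05,
        "accel_mean_median": 27.6,
        "accel_mean_sigma": 0.26,
    }


def generate_activity(
    n: int, params: dict | None = None, seed=None
) -> pd.DataFrame:
    """Draw per-subject activity columns; ``seed`` may be an int or Generator."""
    if n <= 0:
        raise ValueError("n must be > 0")
    p = default_activity_params()
    if params:
        p.update(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def minutes(median, sigma):
        if median <= 0:
            return np.zeros(n)
        return rng.lognormal(np.log(median), sigma, n)

    df = pd.DataFrame(
        {
            "walking_min": minutes(p["walking_min_median"], p["walking_min_sigma"]),
            "walking_days": rng.binomial(7, p["walking_days_p"], n).astype(float),
            "moderate_min": minutes(p["moderate_min_median"], p["moderate_min_sigma"]),
            "moderate_days": rng.binomial(7, p["moderate_days_p"], n).astype(float),
            "vigorous_min": minutes(p["vigorous_min_median"], p["vigorous_min_sigma"]),
            "vigorous_days": rng.binomial(7, p["vigorous_days_p"], n).astype(float),
        }
    )
    df["vigorous_MET"] = 8.0 * df.vigorous_min * df.vigorous_days
    df["TPA"] = (
        3.3 * df.walking_min * df.walking_days
        + 4.0 * df.moderate_min * df.moderate_days
        + df.vigorous_MET
    )
    available = rng.random(n) < p["accel_available_fraction"]
    wear_ok = rng.random(n) >= p["wear_fail_fraction"]
    df["accel_valid"] = available & wear_ok
    accel = rng.lognormal(np.log(p["accel_mean_median"]), p["accel_mean_sigma"], n)
    df["accel_mean"] = np.where(df.accel_valid, accel, np.nan)
    return df
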