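"""Stratum summaries: means with t-intervals, proportions with Wilson scores.

Mirrors the survey's descriptive reporting: per location x vulnerability
cell, mean hemoglobin with a confidence interval, anemia prevalence with a
Wilson score interval, and mean weekly consumption days for each animal
source food; plus the percentage of children eating wildmeat by age bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import flag_anemia

__all__ = [
    "ProportionCI",
    "wilson_interval",
    "mean_ci",
    "stratum_summary",
    "age_bin_consumption",
    "DEFAULT_AGE_BINS",
]

#: Age-bin edges (years): infants (<1), second year of life, ages two-to-five.
DEFAULT_AGE_BINS = (0.5, 1.0, 2.0, 5.0)


@dataclass(frozen=True)
class ProportionCI:
    successes: int
    trials: int
    point: float
    lower: float
    upper: float
    confidence: float = 0.95

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.point + 1e-12
                and self.point - 1e-12 <= self.upper <= 1.0):
            raise ValueError("interval must satisfy 0 <= lower <= point <= upper <= 1")


def wilson_interval(k: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    Parameters
    ----------
    k, n : int
        Successes and trials, 0 <= k <= n, n >= 1.
    conf : float
        Confidence level.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    lower, upper = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    point = k / n
    # guard against floating-point excursions outside [0, point] / [point, 1]
    lower = min(max(float(lower), 0.0), point)
    upper = max(min(float(upper), 1.0), point)
    return ProportionCI(successes=int(k), trials=int(n), point=point,
                        lower=lower, upper=upper, confidence=conf)


def mean_ci(values, conf: float = 0.95, method: str = "t") -> tuple[float, float, float]:
    """Mean with a t-based (default) or normal-approximation interval.

    Degenerate inputs (n == 1 or zero spread) give a zero-width interval at
    the mean.
    """
    x = np.asarray(values, dtype=float)
    m = float(np.mean(x))
    if len(x) < 2:
        return m, m, m
    se = float(np.std(x, ddof=1)) / np.sqrt(len(x))
    if se == 0.0:
        return m, m, m
    if method == "t":
        q = stats.t.ppf(0.5 + conf / 2.0, df=len(x) - 1)
    elif method == "normal":
        q = stats.norm.ppf(0.5 + conf / 2.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return m, m - q * se, m + q * se


def _summary_row(cell: pd.DataFrame, conf: float, method: str) -> dict:
    hb = cell["hemoglobin_gdl"].to_numpy()
    anemic = int(flag_anemia(hb).sum())
    n = len(cell)
    prev = wilson_interval(anemic, n, conf)
    m, lo, hi = mean_ci(hb, conf, method)
    row = {
        "n_children": n,
        "mean_hb": m, "mean_hb_lower": lo, "mean_hb_upper": hi,
        "anemia_pct": 100.0 * prev.point,
        "anemia_pct_lower": 100.0 * prev.lower,
        "anemia_pct_upper": 100.0 * prev.upper,
    }
    for asf in ("wildmeat", "fish", "chicken", "beef"):
        col = "wildmeat_days_week" if asf == "wildmeat" else f"days_per_week_{asf}"
        m, lo, hi = mean_ci(cell[col].to_numpy(), conf, method)
        row[f"{asf}_days_mean"] = m
        row[f"{asf}_days_lower"] = lo
        row[f"{asf}_days_upper"] = hi
    return row


def stratum_summary(
    children: pd.DataFrame,
    households: pd.DataFrame,
    labels: pd.DataFrame,
    scheme: str = "by_income",
    conf: float = 0.95,
    mean_method: str = "t",
) -> pd.DataFrame:
    """Summary table per (location x vulnerability) cell plus whole-location rows.

    Household 30-day wildmeat meal counts are expressed as days/week
    (meals * 7/30) so all four animal source foods share a scale.  Empty
    cells are reported with ``n_children = 0`` and NaN statistics rather
    than dropped.
    """
    hh_cols = ["household_id", "wildmeat_meals_30d",
               "days_per_week_fish", "days_per_week_chicken", "days_per_week_beef"]
    data = children.merge(households[hh_cols], on="household_id")
    data = data.merge(labels[["child_id", "location", scheme]], on="child_id")
    data["wildmeat_days_week"] = data["wildmeat_meals_30d"] * 7.0 / 30.0

    rows = []
    for loc in sorted(data["location"].unique()):
        loc_data = data[data["location"] == loc]
        for vuln in ("most", "least"):
            cell = loc_data[loc_data[scheme] == vuln]
            row = {"location": loc, "vulnerability": vuln}
            if len(cell) == 0:
                row.update({"n_children": 0})
            else:
                row.update(_summary_row(cell, conf, mean_method))
            rows.append(row)
        rows.append(
            {"location": loc, "vulnerability": "all",
             **_summary_row(loc_data, conf, mean_method)}
        )
    return pd.DataFrame(rows)


def age_bin_consumption(
    children: pd.DataFrame,
    households: pd.DataFrame,
    bins=DEFAULT_AGE_BINS,
    conf: float = 0.95,
    consuming_only: bool = True,
) -> pd.DataFrame:
    """Percent of children ever / normally eating wildmeat by age bin x location.

    By default restricts to children in households that consumed wildmeat in
    the previous 12 months (the denominator used for the introduction-age
    reporting).  Empty bins are returned with ``n = 0`` and NaN percentages.
    """
    hh = households
    if consuming_only:
        hh = hh[hh["consumed_wildmeat_12mo"]]
    data = children.merge(hh[["household_id", "location"]], on="household_id")
    edges = np.asarray(bins, dtype=float)
    data["age_bin"] = pd.cut(data["age_years"], edges, right=False,
                             include_lowest=True)

    rows = []
    for loc in sorted(data["location"].unique()):
        loc_data = data[data["location"] == loc]
        for interval in data["age_bin"].cat.categories:
            cell = loc_data[loc_data["age_bin"] == interval]
            row = {"location": loc, "age_bin": str(interval), "n": len(cell)}
            for flag in ("ever_ate_wildmeat", "normally_eats_wildmeat"):
                prefix = "ever" if flag.startswith("ever") else "normally"
                if len(cell) == 0:
                    row[f"{prefix}_pct"] = np.nan
                    row[f"{prefix}_lower"] = np.nan
                    row[f"{prefix}_upper"] = np.nan
                else:
                    ci = wilson_interval(int(cell[flag].sum()), len(cell), conf)
                    row[f"{prefix}_pct"] = 100.0 * ci.point
                    row[f"{prefix}_lower"] = 100.0 * ci.lower
                    row[f"{prefix}_upper"] = 100.0 * ci.upper
            rows.append(row)
    return pd.DataFrame(rows)
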