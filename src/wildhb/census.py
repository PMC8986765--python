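"""Census-based scale-up of scenario effects to the study universe.

Grouped census income classes (per-capita household income as fractions of
the national minimum wage) bound the share of extremely vulnerable
households in each municipality: a lower bound counts households at or
below 1/8 of the minimum wage per capita, an upper bound adds the
(1/8, 1/4] class.  No-income households are included in both bounds.
Multiplying each municipality's young-child count by its rural share and
those household fractions bounds the number of vulnerable rural children;
2019 population estimates supply a uniform growth adjustment; and a
prevalence shift (percentage points) from the scenario engine converts
child counts into additional anemia cases.

All arithmetic is kept fractional internally; rounding happens only in the
reporting fields (headline counts to the nearest hundred).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScaleUpResult",
    "vulnerable_children_bounds",
    "growth_adjust",
    "additional_anemic",
    "aggregate",
]

_CLASS_LOWER = ["hh_no_income", "hh_income_le_eighth_mw"]
_CLASS_UPPER = _CLASS_LOWER + ["hh_income_eighth_to_quarter_mw"]


@dataclass
class ScaleUpResult:
    per_municipality: pd.DataFrame
    vulnerable_children_lower: float
    vulnerable_children_upper: float
    additional_anemic_lower: float
    additional_anemic_upper: float
    additional_anemic_lower_headline: int
    additional_anemic_upper_headline: int
    delta_prevalence_pp: float
    share_of_children_lower: float
    share_of_children_upper: float


def _poor_fractions(row) -> tuple[float, float]:
    total = float(row["households_total"])
    if total <= 0:
        raise ValueError(
            f"households_total must be positive (municipality "
            f"{row.get('municipality_id', '?')})"
        )
    lower = sum(float(row[c]) for c in _CLASS_LOWER) / total
    upper = sum(float(row[c]) for c in _CLASS_UPPER) / total
    return lower, upper


def vulnerable_children_bounds(row) -> tuple[float, float]:
    """(lower, upper) estimated vulnerable rural children for one municipality.

    children_6m_5y x rural_fraction x (fraction of households in the poorest
    income classes).  Kept fractional; round only when reporting.
    """
    f_lo, f_hi = _poor_fractions(row)
    base = float(row["children_6m_5y"]) * float(row["rural_fraction"])
    return base * f_lo, base * f_hi


def growth_adjust(row, counts) -> np.ndarray:
    """Scale counts by the municipality's overall population change.

    Multiplies by pop_2019 / pop_2010, applied uniformly (no differential
    rural/urban growth).
    """
    pop_2010 = float(row["pop_2010"])
    if pop_2010 <= 0:
        raise ValueError("pop_2010 must be positive")
    factor = float(row["pop_2019"]) / pop_2010
    return np.asarray(counts, dtype=float) * factor


def additional_anemic(
    vulnerable_children: float, delta_prevalence_pp: float
) -> tuple[float, int]:
    """Children pushed into anemia by a prevalence shift.

    Returns (raw value, headline value rounded to the nearest hundred).
    """
    raw = float(vulnerable_children) * delta_prevalence_pp / 100.0
    headline = int(round(raw / 100.0) * 100)
    return raw, headline


def aggregate(
    census: pd.DataFrame,
    delta_prevalence_pp: float,
    adjust_growth: bool = True,
) -> ScaleUpResult:
    """Per-municipality and aggregate scale-up for a census table."""
    rows = []
    for _, row in census.iterrows():
        lo, hi = vulnerable_children_bounds(row)
        children = float(row["children_6m_5y"]) * float(row["rural_fraction"])
        if adjust_growth:
            lo, hi, children = growth_adjust(row, [lo, hi, children])
        add_lo, _ = additional_anemic(lo, delta_prevalence_pp)
        add_hi, _ = additional_anemic(hi, delta_prevalence_pp)
        rows.append(
            {
                "municipality_id": row["municipality_id"],
                "rural_children": children,
                "vulnerable_children_lower": lo,
                "vulnerable_children_upper": hi,
                "additional_anemic_lower": add_lo,
                "additional_anemic_upper": add_hi,
            }
        )
    per = pd.DataFrame(rows)
    vlo = float(per["vulnerable_children_lower"].sum())
    vhi = float(per["vulnerable_children_upper"].sum())
    total_children = float(per["rural_children"].sum())
    add_lo, head_lo = additional_anemic(vlo, delta_prevalence_pp)
    add_hi, head_hi = additional_anemic(vhi, delta_prevalence_pp)
    return ScaleUpResult(
        per_municipality=per,
        vulnerable_children_lower=vlo,
        vulnerable_children_upper=vhi,
        additional_anemic_lower=add_lo,
        additional_anemic_upper=add_hi,
        additional_anemic_lower_headline=head_lo,
        additional_anemic_upper_headline=head_hi,
        delta_prevalence_pp=float(delta_prevalence_pp),
        share_of_children_lower=vlo / total_children if total_children else np.nan,
        share_of_children_upper=vhi / total_children if total_children else np.nan,
    )
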