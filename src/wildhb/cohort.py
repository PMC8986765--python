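"""Deterministic cohort-construction rules.

Vulnerability classification (monetary income and multidimensional
scorecard median splits, computed within location), derivation of each
child's monthly wildmeat-meal exposure from the household meal count, the
anemia rule (hemoglobin strictly below 11 g/dL), and 30-day consumption
frequency categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import PPI_ITEM_NAMES

__all__ = [
    "ANEMIA_THRESHOLD_GDL",
    "PPIScorecard",
    "VulnerabilityClassifier",
    "classify_by_income",
    "classify_by_ppi",
    "score_ppi",
    "label_children",
    "derive_child_meals",
    "filter_consuming_households",
    "flag_anemia",
    "frequency_category",
    "frequency_table",
]

#: Children with hemoglobin strictly below this are anemic; exactly 11.0 is not.
ANEMIA_THRESHOLD_GDL = 11.0

#: Households with at least this many meals per 30 days eat wildmeat "at
#: least weekly" (about once per week); >= 1 meal is "at least monthly".
WEEKLY_MEALS_CUT = 4
MONTHLY_MEALS_CUT = 1


@dataclass
class PPIScorecard:
    """A 0-100 multidimensional poverty scorecard; higher = less poor.

    ``items`` maps item name -> points awarded for the better-off answer
    (binary items).  The default gives 10 points to each of ten service and
    asset indicators; a replacement can be loaded from YAML.
    """

    items: dict = field(
        default_factory=lambda: {name: 10.0 for name in PPI_ITEM_NAMES}
    )

    def __post_init__(self):
        if any(p < 0 for p in self.items.values()):
            raise ValueError("scorecard points must be nonnegative")
        if abs(sum(self.items.values()) - 100.0) > 1e-9:
            raise ValueError("scorecard maximum score must equal 100")

    @classmethod
    def from_yaml(cls, path) -> "PPIScorecard":
        with open(path, encoding="utf-8") as fh:
            return cls(items=yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dict(self.items), fh, sort_keys=False)


def score_ppi(households: pd.DataFrame, scorecard: PPIScorecard | None = None) -> pd.Series:
    """Sum scorecard points per household (columns ``ppi_<item>``)."""
    card = scorecard or PPIScorecard()
    score = pd.Series(0.0, index=households.index)
    for name, points in card.items.items():
        col = f"ppi_{name}"
        if col not in households.columns:
            raise KeyError(f"scorecard item '{name}' has no column '{col}'")
        answers = households[col]
        if answers.isna().any():
            bad = int(np.flatnonzero(answers.isna().to_numpy())[0])
            raise ValueError(f"unanswered scorecard item '{name}' at row {bad}")
        score = score + answers.astype(float) * points
    return score.rename("ppi_score")


class VulnerabilityClassifier(BaseEstimator, TransformerMixin):
    """Within-location median split of households into most/least vulnerable.

    Parameters
    ----------
    scheme : {'income', 'ppi'}
        Classify by monetary per-capita income or by multidimensional
        scorecard score (lower score = poorer).
    scorecard : PPIScorecard, optional
        Used only for ``scheme='ppi'``.

    Households at or below the within-location median of the chosen measure
    are labelled ``'most'`` (ties go to the protected group); the rest
    ``'least'``.  Medians are learned in :meth:`fit` and stored in
    ``medians_`` so a fitted classifier can label new tables consistently.
    """

    def __init__(self, scheme: str = "income", scorecard: PPIScorecard | None = None):
        self.scheme = scheme
        self.scorecard = scorecard

    def _measure(self, households: pd.DataFrame) -> pd.Series:
        if self.scheme == "income":
            return households["monthly_income_per_capita"].astype(float)
        if self.scheme == "ppi":
            return score_ppi(households, self.scorecard)
        raise ValueError(f"unknown scheme {self.scheme!r}")

    def fit(self, households: pd.DataFrame, y=None) -> "VulnerabilityClassifier":
        measure = self._measure(households)
        self.medians_ = {}
        for loc, grp in measure.groupby(households["location"]):
            if len(grp) == 0:
                continue
            self.medians_[loc] = float(grp.median())
        if not self.medians_:
            raise ValueError("no households to classify")
        return self

    def transform(self, households: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "medians_"):
            raise RuntimeError("classifier is not fitted")
        measure = self._measure(households)
        out = pd.Series(pd.NA, index=households.index, dtype="object")
        for loc, med in self.medians_.items():
            mask = (households["location"] == loc).to_numpy()
            out[mask] = np.where(measure[mask] <= med, "most", "least")
        missing = out.isna()
        if missing.any():
            locs = sorted(households.loc[missing, "location"].unique())
            raise ValueError(f"no fitted median for location(s) {locs}")
        return out.rename(f"by_{self.scheme}")

    def fit_transform(self, households: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(households).transform(households)


def classify_by_income(households: pd.DataFrame) -> pd.Series:
    """Most/least vulnerable by within-location median monetary income."""
    return VulnerabilityClassifier(scheme="income").fit_transform(households)


def classify_by_ppi(
    households: pd.DataFrame, scorecard: PPIScorecard | None = None
) -> pd.Series:
    """Most/least vulnerable by within-location median scorecard score."""
    return VulnerabilityClassifier(scheme="ppi", scorecard=scorecard).fit_transform(
        households
    )


def label_children(
    children: pd.DataFrame,
    households: pd.DataFrame,
    scorecard: PPIScorecard | None = None,
) -> pd.DataFrame:
    """Label every child under both vulnerability schemes.

    Medians are computed over the analyzed cohort, i.e. households that
    appear in the child table.  Returns a frame keyed by ``child_id`` with
    ``location``, ``by_income`` and ``by_ppi`` columns.
    """
    cohort_hh = households[
        households["household_id"].isin(children["household_id"])
    ].reset_index(drop=True)
    labels = cohort_hh[["household_id", "location"]].copy()
    labels["by_income"] = classify_by_income(cohort_hh).to_numpy()
    labels["by_ppi"] = classify_by_ppi(cohort_hh, scorecard).to_numpy()
    out = children[["child_id", "household_id"]].merge(
        labels, on="household_id", how="left"
    )
    if out["by_income"].isna().any():
        bad = out.loc[out["by_income"].isna(), "child_id"].iloc[0]
        raise KeyError(f"child {bad} references a household with no label")
    return out[["child_id", "household_id", "location", "by_income", "by_ppi"]]


def derive_child_meals(children: pd.DataFrame, households: pd.DataFrame) -> pd.Series:
    """Monthly wildmeat meals per child.

    A child inherits the household's full 30-day meal count when the
    caregiver reports that the child normally eats wildmeat when available;
    otherwise the exposure is zero.
    """
    hh_meals = households.set_index("household_id")["wildmeat_meals_30d"]
    missing = ~children["household_id"].isin(hh_meals.index)
    if missing.any():
        bad = children.loc[missing, "household_id"].iloc[0]
        raise KeyError(f"child references unknown household_id {bad!r}")
    inherited = children["household_id"].map(hh_meals).to_numpy()
    meals = np.where(children["normally_eats_wildmeat"].to_numpy(), inherited, 0)
    return pd.Series(meals.astype(int), index=children.index, name="child_meals_30d")


def filter_consuming_households(households: pd.DataFrame) -> pd.DataFrame:
    """Keep households that consumed wildmeat in the previous 12 months.

    Returns an empty (zero-row) frame with the same columns when none did.
    """
    return households[households["consumed_wildmeat_12mo"]].reset_index(drop=True)


def flag_anemia(hemoglobin_gdl) -> pd.Series:
    """True where hemoglobin is strictly below 11 g/dL."""
    hb = pd.Series(hemoglobin_gdl)
    return (hb < ANEMIA_THRESHOLD_GDL).rename("anemic")


def frequency_category(
    meals_30d,
    monthly_cut: int = MONTHLY_MEALS_CUT,
    weekly_cut: int = WEEKLY_MEALS_CUT,
) -> pd.Series:
    """Finest 30-day consumption category per household.

    ``'none-in-30d'`` (0 meals), ``'monthly'`` (monthly_cut..weekly_cut-1)
    or ``'weekly'`` (>= weekly_cut meals).  The "at least monthly" and "at
    least weekly" categories used in reporting are cumulative: weekly
    households are also monthly consumers (see :func:`frequency_table`).
    """
    meals = np.asarray(meals_30d)
    cat = np.where(
        meals >= weekly_cut, "weekly", np.where(meals >= monthly_cut, "monthly", "none-in-30d")
    )
    return pd.Series(
        pd.Categorical(cat, categories=["none-in-30d", "monthly", "weekly"], ordered=True),
        name="frequency_category",
    )


def frequency_table(
    households: pd.DataFrame,
    monthly_cut: int = MONTHLY_MEALS_CUT,
    weekly_cut: int = WEEKLY_MEALS_CUT,
) -> pd.DataFrame:
    """Cumulative consumption-frequency shares by location.

    Reports, per location, the percentage of households eating wildmeat at
    least monthly and at least weekly in the previous 30 days.
    """
    rows = []
    for loc, grp in households.groupby("location"):
        meals = grp["wildmeat_meals_30d"].to_numpy()
        n = len(meals)
        rows.append(
            {
                "location": loc,
                "n_households": n,
                "pct_at_least_monthly": 100.0 * np.mean(meals >= monthly_cut),
                "pct_at_least_weekly": 100.0 * np.mean(meals >= weekly_cut),
            }
        )
    return pd.DataFrame(rows)
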