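import pandas as pd
import pytest

from wildhb import SimConfig, generate_cohort
from wildhb.recovery import assemble_analysis_frame


@pytest.fixture(scope="session")
def default_cohort():
    """Full-design synthetic cohort: 800 urban + 311 rural households."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, small cohort for plumbing tests."""
    cfg = SimConfig(
        seed=11,
        n_urban_households=60,
        n_rural_households=60,
        communities_per_rural_municipality=3,
        fraction_with_children_urban=0.6,
        fraction_with_children_rural=0.7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def analysis_frame(default_cohort):
    hh, ch = default_cohort
    return assemble_analysis_frame(hh, ch)


@pytest.fixture()
def toy_households():
    rows = []
    for i, (loc, inc, cons, meals) in enumerate(
        [
            ("rural", 100.0, True, 5),
            ("rural", 200.0, True, 0),
            ("rural", 300.0, False, 0),
            ("rural", 400.0, True, 12),
            ("urban", 500.0, False, 0),
            ("urban", 800.0, True, 2),
        ]
    ):
        rows.append(
            {
                "household_id": f"H{i + 1}",
                "municipality_id": "M1",
                "community_id": "M1-C01" if loc == "rural" else "",
                "location": loc,
                "monthly_income_per_capita": inc,
                "consumed_wildmeat_12mo": cons,
                "wildmeat_meals_30d": meals,
            }
        )
    return pd.DataFrame(rows)
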