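"""Synthetic cohort generator.

Generates seeded household and child tables with the nested structure the
downstream analyses assume: children in households, households in riverine
communities (rural) and municipalities, a two-season survey design, and a
hemoglobin outcome driven by a Gaussian mixed model whose only wildmeat
effect acts in the most-vulnerable rural stratum.

Hemoglobin for child *i* in household *h*, community *c* is drawn as::

    Hb_i = mu(location) + effects(covariates_i, centered within location)
           + beta_meal * (meals_i - mean_meals_MV) * 1[most-vulnerable rural]
           + u_c + u_h + e_i

with u_c ~ N(0, sigma_community^2) (rural only), u_h ~ N(0, sigma_household^2)
and e_i ~ N(0, sigma_residual^2).  Because every systematic term is centered
within location (and the meal effect within the most-vulnerable rural
stratum), the configured location means are the marginal means of the
generated hemoglobin — which is what the generative-mean oracles check.

Whether a child *normally eats* wildmeat is Bernoulli with log-odds::

    intercept(location) + log(age_or_per_year) * age
    + log(migrant_or) * 1[migrant head, urban] + v_h

with a household-level logit effect v_h ~ N(0, sigma_logit_household^2);
"ever ate" uses the same linear predictor shifted upward so that it is
implied by "normally eats" and shares its monotone age profile.

A child's monthly wildmeat meal exposure equals the household's 30-day meal
count when the child normally eats wildmeat and zero otherwise — the same
rule the analysis side applies — so generation and inference agree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

__all__ = [
    "generate_cohort",
    "generate_census",
    "HOUSEHOLD_COLUMNS",
    "CHILD_COLUMNS",
    "PPI_ITEM_NAMES",
]

#: Binary scorecard items emulating a multidimensional poverty scorecard:
#: access to services plus selected assets.  Each is worth 10 points.
PPI_ITEM_NAMES = [
    "electricity",
    "piped_water",
    "sanitation",
    "fridge",
    "motorized_vehicle",
    "tv",
    "mobile_phone",
    "gas_stove",
    "head_completed_primary",
    "formal_employment",
]

# Baseline log-odds of the "better-off" answer for each item, before the
# income gradient; ordered as PPI_ITEM_NAMES.
_PPI_ITEM_BASE_LOGIT = {
    "electricity": 1.2,
    "piped_water": 0.2,
    "sanitation": None,  # taken from the private_toilet draw
    "fridge": 0.6,
    "motorized_vehicle": -0.4,
    "tv": 0.8,
    "mobile_phone": 0.9,
    "gas_stove": 1.0,
    "head_completed_primary": 0.1,
    "formal_employment": -0.9,
}

HOUSEHOLD_COLUMNS = [
    "household_id",
    "municipality_id",
    "community_id",
    "location",
    "monthly_income_per_capita",
    "migrant_head",
    "season",
    "n_members",
    "private_toilet",
    "fluvial_distance_km",
    "consumed_wildmeat_12mo",
    "wildmeat_meals_30d",
    "days_per_week_fish",
    "days_per_week_chicken",
    "days_per_week_beef",
] + [f"ppi_{name}" for name in PPI_ITEM_NAMES]

CHILD_COLUMNS = [
    "child_id",
    "household_id",
    "age_years",
    "sex",
    "maternal_education_years",
    "hemoglobin_gdl",
    "ever_ate_wildmeat",
    "normally_eats_wildmeat",
    "malaria_12mo",
    "worms_3mo",
]


def _split_counts(total: int, parts: int) -> np.ndarray:
    """Split `total` into `parts` near-equal integer counts."""
    base = total // parts
    out = np.full(parts, base, dtype=int)
    out[: total - base * parts] += 1
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _center(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Center x within mask (returns zeros outside the mask)."""
    out = np.zeros_like(x, dtype=float)
    out[mask] = x[mask] - x[mask].mean()
    return out


def generate_cohort(config: SimConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Parameters
    ----------
    config : SimConfig, optional
        Generator parameters; defaults describe the full study design
        (800 urban + 311 rural households in 4 municipalities).

    Returns
    -------
    (households, children) : tuple of DataFrame
        Household and child tables with the documented column schemas.
        Deterministic given ``config.seed``.
    """
    cfg = config if config is not None else SimConfig()
    cfg.validate()

    ss = np.random.SeedSequence(cfg.seed)
    rng_h, rng_c, rng_hb = (np.random.default_rng(s) for s in ss.spawn(3))

    # ---------------- households ----------------
    munis = [f"M{i + 1}" for i in range(cfg.n_municipalities)]
    urban_counts = _split_counts(cfg.n_urban_households, cfg.n_municipalities)
    rural_counts = _split_counts(cfg.n_rural_households, cfg.n_municipalities)

    muni, comm, loc = [], [], []
    for m, nu, nr in zip(munis, urban_counts, rural_counts):
        muni += [m] * nu
        comm += [""] * nu
        loc += ["urban"] * nu
        # rural households assigned uniformly to this municipality's communities
        cids = rng_h.integers(0, cfg.communities_per_rural_municipality, size=nr)
        muni += [m] * nr
        comm += [f"{m}-C{c + 1:02d}" for c in cids]
        loc += ["rural"] * nr

    n_hh = len(muni)
    hh = pd.DataFrame(
        {
            "household_id": [f"H{i + 1:04d}" for i in range(n_hh)],
            "municipality_id": muni,
            "community_id": comm,
            "location": loc,
        }
    )
    rural = (hh["location"] == "rural").to_numpy()
    urban = ~rural

    # fluvial travel distance: one draw per community, shared by its households
    communities = sorted({c for c in comm if c})
    comm_dist = {
        c: float(np.round(rng_h.lognormal(np.log(40.0), 0.8), 1)) for c in communities
    }
    hh["fluvial_distance_km"] = [comm_dist.get(c, 0.0) for c in comm]

    mu_inc = np.where(rural, cfg.income_lognorm_mu_rural, cfg.income_lognorm_mu_urban)
    hh["monthly_income_per_capita"] = np.round(
        rng_h.lognormal(mu_inc, cfg.income_lognorm_sigma), 2
    )
    hh["migrant_head"] = urban & (rng_h.random(n_hh) < cfg.p_migrant_urban)
    hh["season"] = np.where(rng_h.random(n_hh) < 0.5, "wet", "dry")
    hh["n_members"] = 2 + rng_h.poisson(3.0, size=n_hh)
    p_toilet = np.where(rural, cfg.p_private_toilet_rural, cfg.p_private_toilet_urban)
    hh["private_toilet"] = rng_h.random(n_hh) < p_toilet

    # wildmeat: 12-month consumer flag, then 30-day meal count (negative
    # binomial among consumers; a consumer may still report 0 meals)
    p12 = np.where(rural, cfg.p_consumer_12mo_rural, cfg.p_consumer_12mo_urban)
    consumer = rng_h.random(n_hh) < p12
    mu_meals = np.where(
        rural,
        cfg.mean_meals_rural / cfg.p_consumer_12mo_rural,
        cfg.mean_meals_urban / cfg.p_consumer_12mo_urban,
    )
    r_disp = np.where(rural, cfg.nb_dispersion_rural, cfg.nb_dispersion_urban)
    meals = rng_h.negative_binomial(r_disp, r_disp / (r_disp + mu_meals))
    hh["consumed_wildmeat_12mo"] = consumer
    hh["wildmeat_meals_30d"] = np.where(consumer, meals, 0).astype(int)

    for asf in ("fish", "chicken", "beef"):
        p = np.where(
            rural,
            cfg.asf_days_mean[f"{asf}_rural"] / 7.0,
            cfg.asf_days_mean[f"{asf}_urban"] / 7.0,
        )
        hh[f"days_per_week_{asf}"] = rng_h.binomial(7, p)

    # scorecard answers: Bernoulli with log-odds monotone in log-income, so
    # the monetary and multidimensional classifications correlate imperfectly
    z_inc = (np.log(hh["monthly_income_per_capita"].to_numpy()) - mu_inc) / (
        cfg.income_lognorm_sigma
    )
    for name in PPI_ITEM_NAMES:
        base = _PPI_ITEM_BASE_LOGIT[name]
        if base is None:
            hh[f"ppi_{name}"] = hh["private_toilet"]
        else:
            eta = base + cfg.ppi_income_strength * z_inc - 0.8 * rural
            hh[f"ppi_{name}"] = rng_h.random(n_hh) < _sigmoid(eta)

    hh = hh[HOUSEHOLD_COLUMNS]

    # ---------------- children ----------------
    frac_kids = np.where(
        rural, cfg.fraction_with_children_rural, cfg.fraction_with_children_urban
    )
    has_children = rng_c.random(n_hh) < frac_kids
    p_two = np.where(rural, cfg.mean_children_rural, cfg.mean_children_urban) - 1.0
    n_children = np.where(
        has_children, 1 + (rng_c.random(n_hh) < p_two).astype(int), 0
    )

    child_hh_idx = np.repeat(np.arange(n_hh), n_children)
    n_ch = len(child_hh_idx)
    if n_ch == 0:
        raise ConfigError("config produced a cohort with no children")

    ch = pd.DataFrame(
        {
            "child_id": [f"C{i + 1:04d}" for i in range(n_ch)],
            "household_id": hh["household_id"].to_numpy()[child_hh_idx],
        }
    )
    ch_rural = rural[child_hh_idx]
    ch["age_years"] = np.clip(
        np.round(rng_c.uniform(0.5, 5.0, size=n_ch), 2), 0.5, 4.99
    )
    ch["sex"] = np.where(rng_c.random(n_ch) < 0.5, "F", "M")

    # maternal education drawn per household, copied to its children
    edu_mean = np.where(
        rural, cfg.maternal_education_mean_rural, cfg.maternal_education_mean_urban
    ).astype(float)
    edu_mean = edu_mean + cfg.maternal_education_migrant_shift * hh[
        "migrant_head"
    ].to_numpy().astype(float)
    edu_hh = np.clip(
        np.round(rng_c.normal(edu_mean, cfg.maternal_education_sd), 1), 0.0, 16.0
    )
    ch["maternal_education_years"] = edu_hh[child_hh_idx]

    p_mal = np.where(
        ch_rural,
        cfg.morbidity_prevalence["malaria_rural"],
        cfg.morbidity_prevalence["malaria_urban"],
    )
    p_worm = np.where(
        ch_rural,
        cfg.morbidity_prevalence["worms_rural"],
        cfg.morbidity_prevalence["worms_urban"],
    )
    ch["malaria_12mo"] = rng_c.random(n_ch) < p_mal
    ch["worms_3mo"] = rng_c.random(n_ch) < p_worm

    # wildmeat introduction: shared household logit effect + age/location/migrant
    v_hh = rng_c.normal(0.0, cfg.sigma_logit_household, size=n_hh)
    intercept = np.where(
        ch_rural, cfg.sharing_intercept_rural, cfg.sharing_intercept_urban
    )
    eta = (
        intercept
        + np.log(cfg.age_or_per_year) * ch["age_years"].to_numpy()
        + np.log(cfg.migrant_or)
        * hh["migrant_head"].to_numpy().astype(float)[child_hh_idx]
        + v_hh[child_hh_idx]
    )
    u = rng_c.random(n_ch)
    ch["normally_eats_wildmeat"] = u < _sigmoid(eta)
    ch["ever_ate_wildmeat"] = u < _sigmoid(eta + cfg.ever_ate_logit_shift)

    # ---------------- hemoglobin ----------------
    hh_meals = hh["wildmeat_meals_30d"].to_numpy()
    child_meals = np.where(
        ch["normally_eats_wildmeat"].to_numpy(), hh_meals[child_hh_idx], 0
    ).astype(float)

    # most-vulnerable rural stratum: income at or below the median of rural
    # households *with children* (the analyzed cohort)
    inc = hh["monthly_income_per_capita"].to_numpy()
    rural_with_kids = rural & (n_children > 0)
    med_rural = np.median(inc[rural_with_kids])
    hh_mv_rural = rural_with_kids & (inc <= med_rural)
    ch_mv_rural = hh_mv_rural[child_hh_idx]

    eff = cfg.covariate_effects
    base = np.where(ch_rural, cfg.mean_hb_rural, cfg.mean_hb_urban)
    lin = base.astype(float)

    z_inc_child = (np.log(inc[child_hh_idx]) - mu_inc[child_hh_idx]) / (
        cfg.income_lognorm_sigma
    )
    muni_offsets = np.array(
        [
            cfg.municipality_hb_offsets[i % len(cfg.municipality_hb_offsets)]
            for i in range(cfg.n_municipalities)
        ]
    )
    muni_idx = np.array(
        [munis.index(m) for m in hh["municipality_id"].to_numpy()[child_hh_idx]]
    )
    wet = (hh["season"].to_numpy()[child_hh_idx] == "wet").astype(float)
    dist = hh["fluvial_distance_km"].to_numpy()[child_hh_idx]
    members = hh["n_members"].to_numpy().astype(float)[child_hh_idx]

    for mask in (ch_rural, ~ch_rural):
        lin += _center(cfg.hb_income_effect * z_inc_child, mask)
        lin += _center(eff["age_per_year"] * ch["age_years"].to_numpy(), mask)
        lin += _center(eff["malaria"] * ch["malaria_12mo"].to_numpy().astype(float), mask)
        lin += _center(eff["worms"] * ch["worms_3mo"].to_numpy().astype(float), mask)
        lin += _center(
            eff["maternal_education_per_year"]
            * ch["maternal_education_years"].to_numpy(),
            mask,
        )
        lin += _center(eff["season_wet"] * wet, mask)
        lin += _center(muni_offsets[muni_idx], mask)
        lin += _center(eff["household_size_per_member"] * members, mask)
    lin += _center(eff["fluvial_distance_per_km"] * dist, ch_rural)
    # the wildmeat effect, centered within its stratum so the rural marginal
    # mean stays at mean_hb_rural
    lin += cfg.beta_meal * _center(child_meals, ch_mv_rural)

    u_comm = {c: rng_hb.normal(0.0, cfg.sigma_community) for c in communities}
    u_house = rng_hb.normal(0.0, cfg.sigma_household, size=n_hh)
    resid = rng_hb.normal(0.0, cfg.sigma_residual, size=n_ch)
    comm_arr = np.array([u_comm.get(c, 0.0) for c in hh["community_id"].to_numpy()])

    hb = lin + comm_arr[child_hh_idx] + u_house[child_hh_idx] + resid
    ch["hemoglobin_gdl"] = np.round(hb, 3)

    ch = ch[CHILD_COLUMNS]
    return hh, ch


# ----------------------------------------------------------------------
def generate_census(
    n_municipalities: int = 44,
    seed: int = 0,
    growth_mean: float = 1.15,
) -> pd.DataFrame:
    """Generate a synthetic municipality census extract.

    Emulates grouped census data for river-dependent municipalities: 2010 and
    2019 population counts, rural population share, counts of young children
    (6 months to 5 years) and household counts per per-capita income class
    expressed as fractions of the minimum wage.  Class proportions are drawn
    Dirichlet with most mass in the poorest classes, consistent with a region
    where one half to four fifths of households fall at or below 1/4 of the
    minimum wage per capita.
    """
    rng = np.random.default_rng(seed)
    pop_2010 = rng.integers(13_000, 65_000, size=n_municipalities)
    growth = rng.normal(growth_mean, 0.08, size=n_municipalities).clip(0.85, 1.45)
    rural_fraction = rng.uniform(0.45, 0.8, size=n_municipalities)
    children = (pop_2010 * rng.uniform(0.08, 0.11, size=n_municipalities)).astype(int)
    households = (pop_2010 / rng.uniform(4.2, 5.2, size=n_municipalities)).astype(int)
    shares = rng.dirichlet(np.array([0.10, 0.45, 0.25, 0.12, 0.08]) * 60.0,
                           size=n_municipalities)
    class_counts = np.floor(shares * households[:, None]).astype(int)
    # remainder into the modal (poorest non-zero-income) class
    class_counts[:, 1] += households - class_counts.sum(axis=1)
    return pd.DataFrame(
        {
            "municipality_id": [f"U{i + 1:02d}" for i in range(n_municipalities)],
            "pop_2010": pop_2010,
            "pop_2019": (pop_2010 * growth).astype(int),
            "rural_fraction": np.round(rural_fraction, 3),
            "children_6m_5y": children,
            "households_total": households,
            "hh_no_income": class_counts[:, 0],
            "hh_income_le_eighth_mw": class_counts[:, 1],
            "hh_income_eighth_to_quarter_mw": class_counts[:, 2],
            "hh_income_quarter_to_half_mw": class_counts[:, 3],
            "hh_income_above_half_mw": class_counts[:, 4],
        }
    )
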