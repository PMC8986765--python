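"""Configuration for the synthetic Amazonian cohort generator.

The generator emulates a two-wave household survey in four river-dependent
municipalities of central Amazonia: in each municipality an urban arm and a
set of riverine rural communities are sampled, children aged 6 months to
5 years are nested in households, and households are nested in communities
(rural) and municipalities.  :class:`SimConfig` holds every knob of that
generative model; its defaults encode the study conditions the package is
designed around (sample-size structure, stratum hemoglobin means, the
0.05 g/dL-per-meal effect in the most-vulnerable rural stratum, an age odds
ratio of 2.4 for wildmeat introduction, and a rural household wildmeat-meal
mean several times the urban one).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["SimConfig", "DEFAULT_COVARIATE_EFFECTS", "DEFAULT_MORBIDITY_PREVALENCE"]

#: Hemoglobin effect sizes (g/dL per natural unit) used by the generator for
#: the control covariates of the hemoglobin model.  All effects are applied
#: centered within location so that stratum means stay at their configured
#: values.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age_per_year": 0.12,
    "malaria": -0.35,
    "worms": -0.25,
    "maternal_education_per_year": 0.03,
    "season_wet": 0.08,
    "fluvial_distance_per_km": -0.002,
    "household_size_per_member": -0.02,
}

#: 12-month malaria and 3-month intestinal-worm diagnosis prevalences.
DEFAULT_MORBIDITY_PREVALENCE: dict[str, float] = {
    "malaria_rural": 0.18,
    "malaria_urban": 0.05,
    "worms_rural": 0.22,
    "worms_urban": 0.12,
}

#: Mean days/week on which each domesticated animal-source food was eaten,
#: by location (binomial(7, mean/7) in the generator).
DEFAULT_ASF_DAYS_MEAN: dict[str, float] = {
    "fish_rural": 6.24,
    "fish_urban": 3.22,
    "chicken_rural": 0.81,
    "chicken_urban": 2.05,
    "beef_rural": 0.15,
    "beef_urban": 1.05,
}


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generative model.

    Counts are per the full study design (e.g. 800 urban + 311 rural
    households); hemoglobin quantities are g/dL; wildmeat meal means are
    meals per 30 days at the household level; odds ratios refer to the
    logistic model for whether a child normally eats wildmeat.
    """

    seed: int = 0

    # --- design structure ---
    n_municipalities: int = 4
    communities_per_rural_municipality: int = 10
    n_urban_households: int = 800
    n_rural_households: int = 311
    fraction_with_children_urban: float = 291 / 800
    fraction_with_children_rural: float = 145 / 311
    # children per child-bearing household: 1 or 2, so mean-1 = P(two children)
    mean_children_urban: float = 390 / 291
    mean_children_rural: float = 220 / 145

    # --- hemoglobin model (g/dL) ---
    beta_meal: float = 0.05
    sigma_household: float = 0.5
    sigma_community: float = 0.3
    sigma_residual: float = 1.0
    mean_hb_rural: float = 10.61
    mean_hb_urban: float = 11.07
    hb_income_effect: float = 0.13
    municipality_hb_offsets: tuple = (0.06, -0.02, 0.01, -0.05)
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )

    # --- household wildmeat consumption (meals / 30 days) ---
    mean_meals_rural: float = 7.1
    mean_meals_urban: float = 1.3
    p_consumer_12mo_rural: float = 0.83
    p_consumer_12mo_urban: float = 0.67
    nb_dispersion_rural: float = 0.7
    nb_dispersion_urban: float = 0.45

    # --- wildmeat introduction into child diets (logistic) ---
    age_or_per_year: float = 2.4
    migrant_or: float = 2.48
    sharing_intercept_rural: float = -0.17
    sharing_intercept_urban: float = -2.09
    sigma_logit_household: float = 0.6
    ever_ate_logit_shift: float = 1.2

    # --- socioeconomics ---
    p_migrant_urban: float = 0.35
    income_lognorm_mu_rural: float = math.log(120.0)
    income_lognorm_mu_urban: float = math.log(250.0)
    income_lognorm_sigma: float = 0.7
    ppi_income_strength: float = 1.2
    maternal_education_mean_rural: float = 6.5
    maternal_education_mean_urban: float = 8.4
    maternal_education_migrant_shift: float = -1.6
    maternal_education_sd: float = 3.0
    p_private_toilet_rural: float = 0.04
    p_private_toilet_urban: float = 0.70

    # --- health & diet ---
    morbidity_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_MORBIDITY_PREVALENCE)
    )
    asf_days_mean: dict = field(default_factory=lambda: dict(DEFAULT_ASF_DAYS_MEAN))

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check invariants; raise :class:`ConfigError` on violation."""
        counts = {
            "n_municipalities": self.n_municipalities,
            "communities_per_rural_municipality": self.communities_per_rural_municipality,
            "n_urban_households": self.n_urban_households,
            "n_rural_households": self.n_rural_households,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        probs = {
            "fraction_with_children_urban": self.fraction_with_children_urban,
            "fraction_with_children_rural": self.fraction_with_children_rural,
            "p_consumer_12mo_rural": self.p_consumer_12mo_rural,
            "p_consumer_12mo_urban": self.p_consumer_12mo_urban,
            "p_migrant_urban": self.p_migrant_urban,
            "p_private_toilet_rural": self.p_private_toilet_rural,
            "p_private_toilet_urban": self.p_private_toilet_urban,
            **{k: v for k, v in self.morbidity_prevalence.items()},
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        # zero-variance limits are permitted so degenerate behaviour is testable
        for name in ("sigma_household", "sigma_community", "sigma_residual",
                     "sigma_logit_household"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("age_or_per_year", "migrant_or"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0 (odds ratio)")
        for name in ("mean_meals_rural", "mean_meals_urban",
                     "nb_dispersion_rural", "nb_dispersion_urban"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("mean_children_urban", "mean_children_rural"):
            if not 1.0 <= getattr(self, name) <= 2.0:
                raise ConfigError(f"{name} must lie in [1, 2] (households have 1 or 2 children)")
        if self.fraction_with_children_urban * self.n_urban_households < 1:
            raise ConfigError("config implies zero urban households with children")
        if self.fraction_with_children_rural * self.n_rural_households < 1:
            raise ConfigError("config implies zero rural households with children")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["municipality_hb_offsets"] = list(self.municipality_hb_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "municipality_hb_offsets" in d:
            d["municipality_hb_offsets"] = tuple(d["municipality_hb_offsets"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SimConfig":
        d = self.to_dict()
        d.update(kwargs)
        return SimConfig.from_dict(d)
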