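"""Parameter containers for the farm model.

All defaults describe a representative Louisiana red-eared slider
(*Trachemys scripta elegans*) farm: a ~2 ha outdoor stock-pond complex
holding the breeding population, an indoor incubation facility, and heated
greenhouse ponds in which retained hatchlings are reared to yearlings
("4-inch turtles", the minimum legal size for US domestic pet sale).

Containers are plain frozen dataclasses validated at construction; all
rates are annual fractions, all abundances are turtles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


# Fixed age-class structure: females mature between five and six years of
# age, males one year earlier, so mature animals pool into F6 / M5.
N_FEMALE_CLASSES = 7  # F0 hatchling, F1 yearling, F2-F5 juvenile stock, F6 adult
N_MALE_CLASSES = 6    # M0, M1, M2-M4 juvenile stock, M5 adult
FIRST_STOCK_CLASS = 2


@dataclass(frozen=True)
class LifeHistory:
    """Demographic rates and reproduction parameters.

    Parameters
    ----------
    stock_survivorship : float
        Annual survival ``s`` of juvenile and adult stock in the outdoor
        ponds (default 0.97; adult mortality is its complement).
    greenhouse_mortality : float
        First-year mortality of the greenhouse cohort (hatchling to
        yearling), default 0.15.  Elevated because cohorts include animals
        with shell and genetic defects.
    clutch_size : float
        Mean eggs per clutch (default 10).
    clutch_sd : float
        Clutch-size standard deviation, used only by the stochastic
        variant (default 2.8).
    clutches_per_season : float
        Clutches laid per female per nesting season (default 3).
    hatch_rate : float
        Fraction of incubated eggs that hatch (default 0.85).
    nesting_fraction : float
        Fraction of adult females laying fertile eggs when the adult sex
        ratio is at or above its optimum (default 0.95).
    """

    stock_survivorship: float = 0.97
    greenhouse_mortality: float = 0.15
    clutch_size: float = 10.0
    clutch_sd: float = 2.8
    clutches_per_season: float = 3.0
    hatch_rate: float = 0.85
    nesting_fraction: float = 0.95

    def __post_init__(self) -> None:
        for name in ("stock_survivorship", "greenhouse_mortality",
                     "hatch_rate", "nesting_fraction"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")
        for name in ("clutch_size", "clutch_sd", "clutches_per_season"):
            _check(getattr(self, name) >= 0.0, f"{name} must be >= 0")

    @property
    def adult_mortality(self) -> float:
        """Annual adult stock mortality, m_A = 1 - s."""
        return 1.0 - self.stock_survivorship

    @property
    def birth_rate(self) -> float:
        """Mean hatchlings per adult female per year at the optimal sex ratio."""
        return per_capita_birth_rate(self.clutch_size, self.clutches_per_season,
                                     self.hatch_rate, self.nesting_fraction)


def per_capita_birth_rate(clutch_size: float, clutches_per_season: float,
                          hatch_rate: float, nesting_fraction: float) -> float:
    """Hatchlings per adult female per year, CS * NC * HR * nesting fraction.

    With the farm defaults (10, 3, 0.85, 0.95) this is 24.225.
    """
    for name, v in (("clutch_size", clutch_size),
                    ("clutches_per_season", clutches_per_season),
                    ("hatch_rate", hatch_rate),
                    ("nesting_fraction", nesting_fraction)):
        _check(v >= 0.0, f"{name} must be >= 0")
    return clutch_size * clutches_per_season * hatch_rate * nesting_fraction


@dataclass(frozen=True)
class StockConfig:
    """Stock-pond capacity and composition limits.

    ``density_per_ha`` is a healthy (not maximal) stocking density; the
    product with pond area gives the 25,000-turtle threshold the farm
    manages toward, split ``female_proportion`` : 1 - ``female_proportion``
    between the sexes.
    """

    density_per_ha: float = 12_500.0
    hectares: float = 2.0
    female_proportion: float = 0.75
    optimal_sex_ratio: float = 0.33  # minimum adult M:F for full fertility

    def __post_init__(self) -> None:
        _check(self.density_per_ha >= 0.0, "density_per_ha must be >= 0")
        _check(self.hectares >= 0.0, "hectares must be >= 0")
        _check(0.0 < self.female_proportion < 1.0,
               "female_proportion must lie in (0, 1)")
        _check(self.optimal_sex_ratio > 0.0, "optimal_sex_ratio must be > 0")

    @property
    def max_females(self) -> float:
        return self.density_per_ha * self.hectares * self.female_proportion

    @property
    def max_males(self) -> float:
        return self.density_per_ha * self.hectares * (1.0 - self.female_proportion)

    @property
    def male_recruit_ratio(self) -> float:
        """Male:female head-start ratio that preserves the stock sex split."""
        return (1.0 - self.female_proportion) / self.female_proportion


def derive_capacities(config: StockConfig) -> tuple[float, float]:
    """Maximum female and male stock abundances (maxF, maxM)."""
    return config.max_females, config.max_males


@dataclass(frozen=True)
class Policy:
    """Managed parameters of the farming operation.

    ``hatchling_harvest`` (h_H) is the fraction of female hatchlings sold
    at emergence; ``birth_adjustment`` (ADJ) the fraction of eggs incubated
    at female-producing temperatures (red-eared sliders have temperature-
    dependent sex determination, so hatchling sex is set in the incubator);
    ``adult_harvest`` (h_A) the fraction of adult stock removed for meat
    markets each year — zero under traditional farming.
    """

    hatchling_harvest: float = 0.0
    adult_harvest: float = 0.0
    birth_adjustment: float = 1.0
    yearling_target: float = 55_000.0

    def __post_init__(self) -> None:
        _check(0.0 <= self.hatchling_harvest < 1.0,
               "hatchling_harvest must lie in [0, 1)")
        _check(0.0 <= self.adult_harvest <= 1.0,
               "adult_harvest must lie in [0, 1]")
        _check(0.0 <= self.birth_adjustment <= 1.0,
               "birth_adjustment must lie in [0, 1]")
        _check(self.yearling_target >= 0.0, "yearling_target must be >= 0")

    def with_(self, **kwargs) -> "Policy":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class OperatingTargets:
    """Constraints the management controller holds at steady state."""

    yearling_target: float = 55_000.0   # yearlings sold per year
    sex_ratio_target: float = 0.33      # minimum adult M:F in the stock
    stock_cap: float = 25_000.0         # total stock threshold (both sexes)

    def __post_init__(self) -> None:
        _check(self.yearling_target > 0.0, "yearling_target must be > 0")
        _check(self.sex_ratio_target > 0.0, "sex_ratio_target must be > 0")
        _check(self.stock_cap > 0.0, "stock_cap must be > 0")


@dataclass(frozen=True)
class EconParams:
    """Prices, costs and discounting for the bio-economic projection.

    Prices/costs are per turtle in USD.  ``discount_rate`` (d) devalues
    future cash flows, ``market_rate`` (m) appreciates future sale prices;
    both compound continuously over the ``horizon`` production cycle.
    """

    price_hatchling: float = 0.35
    price_yearling: float = 7.50
    cost_hatchling: float = 0.25
    cost_yearling: float = 4.50
    discount_rate: float = 0.05
    market_rate: float = 0.05
    horizon: int = 40
    adult_mass_kg: float = 1.6
    meat_yield: float = 0.4

    def __post_init__(self) -> None:
        for name in ("price_hatchling", "price_yearling",
                     "cost_hatchling", "cost_yearling"):
            _check(getattr(self, name) >= 0.0, f"{name} must be >= 0")
        _check(self.horizon >= 1, "horizon must be >= 1")
        _check(0.0 < self.meat_yield <= 1.0, "meat_yield must lie in (0, 1]")
        _check(self.discount_rate >= 0.0 and self.market_rate >= 0.0,
               "discount_rate and market_rate must be >= 0")
        _check(self.adult_mass_kg > 0.0, "adult_mass_kg must be > 0")


@dataclass(frozen=True)
class StochasticConfig:
    """Configuration of the stochastic model variant.

    Clutch size varies from season to season as a truncated normal draw;
    warm winters trigger a mass die-off of the outdoor stock (the heated
    greenhouse is unaffected) with probability ``mass_mortality_prob`` per
    year, killing ``mass_mortality_fraction`` of every stock class (or a
    Uniform(0, fraction) share when ``mortality_mode`` is "uniform").
    """

    clutch_mean: float = 10.0
    clutch_sd: float = 2.8
    clutch_bounds: tuple[float, float] = (1.0, 22.0)
    mass_mortality_prob: float = 1.0 / 6.0
    mass_mortality_fraction: float = 0.10
    mortality_mode: str = "fixed"  # "fixed" | "uniform"
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.clutch_sd >= 0.0, "clutch_sd must be >= 0")
        lo, hi = self.clutch_bounds
        _check(lo <= hi, "clutch_bounds must be ordered")
        _check(0.0 <= self.mass_mortality_prob <= 1.0,
               "mass_mortality_prob must lie in [0, 1]")
        _check(0.0 <= self.mass_mortality_fraction <= 1.0,
               "mass_mortality_fraction must lie in [0, 1]")
        _check(self.mortality_mode in ("fixed", "uniform"),
               "mortality_mode must be 'fixed' or 'uniform'")
        _check(self.n_reps >= 1, "n_reps must be >= 1")


def _public_fields(cls) -> tuple[str, ...]:
    return tuple(f.name for f in fields(cls))
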