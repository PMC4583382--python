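"""Bio-economic layer: revenue, cost, discounted accumulation, break-even.

Annual revenue is hatchling exports plus domestic yearling sales; annual
cost covers hatchling production and the rearing of every greenhouse
yearling, including the head-starts that are never sold.  Expected total
profit over an ``n``-year production cycle discounts costs at the discount
rate ``d`` and lets revenue appreciate at the market rate ``m``, both
compounding continuously:

    E(P) = sum_k exp((m - d) k) R  -  sum_k exp(-d k) C

with the year index ``k`` running 0 .. n-1 by default (the calibrated
convention; ``convention="one_based"`` gives the literal 1 .. n variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .dynamics import AnnualReport
from .params import EconParams, ParameterError

Convention = Literal["zero_based", "one_based"]

__all__ = [
    "ProfitProjection", "accumulated_profit", "annual_cost",
    "annual_discounted_profit_series", "annual_profit", "annual_revenue",
    "min_adult_price", "price_per_kg_meat", "profit_grid", "project",
]


def annual_revenue(report: AnnualReport, econ: EconParams) -> float:
    """Hatchling plus yearling revenue, USD per year."""
    return report.H * econ.price_hatchling + report.Y_sold * econ.price_yearling


def annual_cost(report: AnnualReport, econ: EconParams) -> float:
    """Hatchling plus yearling production cost, USD per year.

    Yearling cost applies to every greenhouse product ``B`` — sold
    yearlings *and* head-starts — since all are reared through a heated
    winter.
    """
    return report.H * econ.cost_hatchling + report.B * econ.cost_yearling


def annual_profit(report: AnnualReport, econ: EconParams) -> float:
    """Undiscounted annual profit, USD per year."""
    return annual_revenue(report, econ) - annual_cost(report, econ)


def _year_index(n: int, convention: Convention) -> np.ndarray:
    if n < 1:
        raise ParameterError("horizon must be >= 1")
    if convention == "zero_based":
        return np.arange(n, dtype=float)
    if convention == "one_based":
        return np.arange(1, n + 1, dtype=float)
    raise ParameterError(f"unknown convention {convention!r}")


def annual_discounted_profit_series(revenue: float, cost: float, d: float,
                                    m: float, n: int,
                                    convention: Convention = "zero_based",
                                    ) -> np.ndarray:
    """Per-year discounted profit terms exp((m-d)k) R - exp(-d k) C.

    The revenue component grows iff m > d and is constant at m = d, so
    the series is eventually increasing exactly when m >= d.
    """
    k = _year_index(n, convention)
    return revenue * np.exp((m - d) * k) - cost * np.exp(-d * k)


def accumulated_profit(revenue: float, cost: float, d: float, m: float,
                       n: int, convention: Convention = "zero_based") -> float:
    """Expected total profit accumulated over the production cycle, USD."""
    return float(annual_discounted_profit_series(
        revenue, cost, d, m, n, convention).sum())


def profit_grid(revenue: float, cost: float, d_values: Iterable[float],
                m_values: Iterable[float], n: int,
                convention: Convention = "zero_based") -> pd.DataFrame:
    """Accumulated profit for every (discount, market) rate combination.

    Rows are discount rates, columns market rates, values USD.  Monotone
    increasing along market rate and decreasing along discount rate.
    """
    d_values = list(d_values)
    m_values = list(m_values)
    if not d_values or not m_values:
        raise ParameterError("rate lists must be non-empty")
    grid = [[accumulated_profit(revenue, cost, d, m, n, convention)
             for m in m_values] for d in d_values]
    return pd.DataFrame(grid, index=pd.Index(d_values, name="d"),
                        columns=pd.Index(m_values, name="m"))


def min_adult_price(profit_traditional: float, profit_nontraditional: float,
                    adults_sold: float) -> float:
    """Break-even profit per harvested adult.

    The per-turtle profit at which selling adults recovers the gap between
    traditional farming profit and the hatchling+yearling profit of the
    harvest scenario.
    """
    if adults_sold <= 0:
        raise ParameterError("scenario sells no adults; break-even price "
                             "is undefined")
    return (profit_traditional - profit_nontraditional) / adults_sold


def price_per_kg_meat(price_per_turtle: float, mass_kg: float,
                      meat_yield: float) -> float:
    """Convert a per-turtle price to USD per kilogram of dressed meat."""
    meat = mass_kg * meat_yield
    if meat <= 0:
        raise ParameterError("mass_kg * meat_yield must be > 0")
    return price_per_turtle / meat


@dataclass(frozen=True)
class ProfitProjection:
    """Annual cash flows and their discounted accumulation."""

    annual_revenue: float
    annual_cost: float
    annual_profit: float
    discounted_series: np.ndarray
    accumulated: float


def project(report: AnnualReport, econ: EconParams,
            convention: Convention = "zero_based") -> ProfitProjection:
    """Full profit projection from a steady-state annual report."""
    r = annual_revenue(report, econ)
    c = annual_cost(report, econ)
    series = annual_discounted_profit_series(
        r, c, econ.discount_rate, econ.market_rate, econ.horizon, convention)
    return ProfitProjection(annual_revenue=r, annual_cost=c,
                            annual_profit=r - c, discounted_series=series,
                            accumulated=float(series.sum()))
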