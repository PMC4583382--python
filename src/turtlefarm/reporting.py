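"""Tabular outputs: annual-report CSVs, scenario grids, headline numbers.

All CSVs are plain RFC-4180 tables with fixed, documented column sets;
counts are rounded to whole turtles only at presentation, never in the
underlying state.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .controller import solve_policy, sweep_harvest
from .dynamics import AnnualReport, simulate, steady_state
from .economics import (accumulated_profit, annual_cost,
                        annual_discounted_profit_series, annual_profit,
                        annual_revenue, min_adult_price, price_per_kg_meat,
                        profit_grid)

__all__ = [
    "ANNUAL_COLUMNS", "trajectory_frame", "steady_summary",
    "npv_grid_frame", "fig4_series_frame", "break_even_summary",
    "run_traditional", "run_tables", "headline",
]

ANNUAL_COLUMNS = (
    ["t"]
    + [f"F{i}" for i in range(7)]
    + [f"M{i}" for i in range(6)]
    + ["H", "Y_sold", "A_sold", "g_F", "g_M", "births", "SR",
       "totalF", "totalM", "B"]
)


def trajectory_frame(reports: Sequence[AnnualReport]) -> pd.DataFrame:
    """One row per simulated year with cohort abundances and fluxes."""
    rows = []
    for r in reports:
        row = {"t": r.t}
        row.update({f"F{i}": r.F[i] for i in range(7)})
        row.update({f"M{i}": r.M[i] for i in range(6)})
        row.update({k: getattr(r, k) for k in
                    ("H", "Y_sold", "A_sold", "g_F", "g_M", "births",
                     "SR", "totalF", "totalM", "B")})
        rows.append(row)
    return pd.DataFrame(rows, columns=ANNUAL_COLUMNS)


def steady_summary(report: AnnualReport, rc: RunConfig) -> dict:
    """Headline production and profit of a steady-state year."""
    econ = rc.economics
    return {
        "hatchlings_sold": report.H,
        "yearlings_sold": report.Y_sold,
        "adults_sold": report.A_sold,
        "headstarts_female": report.g_F,
        "headstarts_male": report.g_M,
        "births": report.births,
        "sex_ratio": report.SR,
        "stock_females": report.totalF,
        "stock_males": report.totalM,
        "greenhouse_products": report.B,
        "annual_revenue": annual_revenue(report, econ),
        "annual_cost": annual_cost(report, econ),
        "annual_profit": annual_profit(report, econ),
    }


def npv_grid_frame(revenue: float, cost: float, d_values, m_values,
                   horizon: int, millions: bool = True) -> pd.DataFrame:
    """Accumulated-profit grid, rows = discount rate, columns = market
    rate, in millions of USD (2 decimals) by default."""
    grid = profit_grid(revenue, cost, d_values, m_values, horizon)
    if millions:
        grid = (grid / 1e6).round(2)
    grid.index = [f"d={d:g}" for d in grid.index]
    grid.columns = [f"m={m:g}" for m in grid.columns]
    return grid


def fig4_series_frame(revenue: float, cost: float, d: float,
                      m_values, horizon: int) -> pd.DataFrame:
    """Annual discounted profit per year, one column per market rate."""
    out = {"year": np.arange(1, horizon + 1)}
    for m in m_values:
        out[f"m={m:g}"] = annual_discounted_profit_series(
            revenue, cost, d, m, horizon)
    return pd.DataFrame(out)


def break_even_summary(rc: RunConfig, h_A: float = 0.4) -> dict:
    """Break-even adult pricing for a harvest scenario.

    Solves the traditional and the ``h_A`` scenarios, compares their
    hatchling+yearling profits and spreads the gap over the harvested
    adults.
    """
    econ = rc.economics
    trad = solve_policy(rc.life_history, rc.stock, 0.0, rc.targets)
    scen = solve_policy(rc.life_history, rc.stock, h_A, rc.targets)
    p_tr = annual_profit(trad.steady_report, econ)
    p_ntr = annual_profit(scen.steady_report, econ)
    adults = scen.steady_report.A_sold
    price = min_adult_price(p_tr, p_ntr, adults)
    return {
        "adult_harvest_rate": h_A,
        "profit_traditional": p_tr,
        "profit_nontraditional": p_ntr,
        "adults_sold": adults,
        "hatchlings_sold": scen.steady_report.H,
        "break_even_price_per_adult": price,
        "break_even_price_per_kg_meat": price_per_kg_meat(
            price, econ.adult_mass_kg, econ.meat_yield),
    }


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2) + "\n")


def run_traditional(rc: RunConfig, outdir: str | Path,
                    years: int = 100) -> dict:
    """Solve and run traditional farming; write trajectory and summaries.

    Emits ``annual_reports.csv``, ``steady_summary.json`` and returns the
    summary dict (augmented with the solved managed rates).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sol = solve_policy(rc.life_history, rc.stock, 0.0, rc.targets)
    reports = simulate(rc.life_history, rc.stock, sol.policy, years)
    trajectory_frame(reports).to_csv(outdir / "annual_reports.csv",
                                     index=False)
    summary = steady_summary(steady_state(reports), rc)
    summary["hatchling_harvest_rate"] = sol.policy.hatchling_harvest
    summary["birth_adjustment_rate"] = sol.policy.birth_adjustment
    _write_json(summary, outdir / "steady_summary.json")
    return summary


def run_tables(rc: RunConfig, outdir: str | Path,
               rates: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5)) -> dict:
    """Write the scenario tables: NPV grid, harvest sweep, profit series.

    Emits ``npv_grid.csv`` (d x m accumulated profit, millions),
    ``harvest_sweep.csv`` (production per adult harvest rate),
    ``profit_series.csv`` (annual discounted profit at d = 5%) and
    ``break_even.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    econ = rc.economics
    trad = solve_policy(rc.life_history, rc.stock, 0.0, rc.targets)
    rev = annual_revenue(trad.steady_report, econ)
    cost = annual_cost(trad.steady_report, econ)

    grid = npv_grid_frame(rev, cost, [0.03, 0.05, 0.07],
                          [0.01, 0.03, 0.05, 0.07, 0.09], econ.horizon)
    grid.to_csv(outdir / "npv_grid.csv", index_label="")

    sweep = sweep_harvest(rc.life_history, rc.stock, rc.targets, list(rates))
    sweep.to_csv(outdir / "harvest_sweep.csv", index=False)

    fig4_series_frame(rev, cost, 0.05, [0.01, 0.03, 0.05, 0.07, 0.09],
                      econ.horizon).to_csv(outdir / "profit_series.csv",
                                           index=False)

    be = break_even_summary(rc)
    _write_json(be, outdir / "break_even.json")
    return {"revenue": rev, "cost": cost, "break_even": be,
            "sweep": sweep, "grid": grid}


def headline(rc: RunConfig) -> dict:
    """All headline quantities of the analysis, computed from scratch.

    Traditional steady-state production and profit, the 40-year
    accumulation at selected rate pairs, the 40% harvest scenario with its
    break-even adult price, and the 50% harvest adult sales.
    """
    econ = rc.economics
    trad = solve_policy(rc.life_history, rc.stock, 0.0, rc.targets)
    rep = trad.steady_report
    rev = annual_revenue(rep, econ)
    cost = annual_cost(rep, econ)
    be = break_even_summary(rc)
    scen50 = solve_policy(rc.life_history, rc.stock, 0.5, rc.targets)
    return {
        "traditional": {
            "hatchlings_sold": rep.H,
            "yearlings_sold": rep.Y_sold,
            "headstarts_female": rep.g_F,
            "headstarts_male": rep.g_M,
            "annual_profit": rev - cost,
            "annual_revenue": rev,
            "annual_cost": cost,
        },
        "accumulated_millions": {
            f"d={d:g},m={m:g}": accumulated_profit(rev, cost, d, m,
                                                   econ.horizon) / 1e6
            for d, m in [(0.05, 0.05), (0.05, 0.09), (0.03, 0.01),
                         (0.07, 0.09)]
        },
        "harvest_0.4": {
            "adults_sold": be["adults_sold"],
            "hatchlings_sold": be["hatchlings_sold"],
            "break_even_price_per_adult": be["break_even_price_per_adult"],
            "break_even_price_per_kg_meat":
                be["break_even_price_per_kg_meat"],
        },
        "harvest_0.5": {"adults_sold": scen50.steady_report.A_sold},
    }
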