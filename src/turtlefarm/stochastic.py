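"""Stochastic variant: clutch-size variability and warm-winter die-offs.

Two sources of environmental noise are layered on the deterministic
projection:

* the seasonal mean clutch size is a truncated-normal draw (one draw per
  year — year-to-year environmental variation, not per-female sampling
  noise, which would average out over ~16,000 nesting females);
* a warm winter occurs independently each year with probability 1/6 and
  kills 10% of every outdoor stock class (the greenhouse is heated and
  unaffected).

Setting the clutch standard deviation and the event probability to zero
recovers the deterministic model exactly, not approximately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (AnnualReport, FarmState, UpdateRule,
                       equilibrium_state, step)
from .economics import annual_profit
from .params import (FIRST_STOCK_CLASS, EconParams, LifeHistory,
                     ParameterError, Policy, StochasticConfig, StockConfig,
                     per_capita_birth_rate)

__all__ = ["MonteCarloResult", "apply_mass_mortality", "monte_carlo",
           "sample_clutch_size", "simulate_stochastic"]


def sample_clutch_size(rng: np.random.Generator,
                       config: StochasticConfig) -> float:
    """One seasonal clutch-size draw from the truncated normal.

    Rejection sampling from Normal(mean, sd) restricted to the bounds; the
    mean is not renormalised after truncation.  A zero standard deviation
    degenerates to the (clipped) mean without consuming randomness.
    """
    lo, hi = config.clutch_bounds
    if config.clutch_sd == 0.0:
        return float(np.clip(config.clutch_mean, lo, hi))
    while True:
        draw = rng.normal(config.clutch_mean, config.clutch_sd)
        if lo <= draw <= hi:
            return float(draw)


def apply_mass_mortality(state: FarmState, rng: np.random.Generator,
                         config: StochasticConfig) -> tuple[FarmState, bool]:
    """Warm-winter die-off of the outdoor stock, with the configured
    probability.  Returns the (possibly reduced) state and whether the
    event occurred.  The greenhouse cohorts are untouched."""
    if config.mass_mortality_prob <= 0.0:
        return state, False
    if rng.random() >= config.mass_mortality_prob:
        return state, False
    frac = config.mass_mortality_fraction
    if config.mortality_mode == "uniform":
        frac = rng.uniform(0.0, frac)
    new = state.copy()
    new.F[FIRST_STOCK_CLASS:] *= 1.0 - frac
    new.M[FIRST_STOCK_CLASS:] *= 1.0 - frac
    return new, True


def simulate_stochastic(lh: LifeHistory, cfg: StockConfig, policy: Policy,
                        stoch: StochasticConfig, rng: np.random.Generator,
                        years: int = 100, init: FarmState | None = None,
                        rule: UpdateRule = "concurrent",
                        ) -> list[AnnualReport]:
    """One stochastic replicate of the annual projection.

    Each year draws the seasonal clutch size (hence birth rate) and the
    winter die-off indicator; the die-off hits the stock after aging, so it
    also depresses that year's nesting.  For a few seasons after a die-off
    the incubator split is re-managed (see :func:`turtlefarm.dynamics.step`,
    ``adaptive_males``) so the male stock — for which the fixed split
    produces no slack by design — can be replenished; without events the
    solved fixed split is used unchanged, which is what makes the
    zero-variance limit exactly deterministic.
    """
    if years < 1:
        raise ParameterError("years must be >= 1")
    state = init.copy() if init is not None else equilibrium_state(
        lh, cfg, policy, rule)
    out: list[AnnualReport] = []
    recovery = 0  # seasons of adaptive incubation left after a die-off
    for _ in range(years):
        cs = sample_clutch_size(rng, stoch)
        br = per_capita_birth_rate(cs, lh.clutches_per_season,
                                   lh.hatch_rate, lh.nesting_fraction)
        shock = 0.0
        if stoch.mass_mortality_prob > 0.0 \
                and rng.random() < stoch.mass_mortality_prob:
            shock = stoch.mass_mortality_fraction
            if stoch.mortality_mode == "uniform":
                shock = rng.uniform(0.0, shock)
            recovery = 4
        state, report = step(state, lh, cfg, policy, rule,
                             birth_rate=br, stock_shock=shock,
                             adaptive_males=recovery > 0)
        recovery = max(0, recovery - 1)
        out.append(report)
    return out


@dataclass(frozen=True)
class MonteCarloResult:
    """Replicate-level means and cross-replicate summary statistics."""

    per_replicate: pd.DataFrame  # one row per replicate
    summary: pd.DataFrame        # mean/sd/quantiles per quantity


_QUANTITIES = ("H", "Y_sold", "A_sold", "g_F", "g_M", "profit")


def monte_carlo(lh: LifeHistory, cfg: StockConfig, policy: Policy,
                stoch: StochasticConfig, econ: EconParams | None = None,
                years: int = 100, burn_in: int = 50,
                rule: UpdateRule = "concurrent") -> MonteCarloResult:
    """Monte Carlo ensemble of stochastic replicates.

    Each replicate runs ``years`` years from the deterministic equilibrium
    with its own child RNG stream (seed, replicate index), and is
    summarised by its post-burn-in mean annual production and profit.
    Identical (seed, n_reps) give bit-identical results.
    """
    if burn_in >= years:
        raise ParameterError("burn_in must be smaller than years")
    econ = econ or EconParams()
    streams = np.random.SeedSequence(stoch.seed).spawn(stoch.n_reps)
    rows = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            reports = simulate_stochastic(lh, cfg, policy, stoch, rng,
                                          years, rule=rule)
        except ParameterError as err:  # replicate-level infeasibility
            rows.append({"rep": rep, "failed": True, "note": str(err),
                         **{q: np.nan for q in _QUANTITIES}})
            continue
        tail = reports[burn_in:]
        row = {"rep": rep, "failed": False, "note": ""}
        for q in _QUANTITIES[:-1]:
            row[q] = float(np.mean([getattr(r, q) for r in tail]))
        row["profit"] = float(np.mean([annual_profit(r, econ) for r in tail]))
        rows.append(row)
    per_rep = pd.DataFrame(rows)
    ok = per_rep[~per_rep["failed"]]
    cols = list(_QUANTITIES)
    summary = pd.DataFrame({
        "mean": ok[cols].mean(),
        "sd": ok[cols].std(ddof=1),
        "q05": ok[cols].quantile(0.05),
        "q50": ok[cols].quantile(0.50),
        "q95": ok[cols].quantile(0.95),
    })
    return MonteCarloResult(per_replicate=per_rep, summary=summary)
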