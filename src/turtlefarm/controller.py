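"""Solver for the managed parameters of the farming operation.

The farm manages three levers: the hatchling harvest rate (fraction of
female hatchlings exported at emergence), the birth adjustment rate
(fraction of eggs incubated at female-producing temperatures) and, in the
non-traditional scenarios, the adult harvest rate.  For a given adult
harvest rate this module solves the other two so that at steady state the
farm

* sells the yearling target (~55,000 four-inch turtles) every year,
* keeps the adult sex ratio at or above its optimum (full fertility),
* keeps the stock at the capacity threshold, replacing every loss with
  head-starts.

The solution is a damped fixed point: simulate to steady state, read off
the head-start requirement and total births, update the two rates from the
constraint residuals, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (AnnualReport, ConvergenceError, UpdateRule,
                       equilibrium_state, simulate, stable_stock,
                       steady_state)
from .params import (LifeHistory, OperatingTargets, ParameterError, Policy,
                     StockConfig)

__all__ = ["InfeasiblePolicyError", "SolvedPolicy", "required_intake",
           "solve_policy", "sweep_harvest", "SWEEP_COLUMNS"]


class InfeasiblePolicyError(RuntimeError):
    """The operating targets cannot be met; names the binding constraint."""

    def __init__(self, constraint: str, detail: str = ""):
        self.constraint = constraint
        super().__init__(f"infeasible policy — binding constraint: "
                         f"{constraint}" + (f" ({detail})" if detail else ""))


@dataclass(frozen=True)
class SolvedPolicy:
    """A converged management solution and its steady-state report."""

    policy: Policy
    steady_report: AnnualReport
    converged: bool
    iterations: int


def required_intake(yearling_target: float, g_F: float, g_M: float,
                    greenhouse_mortality: float) -> float:
    """Hatchlings that must enter the greenhouse to deliver the yearling
    target plus the head-start requirement after first-year mortality."""
    if not 0.0 <= greenhouse_mortality < 1.0:
        raise ParameterError("greenhouse_mortality must lie in [0, 1)")
    return (yearling_target + g_F + g_M) / (1.0 - greenhouse_mortality)


def _rates_from(births: float, g_F: float, g_M: float, target: float,
                m_G: float) -> tuple[float, float]:
    """Birth adjustment and hatchling harvest implied by a steady state.

    Males are incubated only to cover the male head-start requirement;
    retained females must cover the yearling target plus the female
    head-start requirement.
    """
    if births <= 0.0:
        raise InfeasiblePolicyError("reproduction",
                                    "no births at steady state")
    m0_needed = g_M / (1.0 - m_G)
    adj = 1.0 - m0_needed / births
    if adj <= 0.0:
        raise InfeasiblePolicyError(
            "male head-start demand", f"needs {m0_needed:.0f} male "
            f"hatchlings but only {births:.0f} eggs hatch")
    f0_needed = (target + g_F) / (1.0 - m_G)
    h_H = 1.0 - f0_needed / (births * adj)
    if h_H < 0.0:
        raise InfeasiblePolicyError(
            "yearling production", f"greenhouse intake {f0_needed:.0f} "
            f"exceeds female births {births * adj:.0f}")
    return adj, h_H


def solve_policy(lh: LifeHistory, cfg: StockConfig, h_A: float = 0.0,
                 targets: OperatingTargets | None = None,
                 rule: UpdateRule = "concurrent", *, years: int = 100,
                 tol: float = 1e-3, damping: float = 0.5,
                 max_iter: int = 200) -> SolvedPolicy:
    """Solve hatchling harvest and birth adjustment for an adult harvest rate.

    The closed-form stable stock provides the first guess; each outer
    iteration re-simulates ``years`` years from the matching equilibrium
    state, reads the steady report, and applies a damped update of the two
    managed rates.  Convergence requires the yearling constraint and the
    male-surplus constraint to hold within ``tol`` (relative) and the inner
    trajectory to have settled.

    Raises
    ------
    InfeasiblePolicyError
        If the targets cannot be met (e.g. reproduction cannot cover the
        greenhouse intake at high adult harvest), naming the binding
        constraint.
    """
    targets = targets or OperatingTargets()
    m_G = lh.greenhouse_mortality
    if not 0.0 <= h_A <= 1.0:
        raise ParameterError("h_A must lie in [0, 1]")

    # analytic first guess from the closed-form stock equilibrium
    g_F, g_M, f_stock, m_stock = stable_stock(lh, cfg, h_A, rule)
    f6, m5 = float(f_stock[-1]), float(m_stock[-1])
    sr = m5 / f6 if f6 > 0 else 0.0
    fert = min(1.0, sr / cfg.optimal_sex_ratio)
    births = f6 * lh.birth_rate * fert
    adj, h_h = _rates_from(births, g_F, g_M, targets.yearling_target, m_G)

    policy = Policy(hatchling_harvest=h_h, adult_harvest=h_A,
                    birth_adjustment=adj,
                    yearling_target=targets.yearling_target)
    report: AnnualReport | None = None
    for iteration in range(1, max_iter + 1):
        init = equilibrium_state(lh, cfg, policy, rule)
        try:
            report = steady_state(simulate(lh, cfg, policy, years, init, rule))
        except ConvergenceError as err:
            raise InfeasiblePolicyError("steady-state convergence", str(err))
        resid_y = (report.Y_sold - targets.yearling_target) \
            / targets.yearling_target
        resid_m = report.Y_M / targets.yearling_target  # male surplus ~ 0
        if abs(resid_y) < tol and abs(resid_m) < tol:
            if report.SR < targets.sex_ratio_target * (1.0 - tol):
                raise InfeasiblePolicyError(
                    "adult sex ratio", f"steady SR {report.SR:.3f} below "
                    f"target {targets.sex_ratio_target}")
            return SolvedPolicy(policy, report, True, iteration)
        adj_new, h_h_new = _rates_from(
            report.births, report.g_F,
            min(cfg.male_recruit_ratio * report.g_F, report.g_M + report.Y_M),
            targets.yearling_target, m_G)
        policy = policy.with_(
            birth_adjustment=policy.birth_adjustment
            + damping * (adj_new - policy.birth_adjustment),
            hatchling_harvest=policy.hatchling_harvest
            + damping * (h_h_new - policy.hatchling_harvest))
    return SolvedPolicy(policy, report, False, max_iter)


SWEEP_COLUMNS = ["h_A", "H", "Y_sold", "A_sold", "g_F", "g_M",
                 "h_H", "ADJ", "converged", "note"]


def sweep_harvest(lh: LifeHistory, cfg: StockConfig,
                  targets: OperatingTargets | None = None,
                  rates: list[float] | None = None,
                  rule: UpdateRule = "concurrent") -> pd.DataFrame:
    """Scenario table of steady-state production across adult harvest rates.

    One row per rate with the hatchling, yearling and adult sales, the
    head-start requirements and the solved managed rates.  A rate whose
    targets are infeasible yields a row of NaNs with the binding constraint
    in ``note``; the sweep continues.
    """
    rates = [0.1, 0.2, 0.3, 0.4, 0.5] if rates is None else list(rates)
    rows = []
    for h_A in rates:
        try:
            sol = solve_policy(lh, cfg, h_A, targets, rule)
            r = sol.steady_report
            rows.append({"h_A": h_A, "H": r.H, "Y_sold": r.Y_sold,
                         "A_sold": r.A_sold, "g_F": r.g_F, "g_M": r.g_M,
                         "h_H": sol.policy.hatchling_harvest,
                         "ADJ": sol.policy.birth_adjustment,
                         "converged": sol.converged, "note": ""})
        except InfeasiblePolicyError as err:
            rows.append({"h_A": h_A, "H": np.nan, "Y_sold": np.nan,
                         "A_sold": np.nan, "g_F": np.nan, "g_M": np.nan,
                         "h_H": np.nan, "ADJ": np.nan,
                         "converged": False, "note": err.constraint})
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
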