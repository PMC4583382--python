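"""Discrete annual two-sex age-structured projection of the farm population.

The farm year runs: last season's greenhouse cohort is graded (greenhouse
mortality), head-starts are transferred to the stock ponds to fill the
capacity deficit measured at the previous census, surplus yearlings are
sold; the stock ages one class with survival and adult harvest; finally the
post-update adult females nest and the incubator output is split into sold
hatchlings and the next greenhouse cohort.  All state variables are
continuous (matrix-model convention); rounding to whole turtles happens
only at presentation.

Two adult-update rules are provided (``update_rule``):

``"concurrent"`` (default)
    Natural mortality and harvest act as competing outflows from the
    standing adult pool within the year, the Euler update of a
    stock-and-flow formulation: ``F6(t) = F6(t-1)*(1-m_A-h_A) + s*F5(t-1)``
    with harvest ``A_F = F6(t-1)*h_A``.
``"after_survival"``
    Survival first, then harvest of the survivors:
    ``F6' = (F5+F6)*s``, ``A_F = F6'*h_A``, ``F6(t) = F6'*(1-h_A)``.

The two coincide when ``h_A = 0``; "concurrent" is the calibrated default
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .params import (FIRST_STOCK_CLASS, N_FEMALE_CLASSES, N_MALE_CLASSES,
                     LifeHistory, ParameterError, Policy, StockConfig)

UpdateRule = Literal["concurrent", "after_survival"]

__all__ = [
    "AnnualReport", "ConvergenceError", "FarmState", "InfeasibleFlowError",
    "age_stock", "allocate_headstarts", "equilibrium_state",
    "fertility_factor", "greenhouse_survivors", "reproduce", "simulate",
    "stable_stock", "steady_state", "step", "yearling_sales",
]


class ConvergenceError(RuntimeError):
    """A trajectory failed to settle to constant production."""


class InfeasibleFlowError(ValueError):
    """A requested flux exceeds the animals available to supply it."""


@dataclass
class FarmState:
    """Cohort abundances at an annual census.

    ``F[0]`` / ``M[0]`` hold the hatchlings placed in the greenhouse this
    year; ``F[1]`` / ``M[1]`` the (pre-mortality) cohort that occupied the
    greenhouse during the year just ended; ``F[2:]`` / ``M[2:]`` the
    outdoor stock classes, with adults pooled in the last class.
    """

    t: int
    F: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.F.shape != (N_FEMALE_CLASSES,) or self.M.shape != (N_MALE_CLASSES,):
            raise ParameterError(
                f"state must have {N_FEMALE_CLASSES} female and "
                f"{N_MALE_CLASSES} male classes")
        if (self.F < 0).any() or (self.M < 0).any():
            raise ParameterError("abundances must be non-negative")

    @property
    def total_females(self) -> float:
        return float(self.F[FIRST_STOCK_CLASS:].sum())

    @property
    def total_males(self) -> float:
        return float(self.M[FIRST_STOCK_CLASS:].sum())

    def copy(self) -> "FarmState":
        return FarmState(self.t, self.F.copy(), self.M.copy())


@dataclass
class AnnualReport:
    """Fluxes and census totals of one farm year."""

    t: int
    H: float            # hatchlings sold
    Y_F: float          # female yearlings sold
    Y_M: float          # male yearlings sold
    Y_sold: float       # yearlings sold, both sexes
    A_F: float          # adult females harvested
    A_M: float          # adult males harvested
    A_sold: float       # adults harvested, both sexes
    g_F: float          # female head-starts added to the stock
    g_M: float          # male head-starts added to the stock
    births: float       # hatched eggs
    SR: float           # realized adult sex ratio M:F after the update
    totalF: float       # stock females at census
    totalM: float       # stock males at census
    B: float            # yearlings produced: Y_sold + g_F + g_M
    F: np.ndarray = field(repr=False)
    M: np.ndarray = field(repr=False)

    SCALAR_FIELDS = ("H", "Y_F", "Y_M", "Y_sold", "A_F", "A_M", "A_sold",
                     "g_F", "g_M", "births", "SR", "totalF", "totalM", "B")


def fertility_factor(sex_ratio: float, optimal_sex_ratio: float) -> float:
    """Fraction of the nesting females laying fertile eggs.

    Full fertility at or above the optimal adult sex ratio; below it the
    fertile fraction declines linearly with the male shortfall.
    """
    if optimal_sex_ratio <= 0:
        raise ParameterError("optimal_sex_ratio must be > 0")
    if sex_ratio < 0:
        raise ParameterError("sex_ratio must be >= 0")
    return min(1.0, sex_ratio / optimal_sex_ratio)


def reproduce(f6: float, sex_ratio: float, birth_rate: float,
              optimal_sex_ratio: float, policy: Policy,
              ) -> tuple[float, float, float]:
    """Incubator output of one nesting season.

    Returns ``(H, F0, M0)``: hatchlings sold, female hatchlings retained
    for the greenhouse, male hatchlings retained.  Hatchling harvest is
    applied to the female portion only (pet markets have no hatchling sex
    preference, and males are produced solely to repopulate the stock), so
    ``H + F0 + M0`` equals total births exactly.
    """
    births = f6 * birth_rate * fertility_factor(sex_ratio, optimal_sex_ratio)
    female_births = births * policy.birth_adjustment
    male_births = births - female_births
    sold = female_births * policy.hatchling_harvest
    return sold, female_births - sold, male_births


def greenhouse_survivors(f1: float, m1: float,
                         greenhouse_mortality: float) -> tuple[float, float]:
    """Yearlings emerging from the greenhouse after first-year mortality."""
    if not 0.0 <= greenhouse_mortality <= 1.0:
        raise ParameterError("greenhouse_mortality must lie in [0, 1]")
    keep = 1.0 - greenhouse_mortality
    return f1 * keep, m1 * keep


def allocate_headstarts(survivors: float, total_stock: float,
                        max_stock: float) -> float:
    """Yearlings transferred to the stock to fill the capacity deficit.

    Zero when the stock is at or above capacity; otherwise the smaller of
    the available survivors and the deficit.
    """
    deficit = max_stock - total_stock
    if deficit <= 0.0:
        return 0.0
    return min(survivors, deficit)


def yearling_sales(survivors: float, headstarts: float) -> float:
    """Yearlings left for the domestic pet market after head-starting."""
    if headstarts < 0 or survivors < 0:
        raise ParameterError("abundances must be >= 0")
    if headstarts > survivors * (1 + 1e-12) + 1e-9:
        raise InfeasibleFlowError(
            f"head-start demand {headstarts} exceeds surviving yearlings "
            f"{survivors}")
    return max(0.0, survivors - headstarts)


def _advance_stock(stock: np.ndarray, s: float, m_adult: float, h_A: float,
                   recruits: float, rule: UpdateRule) -> tuple[np.ndarray, float]:
    """One-year update of the stock classes of one sex.

    ``stock`` is the slice of classes from first juvenile to adult.
    Returns the new classes and the adult harvest.
    """
    new = np.empty_like(stock)
    new[0] = recruits
    new[1:-1] = stock[:-2] * s
    if rule == "concurrent":
        loss = m_adult + h_A
        if loss <= 1.0:
            harvested = stock[-1] * h_A
            remaining = stock[-1] * (1.0 - loss)
        else:  # outflows exceed the pool: split it by competing risks
            harvested = stock[-1] * (h_A / loss)
            remaining = 0.0
        new[-1] = remaining + stock[-2] * s
    elif rule == "after_survival":
        aged = (stock[-2] + stock[-1]) * s
        harvested = aged * h_A
        new[-1] = aged - harvested
    else:
        raise ParameterError(f"unknown update_rule {rule!r}")
    return new, harvested


def age_stock(state: FarmState, lh: LifeHistory, h_A: float,
              g_F: float, g_M: float, rule: UpdateRule = "concurrent",
              ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Survival, aging, adult harvest and head-start entry for both sexes.

    Head-starts enter the first stock class; juveniles move one class with
    survival ``s``; the adult class accumulates survivors and loses natural
    mortality plus harvest.  Returns ``(F', M', A_F, A_M)``.
    """
    s = lh.stock_survivorship
    m = lh.adult_mortality
    newF = state.F.copy()
    newM = state.M.copy()
    newF[FIRST_STOCK_CLASS:], a_f = _advance_stock(
        state.F[FIRST_STOCK_CLASS:], s, m, h_A, g_F, rule)
    newM[FIRST_STOCK_CLASS:], a_m = _advance_stock(
        state.M[FIRST_STOCK_CLASS:], s, m, h_A, g_M, rule)
    return newF, newM, a_f, a_m


def step(state: FarmState, lh: LifeHistory, cfg: StockConfig, policy: Policy,
         rule: UpdateRule = "concurrent", *, birth_rate: float | None = None,
         stock_shock: float = 0.0, adaptive_males: bool = False,
         ) -> tuple[FarmState, AnnualReport]:
    """Advance the farm one year.

    ``birth_rate`` overrides the deterministic per-capita birth rate (used
    by the stochastic variant); ``stock_shock`` removes that fraction of
    every outdoor stock class after aging (warm-winter mass mortality).
    With ``adaptive_males`` the incubator split is re-managed this season:
    if the policy's fixed birth adjustment would retain fewer male
    hatchlings than the current male capacity deficit requires, extra eggs
    are incubated male at the expense of the female (sale + retention)
    share.  The stochastic variant enables this for the seasons following
    a die-off; it is a no-op whenever the fixed split already suffices.
    """
    # 1. greenhouse cohort: last year's retained hatchlings become yearlings
    f1, m1 = float(state.F[0]), float(state.M[0])
    yF, yM = greenhouse_survivors(f1, m1, lh.greenhouse_mortality)

    # 2. head-starts fill the deficit measured at the previous census;
    #    males are recruited in the stock sex proportion, never beyond
    #    their own capacity deficit
    g_F = allocate_headstarts(yF, state.total_females, cfg.max_females)
    g_M = min(allocate_headstarts(yM, state.total_males, cfg.max_males),
              cfg.male_recruit_ratio * g_F)

    # 3. surplus yearlings go to the domestic pet market
    y_f = yearling_sales(yF, g_F)
    y_m = yearling_sales(yM, g_M)

    # 4. stock survival, aging and adult harvest
    newF, newM, a_f, a_m = age_stock(state, lh, policy.adult_harvest,
                                     g_F, g_M, rule)
    if stock_shock > 0.0:
        newF[FIRST_STOCK_CLASS:] *= 1.0 - stock_shock
        newM[FIRST_STOCK_CLASS:] *= 1.0 - stock_shock

    # 5. nesting from the post-update adult classes
    f6 = float(newF[-1])
    m5 = float(newM[-1])
    sr = m5 / f6 if f6 > 0 else 0.0
    br = lh.birth_rate if birth_rate is None else birth_rate
    sold, f0, m0 = reproduce(f6, sr, br, cfg.optimal_sex_ratio, policy)
    if adaptive_males:
        births = sold + f0 + m0
        deficit_m = max(0.0, cfg.max_males
                        - float(newM[FIRST_STOCK_CLASS:].sum()))
        floor = deficit_m / (1.0 - lh.greenhouse_mortality) \
            if lh.greenhouse_mortality < 1.0 else 0.0
        if floor > m0:
            m0 = min(births, floor)
            female = births - m0
            sold = female * policy.hatchling_harvest
            f0 = female - sold
    newF[1] = f1  # bookkeeping: cohort processed this year (pre-mortality)
    newM[1] = m1
    newF[0] = f0
    newM[0] = m0

    new_state = FarmState(state.t + 1, newF, newM)
    report = AnnualReport(
        t=new_state.t, H=sold, Y_F=y_f, Y_M=y_m, Y_sold=y_f + y_m,
        A_F=a_f, A_M=a_m, A_sold=a_f + a_m, g_F=g_F, g_M=g_M,
        births=sold + f0 + m0, SR=sr,
        totalF=new_state.total_females, totalM=new_state.total_males,
        B=y_f + y_m + g_F + g_M, F=newF.copy(), M=newM.copy())
    return new_state, report


def stable_stock(lh: LifeHistory, cfg: StockConfig, h_A: float = 0.0,
                 rule: UpdateRule = "concurrent",
                 ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Closed-form steady state of the stock side of the model.

    With head-starts filling the female capacity deficit every year and
    males recruited in the stock sex proportion, the juvenile classes form
    a geometric ladder ``g, g*s, g*s**2, ...`` and the adult pool balances
    its inflow against mortality plus harvest.  Returns
    ``(g_F, g_M, F_stock, M_stock)`` where the stock arrays cover the
    juvenile-to-adult classes.
    """
    s = lh.stock_survivorship
    m = lh.adult_mortality
    if rule == "concurrent":
        denom = min(1.0, m + h_A)  # outflows cannot exceed the pool
        if denom <= 0.0:
            raise ParameterError(
                "immortal unharvested adults have no stationary abundance")
        adult_f = s ** 4 / denom
        adult_m = s ** 3 / denom
    elif rule == "after_survival":
        denom = 1.0 - s * (1.0 - h_A)
        if denom <= 0.0:
            raise ParameterError(
                "immortal unharvested adults have no stationary abundance")
        adult_f = s ** 4 * (1.0 - h_A) / denom
        adult_m = s ** 3 * (1.0 - h_A) / denom
    else:
        raise ParameterError(f"unknown update_rule {rule!r}")

    ladder_f = np.array([1.0, s, s ** 2, s ** 3, adult_f])
    ladder_m = np.array([1.0, s, s ** 2, adult_m])
    g_F = cfg.max_females / (1.0 + ladder_f.sum())
    g_M = min(cfg.male_recruit_ratio * g_F,
              cfg.max_males / (1.0 + ladder_m.sum()))
    return g_F, g_M, g_F * ladder_f, g_M * ladder_m


def equilibrium_state(lh: LifeHistory, cfg: StockConfig, policy: Policy,
                      rule: UpdateRule = "concurrent") -> FarmState:
    """Default initial condition: stock at the closed-form stable age
    distribution, greenhouse stocked with the policy's equilibrium
    incubator output."""
    _, _, f_stock, m_stock = stable_stock(lh, cfg, policy.adult_harvest, rule)
    F = np.zeros(N_FEMALE_CLASSES)
    M = np.zeros(N_MALE_CLASSES)
    F[FIRST_STOCK_CLASS:] = f_stock
    M[FIRST_STOCK_CLASS:] = m_stock
    f6 = float(F[-1])
    sr = float(M[-1]) / f6 if f6 > 0 else 0.0
    _, f0, m0 = reproduce(f6, sr, lh.birth_rate, cfg.optimal_sex_ratio, policy)
    F[0] = F[1] = f0
    M[0] = M[1] = m0
    return FarmState(0, F, M)


def simulate(lh: LifeHistory, cfg: StockConfig, policy: Policy,
             years: int = 100, init: FarmState | None = None,
             rule: UpdateRule = "concurrent") -> list[AnnualReport]:
    """Deterministic trajectory of ``years`` annual reports.

    Identical inputs produce bit-identical trajectories.  Convergence is
    *not* assumed: pass the result to :func:`steady_state`, which raises if
    production has not settled.
    """
    if years < 1:
        raise ParameterError("years must be >= 1")
    state = init.copy() if init is not None else equilibrium_state(
        lh, cfg, policy, rule)
    out: list[AnnualReport] = []
    for _ in range(years):
        state, report = step(state, lh, cfg, policy, rule)
        out.append(report)
    return out


def _mean_report(window: Sequence[AnnualReport]) -> AnnualReport:
    vals = {f: float(np.mean([getattr(r, f) for r in window]))
            for f in AnnualReport.SCALAR_FIELDS}
    return AnnualReport(t=window[-1].t,
                        F=np.mean([r.F for r in window], axis=0),
                        M=np.mean([r.M for r in window], axis=0), **vals)


def steady_state(trajectory: Sequence[AnnualReport], rel_tol: float = 1e-6,
                 window: int = 10) -> AnnualReport:
    """Average report over the final ``window`` years of a converged run.

    Raises :class:`ConvergenceError` if any production quantity still
    varies by more than ``rel_tol`` (relative, with a floor of one animal)
    across the window — the signature of oscillation or an infeasible
    policy, which must not be silently averaged away.
    """
    if len(trajectory) < window:
        raise ConvergenceError(
            f"trajectory of length {len(trajectory)} is shorter than the "
            f"averaging window ({window})")
    tail = trajectory[-window:]
    for name in AnnualReport.SCALAR_FIELDS:
        vals = np.array([getattr(r, name) for r in tail])
        scale = max(float(np.abs(vals).max()), 1.0)
        span = float(vals.max() - vals.min())
        if span > rel_tol * scale:
            raise ConvergenceError(
                f"{name} still varies by {span:.3g} (relative "
                f"{span / scale:.3g}) across the final {window} years")
    return _mean_report(tail)
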