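"""Unit tests for the annual farm projection primitives."""

import numpy as np
import pytest

import turtlefarm as tf
from turtlefarm.dynamics import FarmState, _advance_stock
from turtlefarm.params import FIRST_STOCK_CLASS


class TestCapacities:
    @pytest.mark.parametrize("density,ha,p,expF,expM", [
        (12_500, 2, 0.75, 18_750, 6_250),   # baseline farm
        (0, 2, 0.75, 0, 0),                 # empty farm
        (10_000, 1, 0.5, 5_000, 5_000),
    ])
    def test_examples(self, density, ha, p, expF, expM):
        cfg = tf.StockConfig(density_per_ha=density, hectares=ha,
                             female_proportion=p)
        assert tf.derive_capacities(cfg) == (expF, expM)

    def test_split_sums_to_total(self):
        cfg = tf.StockConfig(density_per_ha=7_321, hectares=1.7,
                             female_proportion=0.62)
        maxF, maxM = tf.derive_capacities(cfg)
        assert maxF + maxM == pytest.approx(7_321 * 1.7)


class TestBirthRate:
    @pytest.mark.parametrize("cs,nc,hr,nest,expected", [
        (10, 3, 0.85, 0.95, 24.225),   # baseline, printed as 24.2
        (0, 3, 0.85, 0.95, 0.0),
        (8, 3, 0.85, 0.95, 19.38),
    ])
    def test_examples(self, cs, nc, hr, nest, expected):
        assert tf.per_capita_birth_rate(cs, nc, hr, nest) == \
            pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(tf.ParameterError):
            tf.per_capita_birth_rate(-1, 3, 0.85, 0.95)


class TestFertility:
    @pytest.mark.parametrize("sr,sro,expected", [
        (0.33, 0.33, 1.0),    # at the optimum: full fertility
        (0.165, 0.33, 0.5),   # linear decline below it
        (0.50, 0.33, 1.0),    # above: still full
        (0.0, 0.33, 0.0),
    ])
    def test_examples(self, sr, sro, expected):
        assert tf.fertility_factor(sr, sro) == pytest.approx(expected)

    def test_invalid_optimum(self):
        with pytest.raises(tf.ParameterError):
            tf.fertility_factor(0.3, 0.0)


class TestReproduce:
    def test_all_female_no_harvest(self):
        pol = tf.Policy(birth_adjustment=1.0, hatchling_harvest=0.0)
        h, f0, m0 = tf.reproduce(1000, 0.33, 24.225, 0.33, pol)
        assert h == 0
        assert f0 == pytest.approx(24_225)
        assert m0 == 0

    def test_harvest_split(self):
        # female births 1000, 20% harvested
        pol = tf.Policy(birth_adjustment=1.0, hatchling_harvest=0.2)
        h, f0, m0 = tf.reproduce(1000, 1.0, 1.0, 0.33, pol)
        assert h == pytest.approx(200)
        assert f0 == pytest.approx(800)

    def test_budget_closes(self):
        pol = tf.Policy(birth_adjustment=0.8, hatchling_harvest=0.4)
        h, f0, m0 = tf.reproduce(16_114, 0.34, 24.225, 0.33, pol)
        assert h + f0 + m0 == pytest.approx(16_114 * 24.225, rel=1e-12)

    def test_no_males_no_births(self):
        pol = tf.Policy()
        h, f0, m0 = tf.reproduce(1000, 0.0, 24.225, 0.33, pol)
        assert h == f0 == m0 == 0


class TestGreenhouse:
    def test_survival(self):
        assert tf.greenhouse_survivors(1000, 0, 0.15) == (850, 0)

    def test_empty(self):
        assert tf.greenhouse_survivors(0, 0, 0.15) == (0, 0)


class TestHeadstartAllocation:
    @pytest.mark.parametrize("survivors,total,cap,expected", [
        (100, 18_750, 18_750, 0),      # at capacity: no transfer
        (100, 18_250, 18_750, 100),    # deficit exceeds supply
        (1000, 18_250, 18_750, 500),   # fill exactly to capacity
        (100, 19_000, 18_750, 0),      # above capacity
    ])
    def test_examples(self, survivors, total, cap, expected):
        assert tf.allocate_headstarts(survivors, total, cap) == expected


class TestYearlingSales:
    def test_surplus_sold(self):
        assert tf.yearling_sales(55_728, 728) == 55_000

    def test_all_retained(self):
        assert tf.yearling_sales(850, 850) == 0

    def test_all_sold(self):
        assert tf.yearling_sales(850, 0) == 850

    def test_infeasible_demand(self):
        with pytest.raises(tf.InfeasibleFlowError):
            tf.yearling_sales(100, 200)


def _state(F, M, t=0):
    return FarmState(t, np.array(F, float), np.array(M, float))


class TestAgeStock:
    def test_juvenile_conveyor(self, lh):
        st = _state([0, 0, 546, 0, 0, 0, 0], [0] * 6)
        F, M, aF, aM = tf.age_stock(st, lh, 0.0, 0.0, 0.0)
        assert F[3] == pytest.approx(546 * 0.97)
        assert F[2] == 0 and aF == 0

    def test_adult_accumulation_concurrent(self, lh):
        # F6(t) = F6*(1-m_A) + s*F5 with no harvest
        st = _state([0, 0, 0, 0, 0, 500, 16_000], [0] * 6)
        F, _, aF, _ = tf.age_stock(st, lh, 0.0, 0.0, 0.0)
        assert F[6] == pytest.approx(16_000 * 0.97 + 500 * 0.97)
        assert aF == 0

    def test_adult_accumulation_after_survival(self, lh):
        st = _state([0, 0, 0, 0, 0, 500, 16_000], [0] * 6)
        F, _, _, _ = tf.age_stock(st, lh, 0.0, 0.0, 0.0,
                                  rule="after_survival")
        assert F[6] == pytest.approx((16_000 + 500) * 0.97)

    def test_full_harvest_empties_adults(self, lh):
        st = _state([0, 0, 0, 0, 0, 0, 1000], [0] * 6)
        for rule in ("concurrent", "after_survival"):
            F, _, aF, _ = tf.age_stock(st, lh, 1.0, 0.0, 0.0, rule=rule)
            assert F[6] == pytest.approx(0.0)
            assert aF > 0

    def test_harvest_plus_mortality_never_negative(self, lh):
        # competing risks split when outflows exceed the pool
        new, harvested = _advance_stock(np.array([0, 0, 0, 0, 100.0]),
                                        0.97, 0.03, 1.0, 0.0, "concurrent")
        assert new[-1] >= 0
        assert harvested == pytest.approx(100 * (1.0 / 1.03))

    def test_headstarts_enter_first_stock_class(self, lh):
        st = _state([0] * 7, [0] * 6)
        F, M, _, _ = tf.age_stock(st, lh, 0.0, 42.0, 14.0)
        assert F[FIRST_STOCK_CLASS] == 42.0
        assert M[FIRST_STOCK_CLASS] == 14.0


class TestStep:
    def test_empty_state_is_absorbing(self, lh, stock):
        st = _state([0] * 7, [0] * 6)
        new, rep = tf.step(st, lh, stock, tf.Policy())
        assert new.F.sum() == 0 and new.M.sum() == 0
        for f in rep.SCALAR_FIELDS:
            assert getattr(rep, f) == 0

    def test_hatchling_budget_closes(self, lh, stock, solved_traditional):
        pol = solved_traditional.policy
        st = tf.equilibrium_state(lh, stock, pol)
        new, rep = tf.step(st, lh, stock, pol)
        retained = new.F[0] + new.M[0]
        assert rep.H + retained == pytest.approx(rep.births, rel=1e-12)

    def test_report_B_identity(self, lh, stock, solved_traditional):
        pol = solved_traditional.policy
        st = tf.equilibrium_state(lh, stock, pol)
        _, rep = tf.step(st, lh, stock, pol)
        assert rep.B == pytest.approx(rep.Y_sold + rep.g_F + rep.g_M)


class TestSimulate:
    def test_trajectory_length(self, lh, stock):
        assert len(tf.simulate(lh, stock, tf.Policy(), years=1)) == 1
        assert len(tf.simulate(lh, stock, tf.Policy(), years=7)) == 7

    def test_years_must_be_positive(self, lh, stock):
        with pytest.raises(tf.ParameterError):
            tf.simulate(lh, stock, tf.Policy(), years=0)

    def test_bit_identical_determinism(self, lh, stock, solved_traditional):
        pol = solved_traditional.policy
        a = tf.simulate(lh, stock, pol, years=30)
        b = tf.simulate(lh, stock, pol, years=30)
        for ra, rb in zip(a, b):
            assert (ra.F == rb.F).all() and (ra.M == rb.M).all()
            for f in ra.SCALAR_FIELDS:
                assert getattr(ra, f) == getattr(rb, f)

    def test_converges_from_solved_equilibrium(self, lh, stock,
                                               solved_traditional):
        traj = tf.simulate(lh, stock, solved_traditional.policy, years=100)
        rep = tf.steady_state(traj, rel_tol=1e-9)
        assert rep.Y_sold == pytest.approx(55_000, rel=1e-6)


class TestSteadyState:
    def test_constant_trajectory_is_identity(self, lh, stock,
                                             solved_traditional):
        traj = tf.simulate(lh, stock, solved_traditional.policy, years=20)
        rep = tf.steady_state(traj)
        assert rep.H == pytest.approx(traj[-1].H)

    def test_unconverged_raises(self, lh, stock):
        # start far from equilibrium with an unsolved policy: oscillating
        st = _state([100, 100, 10, 10, 10, 10, 10], [10] * 6)
        pol = tf.Policy(hatchling_harvest=0.2, birth_adjustment=0.9)
        traj = tf.simulate(lh, stock, pol, years=12, init=st)
        with pytest.raises(tf.ConvergenceError):
            tf.steady_state(traj)

    def test_short_trajectory_raises(self, lh, stock):
        traj = tf.simulate(lh, stock, tf.Policy(), years=3)
        with pytest.raises(tf.ConvergenceError):
            tf.steady_state(traj, window=10)


class TestClosedForm:
    def test_equilibrium_is_fixed_point(self, lh, stock,
                                        solved_traditional):
        """One step from the closed-form equilibrium returns to it."""
        pol = solved_traditional.policy
        st = tf.equilibrium_state(lh, stock, pol)
        new, _ = tf.step(st, lh, stock, pol)
        np.testing.assert_allclose(new.F, st.F, rtol=1e-9)
        np.testing.assert_allclose(new.M, st.M, rtol=1e-9)

    @pytest.mark.parametrize("h_A", [0.0, 0.2, 0.5])
    def test_perturbed_init_returns_to_closed_form(self, lh, stock,
                                                   targets, h_A):
        sol = tf.solve_policy(lh, stock, h_A, targets)
        st = tf.equilibrium_state(lh, stock, sol.policy)
        st.F[FIRST_STOCK_CLASS:] *= 0.9  # knock the stock 10% down
        st.M[FIRST_STOCK_CLASS:] *= 0.9
        traj = tf.simulate(lh, stock, sol.policy, years=1000, init=st)
        eq = tf.equilibrium_state(lh, stock, sol.policy)
        np.testing.assert_allclose(traj[-1].F, eq.F, rtol=1e-6)
        np.testing.assert_allclose(traj[-1].M, eq.M, rtol=1e-6)
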