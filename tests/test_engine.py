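"""Cohort engine: costs, discounting, half-cycle correction, conservation."""

import dataclasses
import math

import numpy as np
import pytest

import markovcea as mc
from markovcea.engine import (
    AccrualMap,
    build_accrual,
    cycle_drug_cost,
    discount_factor,
    expected_ae_cost,
    loperamide_prophylaxis_cost,
    run_cohort,
    run_strategy,
)
from markovcea.parameters import (
    DomainError,
    DrugDosing,
    LoperamideSchedule,
    ModelSettings,
    STATES,
)
from markovcea.transitions import TransitionMatrix, assemble_matrix
from markovcea.synthetic import make_strategy


def _raw_matrix(m):
    return TransitionMatrix(matrix=np.asarray(m, dtype=float), primitives={}, provenance={})


def _uniform_accrual(u=1.0, c=0.0, one_time=0.0):
    return AccrualMap(
        state_utilities={s: u for s in STATES},
        state_cycle_costs={s: c for s in STATES},
        one_time_cost=one_time,
    )


class TestDiscountFactor:
    def test_cycle_zero_and_zero_rate_are_unity(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(17, 0.0) == 1.0

    def test_one_year_at_three_percent(self):
        # a cycle length of exactly one year makes the closed form 1/1.03
        assert discount_factor(1, 0.03, cycle_days=365.25) == pytest.approx(1 / 1.03)

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            discount_factor(1, -0.01)


class TestDrugCosts:
    def test_neratinib_component(self):
        # 240 mg daily from 40 mg units: 6 units x $13.46 x 21 days
        s = make_strategy("n", 24, 8.8, 8.5)
        s = dataclasses.replace(
            s,
            costs=dataclasses.replace(
                s.costs,
                dosing=(DrugDosing(drug="neratinib", dose_mg=240, unit_mg=40,
                                   unit_price=13.46, days_per_cycle=21),),
            ),
        )
        assert cycle_drug_cost(s) == pytest.approx(1695.96)

    def test_reference_regimen_cycle_costs(self, whole_group):
        (nc, lc), _ = whole_group
        # capecitabine 1500 mg/m2 x 1.67 m2 -> ceil(2505/150)=17 units,
        # twice daily on days 1-14: 17 x $0.6 x 2 x 14 = $285.60
        assert cycle_drug_cost(nc) == pytest.approx(1695.96 + 285.60)
        assert cycle_drug_cost(lc) == pytest.approx(1692.60 + 386.40)

    def test_zero_dose_drug_costs_nothing(self):
        s = make_strategy("z", 24, 8.8, 8.5)
        s = dataclasses.replace(
            s,
            costs=dataclasses.replace(
                s.costs,
                dosing=(DrugDosing(drug="none", dose_mg=0, unit_mg=40, unit_price=9.0),),
            ),
        )
        assert cycle_drug_cost(s) == 0.0


class TestOneTimeCosts:
    def test_loperamide_schedule_readings(self):
        q6h = LoperamideSchedule(unit_price=0.23)
        assert q6h.tablet_count == 92
        assert loperamide_prophylaxis_cost(q6h) == pytest.approx(21.16)
        q8h = LoperamideSchedule(unit_price=0.23, maintenance_doses_per_day=3)
        assert q8h.tablet_count == 74
        assert loperamide_prophylaxis_cost(q8h) == pytest.approx(17.02)
        assert loperamide_prophylaxis_cost(None) == 0.0
        free = LoperamideSchedule(unit_price=0.0)
        assert loperamide_prophylaxis_cost(free) == 0.0

    def test_expected_ae_cost_is_incidence_weighted_sum(self, whole_group):
        (nc, lc), _ = whole_group
        assert expected_ae_cost(nc.costs) == pytest.approx(1798.15, abs=0.01)
        manual = sum(a.incidence * a.cost_per_event for a in lc.costs.ae_profile)
        assert expected_ae_cost(lc.costs) == pytest.approx(manual)

    def test_no_events_costs_nothing(self):
        s = make_strategy("z", 24, 8.8, 8.5, with_costs=False)
        assert expected_ae_cost(s.costs) == 0.0


class TestRunCohort:
    def test_identity_matrix_keeps_occupancy_constant(self):
        tm = _raw_matrix(np.eye(4))
        trace = run_cohort(tm, _uniform_accrual(), ModelSettings())
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_all_death_matrix_absorbs_in_one_cycle(self):
        m = np.zeros((4, 4))
        m[:, 3] = 1.0
        trace = run_cohort(_raw_matrix(m), _uniform_accrual(), ModelSettings())
        assert np.allclose(trace.occupancy[1:, 3], 1.0)
        assert trace.death_fraction == 1.0

    def test_two_state_geometric_closed_form(self):
        # alive->dead with probability p per cycle, utility 1, no discount,
        # no half-cycle correction: life-years follow the geometric series
        p = 0.07
        m = np.eye(4)
        m[0, 0], m[0, 3] = 1 - p, p
        settings = ModelSettings(
            annual_discount_rate=0.0, half_cycle_correction=False,
            rounding_mode="full_precision",
        )
        u = {s: 0.0 for s in STATES}
        u["SD"] = 1.0
        accrual = AccrualMap(state_utilities=u, state_cycle_costs={})
        trace = run_cohort(_raw_matrix(m), accrual, settings)
        n = settings.n_cycles
        expected = (1 - (1 - p) ** n) / p * settings.cycle_years
        assert trace.total_qaly == pytest.approx(expected, abs=1e-9)

    def test_conservation_and_absorption(self, whole_group_results):
        (res_nc, res_lc), _ = whole_group_results
        for r in (res_nc, res_lc):
            occ = r.trace.occupancy
            assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-10
            de = occ[:, 3]
            assert (np.diff(de) >= -1e-12).all()

    def test_one_time_costs_enter_cycle_zero_undiscounted(self):
        tm = _raw_matrix(np.eye(4))
        accrual = _uniform_accrual(u=0.0, c=0.0, one_time=123.0)
        trace = run_cohort(tm, accrual, ModelSettings())
        assert trace.per_cycle_cost[0] == pytest.approx(123.0)
        assert trace.total_cost == pytest.approx(123.0)

    def test_non_stochastic_matrix_rejected(self):
        bad = np.eye(4)
        bad[0, 0] = 0.7
        with pytest.raises(DomainError):
            run_cohort(_raw_matrix(bad), _uniform_accrual(), ModelSettings())


class TestAccrualConventions:
    def test_full_utility_no_death_gives_horizon_years(self):
        # utility 1 everywhere, no exits, no discount: QALYs = simulated years
        tm = assemble_matrix(0.0, 0.0, 0.0, 0.0)
        settings = ModelSettings(annual_discount_rate=0.0, rounding_mode="full_precision")
        trace = run_cohort(tm, _uniform_accrual(u=1.0), settings)
        assert trace.total_qaly == pytest.approx(settings.n_cycles * settings.cycle_years)

    def test_half_cycle_correction_between_start_and_end_conventions(self, whole_group):
        (nc, _), _ = whole_group
        settings = ModelSettings(annual_discount_rate=0.0)
        hcc = run_strategy(nc, settings)
        trace = hcc.trace
        u = np.array([nc.utilities.state_utilities()[s] for s in STATES])
        per_point = trace.occupancy @ u * settings.cycle_years
        start = per_point[:-1].sum()
        end = per_point[1:].sum()
        assert end <= trace.total_qaly <= start
        assert end < start  # death makes the conventions genuinely differ

    def test_discounting_never_increases_totals(self, whole_group):
        (nc, _), _ = whole_group
        disc = run_strategy(nc, ModelSettings(annual_discount_rate=0.03))
        undisc = run_strategy(nc, ModelSettings(annual_discount_rate=0.0))
        assert disc.total_qaly < undisc.total_qaly
        assert disc.total_cost < undisc.total_cost

    def test_qalys_weakly_increase_with_utilities_and_os(self, whole_group):
        (nc, _), settings = whole_group
        base = run_strategy(nc, settings).total_qaly
        richer = dataclasses.replace(
            nc, utilities=dataclasses.replace(nc.utilities, remission=0.95)
        )
        assert run_strategy(richer, settings).total_qaly > base
        longer = dataclasses.replace(
            nc,
            clinical=dataclasses.replace(nc.clinical, os_months=30.0, rr=None),
        )
        assert run_strategy(longer, settings).total_qaly >= base

    def test_drug_cost_accrues_pre_progression_only(self, whole_group):
        (nc, _), settings = whole_group
        accrual = build_accrual(nc, settings)
        drug = cycle_drug_cost(nc)
        exam = 4552.0 * settings.cycle_days / 365.25
        assert accrual.state_cycle_costs["SD"] == pytest.approx(drug + exam)
        assert accrual.state_cycle_costs["RE"] == pytest.approx(drug + exam)
        assert accrual.state_cycle_costs["PD"] == pytest.approx(
            (3200.0 + 2176.0) * settings.cycle_days / 365.25
        )
        assert accrual.state_cycle_costs["DE"] == 0.0


class TestOracleEquivalence:
    def test_totals_match_matrix_power_expressions(self):
        """Engine accruals equal an independent matrix-power evaluation on
        random row-stochastic matrices over short horizons."""
        rng = np.random.default_rng(20240917)
        for _ in range(50):
            m = rng.dirichlet(np.ones(4), size=4)
            n = int(rng.integers(2, 11))
            settings = ModelSettings(
                horizon_years=(n * 21 + 0.5) / 365.25,
                annual_discount_rate=float(rng.uniform(0, 0.08)),
                rounding_mode="full_precision",
            )
            assert settings.n_cycles == n
            u = rng.uniform(0, 1, size=4)
            c = rng.uniform(0, 500, size=4)
            init = rng.dirichlet(np.ones(4))
            settings = dataclasses.replace(settings, initial_distribution=tuple(init))
            accrual = AccrualMap(
                state_utilities=dict(zip(STATES, u)),
                state_cycle_costs=dict(zip(STATES, c)),
            )
            trace = run_cohort(_raw_matrix(m), accrual, settings)
            # oracle: explicit powers and scalar sums
            exp_q, exp_c = 0.0, 0.0
            for t in range(n + 1):
                occ_t = init @ np.linalg.matrix_power(m, t)
                w = 0.5 if t in (0, n) else 1.0
                d = (1 + settings.annual_discount_rate) ** (-t * 21 / 365.25)
                exp_q += w * d * float(occ_t @ u) * 21 / 365.25
                exp_c += w * d * float(occ_t @ c)
            assert trace.total_qaly == pytest.approx(exp_q, abs=1e-10)
            assert trace.total_cost == pytest.approx(exp_c, abs=1e-8)
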