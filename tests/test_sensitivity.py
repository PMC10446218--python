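"""Distribution fitting, one-way DSA, PSA and acceptability curves."""

import dataclasses
import math

import numpy as np
import pytest

from markovcea.parameters import DomainError
from markovcea.sensitivity import (
    FitError,
    ModelBundle,
    ModelParameter,
    build_parameters,
    ceac,
    evaluate,
    fit_distribution,
    one_way_dsa,
    run_psa,
)


class TestFitDistribution:
    def test_beta_moments_from_published_range(self):
        d = fit_distribution(0.189, 0.1701, 0.2079, "beta")
        assert d.family == "beta"
        assert d.mean == 0.189
        assert d.sd == pytest.approx((0.2079 - 0.1701) / 3.92)
        a, b = d.shape
        assert a / (a + b) == pytest.approx(0.189, abs=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(d.sd, rel=1e-9)

    def test_gamma_moments_from_published_range(self):
        d = fit_distribution(13.46, 12.114, 14.806, "gamma")
        shape, scale = d.shape
        assert shape * scale == pytest.approx(13.46, abs=1e-9)
        assert math.sqrt(shape) * scale == pytest.approx((14.806 - 12.114) / 3.92)

    def test_degenerate_range_gives_point_mass(self):
        d = fit_distribution(0.5, 0.5, 0.5, "beta")
        assert d.family == "point"
        rng = np.random.default_rng(0)
        assert (d.sample(rng, 10) == 0.5).all()

    def test_infeasible_beta_variance_raises_with_guidance(self):
        with pytest.raises(FitError, match="variance"):
            fit_distribution(0.01, -3.0, 3.0, "beta")

    def test_base_outside_range_rejected(self):
        with pytest.raises(FitError):
            fit_distribution(0.9, 0.1, 0.2, "beta")

    def test_sample_means_converge_to_base(self):
        rng = np.random.default_rng(7)
        for base, lo, hi, fam in [
            (0.189, 0.1701, 0.2079, "beta"),
            (0.85, 0.68, 1.0, "beta"),
            (13.46, 12.114, 14.806, "gamma"),
            (3200.0, 2880.0, 3520.0, "gamma"),
        ]:
            d = fit_distribution(base, lo, hi, fam)
            x = d.sample(rng, 1000)
            se = d.sd / math.sqrt(1000)
            assert abs(x.mean() - base) < 3 * se


class TestParameterRegistry:
    def test_probabilities_are_arm_specific_and_utilities_shared(self, whole_group_bundle):
        params = build_parameters(whole_group_bundle)
        pids = {p.pid for p in params}
        assert "shared:u_remission" in pids
        assert "shared:cost_ae_diarrhea" in pids
        assert "shared:price_capecitabine" in pids
        assert "neratinib+capecitabine:p_remission_remission" in pids
        assert "lapatinib+capecitabine:p_relapse_death" in pids
        assert "settings:discount_rate" in pids
        assert not any(p.pid.startswith("shared:p_") for p in params)

    def test_drug_prices_stay_arm_specific(self, whole_group_bundle):
        pids = {p.pid for p in build_parameters(whole_group_bundle)}
        assert "neratinib+capecitabine:price_neratinib" in pids
        assert "lapatinib+capecitabine:price_lapatinib" in pids


class TestEvaluate:
    def test_no_overrides_reproduces_base_case(self, whole_group_bundle):
        a = evaluate(whole_group_bundle)
        b = evaluate(whole_group_bundle, {})
        assert a.icer == b.icer
        assert a.cost_a == b.cost_a

    def test_override_at_base_value_reproduces_base_case(self, whole_group_bundle):
        base = evaluate(whole_group_bundle)
        for p in build_parameters(whole_group_bundle):
            res = evaluate(whole_group_bundle, {p.pid: p.base})
            assert res.icer == pytest.approx(base.icer, rel=1e-9), p.pid

    def test_complement_override_moves_constituent(self, whole_group_bundle):
        name = whole_group_bundle.strategies[0].name
        base = evaluate(whole_group_bundle)
        res = evaluate(whole_group_bundle, {f"{name}:p_remission_remission": 0.90})
        assert res.qaly_a < base.qaly_a  # more relapse from remission

    def test_utility_override_applies_to_both_arms_when_shared(self, whole_group_bundle):
        base = evaluate(whole_group_bundle)
        res = evaluate(whole_group_bundle, {"shared:u_remission": 0.95})
        assert res.qaly_a > base.qaly_a
        assert res.qaly_b > base.qaly_b

    def test_discount_override(self, whole_group_bundle):
        res0 = evaluate(whole_group_bundle, {"settings:discount_rate": 0.0})
        base = evaluate(whole_group_bundle)
        assert res0.qaly_a > base.qaly_a

    def test_invalid_probability_override_raises(self, whole_group_bundle):
        name = whole_group_bundle.strategies[0].name
        with pytest.raises(DomainError):
            evaluate(whole_group_bundle, {f"{name}:p_stable_relapse": 0.95})


class TestDsa:
    def test_rows_sorted_by_bar_width(self, whole_group_bundle):
        rows = one_way_dsa(whole_group_bundle)
        widths = [r.bar_width for r in rows]
        assert widths == sorted(widths, reverse=True)
        assert len(rows) == len(build_parameters(whole_group_bundle))

    def test_zero_width_range_gives_zero_bar(self, whole_group_bundle):
        p0 = build_parameters(whole_group_bundle)[0]
        frozen = ModelParameter(
            pid=p0.pid, arm=p0.arm, key=p0.key, base=p0.base,
            low=p0.base, high=p0.base, family=p0.family, kind=p0.kind,
        )
        (row,) = one_way_dsa(whole_group_bundle, [frozen])
        assert row.bar_width == 0.0
        assert row.icer_at_low == row.icer_at_high

    def test_breaking_variation_is_flagged_not_raised(self, whole_group_bundle):
        name = whole_group_bundle.strategies[0].name
        bad = ModelParameter(
            pid=f"{name}:p_stable_relapse", arm=0, key="p_stable_relapse",
            base=0.236, low=0.236, high=0.95, family="beta", kind="prob_direct",
        )
        (row,) = one_way_dsa(whole_group_bundle, [bad])
        assert not row.valid
        assert "high" in row.note


class TestPsa:
    def test_seeded_runs_are_bit_identical(self, whole_group_bundle):
        a = run_psa(whole_group_bundle, n_draws=40, seed=11)
        b = run_psa(whole_group_bundle, n_draws=40, seed=11)
        assert np.array_equal(a.cost_a, b.cost_a)
        assert np.array_equal(a.qaly_b, b.qaly_b)
        c = run_psa(whole_group_bundle, n_draws=40, seed=12)
        assert not np.array_equal(a.cost_a, c.cost_a)

    def test_quadrant_fractions_sum_to_one(self, whole_group_bundle):
        psa = run_psa(whole_group_bundle, n_draws=60, seed=3)
        fr = psa.quadrant_fractions()
        assert sum(fr.values()) == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in fr.values())

    def test_degenerate_distributions_collapse_to_base(self, whole_group_bundle):
        base = evaluate(whole_group_bundle)
        params = [
            dataclasses.replace(p, low=p.base, high=p.base)
            for p in build_parameters(whole_group_bundle, include_discount=False)
        ]
        psa = run_psa(whole_group_bundle, n_draws=5, seed=0, params=params)
        assert np.allclose(psa.cost_a, base.cost_a)
        assert np.allclose(psa.qaly_b, base.qaly_b)
        fr = psa.quadrant_fractions()
        assert max(fr.values()) == 1.0  # a single category holds every draw

    def test_identical_arms_are_indifferent(self):
        from markovcea.synthetic import ScenarioSpec, generate_scenario

        strategies, settings = generate_scenario(ScenarioSpec(seed=5, identical_arms=True))
        bundle = ModelBundle(strategies=strategies, settings=settings)
        base = evaluate(bundle)
        assert base.icer is None
        assert base.icer_tag == "indifferent"

    def test_zero_draws_rejected(self, whole_group_bundle):
        with pytest.raises(DomainError):
            run_psa(whole_group_bundle, n_draws=0, seed=1)


class TestCeac:
    def test_curves_sum_to_one_and_are_probabilities(self, whole_group_bundle):
        psa = run_psa(whole_group_bundle, n_draws=50, seed=2)
        curve = ceac(psa)
        assert np.allclose(curve["p_strategy_a"] + curve["p_strategy_b"], 1.0)
        assert ((curve["p_strategy_a"] >= 0) & (curve["p_strategy_a"] <= 1)).all()

    def test_wtp_zero_reduces_to_probability_of_lower_cost(self, whole_group_bundle):
        psa = run_psa(whole_group_bundle, n_draws=50, seed=2)
        curve = ceac(psa, np.array([0.0]))
        p_cheaper = (psa.cost_a < psa.cost_b).mean() + 0.5 * (psa.cost_a == psa.cost_b).mean()
        assert curve["p_strategy_a"].iloc[0] == pytest.approx(p_cheaper)

    def test_dominant_degenerate_psa_gives_flat_unit_curve(self, whole_group_bundle):
        from markovcea.sensitivity import PsaResult

        psa = PsaResult(
            n_draws=4, seed=0,
            cost_a=np.full(4, 100.0), cost_b=np.full(4, 200.0),
            qaly_a=np.full(4, 2.0), qaly_b=np.full(4, 1.0),
            wtp=36000.0,
        )
        curve = ceac(psa)
        assert (curve["p_strategy_a"] == 1.0).all()

    def test_empty_grid_rejected(self, whole_group_bundle):
        psa = run_psa(whole_group_bundle, n_draws=5, seed=2)
        with pytest.raises(DomainError):
            ceac(psa, np.array([]))
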