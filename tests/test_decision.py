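"""Markov model, trial simulation, and value-of-information engine."""

import math

import numpy as np
import pytest

from metapriors.decision import (
    DecisionModelInputs,
    ParameterSet,
    PopulationInputs,
    TrialDesign,
    draw_psa_parameters,
    effective_population,
    evpi,
    evsi_nested,
    expected_outcomes,
    markov_trace,
    net_benefit,
    population_scale,
    posterior_update,
    simulate_trial,
)
from metapriors.priors import GammaPrior

INPUTS = DecisionModelInputs()
MEANS = ParameterSet(5_585.0, 17_727.0, 0.997, 0.96)


class TestPsaDraws:
    def test_zero_se_returns_means(self, rng):
        inp = DecisionModelInputs(
            cost_surveillance_se=0.0, cost_recurrent_se=0.0,
            utility_failure_free_se=0.0, utility_recurrent_se=0.0,
        )
        p = draw_psa_parameters(inp, rng)
        assert (p.cost_surveillance, p.cost_recurrent) == (5_585.0, 17_727.0)
        assert (p.utility_failure_free, p.utility_recurrent) == (0.997, 0.96)

    def test_cost_moments_recovered(self):
        rng = np.random.default_rng(7)
        p = draw_psa_parameters(INPUTS, rng, size=100_000)
        n = 100_000
        assert p.cost_surveillance.mean() == pytest.approx(5_585, abs=3 * 1_117 / math.sqrt(n))
        assert p.cost_surveillance.std(ddof=1) == pytest.approx(1_117, rel=0.02)
        assert p.cost_recurrent.mean() == pytest.approx(17_727, abs=3 * 3_545 / math.sqrt(n))

    def test_utilities_in_unit_interval(self):
        rng = np.random.default_rng(8)
        p = draw_psa_parameters(INPUTS, rng, size=50_000)
        for u in (p.utility_failure_free, p.utility_recurrent):
            assert np.all(u >= 0) and np.all(u <= 1)

    def test_seeded_determinism(self):
        p1 = draw_psa_parameters(INPUTS, np.random.default_rng(5), size=10)
        p2 = draw_psa_parameters(INPUTS, np.random.default_rng(5), size=10)
        np.testing.assert_array_equal(p1.cost_surveillance, p2.cost_surveillance)
        np.testing.assert_array_equal(p1.utility_recurrent, p2.utility_recurrent)

    def test_infeasible_beta_falls_back(self, rng, caplog):
        inp = DecisionModelInputs(utility_recurrent_se=0.9)
        with caplog.at_level("WARNING"):
            p = draw_psa_parameters(inp, rng, size=1_000)
        assert np.all((p.utility_recurrent >= 0) & (p.utility_recurrent <= 1))
        assert any("infeasible" in r.message for r in caplog.records)


class TestMarkovTrace:
    def test_zero_rate_zero_mortality_stays_free(self):
        inp = DecisionModelInputs(survival_5y_post_failure=1.0 - 1e-12)
        tr = markov_trace(0.0, 0.0, None, inp)
        np.testing.assert_allclose(tr["control"][:, 0], 1.0, atol=1e-9)

    def test_control_one_year_failure_free_is_075(self):
        tr = markov_trace(INPUTS.control_rate, 0.1, None, INPUTS)
        assert tr["control"][1, 0] == pytest.approx(0.75)

    def test_two_cycle_hand_computation(self):
        rate, cycle = 0.3, 1.0
        p_fail = 1 - math.exp(-rate)
        p_die = 1 - math.exp(-(-math.log(0.79) / 5))
        tr = markov_trace(rate, rate, None, INPUTS, horizon=2.0)["control"]
        f1 = 1 - p_fail
        r1 = p_fail
        f2 = f1 * (1 - p_fail)
        r2 = r1 * (1 - p_die) + f1 * p_fail
        d2 = r1 * p_die
        np.testing.assert_allclose(tr[1], [f1, r1, 0.0], atol=1e-12)
        np.testing.assert_allclose(tr[2], [f2, r2, d2], atol=1e-12)

    def test_occupancy_conservation(self):
        for bg in (0.0, 0.02):
            inp = DecisionModelInputs(background_mortality_rate=bg)
            tr = markov_trace(0.3, 0.1, None, inp)
            for arm in tr.values():
                np.testing.assert_allclose(arm.sum(axis=1), 1.0, atol=1e-12)

    def test_dead_absorbing(self):
        tr = markov_trace(0.5, 0.5, None, INPUTS)["control"]
        assert np.all(np.diff(tr[:, 2]) >= -1e-15)

    def test_horizon_below_cycle_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            markov_trace(0.1, 0.1, None, INPUTS, horizon=0.5, cycle=1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            markov_trace(-0.1, 0.1, None, INPUTS)


class TestExpectedOutcomes:
    def test_equal_rates_differ_only_by_added_cost_stream(self):
        tr = markov_trace(0.25, 0.25, None, INPUTS)
        c_ctrl, q_ctrl = expected_outcomes(tr["control"], MEANS, INPUTS, arm="control")
        c_trt, q_trt = expected_outcomes(tr["experimental"], MEANS, INPUTS, arm="experimental")
        assert q_trt == pytest.approx(q_ctrl)
        alive = tr["control"][:-1, :2].sum(axis=1)
        disc = 1.03 ** (-np.arange(len(alive)))
        assert c_trt - c_ctrl == pytest.approx(147.18 * float((alive * disc).sum()))

    def test_single_cycle_no_discount(self):
        inp = DecisionModelInputs(discount=0.0)
        tr = markov_trace(0.0, 0.0, None, inp, horizon=1.0)
        c, q = expected_outcomes(tr["control"], MEANS, inp, discount=0.0)
        assert c == pytest.approx(5_585.0)
        assert q == pytest.approx(0.997)

    def test_matches_brute_force_five_cycle_sum(self):
        tr = markov_trace(0.3, 0.3, None, INPUTS, horizon=5.0)["control"]
        cost = qaly = 0.0
        for t in range(5):
            d = 1.03**-t
            free, fail, _ = tr[t]
            cost += d * (5_585.0 * free + 17_727.0 * fail)
            qaly += d * (0.997 * free + 0.96 * fail)
        got_c, got_q = expected_outcomes(tr, MEANS, INPUTS)
        assert got_c == pytest.approx(cost)
        assert got_q == pytest.approx(qaly)


def test_net_benefit():
    assert net_benefit(0.0, 1.0, 150_000.0) == 150_000.0
    assert net_benefit(150_000.0, 1.0, 150_000.0) == 0.0
    # linear in QALYs
    assert net_benefit(10.0, 2.0, 50_000.0) - net_benefit(10.0, 1.0, 50_000.0) == 50_000.0


class TestTrial:
    def test_zero_rate_zero_events(self, rng):
        events, py = simulate_trial(0.0, TrialDesign(), rng)
        assert events == 0
        assert py == pytest.approx(308 * 2.5)

    def test_event_mean_matches_exposure(self):
        rng = np.random.default_rng(3)
        events, py = simulate_trial(np.full(100_000, 0.26), TrialDesign(), rng)
        assert events.mean() == pytest.approx(0.26 * py, rel=0.01)

    def test_seeded_determinism(self):
        e1, _ = simulate_trial(np.full(10, 0.3), TrialDesign(), np.random.default_rng(4))
        e2, _ = simulate_trial(np.full(10, 0.3), TrialDesign(), np.random.default_rng(4))
        np.testing.assert_array_equal(e1, e2)

    def test_posterior_update_conjugacy(self):
        post = posterior_update(GammaPrior(1, 1), 10, 40.0)
        assert (post.shape, post.rate) == (11.0, 41.0)
        unchanged = posterior_update(GammaPrior(2, 3), 0, 0.0)
        assert (unchanged.shape, unchanged.rate) == (2.0, 3.0)

    def test_posterior_mean_between_prior_and_data(self):
        prior = GammaPrior(2, 10)  # mean 0.2
        post = posterior_update(prior, 30, 50.0)  # data mean 0.6
        assert prior.mean < post.mean < 30 / 50.0


class TestValueOfInformation:
    def test_tight_prior_off_boundary_has_negligible_evpi(self):
        # essentially a point mass at rate 1, far from the decision
        # boundary: residual EVPI comes only from rare utility-draw flips
        tight = evpi(GammaPrior(1e6, 1e6), INPUTS, n_sims=20_000, seed=1)
        loose = evpi(GammaPrior(1, 1), INPUTS, n_sims=20_000, seed=1)
        assert tight < 0.01 * loose

    def test_evpi_at_least_evsi(self):
        prior = GammaPrior(1, 1)
        e_vpi = evpi(prior, INPUTS, n_sims=200_000, seed=3)
        e_vsi = evsi_nested(prior, INPUTS, TrialDesign(), n_outer=400, n_inner=400, seed=3)
        assert e_vsi.per_person <= e_vpi + 3 * e_vsi.mc_se

    def test_no_trial_no_information(self):
        res = evsi_nested(
            GammaPrior(1, 1), INPUTS, TrialDesign(n_total=0),
            n_outer=400, n_inner=400, seed=5,
        )
        assert abs(res.per_person) < 4 * res.mc_se

    def test_monotone_in_sample_size(self):
        values = []
        for n in (0, 62, 616, 6_160):
            res = evsi_nested(
                GammaPrior(1, 1), INPUTS, TrialDesign(n_total=n),
                n_outer=500, n_inner=300, seed=11,
            )
            values.append(res.per_person)
        slack = 3_000.0  # common-seed MC slack
        assert all(b >= a - slack for a, b in zip(values, values[1:]))

    def test_tighter_prior_lower_evsi_matched_seeds(self):
        loose = evsi_nested(GammaPrior(1, 1), INPUTS, TrialDesign(),
                            n_outer=300, n_inner=300, seed=17)
        tight = evsi_nested(GammaPrior(17.3, 66.1), INPUTS, TrialDesign(),
                            n_outer=300, n_inner=300, seed=17)
        assert tight.per_person < loose.per_person

    def test_result_determinism(self):
        r1 = evsi_nested(GammaPrior(1, 1), INPUTS, TrialDesign(), n_outer=50, n_inner=50, seed=9)
        r2 = evsi_nested(GammaPrior(1, 1), INPUTS, TrialDesign(), n_outer=50, n_inner=50, seed=9)
        assert r1.per_person == r2.per_person

    def test_json_round_trip_fields(self):
        import json

        r = evsi_nested(GammaPrior(1, 1), INPUTS, TrialDesign(), n_outer=50, n_inner=50, seed=9)
        payload = json.loads(r.to_json())
        assert payload["n_outer"] == 50 and payload["prior"]["shape"] == 1


class TestPopulationScale:
    def test_single_year_no_discount(self):
        pop = PopulationInputs(patients_per_year=25_900, horizon_years=1, discount=0.0)
        assert population_scale(2.0, pop) == pytest.approx(2 * 25_900)

    def test_monotone_decreasing_in_discount(self):
        pops = [PopulationInputs(discount=d) for d in (0.0, 0.03, 0.06)]
        vals = [population_scale(1.0, p) for p in pops]
        assert vals[0] > vals[1] > vals[2]

    def test_three_year_hand_sum(self):
        pop = PopulationInputs(patients_per_year=100, horizon_years=3, discount=0.03)
        expected = 100 * (1 + 1 / 1.03 + 1 / 1.03**2)
        assert effective_population(pop) == pytest.approx(expected)
        assert population_scale(10.0, pop) == pytest.approx(10 * expected)

    def test_negative_per_person_rejected(self):
        with pytest.raises(ValueError):
            population_scale(-1.0, PopulationInputs())
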