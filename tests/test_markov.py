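import dataclasses

import numpy as np
import pytest

from rosscea import (
    DeckValidationError,
    accumulate_outcomes,
    build_transition_model,
    compute_nmb,
    evaluate,
    rate_to_probability,
    run_markov,
    run_psa,
)
from tests._microsim import microsimulate


def _zeroed(deck, horizon=25, **overrides):
    """Deck with all event rates and early probabilities set to zero."""
    d = dataclasses.replace(deck, params=dict(deck.params), horizon=horizon)
    for name in list(d.params):
        if name.startswith(("rate.", "early.")):
            d = d.with_value(name, 0.0)
    for name, value in overrides.items():
        d = d.with_value(name, value)
    return d


class TestTransitionStructure:
    def test_mixture_weight_zero_equals_mechanical_only(self, deck):
        d0 = dataclasses.replace(deck, params=dict(deck.params), mixture_weight_bio=0.0)
        cavr = build_transition_model(d0, "cavr")
        assert float(cavr.p_death_bg) == pytest.approx(
            rate_to_probability(deck.value("rate.mechAVR.total_mortality")), rel=1e-12
        )
        assert float(cavr.p_bleed) == pytest.approx(
            rate_to_probability(deck.value("rate.mechAVR.bleeding")), rel=1e-12
        )

    def test_mixture_weight_one_equals_biological_only(self, deck):
        d1 = dataclasses.replace(deck, params=dict(deck.params), mixture_weight_bio=1.0)
        cavr = build_transition_model(d1, "cavr")
        assert float(cavr.p_death_bg) == pytest.approx(
            rate_to_probability(deck.value("rate.bioAVR.total_mortality")), rel=1e-12
        )

    def test_base_case_mixture_mortality(self, deck):
        """0.77 x 1.38 + 0.23 x 2.54 = 1.6468 %/yr before conversion."""
        cavr = build_transition_model(deck, "cavr")
        assert float(cavr.p_death_bg) == pytest.approx(
            rate_to_probability(1.6468), rel=1e-12
        )

    def test_rvot_reintervention_is_ross_specific(self, deck):
        assert float(build_transition_model(deck, "cavr").p_rvot) == 0.0
        assert float(build_transition_model(deck, "ross").p_rvot) > 0.0

    def test_unknown_strategy_rejected(self, deck):
        with pytest.raises(ValueError, match="strategy"):
            build_transition_model(deck, "tavi")


class TestMarkovTrace:
    def test_zero_rates_keep_cohort_well(self, deck):
        d = _zeroed(deck)
        trace = run_markov(build_transition_model(d, "ross"), d)
        assert np.allclose(trace.occupancy[:, 0], 1.0, atol=1e-14)
        assert np.all(trace.occupancy[:, 1:] == 0.0)
        assert np.all(trace.expected_events == 0.0)

    def test_certain_background_death_empties_cohort(self, deck):
        # 1e5 %/yr converts to a per-cycle death probability of 1 in floats
        d = _zeroed(deck, **{"rate.ross.total_mortality": 1e5})
        trace = run_markov(build_transition_model(d, "ross"), d)
        assert trace.occupancy[0, 3] == 0.0
        assert np.all(trace.occupancy[1:, 3] == 1.0)

    def test_single_stroke_channel_splits_by_disability(self, deck):
        d = _zeroed(
            deck,
            **{
                "rate.ross.thromboembolism": 100.0,
                "cond.disability_given_stroke": 0.4,
                "cond.death_given_stroke": 0.0,
            },
        )
        model = build_transition_model(d, "ross")
        trace = run_markov(model, d)
        p = rate_to_probability(100.0)
        assert trace.occupancy[1, 2] == pytest.approx(0.4 * p, rel=1e-12)
        assert trace.occupancy[1, 1] == pytest.approx(0.6 * p, rel=1e-12)

    def test_single_stroke_channel_agrees_with_microsimulation(self, deck):
        d = _zeroed(
            deck,
            horizon=1,
            **{
                "rate.ross.thromboembolism": 100.0,
                "cond.disability_given_stroke": 0.4,
                "cond.death_given_stroke": 0.0,
            },
        )
        model = build_transition_model(d, "ross")
        trace = run_markov(model, d)
        rng = np.random.default_rng(11)
        n = 1_000_000
        stroke = rng.random(n) < rate_to_probability(100.0)
        disabled = stroke & (rng.random(n) < 0.4)
        frac = disabled.mean()
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(trace.occupancy[1, 2] - frac) < 3 * se

    def test_occupancy_conserved_and_death_monotone_over_psa_batch(self, deck):
        from rosscea.deck import sample_parameters
        from rosscea.markov import build_transition_model as btm

        draws = sample_parameters(deck, np.random.default_rng(2), 200)
        for strategy in ("ross", "cavr"):
            trace = run_markov(btm(deck, strategy, draws), deck)
            assert np.allclose(trace.occupancy.sum(axis=-1), 1.0, atol=1e-12)
            dead = trace.occupancy[..., 3]
            assert np.all(np.diff(dead, axis=0) >= -1e-15)
            assert np.all((trace.occupancy >= 0) & (trace.occupancy <= 1))


class TestOutcomeAccumulation:
    def test_cycle_zero_only_returns_procedure_cost_and_full_utility(self, deck):
        d = _zeroed(deck, horizon=0, **{"util.state.well": 1.0})
        cost, qaly = evaluate(d, strategies=("ross",))["ross"]
        assert float(cost) == pytest.approx(d.value("cost.procedure.ross"))
        assert float(qaly) == pytest.approx(1.0)

    def test_discounted_survival_is_geometric_series(self, deck):
        """Utility 1, no events, 25 cycles at 3.5%: sum of 1.035^-t = 17.0581."""
        d = _zeroed(deck, horizon=24, **{"util.state.well": 1.0})
        _, qaly = evaluate(d, strategies=("ross",))["ross"]
        assert float(qaly) == pytest.approx(sum(1.035**-t for t in range(25)), rel=1e-12)
        assert float(qaly) == pytest.approx(17.058, abs=1e-3)

    def test_undiscounted_qaly_counts_cycles(self, deck):
        d = _zeroed(deck, horizon=24, **{"util.state.well": 1.0})
        d = dataclasses.replace(d, params=d.params, discount_rate=0.0)
        _, qaly = evaluate(d, strategies=("ross",))["ross"]
        assert float(qaly) == pytest.approx(25.0)

    def test_doubling_costs_doubles_lifetime_cost(self, deck):
        doubled = dataclasses.replace(deck, params=dict(deck.params))
        for name in deck.params:
            if name.startswith("cost."):
                doubled = doubled.with_value(name, 2 * deck.value(name))
        for strategy in ("ross", "cavr"):
            c1, _ = evaluate(deck, strategies=(strategy,))[strategy]
            c2, _ = evaluate(doubled, strategies=(strategy,))[strategy]
            assert float(c2) == pytest.approx(2 * float(c1), rel=1e-12)

    def test_negative_per_cycle_qaly_raises(self, deck):
        bad = deck.with_value("util.state.well", 0.0)
        bad = bad.with_value("util.state.poststroke_nondisabled", 0.0)
        bad = bad.with_value("util.state.poststroke_disabled", 0.0)
        bad = bad.with_value("disutil.event.stroke", 1.0)
        with pytest.raises(DeckValidationError, match="negative per-cycle QALY"):
            evaluate(bad, strategies=("cavr",))

    def test_half_cycle_correction_shrinks_totals(self, deck):
        model = build_transition_model(deck, "ross")
        trace = run_markov(model, deck)
        c_full, q_full = accumulate_outcomes(trace, deck)
        c_half, q_half = accumulate_outcomes(trace, deck, half_cycle_correction=True)
        assert float(q_half) < float(q_full)
        assert float(c_half) < float(c_full)


class TestMicrosimEquivalence:
    @pytest.mark.parametrize("strategy", ["ross", "cavr"])
    def test_cohort_engine_matches_walker_simulation(self, small_deck, strategy):
        values = small_deck.values()
        model = build_transition_model(small_deck, strategy, values)
        trace = run_markov(model, small_deck)
        cost, qaly = accumulate_outcomes(trace, small_deck, values)
        n = 200_000
        sim_cost, sim_qaly = microsimulate(model, small_deck, values, n, seed=42)
        for expected, sample in ((float(cost), sim_cost), (float(qaly), sim_qaly)):
            se = sample.std(ddof=1) / np.sqrt(n)
            assert abs(sample.mean() - expected) < 3 * se


class TestNMB:
    def test_zero_wtp_is_negative_cost(self):
        assert compute_nmb(1234.0, 5.0, 0.0) == -1234.0

    def test_published_lifetime_means_reproduce_nmb(self):
        """20 000 x 15.2 - 46 135 = 257 865, the printed mean within rounding."""
        assert float(compute_nmb(46_135.0, 15.2, 20_000.0)) == pytest.approx(257_865.0)
        assert float(compute_nmb(46_135.0, 15.2, 20_000.0)) == pytest.approx(
            257_337.0, rel=0.005
        )

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            compute_nmb(0.0, 1.0, -1.0)


def test_psa_batch_and_scalar_evaluations_agree(deck):
    """The vectorised batch path must equal per-draw scalar evaluation."""
    from rosscea.deck import sample_parameters

    draws = sample_parameters(deck, np.random.default_rng(9), 3)
    batch = evaluate(deck, draws)
    for i in range(3):
        single = evaluate(deck, {k: v[i] for k, v in draws.items()})
        for strategy in ("ross", "cavr"):
            assert float(batch[strategy][0][i]) == pytest.approx(
                float(single[strategy][0]), rel=1e-12
            )
            assert float(batch[strategy][1][i]) == pytest.approx(
                float(single[strategy][1]), rel=1e-12
            )
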