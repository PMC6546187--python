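"""Individual-level microsimulation oracle for the cohort engine.

Simulates walkers one Bernoulli draw at a time under exactly the semantics
the cohort engine computes in expectation: independent within-cycle event
occurrences, stroke cascades after reoperations, complement-product death,
severity-ordered state updates, end-of-cycle state payoffs and per-event
one-off payoffs.  Used only as a test oracle; deliberately simple and
independent of the enumeration code in ``rosscea.markov``.
"""

from __future__ import annotations

import numpy as np

from rosscea import markov


def microsimulate(model, deck, values, n_walkers: int, seed: int):
    """Return per-walker discounted (cost, qaly) arrays."""
    rng = np.random.default_rng(seed)
    g = lambda k: float(np.asarray(values[k]))  # noqa: E731
    f = lambda a: float(np.asarray(a))  # noqa: E731
    m = model

    state = np.zeros(n_walkers, dtype=np.int8)  # 0 well, 1 psn, 2 psd, 3 dead
    cost = np.zeros(n_walkers)
    qaly = np.zeros(n_walkers)

    state_cost = np.array([0.0, 0.0, g("cost.state.poststroke_disabled_annual"), 0.0])
    state_util = np.array(
        [
            g("util.state.well"),
            g("util.state.poststroke_nondisabled"),
            g("util.state.poststroke_disabled"),
            0.0,
        ]
    )
    event_cost = {
        "bleed": g("cost.event.bleed"),
        "stroke": g("cost.event.stroke"),
        "cons_ie": g("cost.event.conservative_ie"),
        "reop_ie": g("cost.event.aov_reop_ie"),
        "reop_other": g("cost.event.aov_reop_other"),
        "rvot": g("cost.event.rvot_reintervention"),
    }
    event_disutil = {
        "bleed": g("disutil.event.bleed"),
        "stroke": g("disutil.event.stroke"),
        "cons_ie": g("disutil.event.conservative_ie"),
        "reop_ie": g("disutil.event.aov_reop"),
        "reop_other": g("disutil.event.aov_reop"),
        "rvot": g("disutil.event.rvot_reintervention"),
    }

    cost += f(markov._procedure_cost(deck, m.strategy, values))

    for t in range(deck.horizon + 1):
        alive = state < 3
        cost_t = np.zeros(n_walkers)
        disutil_t = np.zeros(n_walkers)
        if t == 0:
            bleed = alive & (rng.random(n_walkers) < f(m.p_early_bleed))
            stroke = alive & (rng.random(n_walkers) < f(m.p_early_stroke))
            death = alive & (rng.random(n_walkers) < f(m.p_op_death))
            death |= bleed & (rng.random(n_walkers) < f(m.d_bleed))
            death |= stroke & (rng.random(n_walkers) < f(m.d_stroke))
            cost_t += bleed * event_cost["bleed"] + stroke * event_cost["stroke"]
            disutil_t += bleed * event_disutil["bleed"] + stroke * event_disutil["stroke"]
        else:
            occurred = {}
            for name, p in [
                ("bleed", m.p_bleed),
                ("cons_ie", m.p_cons_ie),
                ("reop_ie", m.p_reop_ie),
                ("reop_other", m.p_reop_other),
                ("rvot", m.p_rvot),
            ]:
                occurred[name] = alive & (rng.random(n_walkers) < f(p))
            stroke = alive & (rng.random(n_walkers) < f(m.p_stroke_direct))
            for name, q in [
                ("reop_ie", m.q_stroke_reop_ie),
                ("reop_other", m.q_stroke_reop_other),
                ("rvot", m.q_stroke_rvot),
            ]:
                stroke |= occurred[name] & (rng.random(n_walkers) < f(q))
            death = alive & (rng.random(n_walkers) < f(m.p_death_bg))
            for name, d in [
                ("bleed", m.d_bleed),
                ("cons_ie", m.d_cons_ie),
                ("reop_ie", m.d_reop_ie),
                ("reop_other", m.d_reop_other),
                ("rvot", m.d_rvot),
            ]:
                death |= occurred[name] & (rng.random(n_walkers) < f(d))
            death |= stroke & (rng.random(n_walkers) < f(m.d_stroke))
            for name, occ in occurred.items():
                cost_t += occ * event_cost[name]
                disutil_t += occ * event_disutil[name]
            cost_t += stroke * event_cost["stroke"]
            disutil_t += stroke * event_disutil["stroke"]

        disabled = stroke & (rng.random(n_walkers) < f(m.p_disability))
        new_state = state.copy()
        new_state[stroke & ~disabled & (state < 1)] = 1
        new_state[disabled & (state < 2)] = 2
        new_state[death] = 3
        state = new_state

        disc = (1.0 + deck.discount_rate) ** (-t)
        cost += disc * (cost_t + state_cost[state])
        qaly += disc * (state_util[state] - disutil_t)
    return cost, qaly
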