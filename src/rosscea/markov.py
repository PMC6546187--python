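"""Discrete-time Markov multistate cohort engine.

The model follows a cohort after an initial Ross or conventional AVR (cAVR)
procedure through annual cycles.  Persistent states record only the history
of the most serious event:

    well  ->  post-stroke non-disabled  ->  post-stroke disabled  ->  dead

Adverse events within a cycle (bleeding, infective endocarditis treated
conservatively, aortic-valve reoperation for IE or other causes, and — after
Ross only — right-ventricular-outflow-tract reintervention) are transient:
they accrue one-off costs and disutilities and can cascade into stroke
(reoperations) or death (all of them), but do not themselves define states.
Thromboembolic events are modelled as strokes.  Within-cycle events are
independent Bernoulli draws; the per-cycle death probability combines the
background hazard and every event-conditional death as a complement product.
State changes obey the severity order dead > disabled > non-disabled > well:
a less severe destination never overwrites a more severe current state.

The engine is deterministic (cohort proportions) and vectorised: every
parameter may be a scalar or an array of Monte Carlo draws, and the whole
probabilistic sensitivity analysis runs as one batched pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .deck import DeckValidationError, InputDeck
from .evidence import rate_to_probability

STATES = ("well", "post_stroke_nondisabled", "post_stroke_disabled", "dead")

EVENTS = (
    "bleed",
    "stroke",
    "conservative_ie",
    "aov_reop_ie",
    "aov_reop_other",
    "rvot_reintervention",
)

STRATEGIES = ("ross", "cavr")

#: deck rate outcome feeding each transient-event channel
_RATE_FOR_CHANNEL = {
    "bleed": "bleeding",
    "stroke_direct": "thromboembolism",
    "conservative_ie": "conservative_ie",
    "aov_reop_ie": "aov_reop_ie",
    "aov_reop_other": "aov_reoperation",
    "rvot_reintervention": "rvot_reintervention",
    "death_bg": "total_mortality",
}


@dataclass
class TransitionModel:
    """Per-cycle event probabilities and cascade probabilities for one strategy.

    All entries are numpy arrays of a common broadcast shape (scalar decks
    give 0-d arrays, PSA evaluation gives one entry per draw).
    """

    strategy: str
    # transient-event per-cycle probabilities
    p_bleed: np.ndarray
    p_stroke_direct: np.ndarray
    p_cons_ie: np.ndarray
    p_reop_ie: np.ndarray
    p_reop_other: np.ndarray
    p_rvot: np.ndarray
    p_death_bg: np.ndarray
    # conditional stroke probabilities after reoperations
    q_stroke_reop_ie: np.ndarray
    q_stroke_reop_other: np.ndarray
    q_stroke_rvot: np.ndarray
    # conditional death probabilities
    d_bleed: np.ndarray
    d_cons_ie: np.ndarray
    d_reop_ie: np.ndarray
    d_reop_other: np.ndarray
    d_rvot: np.ndarray
    d_stroke: np.ndarray
    # stroke severity split
    p_disability: np.ndarray
    # cycle-0 probabilities
    p_op_death: np.ndarray
    p_early_stroke: np.ndarray
    p_early_bleed: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return np.broadcast_shapes(
            *(getattr(self, f).shape for f in self.__dataclass_fields__ if f != "strategy")
        )


@dataclass
class MarkovTrace:
    """State occupancy and expected transient-event counts per annual cycle.

    ``occupancy`` has shape (cycles,) + batch + (4,) ordered as
    :data:`STATES`; ``expected_events`` (cycles,) + batch + (6,) ordered as
    :data:`EVENTS`.  Rows of ``occupancy`` sum to 1.
    """

    strategy: str
    occupancy: np.ndarray
    expected_events: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def to_dataframes(self):
        """Cycle-by-state and cycle-by-event tables (scalar traces only)."""
        import pandas as pd

        if self.occupancy.ndim != 2:
            raise ValueError("to_dataframes requires an unbatched trace")
        occ = pd.DataFrame(self.occupancy, columns=list(STATES))
        occ.insert(0, "cycle", np.arange(self.n_cycles))
        ev = pd.DataFrame(self.expected_events, columns=list(EVENTS))
        ev.insert(0, "cycle", np.arange(self.n_cycles))
        return occ, ev


def _mixture(values: dict, key_fmt: str, w: float, default: float | None = None):
    """(1-w)·mechAVR + w·bioAVR for a per-arm parameter."""

    def get(arm):
        key = key_fmt.format(arm=arm)
        if key in values:
            return np.asarray(values[key], dtype=float)
        if default is not None:
            return np.asarray(default, dtype=float)
        raise KeyError(key)

    return (1.0 - w) * get("mechAVR") + w * get("bioAVR")


def build_transition_model(
    deck: InputDeck, strategy: str, values: dict | None = None
) -> TransitionModel:
    """Assemble the per-cycle transition structure for one strategy.

    ``values`` maps parameter names to scalars or draw arrays; defaults to
    the deck's point estimates.  For the cAVR strategy every annual rate and
    early probability is the biological/mechanical mixture
    (1-w)·mechAVR + w·bioAVR (w = ``deck.mixture_weight_bio``) formed on the
    %/year scale before conversion to per-cycle probabilities.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if values is None:
        values = deck.values()

    def rate(channel: str) -> np.ndarray:
        outcome = _RATE_FOR_CHANNEL[channel]
        if strategy == "ross":
            key = f"rate.ross.{outcome}"
            if key not in values:
                raise DeckValidationError(f"missing rate for ross strategy: {outcome}")
            return np.asarray(values[key], dtype=float)
        if outcome == "rvot_reintervention":
            return np.asarray(0.0)
        try:
            return _mixture(values, "rate.{arm}." + outcome, deck.mixture_weight_bio)
        except KeyError as exc:
            raise DeckValidationError(f"missing rate for cavr strategy: {exc}") from exc

    def early(which: str) -> np.ndarray:
        if strategy == "ross":
            return np.asarray(values[f"early.ross.{which}"], dtype=float)
        return _mixture(values, "early.{arm}." + which, deck.mixture_weight_bio)

    def cond(name: str) -> np.ndarray:
        return np.asarray(values[f"cond.{name}"], dtype=float)

    return TransitionModel(
        strategy=strategy,
        p_bleed=rate_to_probability(rate("bleed")),
        p_stroke_direct=rate_to_probability(rate("stroke_direct")),
        p_cons_ie=rate_to_probability(rate("conservative_ie")),
        p_reop_ie=rate_to_probability(rate("aov_reop_ie")),
        p_reop_other=rate_to_probability(rate("aov_reop_other")),
        p_rvot=rate_to_probability(rate("rvot_reintervention")),
        p_death_bg=rate_to_probability(rate("death_bg")),
        q_stroke_reop_ie=cond("stroke_given_reop_ie"),
        q_stroke_reop_other=cond("stroke_given_reop_other"),
        q_stroke_rvot=cond("stroke_given_rvot"),
        d_bleed=cond("death_given_bleed"),
        d_cons_ie=cond("death_given_cons_ie"),
        d_reop_ie=cond("death_given_reop_ie"),
        d_reop_other=cond("death_given_reop_other"),
        d_rvot=cond("death_given_rvot"),
        d_stroke=cond("death_given_stroke"),
        p_disability=cond("disability_given_stroke"),
        p_op_death=np.asarray(early("death"), dtype=float),
        p_early_stroke=np.asarray(early("stroke"), dtype=float),
        p_early_bleed=np.asarray(early("bleed"), dtype=float),
    )


def _cycle_kernel(channels, p_bg, d_stroke):
    """Exact within-cycle outcome distribution for an alive individual.

    ``channels`` is a list of (p_occur, q_stroke, d_death) triples of
    broadcastable arrays; occurrences are independent, and given occurrence
    the stroke and death cascades fire independently.  Death from any source
    (background ``p_bg``, an event's conditional death, or ``d_stroke`` once
    a stroke has occurred from any source) combines as a complement product.

    Returns (p_die, p_survive_stroke, p_survive_nostroke, e_stroke) where
    ``e_stroke`` is the marginal probability that a stroke occurs (counted
    whether or not the individual survives the cycle).
    """
    surv_stroke = 0.0
    surv_nostroke = 0.0
    e_stroke = 0.0
    s_bg = 1.0 - np.asarray(p_bg, dtype=float)
    for bits in product((0, 1), repeat=len(channels)):
        w = 1.0
        no_stroke = 1.0
        surv_ev = 1.0
        for bit, (p, q, d) in zip(bits, channels):
            if bit:
                w = w * p
                no_stroke = no_stroke * (1.0 - q)
                surv_ev = surv_ev * (1.0 - d)
            else:
                w = w * (1.0 - p)
        p_stroke_c = 1.0 - no_stroke
        base = w * s_bg * surv_ev
        surv_stroke = surv_stroke + base * p_stroke_c * (1.0 - d_stroke)
        surv_nostroke = surv_nostroke + base * (1.0 - p_stroke_c)
        e_stroke = e_stroke + w * p_stroke_c
    p_die = 1.0 - surv_stroke - surv_nostroke
    return (
        np.asarray(p_die),
        np.asarray(surv_stroke),
        np.asarray(surv_nostroke),
        np.asarray(e_stroke),
    )


def _check_probability(name: str, p: np.ndarray, where: str) -> None:
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise DeckValidationError(f"{name} outside [0, 1] at {where}")


def run_markov(model: TransitionModel, deck: InputDeck) -> MarkovTrace:
    """Propagate the cohort through cycles t = 0..deck.horizon.

    Cycle 0 applies the early (peri-operative) probabilities; each later
    cycle applies the time-homogeneous kernel built from the annual rates.
    Occupancy rows record the state distribution at the end of each cycle.
    """
    horizon = deck.horizon
    if horizon < 0:
        raise DeckValidationError("horizon must be >= 0")

    zeros = np.asarray(0.0)
    # cycle 0: operative death + early stroke + early bleed
    die0, str0, nostr0, e_stroke0 = _cycle_kernel(
        [
            (model.p_early_bleed, zeros, model.d_bleed),
            (model.p_early_stroke, np.asarray(1.0), zeros),
        ],
        model.p_op_death,
        model.d_stroke,
    )
    # recurring annual kernel (constant across cycles)
    die, strk, nostrk, e_stroke = _cycle_kernel(
        [
            (model.p_bleed, zeros, model.d_bleed),
            (model.p_cons_ie, zeros, model.d_cons_ie),
            (model.p_reop_ie, model.q_stroke_reop_ie, model.d_reop_ie),
            (model.p_reop_other, model.q_stroke_reop_other, model.d_reop_other),
            (model.p_rvot, model.q_stroke_rvot, model.d_rvot),
            (model.p_stroke_direct, np.asarray(1.0), zeros),
        ],
        model.p_death_bg,
        model.d_stroke,
    )
    for name, p in (("cycle-0 death", die0), ("per-cycle death", die)):
        _check_probability(name, p, "kernel assembly")

    shape = np.broadcast_shapes(die0.shape, die.shape, model.p_disability.shape)
    occupancy = np.zeros((horizon + 1,) + shape + (4,))
    events = np.zeros((horizon + 1,) + shape + (len(EVENTS),))
    ev_idx = {e: i for i, e in enumerate(EVENTS)}

    p_dis = model.p_disability
    occupancy[0, ..., 3] = die0
    occupancy[0, ..., 2] = str0 * p_dis
    occupancy[0, ..., 1] = str0 * (1.0 - p_dis)
    occupancy[0, ..., 0] = nostr0
    events[0, ..., ev_idx["bleed"]] = model.p_early_bleed
    events[0, ..., ev_idx["stroke"]] = e_stroke0

    surv = strk + nostrk  # overall per-cycle survival
    for t in range(1, horizon + 1):
        well, psn, psd, dead = (occupancy[t - 1, ..., i] for i in range(4))
        alive = well + psn + psd
        occupancy[t, ..., 0] = well * nostrk
        occupancy[t, ..., 1] = well * strk * (1.0 - p_dis) + psn * (
            strk * (1.0 - p_dis) + nostrk
        )
        occupancy[t, ..., 2] = (well + psn) * strk * p_dis + psd * surv
        occupancy[t, ..., 3] = dead + alive * die
        events[t, ..., ev_idx["bleed"]] = alive * model.p_bleed
        events[t, ..., ev_idx["stroke"]] = alive * e_stroke
        events[t, ..., ev_idx["conservative_ie"]] = alive * model.p_cons_ie
        events[t, ..., ev_idx["aov_reop_ie"]] = alive * model.p_reop_ie
        events[t, ..., ev_idx["aov_reop_other"]] = alive * model.p_reop_other
        events[t, ..., ev_idx["rvot_reintervention"]] = alive * model.p_rvot

    row_sums = occupancy.sum(axis=-1)
    if np.any(np.abs(row_sums - 1.0) > 1e-9):
        t_bad = int(np.argwhere(np.abs(row_sums - 1.0) > 1e-9)[0][0])
        raise DeckValidationError(f"occupancy row does not sum to 1 at cycle {t_bad}")
    return MarkovTrace(strategy=model.strategy, occupancy=occupancy, expected_events=events)


def _procedure_cost(deck: InputDeck, strategy: str, values: dict) -> np.ndarray:
    if strategy == "ross":
        return np.asarray(values["cost.procedure.ross"], dtype=float)
    return _mixture(values, "cost.procedure.{arm}", deck.mixture_weight_bio)


def accumulate_outcomes(
    trace: MarkovTrace,
    deck: InputDeck,
    values: dict | None = None,
    half_cycle_correction: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Discounted lifetime cost and QALY totals for a trace.

    Per cycle t: cost = Σ occupancy × annual state cost + Σ expected events ×
    one-off event cost; QALY = Σ occupancy × state utility − Σ expected
    events × event disutility; both discounted by (1 + r)^-t (cycle 0
    undiscounted).  The initial procedure cost is added at cycle 0.  A
    negative per-cycle QALY indicates a mis-specified deck and raises
    :class:`DeckValidationError` rather than being clamped.

    ``half_cycle_correction`` applies trapezoidal weights (0.5 on the first
    and last cycle); it is off by default.
    """
    if values is None:
        values = deck.values()
    g = lambda k: np.asarray(values[k], dtype=float)  # noqa: E731

    state_cost = np.stack(
        np.broadcast_arrays(
            np.asarray(0.0),
            np.asarray(0.0),
            g("cost.state.poststroke_disabled_annual"),
            np.asarray(0.0),
        ),
        axis=-1,
    )
    state_util = np.stack(
        np.broadcast_arrays(
            g("util.state.well"),
            g("util.state.poststroke_nondisabled"),
            g("util.state.poststroke_disabled"),
            np.asarray(0.0),
        ),
        axis=-1,
    )
    event_cost = np.stack(
        np.broadcast_arrays(
            g("cost.event.bleed"),
            g("cost.event.stroke"),
            g("cost.event.conservative_ie"),
            g("cost.event.aov_reop_ie"),
            g("cost.event.aov_reop_other"),
            g("cost.event.rvot_reintervention"),
        ),
        axis=-1,
    )
    event_disutil = np.stack(
        np.broadcast_arrays(
            g("disutil.event.bleed"),
            g("disutil.event.stroke"),
            g("disutil.event.conservative_ie"),
            g("disutil.event.aov_reop"),
            g("disutil.event.aov_reop"),
            g("disutil.event.rvot_reintervention"),
        ),
        axis=-1,
    )

    n_cycles = trace.n_cycles
    t = np.arange(n_cycles)
    disc = (1.0 + deck.discount_rate) ** (-t)
    weights = np.ones(n_cycles)
    if half_cycle_correction and n_cycles > 1:
        weights[0] = weights[-1] = 0.5
    disc = disc * weights
    disc = disc.reshape((n_cycles,) + (1,) * (trace.occupancy.ndim - 2))

    cost_t = np.sum(trace.occupancy * state_cost, axis=-1) + np.sum(
        trace.expected_events * event_cost, axis=-1
    )
    qaly_t = np.sum(trace.occupancy * state_util, axis=-1) - np.sum(
        trace.expected_events * event_disutil, axis=-1
    )
    if np.any(qaly_t < -1e-12):
        raise DeckValidationError(
            "negative per-cycle QALY: event disutilities exceed state utility "
            "(deck mis-specified)"
        )
    cost = np.sum(cost_t * disc, axis=0) + _procedure_cost(deck, trace.strategy, values)
    qaly = np.sum(qaly_t * disc, axis=0)
    return np.asarray(cost), np.asarray(qaly)


def compute_nmb(cost, qaly, wtp: float):
    """Net monetary benefit: wtp × QALYs − cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * np.asarray(qaly) - np.asarray(cost)


def evaluate(
    deck: InputDeck,
    values: dict | None = None,
    strategies: tuple[str, ...] = STRATEGIES,
    half_cycle_correction: bool = False,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Run the full model for each strategy on one parameter vector (or a
    batch of draws) and return {strategy: (lifetime_cost, lifetime_qaly)}.
    """
    out = {}
    for strategy in strategies:
        model = build_transition_model(deck, strategy, values)
        trace = run_markov(model, deck)
        out[strategy] = accumulate_outcomes(
            trace, deck, values, half_cycle_correction=half_cycle_correction
        )
    return out
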