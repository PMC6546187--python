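"""Deterministic sensitivity analyses.

One-way analyses perturb the deck's fixed (non-sampled) cost and utility
entries to 50% and 150% of their values and re-run the deterministic model;
comparator-scenario analyses replace the biological/mechanical mixture
behind the conventional-AVR strategy with a single prosthesis type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import pandas as pd

from . import markov, psa as psa_mod
from .deck import InputDeck

logger = logging.getLogger(__name__)

_OWSA_FAMILIES = ("cost", "util", "disutil")


@dataclass(frozen=True)
class OWSAResult:
    """One perturbation of one fixed parameter."""

    parameter: str
    multiplier: float
    incremental_cost: float
    incremental_qaly: float
    inmb: float
    base_inmb: float


def _deterministic_incrementals(
    deck: InputDeck, wtp: float, strategy: str = "ross", comparator: str = "cavr"
) -> tuple[float, float, float]:
    out = markov.evaluate(deck, strategies=(strategy, comparator))
    (c1, q1), (c0, q0) = out[strategy], out[comparator]
    d_cost = float(c1 - c0)
    d_qaly = float(q1 - q0)
    return d_cost, d_qaly, float(markov.compute_nmb(d_cost, d_qaly, wtp))


def one_way_sensitivity(
    deck: InputDeck,
    parameters: list[str] | None = None,
    multipliers: tuple[float, ...] = (0.5, 1.5),
    wtp: float = 20_000.0,
) -> list[OWSAResult]:
    """Perturb each fixed parameter by each multiplier and report the INMB.

    Defaults to all fixed cost/utility/disutility deck entries.  Utilities
    exceeding 1 after multiplication are capped at 1 with a logged warning.
    All uncertain parameters stay at their point estimates (deterministic
    runs), so a multiplier of 1.0 reproduces the base case bit-exactly.
    """
    deck.validate()
    if parameters is None:
        parameters = [
            n for n in deck.fixed_names() if n.split(".", 1)[0] in _OWSA_FAMILIES
        ]
    for m in multipliers:
        if m <= 0:
            raise ValueError(f"multiplier must be positive, got {m}")
    unknown = [p for p in parameters if p not in deck.params]
    if unknown:
        raise KeyError(f"unknown parameters: {unknown}")

    base_cost, base_qaly, base_inmb = _deterministic_incrementals(deck, wtp)
    results = []
    for name in parameters:
        for m in multipliers:
            value = deck.value(name) * m
            if name.split(".", 1)[0] in ("util", "disutil") and value > 1.0:
                logger.warning("capping %s at 1.0 (%.3f after ×%g)", name, value, m)
                value = 1.0
            if m == 1.0:
                d_cost, d_qaly, inmb = base_cost, base_qaly, base_inmb
            else:
                d_cost, d_qaly, inmb = _deterministic_incrementals(
                    deck.with_value(name, value), wtp
                )
            results.append(
                OWSAResult(
                    parameter=name,
                    multiplier=m,
                    incremental_cost=d_cost,
                    incremental_qaly=d_qaly,
                    inmb=inmb,
                    base_inmb=base_inmb,
                )
            )
    return results


def tornado_frame(results: list[OWSAResult]) -> pd.DataFrame:
    """Tornado-style table: one row per parameter, INMB at the low and high
    multiplier, sorted by swing."""
    df = pd.DataFrame([r.__dict__ for r in results])
    lo = df[df.multiplier == df.multiplier.min()].set_index("parameter")["inmb"]
    hi = df[df.multiplier == df.multiplier.max()].set_index("parameter")["inmb"]
    out = pd.DataFrame({"inmb_low": lo, "inmb_high": hi})
    out["swing"] = (out.inmb_high - out.inmb_low).abs()
    return out.sort_values("swing", ascending=False).reset_index()


@dataclass
class ScenarioResult:
    """Deterministic (and optionally probabilistic) cost-effectiveness
    summary under one comparator definition."""

    comparator: str
    mixture_weight_bio: float
    cost: dict[str, float]
    qaly: dict[str, float]
    incremental_cost: float
    incremental_qaly: float
    inmb: float
    wtp: float
    psa_summary: pd.DataFrame | None = None


_COMPARATOR_WEIGHTS = {"mixture": None, "mech_only": 0.0, "bio_only": 1.0}


def scenario_comparator(
    deck: InputDeck,
    comparator: str = "mixture",
    wtp: float = 20_000.0,
    n_draws: int = 0,
    seed: int = 0,
) -> ScenarioResult:
    """Re-run the analysis with cAVR defined as a mixture, mechanical-only
    (w = 0) or biological-only (w = 1) cohort.

    ``n_draws >= 2`` additionally runs a PSA under the scenario and attaches
    its summary table.
    """
    if comparator not in _COMPARATOR_WEIGHTS:
        raise ValueError(
            f"unknown comparator {comparator!r}; expected one of "
            f"{tuple(_COMPARATOR_WEIGHTS)}"
        )
    w = _COMPARATOR_WEIGHTS[comparator]
    scenario_deck = (
        deck if w is None else dc_replace(deck, params=dict(deck.params), mixture_weight_bio=w)
    )
    scenario_deck.validate()
    out = markov.evaluate(scenario_deck)
    (c_ross, q_ross), (c_cavr, q_cavr) = out["ross"], out["cavr"]
    d_cost = float(c_ross - c_cavr)
    d_qaly = float(q_ross - q_cavr)
    psa_summary = None
    if n_draws >= 2:
        psa_summary = psa_mod.run_psa(scenario_deck, n_draws=n_draws, seed=seed).summary(
            wtps=(wtp,)
        )
    return ScenarioResult(
        comparator=comparator,
        mixture_weight_bio=scenario_deck.mixture_weight_bio,
        cost={"ross": float(c_ross), "cavr": float(c_cavr)},
        qaly={"ross": float(q_ross), "cavr": float(q_cavr)},
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        inmb=float(markov.compute_nmb(d_cost, d_qaly, wtp)),
        wtp=wtp,
        psa_summary=psa_summary,
    )
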