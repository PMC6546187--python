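"""Value-of-information analysis: EVPI, EVPPI and population scaling.

EVPI (expected value of perfect information) is the expected gain from
resolving all parameter uncertainty before choosing a strategy:

    EVPI = E[max_d NMB_d] - max_d E[NMB_d]

EVPPI for a parameter subset phi replaces the inner NMB with its conditional
expectation over the complementary parameters:

    EVPPI(phi) = E_phi[max_d E[NMB_d | phi]] - max_d E[NMB_d]

The nested (two-level) Monte Carlo estimator is the oracle: slow but
transparent.  The multilevel Monte Carlo (MLMC) estimator expresses the same
nested expectation as a telescoping sum of corrections across geometrically
growing inner sample sizes, with antithetic coupling between the fine
estimator and the average of two half-sample coarse estimators, and is the
production estimator.

Per-person values are scaled to the population affected over a discounted
technology horizon (the years a reimbursement decision stays relevant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import markov
from .deck import InputDeck, sample_parameters
from .psa import PSAResults


@dataclass
class VOIResult:
    """One EVPI/EVPPI estimate with Monte Carlo error and population scaling."""

    quantity: str  # "evpi" | "evppi"
    parameter_subset: str
    wtp: float
    per_person_value: float
    per_person_ci: tuple[float, float]
    se: float
    estimator: str  # "psa_direct" | "nested_mc" | "mlmc"
    n_samples: dict
    population_size: float | None = None
    population_value: float | None = None
    population_ci: tuple[float, float] | None = None
    warning: str | None = None

    def scaled(
        self,
        incidence_per_year: float = 960.0,
        horizon_years: int = 25,
        discount: float = 0.035,
    ) -> "VOIResult":
        """Attach population-level values over the technology horizon."""
        pop = population_size(incidence_per_year, horizon_years, discount)
        self.population_size = pop
        self.population_value = self.per_person_value * pop
        self.population_ci = (self.per_person_ci[0] * pop, self.per_person_ci[1] * pop)
        return self


def population_size(
    incidence_per_year: float = 960.0,
    horizon_years: int = 25,
    discount: float = 0.035,
) -> float:
    """Discounted number of people affected by the decision.

    incidence × sum_{t=0}^{horizon-1} (1 + discount)^-t — the first year is
    undiscounted.
    """
    if incidence_per_year < 0 or horizon_years < 0 or discount < 0:
        raise ValueError("population scaling arguments must be >= 0")
    t = np.arange(horizon_years)
    return float(incidence_per_year * np.sum((1.0 + discount) ** (-t)))


def population_scale(
    per_person: float,
    incidence_per_year: float = 960.0,
    horizon_years: int = 25,
    discount: float = 0.035,
) -> float:
    """Per-person value × discounted technology-horizon population size."""
    return per_person * population_size(incidence_per_year, horizon_years, discount)


def compute_evpi(
    results: PSAResults, wtp: float, n_boot: int = 1000, seed: int = 0
) -> VOIResult:
    """Per-person EVPI from stored PSA draws, with a bootstrap CI."""
    nmb = np.column_stack([results.nmb(wtp)[s] for s in results.strategies])
    evpi = float(np.mean(nmb.max(axis=1)) - np.max(nmb.mean(axis=0)))

    rng = np.random.default_rng(seed)
    n = nmb.shape[0]
    boots = np.empty(n_boot)
    row_max = nmb.max(axis=1)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = row_max[idx].mean() - nmb[idx].mean(axis=0).max()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return VOIResult(
        quantity="evpi",
        parameter_subset="all",
        wtp=wtp,
        per_person_value=evpi,
        per_person_ci=(float(lo), float(hi)),
        se=float(boots.std(ddof=1)),
        estimator="psa_direct",
        n_samples={"n_draws": n, "n_boot": n_boot},
    )


def _resolve_subset(deck: InputDeck, subset) -> tuple[str, list[str]]:
    if isinstance(subset, str):
        return subset, deck.subset_names(subset)
    names = list(subset)
    unknown = [n for n in names if n not in deck.params]
    if unknown:
        raise KeyError(f"unknown parameters in subset: {unknown}")
    return "+".join(names), names


def _conditional_nmb_samples(
    deck: InputDeck,
    names: list[str],
    wtp: float,
    n_outer: int,
    n_inner: int,
    rng: np.random.Generator,
    strategies: tuple[str, ...],
) -> np.ndarray:
    """NMB evaluations on a (n_outer × n_inner) nested design.

    Outer draws fix the subset parameters; inner draws vary the complement.
    Returns an array of shape (n_outer, n_inner, n_strategies).
    """
    outer = sample_parameters(deck, rng, n_outer)
    inner = sample_parameters(deck, rng, n_outer * n_inner)
    for name in names:
        inner[name] = np.repeat(outer[name], n_inner)
    outcomes = markov.evaluate(deck, inner, strategies=strategies)
    nmb = np.stack(
        [markov.compute_nmb(c, q, wtp) for c, q in outcomes.values()], axis=-1
    )
    return nmb.reshape(n_outer, n_inner, len(strategies))


def nested_evppi(sampler, n_outer: int, n_inner: int, rng) -> tuple[float, float]:
    """Core nested estimator, independent of the decision model.

    ``sampler(n_outer, n_inner, rng)`` must return conditional NMB samples
    of shape (n_outer, n_inner, n_strategies): outer index fixes the subset
    parameters, inner index varies the complement.  Returns (evppi, se),
    where the SE covers the outer-level Monte Carlo error of the coupled
    difference max_d inner-mean minus inner-mean of the on-average-best
    strategy.
    """
    if n_outer < 2 or n_inner < 2:
        raise ValueError("n_outer and n_inner must both be >= 2")
    nmb = sampler(n_outer, n_inner, rng)
    inner_means = nmb.mean(axis=1)  # (n_outer, n_strat)
    d_star = int(np.argmax(inner_means.mean(axis=0)))
    per_outer = inner_means.max(axis=1) - inner_means[:, d_star]
    return float(per_outer.mean()), float(per_outer.std(ddof=1) / np.sqrt(n_outer))


def mlmc_evppi(
    sampler, levels: int, n0: int, n_outer: int, rng
) -> tuple[float, float, list[float], list[float]]:
    """Core multilevel estimator, independent of the decision model.

    Level l draws max(2, n_outer/2^l) outer samples with n0·2^l inner
    samples each; the level-l correction couples the fine estimator
    max_d mean(all inner) to the antithetic average of the two half-sample
    coarse estimators.  Level 0 is coupled to the unconditional baseline
    max_d E[NMB_d].  Returns (evppi, se, level_means, level_variances).
    """
    if levels < 1 or n0 < 2 or n_outer < 2:
        raise ValueError("levels >= 1, n0 >= 2 and n_outer >= 2 required")
    level_means: list[float] = []
    level_vars: list[float] = []
    for level in range(levels + 1):
        m_out = max(2, n_outer // 2**level)
        m_in = n0 * 2**level
        nmb = sampler(m_out, m_in, rng)
        fine = nmb.mean(axis=1).max(axis=1)  # (m_out,)
        if level == 0:
            flat_mean = nmb.reshape(-1, nmb.shape[-1]).mean(axis=0)
            d_star = int(np.argmax(flat_mean))
            corr = fine - nmb[..., d_star].mean(axis=1)
        else:
            half = m_in // 2
            coarse = 0.5 * (
                nmb[:, :half].mean(axis=1).max(axis=1)
                + nmb[:, half:].mean(axis=1).max(axis=1)
            )
            corr = fine - coarse
        level_means.append(float(corr.mean()))
        level_vars.append(float(corr.var(ddof=1) / m_out))
    total = float(np.sum(level_means))
    se = float(np.sqrt(np.sum(level_vars)))
    return total, se, level_means, level_vars


def compute_evppi_nested(
    deck: InputDeck,
    subset,
    wtp: float,
    n_outer: int = 64,
    n_inner: int = 64,
    seed: int = 0,
    strategies: tuple[str, ...] = markov.STRATEGIES,
) -> VOIResult:
    """Nested two-level Monte Carlo EVPPI (the oracle estimator).

    ``subset`` is a named parameter set (see ``InputDeck.subset_names``) or
    an explicit list of parameter names.  An empty subset returns exactly 0.
    """
    label, names = _resolve_subset(deck, subset)
    if not names:
        return VOIResult(
            quantity="evppi",
            parameter_subset=label,
            wtp=wtp,
            per_person_value=0.0,
            per_person_ci=(0.0, 0.0),
            se=0.0,
            estimator="nested_mc",
            n_samples={"n_outer": 0, "n_inner": 0},
        )
    rng = np.random.default_rng(seed)
    sampler = lambda m_out, m_in, r: _conditional_nmb_samples(  # noqa: E731
        deck, names, wtp, m_out, m_in, r, strategies
    )
    evppi, se = nested_evppi(sampler, n_outer, n_inner, rng)
    return VOIResult(
        quantity="evppi",
        parameter_subset=label,
        wtp=wtp,
        per_person_value=evppi,
        per_person_ci=(evppi - 1.96 * se, evppi + 1.96 * se),
        se=se,
        estimator="nested_mc",
        n_samples={"n_outer": n_outer, "n_inner": n_inner},
    )


def compute_evppi_mlmc(
    deck: InputDeck,
    subset,
    wtp: float,
    levels: int = 4,
    n0: int = 8,
    n_outer: int = 256,
    seed: int = 0,
    strategies: tuple[str, ...] = markov.STRATEGIES,
) -> VOIResult:
    """Multilevel Monte Carlo EVPPI.

    Level l uses inner sample size n0·2^l and outer sample size
    max(2, n_outer / 2^l) (the geometric allocation keeps per-level cost
    constant).  The level-l correction couples the fine estimator
    max_d mean(all inner) with the antithetic coarse estimator
    ½[max_d mean(first half) + max_d mean(second half)]; the telescoping sum
    of corrections estimates E[max_d E(NMB_d | subset)], from which the
    unconditional max_d E[NMB_d] (estimated on the level-0 sample) is
    subtracted.

    If the estimated level corrections stop decaying over the last two
    levels, the result carries a ``warning`` flag instead of failing.
    """
    label, names = _resolve_subset(deck, subset)
    if not names:
        return VOIResult(
            quantity="evppi",
            parameter_subset=label,
            wtp=wtp,
            per_person_value=0.0,
            per_person_ci=(0.0, 0.0),
            se=0.0,
            estimator="mlmc",
            n_samples={"levels": 0, "n0": 0},
        )
    rng = np.random.default_rng(seed)
    sampler = lambda m_out, m_in, r: _conditional_nmb_samples(  # noqa: E731
        deck, names, wtp, m_out, m_in, r, strategies
    )
    evppi, se, level_means, _level_vars = mlmc_evppi(sampler, levels, n0, n_outer, rng)

    warning = None
    if levels >= 2 and abs(level_means[-1]) > abs(level_means[-2]):
        warning = (
            "level corrections are not decaying over the last two levels; "
            "increase n0 or levels"
        )
    return VOIResult(
        quantity="evppi",
        parameter_subset=label,
        wtp=wtp,
        per_person_value=evppi,
        per_person_ci=(evppi - 1.96 * se, evppi + 1.96 * se),
        se=se,
        estimator="mlmc",
        n_samples={
            "levels": levels,
            "n0": n0,
            "n_outer": n_outer,
            "level_corrections": level_means,
        },
        warning=warning,
    )
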