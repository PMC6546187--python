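"""Probabilistic sensitivity analysis.

Samples the joint parameter distribution of an input deck, pushes every draw
through the cohort engine for both strategies (common random parameters, so
incremental quantities are properly correlated), and summarises lifetime
costs, QALYs, net monetary benefit and the cost-effectiveness acceptability
curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import markov
from .deck import DeckValidationError, InputDeck, sample_parameters

logger = logging.getLogger(__name__)

_PROB_FAMILIES = ("early", "cond", "util", "disutil")


@dataclass
class PSAResults:
    """Per-draw lifetime outcomes for each strategy plus sampling metadata.

    ``costs``/``qalys`` map strategy name to arrays of length ``n_draws``.
    Draw ``i`` of every strategy shares one parameter realisation.
    """

    strategies: tuple[str, ...]
    n_draws: int
    seed: int
    costs: dict[str, np.ndarray]
    qalys: dict[str, np.ndarray]
    n_rejected: int = 0
    parameter_draws: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def nmb(self, wtp: float) -> dict[str, np.ndarray]:
        return {
            s: markov.compute_nmb(self.costs[s], self.qalys[s], wtp)
            for s in self.strategies
        }

    def inmb(self, wtp: float, strategy: str = "ross", comparator: str = "cavr") -> np.ndarray:
        nmb = self.nmb(wtp)
        return nmb[strategy] - nmb[comparator]

    def summary(self, wtps: tuple[float, ...] = (20_000.0, 50_000.0)) -> pd.DataFrame:
        """Means and equal-tailed 95% credible intervals, plus incrementals."""
        rows = []

        def add(quantity, values_by_col):
            for col, x in values_by_col.items():
                lo, hi = np.percentile(x, [2.5, 97.5])
                rows.append(
                    {
                        "quantity": quantity,
                        "strategy": col,
                        "mean": float(np.mean(x)),
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                    }
                )

        s0, s1 = self.strategies[0], self.strategies[1]
        add("cost", {**self.costs, "incremental": self.costs[s0] - self.costs[s1]})
        add("qaly", {**self.qalys, "incremental": self.qalys[s0] - self.qalys[s1]})
        for wtp in wtps:
            nmb = self.nmb(wtp)
            add(f"nmb@{wtp:g}", {**nmb, "incremental": nmb[s0] - nmb[s1]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                **{f"cost_{s}": self.costs[s] for s in self.strategies},
                **{f"qaly_{s}": self.qalys[s] for s in self.strategies},
            }
        )
        df.insert(0, "draw_id", np.arange(self.n_draws))
        df.to_csv(path, index=False)
        return df

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "PSAResults":
        df = pd.read_csv(path)
        strategies = tuple(
            c[len("cost_") :] for c in df.columns if c.startswith("cost_")
        )
        return cls(
            strategies=strategies,
            n_draws=len(df),
            seed=seed,
            costs={s: df[f"cost_{s}"].to_numpy() for s in strategies},
            qalys={s: df[f"qaly_{s}"].to_numpy() for s in strategies},
        )


def _valid_mask(draws: dict[str, np.ndarray], n: int) -> np.ndarray:
    ok = np.ones(n, dtype=bool)
    for name, x in draws.items():
        head = name.split(".", 1)[0]
        if head in _PROB_FAMILIES:
            ok &= (x >= 0.0) & (x <= 1.0)
        else:
            ok &= x >= 0.0
    return ok


def run_psa(
    deck: InputDeck,
    n_draws: int = 10_000,
    seed: int = 0,
    strategies: tuple[str, ...] = markov.STRATEGIES,
    keep_parameter_draws: bool = False,
) -> PSAResults:
    """Sample ``n_draws`` parameter sets and evaluate both strategies on each.

    Draws violating deck invariants are rejected and resampled (with a
    logged count); more than 1% rejections aborts, signalling a deck whose
    fitted distributions disagree with their support.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    deck.validate()
    rng = np.random.default_rng(seed)
    draws = sample_parameters(deck, rng, n_draws)
    ok = _valid_mask(draws, n_draws)
    n_rejected = int(n_draws - ok.sum())
    if n_rejected:
        if n_rejected > 0.01 * n_draws:
            raise DeckValidationError(
                f"{n_rejected}/{n_draws} PSA draws violate parameter support"
            )
        logger.warning("resampling %d invalid PSA draws", n_rejected)
        while not ok.all():
            bad = np.flatnonzero(~ok)
            redraw = sample_parameters(deck, rng, bad.size)
            for name in draws:
                draws[name][bad] = redraw[name]
            ok[bad] = _valid_mask({k: v[bad] for k, v in draws.items()}, bad.size)

    outcomes = markov.evaluate(deck, draws, strategies=strategies)
    return PSAResults(
        strategies=strategies,
        n_draws=n_draws,
        seed=seed,
        costs={s: outcomes[s][0] for s in strategies},
        qalys={s: outcomes[s][1] for s in strategies},
        n_rejected=n_rejected,
        parameter_draws=draws if keep_parameter_draws else None,
    )


@dataclass
class CEAC:
    """Cost-effectiveness acceptability curve.

    ``probability[i, j]``: fraction of draws in which strategy ``j`` has the
    highest net monetary benefit at ``wtp_grid[i]`` (ties split equally).
    """

    wtp_grid: np.ndarray
    strategies: tuple[str, ...]
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probability, columns=[f"p_{s}" for s in self.strategies])
        df.insert(0, "wtp", self.wtp_grid)
        return df


def compute_ceac(results: PSAResults, wtp_grid=None) -> CEAC:
    """Probability each strategy is most cost-effective along a WTP grid."""
    if len(results.strategies) < 2:
        raise ValueError("CEAC needs at least two strategies")
    if wtp_grid is None or len(wtp_grid) == 0:
        raise ValueError("empty willingness-to-pay grid")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    prob = np.zeros((wtp_grid.size, len(results.strategies)))
    for i, wtp in enumerate(wtp_grid):
        nmb = np.column_stack([results.nmb(wtp)[s] for s in results.strategies])
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb == best
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        prob[i] = weights.mean(axis=0)
    return CEAC(wtp_grid=wtp_grid, strategies=results.strategies, probability=prob)
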