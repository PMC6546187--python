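"""The model input deck: every parameter of the decision model in one
validated, serialisable container.

Each uncertain quantity is stored as a point estimate plus a 95% interval and
a distribution family; probabilistic analyses fit the family to (point, CI)
by method of moments and sample from it.  Quantities flagged ``fixed`` (the
tariff costs and a subset of utilities/disutilities) never vary in the PSA
and are instead exercised by the deterministic one-way sensitivity analysis.

Distribution families follow the conventional health-economics assignment:
log-normal for annual event rates, Beta for probabilities and utilities,
Gamma for the post-stroke disability annual cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

DECK_VERSION = 1

_Z95 = 1.959963984540054

ARMS = ("ross", "mechAVR", "bioAVR")

#: annual-rate outcomes the cycle engine consumes, per arm (%/year)
MODEL_RATE_OUTCOMES = (
    "total_mortality",
    "aov_reoperation",
    "bleeding",
    "thromboembolism",
    "aov_reop_ie",
    "conservative_ie",
    "rvot_reintervention",  # Ross arm only; 0 for prosthetic arms
)

#: named parameter subsets used by the value-of-information analysis
VOI_SUBSETS = (
    "meta_analysis",
    "utilities",
    "poststroke_disability_costs",
    "early_bleed_stroke",
    "other_epidemiological",
    "ross_trial_all_epi",
    "all",
)


class DeckValidationError(ValueError):
    """An input deck (or a sampled draw from it) violates its invariants."""


@dataclass(frozen=True)
class Param:
    """One deck entry.

    ``dist`` is one of ``fixed``, ``lognormal``, ``beta``, ``gamma``.
    ``ci`` is the 95% interval the distribution is fitted to (``None`` for
    fixed quantities).  ``group`` assigns the parameter to a VOI subset.
    ``provenance`` records where the number came from; anything not read off
    a published pooled-estimate table is tagged ``placeholder_not_from_paper``.
    """

    name: str
    value: float
    dist: str = "fixed"
    ci: tuple[float, float] | None = None
    group: str = ""
    provenance: str = "placeholder_not_from_paper"

    @property
    def sampled(self) -> bool:
        if self.dist == "fixed" or self.ci is None:
            return False
        lo, hi = self.ci
        return hi > lo

    def fit(self) -> tuple[str, tuple[float, ...]]:
        """Method-of-moments fit of the distribution family to (value, ci).

        Returns ("fixed", ()) for degenerate entries, otherwise the family
        name with its parameters:
          lognormal -> (mu, sigma) of log
          beta      -> (a, b)
          gamma     -> (shape, scale)
        """
        if not self.sampled:
            return "fixed", ()
        lo, hi = self.ci  # type: ignore[misc]
        if self.dist == "lognormal":
            if lo <= 0 or self.value <= 0:
                raise DeckValidationError(f"{self.name}: lognormal needs positive value/CI")
            mu = math.log(self.value)
            sigma = (math.log(hi) - math.log(lo)) / (2 * _Z95)
            return "lognormal", (mu, sigma)
        if self.dist == "beta":
            m = self.value
            if not (0.0 < m < 1.0) or lo < 0 or hi > 1:
                raise DeckValidationError(
                    f"{self.name}: beta mean/CI must lie inside [0, 1], got "
                    f"{m} ({lo}, {hi})"
                )
            sd = (hi - lo) / (2 * _Z95)
            if sd**2 >= m * (1 - m):
                raise DeckValidationError(f"{self.name}: CI too wide for a Beta fit")
            k = m * (1 - m) / sd**2 - 1.0
            return "beta", (m * k, (1 - m) * k)
        if self.dist == "gamma":
            if self.value <= 0 or lo <= 0:
                raise DeckValidationError(f"{self.name}: gamma needs positive value/CI")
            sd = (hi - lo) / (2 * _Z95)
            shape = (self.value / sd) ** 2
            return "gamma", (shape, sd**2 / self.value)
        raise DeckValidationError(f"{self.name}: unknown distribution {self.dist!r}")


@dataclass
class InputDeck:
    """Complete parameterisation of the decision model.

    ``params`` maps hierarchical names to :class:`Param`:

    - ``rate.<arm>.<outcome>``  annual event rates in %/year
    - ``early.<arm>.death|stroke|bleed``  cycle-0 probabilities
    - ``cond.<name>``  conditional cascade probabilities
    - ``cost.procedure.<arm>``, ``cost.event.<name>``  one-off costs (GBP)
    - ``cost.state.poststroke_disabled_annual``  annual state cost (GBP)
    - ``util.state.<state>``, ``disutil.event.<name>``  utility weights
    """

    params: dict[str, Param]
    mixture_weight_bio: float = 0.23
    discount_rate: float = 0.035
    start_age: float = 44.5
    horizon: int = 55  # last cycle index; 56 annual cycles t = 0..55
    wtp_grid: list[float] = field(
        default_factory=lambda: [float(w) for w in range(0, 100_001, 500)]
    )
    deck_version: int = DECK_VERSION
    metadata: dict = field(default_factory=dict)

    # -- access helpers ----------------------------------------------------
    def value(self, name: str) -> float:
        return self.params[name].value

    def values(self) -> dict[str, float]:
        """Point-estimate parameter vector (the deterministic base case)."""
        return {name: p.value for name, p in self.params.items()}

    def sampled_names(self) -> list[str]:
        return [name for name, p in self.params.items() if p.sampled]

    def fixed_names(self) -> list[str]:
        return [name for name, p in self.params.items() if not p.sampled]

    def subset_names(self, subset: str) -> list[str]:
        """Resolve a named VOI parameter subset to sampled parameter names."""
        if subset == "all":
            return self.sampled_names()
        if subset == "ross_trial_all_epi":
            groups = {"meta_analysis", "early_bleed_stroke", "other_epidemiological"}
        elif subset in VOI_SUBSETS:
            groups = {subset}
        else:
            raise KeyError(
                f"unknown parameter subset {subset!r}; valid names: {VOI_SUBSETS}"
            )
        return [n for n, p in self.params.items() if p.sampled and p.group in groups]

    def with_value(self, name: str, value: float) -> "InputDeck":
        """A copy of the deck with one parameter's point estimate replaced."""
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}")
        params = dict(self.params)
        params[name] = replace(params[name], value=value)
        out = InputDeck(
            params=params,
            mixture_weight_bio=self.mixture_weight_bio,
            discount_rate=self.discount_rate,
            start_age=self.start_age,
            horizon=self.horizon,
            wtp_grid=list(self.wtp_grid),
            deck_version=self.deck_version,
            metadata=dict(self.metadata),
        )
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not (0.0 <= self.mixture_weight_bio <= 1.0):
            raise DeckValidationError("mixture_weight_bio must lie in [0, 1]")
        if self.discount_rate < 0:
            raise DeckValidationError("discount_rate must be >= 0")
        if self.horizon < 0:
            raise DeckValidationError("horizon must be >= 0")
        for name, p in self.params.items():
            if p.name != name:
                raise DeckValidationError(f"param key {name!r} != param name {p.name!r}")
            head = name.split(".", 1)[0]
            if head in ("early", "cond", "util", "disutil"):
                if not (0.0 <= p.value <= 1.0):
                    raise DeckValidationError(f"{name}: probability/utility outside [0, 1]")
            elif head == "rate":
                if p.value < 0:
                    raise DeckValidationError(f"{name}: rate must be >= 0")
            elif head == "cost":
                if p.value < 0:
                    raise DeckValidationError(f"{name}: cost must be >= 0")
            else:
                raise DeckValidationError(f"{name}: unknown parameter family {head!r}")
            if p.sampled:
                p.fit()  # raises on inconsistent CI/support
        # the engine needs every rate outcome for every arm
        for arm in ARMS:
            missing = [
                o
                for o in MODEL_RATE_OUTCOMES
                if f"rate.{arm}.{o}" not in self.params
                and not (o == "rvot_reintervention" and arm != "ross")
            ]
            if missing:
                raise DeckValidationError(f"arm {arm!r} missing rates: {missing}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "deck_version": self.deck_version,
            "mixture_weight_bio": self.mixture_weight_bio,
            "discount_rate": self.discount_rate,
            "start_age": self.start_age,
            "horizon": self.horizon,
            "wtp_grid": list(self.wtp_grid),
            "metadata": dict(self.metadata),
            "params": {
                name: {
                    "value": p.value,
                    "dist": p.dist,
                    "ci": list(p.ci) if p.ci is not None else None,
                    "group": p.group,
                    "provenance": p.provenance,
                }
                for name, p in self.params.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputDeck":
        version = d.get("deck_version")
        if version != DECK_VERSION:
            raise DeckValidationError(
                f"unsupported deck_version {version!r} (expected {DECK_VERSION})"
            )
        params = {
            name: Param(
                name=name,
                value=float(entry["value"]),
                dist=entry.get("dist", "fixed"),
                ci=tuple(entry["ci"]) if entry.get("ci") is not None else None,
                group=entry.get("group", ""),
                provenance=entry.get("provenance", "placeholder_not_from_paper"),
            )
            for name, entry in d["params"].items()
        }
        deck = cls(
            params=params,
            mixture_weight_bio=float(d["mixture_weight_bio"]),
            discount_rate=float(d["discount_rate"]),
            start_age=float(d["start_age"]),
            horizon=int(d["horizon"]),
            wtp_grid=[float(w) for w in d["wtp_grid"]],
            deck_version=int(version),
            metadata=dict(d.get("metadata", {})),
        )
        deck.validate()
        return deck

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "InputDeck":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sample_parameters(
    deck: InputDeck, rng: np.random.Generator, n: int = 1
) -> dict[str, np.ndarray]:
    """Draw ``n`` joint realisations of every sampled deck parameter.

    Fixed parameters are carried through unchanged (broadcast to length
    ``n``).  Parameters are sampled independently, in deterministic name
    order, so a given (seed, n) always yields the same draws.
    """
    out: dict[str, np.ndarray] = {}
    for name in deck.params:  # insertion order: stable across runs
        p = deck.params[name]
        family, args = p.fit()
        if family == "fixed":
            out[name] = np.full(n, p.value)
        elif family == "lognormal":
            mu, sigma = args
            out[name] = rng.lognormal(mu, sigma, size=n)
        elif family == "beta":
            a, b = args
            out[name] = rng.beta(a, b, size=n)
        elif family == "gamma":
            shape, scale = args
            out[name] = rng.gamma(shape, scale, size=n)
    return out
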