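"""Random-effects meta-analysis of study-level valve-replacement outcomes.

Pools annual event rates (events per person-year, reported as %/year) and
early-mortality proportions across published surgical cohorts, separately for
each treatment arm (Ross autograft, mechanical AVR, biological AVR), and
tests for between-arm differences.

Pooling is DerSimonian–Laird random effects on the log incidence-rate scale
(log-odds scale for proportions), the standard closed-form estimator for
sparse event-count outcomes.  Zero-event studies receive a 0.5 continuity
correction so every study contributes a finite log estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ARMS = ("ross", "mechAVR", "bioAVR")

#: outcomes measured against person-years at risk (reported as %/year)
RATE_OUTCOMES = (
    "late_death",
    "aov_reoperation",
    "bleeding",
    "thromboembolism",
    "aov_reop_ie",
    "conservative_ie",
    "total_ie",
    "rvot_reintervention",
)

#: outcomes measured against the number of procedures (reported as %)
PROPORTION_OUTCOMES = ("early_death",)

ALL_OUTCOMES = PROPORTION_OUTCOMES + RATE_OUTCOMES

_Z95 = 1.959963984540054


class NoDataError(ValueError):
    """Raised when no eligible study carries the requested outcome/arm."""


@dataclass(frozen=True)
class CohortStudy:
    """One arm of one published surgical cohort.

    ``events`` maps outcome names (see :data:`ALL_OUTCOMES`) to non-negative
    counts.  ``early_death`` is a per-procedure count (denominator
    ``n_patients``); every other outcome is a time-at-risk count
    (denominator ``person_years``).
    """

    study_id: str
    arm: str
    n_patients: int
    person_years: float
    events: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.person_years <= 0:
            raise ValueError("person_years must be positive")
        for outcome, count in self.events.items():
            if outcome not in ALL_OUTCOMES:
                raise ValueError(f"unknown outcome {outcome!r}")
            if count < 0:
                raise ValueError(f"negative event count for {outcome!r}")


@dataclass(frozen=True)
class PooledRate:
    """Random-effects pooled estimate for one arm and outcome.

    ``rate``/``ci_low``/``ci_high`` are on the reporting scale: %/year for
    time-at-risk outcomes, % for per-procedure proportions.  ``estimate`` and
    ``se`` are the pooled value and standard error on the transformed (log or
    logit) scale, retained for between-arm heterogeneity tests.
    """

    arm: str
    outcome: str
    rate: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int
    estimate: float
    se: float
    scale: str  # "log" (rates) or "logit" (proportions)
    continuity_corrected: bool = False


@dataclass(frozen=True)
class ArmComparison:
    """Between-arm heterogeneity test for one outcome."""

    outcome: str
    pooled: dict[str, PooledRate]
    q_between: float
    p_value: float


def _dersimonian_laird(y: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """DerSimonian–Laird pooled mean, its SE, and tau^2.

    Closed-form moment estimator: tau^2 = max(0, (Q - df) / c) with
    c = sum(w) - sum(w^2)/sum(w) under fixed-effect weights w = 1/v.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = y.size
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    if k == 1:
        return mu_fe, float(math.sqrt(v[0])), 0.0
    q = float(np.sum(w * (y - mu_fe) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(1.0 / math.sqrt(np.sum(w_re)))
    return mu, se, tau2


def _select(studies: list[CohortStudy], outcome: str, arm: str) -> list[CohortStudy]:
    chosen = [s for s in studies if s.arm == arm and outcome in s.events]
    if not chosen:
        raise NoDataError(f"no study records outcome {outcome!r} for arm {arm!r}")
    return chosen


def pool_rates(studies: list[CohortStudy], outcome: str, arm: str) -> PooledRate:
    """Pool a time-at-risk outcome into an annual rate in %/year.

    Study-level estimate is ln(events / person_years) with Poisson variance
    1/events; zero-event studies get events + 0.5.  The pooled log rate is
    back-transformed with a 95% CI of exp(estimate ± 1.96·se).
    """
    if outcome not in RATE_OUTCOMES:
        raise ValueError(f"{outcome!r} is not a time-at-risk outcome")
    chosen = _select(studies, outcome, arm)
    events = np.array([s.events[outcome] for s in chosen], dtype=float)
    py = np.array([s.person_years for s in chosen], dtype=float)
    corrected = bool(np.any(events == 0))
    if np.all(events == 0):
        warnings.warn(
            f"all {len(chosen)} studies have zero {outcome} events for {arm}; "
            "pooled rate rests entirely on the 0.5 continuity correction",
            stacklevel=2,
        )
    events = np.where(events == 0, 0.5, events)
    y = np.log(events / py)
    v = 1.0 / events
    mu, se, tau2 = _dersimonian_laird(y, v)
    return PooledRate(
        arm=arm,
        outcome=outcome,
        rate=100.0 * math.exp(mu),
        ci_low=100.0 * math.exp(mu - _Z95 * se),
        ci_high=100.0 * math.exp(mu + _Z95 * se),
        tau2=tau2,
        k=len(chosen),
        estimate=mu,
        se=se,
        scale="log",
        continuity_corrected=corrected,
    )


def pool_proportion(
    studies: list[CohortStudy], outcome: str = "early_death", arm: str = "ross"
) -> PooledRate:
    """Pool a per-procedure outcome (early mortality) into a % proportion.

    Logit-scale random-effects pooling with a 0.5 continuity correction
    applied to both cells of any study with an empty cell.  Study variances
    use expected counts under a common initial proportion (the total-event
    proportion), 1/(n·p0) + 1/(n·(1-p0)), rather than observed counts: for
    rare outcomes observed-count inverse-variance weights are proportional
    to the event count itself, which biases the pooled estimate upward by a
    factor of roughly (1 + 1/E[events per study]).
    """
    if outcome not in PROPORTION_OUTCOMES:
        raise ValueError(f"{outcome!r} is not a per-procedure outcome")
    chosen = _select(studies, outcome, arm)
    events = np.array([s.events[outcome] for s in chosen], dtype=float)
    n = np.array([s.n_patients for s in chosen], dtype=float)
    corrected = bool(np.any((events == 0) | (events == n)))
    if np.all(events == 0):
        warnings.warn(
            f"all {len(chosen)} studies have zero {outcome} events for {arm}; "
            "pooled proportion rests entirely on the 0.5 continuity correction",
            stacklevel=2,
        )
    n_total = float(np.sum(n))
    p0 = float(np.clip(np.sum(events) / n_total, 0.5 / n_total, 1.0 - 0.5 / n_total))
    empty = (events == 0) | (events == n)
    events = np.where(empty, events + 0.5, events)
    n_adj = np.where(empty, n + 1.0, n)
    y = np.log(events / (n_adj - events))
    v = 1.0 / (n * p0) + 1.0 / (n * (1.0 - p0))
    mu, se, tau2 = _dersimonian_laird(y, v)
    expit = lambda x: 1.0 / (1.0 + math.exp(-x))  # noqa: E731
    return PooledRate(
        arm=arm,
        outcome=outcome,
        rate=100.0 * expit(mu),
        ci_low=100.0 * expit(mu - _Z95 * se),
        ci_high=100.0 * expit(mu + _Z95 * se),
        tau2=tau2,
        k=len(chosen),
        estimate=mu,
        se=se,
        scale="logit",
        continuity_corrected=corrected,
    )


def compare_arms(pooled: dict[str, PooledRate], outcome: str) -> ArmComparison:
    """Between-arm subgroup heterogeneity Q test on pooled transformed estimates.

    Q_between = sum_a w_a (est_a - est_bar)^2 with w_a = 1/se_a^2, referred
    to a chi-square with (#arms - 1) degrees of freedom.
    """
    relevant = {a: p for a, p in pooled.items() if p.outcome == outcome}
    if len(relevant) < 2:
        raise ValueError(f"need >=2 pooled arms for {outcome!r}, got {len(relevant)}")
    scales = {p.scale for p in relevant.values()}
    if len(scales) > 1:
        raise ValueError("cannot compare arms pooled on different scales")
    est = np.array([p.estimate for p in relevant.values()])
    w = np.array([1.0 / p.se**2 for p in relevant.values()])
    mean = np.sum(w * est) / np.sum(w)
    q = float(np.sum(w * (est - mean) ** 2))
    p_value = float(stats.chi2.sf(q, df=len(relevant) - 1))
    return ArmComparison(outcome=outcome, pooled=relevant, q_between=q, p_value=p_value)


def rate_to_probability(rate: float | np.ndarray, t: float = 1.0) -> float | np.ndarray:
    """Convert an annual event rate in %/year to a probability over ``t`` years.

    Assumes a constant hazard within the interval: p = 1 - exp(-(rate/100)·t).
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    if t <= 0:
        raise ValueError("t must be positive")
    p = -np.expm1(-(rate / 100.0) * t)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# delimited-table interface

_CSV_META_COLS = ("study_id", "arm", "n_patients", "person_years")


def read_cohort_csv(path) -> list[CohortStudy]:
    """Read a cohort table (one row per study arm, one column per outcome count).

    Missing/empty outcome cells mean "not recorded" and are omitted from the
    study's events map (the outcome does not contribute to pooling).
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    outcome_cols = [c for c in df.columns if c in ALL_OUTCOMES]
    studies = []
    for _, row in df.iterrows():
        events = {
            c: int(row[c]) for c in outcome_cols if pd.notna(row[c])
        }
        studies.append(
            CohortStudy(
                study_id=str(row["study_id"]),
                arm=str(row["arm"]),
                n_patients=int(row["n_patients"]),
                person_years=float(row["person_years"]),
                events=events,
            )
        )
    return studies


def write_cohort_csv(studies: list[CohortStudy], path) -> pd.DataFrame:
    rows = []
    for s in studies:
        row = {
            "study_id": s.study_id,
            "arm": s.arm,
            "n_patients": s.n_patients,
            "person_years": s.person_years,
        }
        row.update(s.events)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def pooled_table(
    studies: list[CohortStudy],
    outcomes: tuple[str, ...] = ALL_OUTCOMES,
    arms: tuple[str, ...] = ARMS,
) -> pd.DataFrame:
    """Pool every outcome for every arm and lay the result out as a summary
    table (one row per outcome, one rate column per arm, between-arm p value).
    """
    rows = []
    for outcome in outcomes:
        pooled: dict[str, PooledRate] = {}
        for arm in arms:
            try:
                if outcome in PROPORTION_OUTCOMES:
                    pooled[arm] = pool_proportion(studies, outcome, arm)
                else:
                    pooled[arm] = pool_rates(studies, outcome, arm)
            except NoDataError:
                continue
        if not pooled:
            continue
        row: dict[str, object] = {
            "outcome": outcome,
            "unit": "%" if outcome in PROPORTION_OUTCOMES else "%/year",
            "k": max(p.k for p in pooled.values()),
        }
        for arm, p in pooled.items():
            row[f"{arm}_rate"] = p.rate
            row[f"{arm}_ci_low"] = p.ci_low
            row[f"{arm}_ci_high"] = p.ci_high
        if len(pooled) >= 2:
            row["p_value"] = compare_arms(pooled, outcome).p_value
        rows.append(row)
    return pd.DataFrame(rows)
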