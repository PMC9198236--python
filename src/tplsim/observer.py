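"""Parametric 2IFC duration-discrimination observers.

The generative model of a simulated participant follows scalar timing: the
internal representation of a physical duration ``t`` is Gaussian with mean
``t`` and standard deviation ``w * t``, where ``w`` is a dimensionless
internal noise coefficient — numerically on the scale of the Weber fraction
the staircase procedure estimates. On each two-interval forced-choice (2IFC)
trial the observer draws one percept per interval and reports the interval
with the larger percept; with probability ``lapse_rate`` it instead guesses
uniformly at random.

Training is modelled as an exponential decay of ``w`` toward an asymptote
over sessions, applied only to the conditions a group is configured to
improve on (trained condition plus same-duration cross-format transfer for
the empty-interval group; no condition for the filled-interval group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CONDITIONS",
    "GROUPS",
    "TRAINED_CONDITION",
    "IMPROVING_CONDITIONS",
    "Condition",
    "ConfigurationError",
    "LearningParams",
    "ObserverParams",
    "percept_sample",
    "respond_2ifc",
    "wf_trajectory",
    "prob_correct_2ifc",
    "delta_at_accuracy",
    "make_cohort",
]

#: A condition is (stimulus format, standard interval in ms).
Condition = tuple[str, int]

CONDITIONS: tuple[Condition, ...] = (
    ("empty", 200),
    ("empty", 400),
    ("filled", 200),
    ("filled", 400),
)
GROUPS = ("EI", "FI")

#: Condition each group trains on.
TRAINED_CONDITION: dict[str, Condition] = {
    "EI": ("empty", 200),
    "FI": ("filled", 200),
}

#: Conditions whose internal noise decays with training, per group. The EI
#: group improves on its trained condition and transfers to the filled
#: interval of the same duration; the FI group stays flat everywhere.
IMPROVING_CONDITIONS: dict[str, tuple[Condition, ...]] = {
    "EI": (("empty", 200), ("filled", 200)),
    "FI": (),
}


class ConfigurationError(ValueError):
    """An observer or experiment is mis-configured (unknown group/condition)."""


@dataclass(frozen=True)
class LearningParams:
    """Session-wise trajectory of one condition's internal noise coefficient.

    ``w(s) = wf_asymptote + (wf_start - wf_asymptote) * exp(-s / tau_sessions)``
    for improving conditions; a flat condition simply has
    ``wf_asymptote == wf_start``.
    """

    wf_start: float
    wf_asymptote: float
    tau_sessions: float

    def __post_init__(self) -> None:
        if not (self.wf_start > 0 and self.wf_asymptote > 0):
            raise ValueError("noise coefficients must be strictly positive")
        if self.wf_asymptote > self.wf_start:
            raise ValueError("wf_asymptote must not exceed wf_start")
        if self.tau_sessions < 0:
            raise ValueError("tau_sessions must be non-negative")

    @classmethod
    def flat(cls, wf: float) -> "LearningParams":
        return cls(wf_start=wf, wf_asymptote=wf, tau_sessions=1.0)


@dataclass(frozen=True)
class ObserverParams:
    """One simulated participant: per-condition noise trajectories and lapses."""

    participant: str
    group: str
    learning: Mapping[Condition, LearningParams]
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5]")
        if not self.learning:
            raise ConfigurationError("observer has no configured conditions")

    def noise_at(self, condition: Condition, session_index: int) -> float:
        return wf_trajectory(self, session_index, condition)


def wf_trajectory(
    observer: ObserverParams, session_index: int, condition: Condition
) -> float:
    """Effective internal noise coefficient at a given session.

    ``session_index`` counts elapsed training: 0 at the pre-test, ``k`` during
    training session ``k`` and 5 at the post-test (day 5). Non-increasing in
    ``session_index`` by construction.
    """
    if session_index < 0:
        raise ValueError("session_index must be >= 0")
    try:
        lp = observer.learning[condition]
    except KeyError:
        raise ConfigurationError(
            f"condition {condition!r} not configured for observer "
            f"{observer.participant!r}"
        ) from None
    if lp.tau_sessions == 0:
        return lp.wf_start if session_index == 0 else lp.wf_asymptote
    decay = math.exp(-session_index / lp.tau_sessions)
    return lp.wf_asymptote + (lp.wf_start - lp.wf_asymptote) * decay


def percept_sample(
    duration: float, noise_coeff: float, rng: np.random.Generator
) -> float:
    """Draw a perceived duration: N(duration, (noise_coeff*duration)^2), truncated at 0.

    Non-positive draws are resampled, keeping the support physical; for any
    realistic ``noise_coeff`` (< ~0.3) the truncated mass is negligible, so
    mean and SD retain the scalar property to high accuracy.
    """
    if duration <= 0 or noise_coeff <= 0:
        raise ValueError("duration and noise_coeff must be strictly positive")
    sd = noise_coeff * duration
    while True:
        draw = rng.normal(duration, sd)
        if draw > 0:
            return draw


def respond_2ifc(
    t1: float,
    t2: float,
    observer: ObserverParams,
    condition: Condition,
    rng: np.random.Generator,
    session_index: int = 0,
) -> tuple[str, bool]:
    """Simulate one 2IFC trial: which of two sequential intervals was longer?

    Returns ``(choice, correct)`` with ``choice`` in {"first", "second"}.
    When ``t1 == t2`` no physically longer interval exists; correctness is
    then assigned at random with p = 0.5 (degenerate-input guard — the
    staircase never presents exact ties while its Δt floor is positive).
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("interval durations must be strictly positive")
    w = wf_trajectory(observer, session_index, condition)
    if observer.lapse_rate > 0 and rng.random() < observer.lapse_rate:
        choice = "first" if rng.random() < 0.5 else "second"
    else:
        p1 = percept_sample(t1, w, rng)
        p2 = percept_sample(t2, w, rng)
        choice = "first" if p1 > p2 else "second"
    if t1 == t2:
        correct = bool(rng.random() < 0.5)
    else:
        longer = "first" if t1 > t2 else "second"
        correct = choice == longer
    return choice, correct


def prob_correct_2ifc(
    delta: float, standard_T: float, noise_coeff: float, lapse_rate: float = 0.0
) -> float:
    """Closed-form probability of a correct 2IFC response at comparison offset Δt.

    Under independent Gaussian percepts with SDs ``w*T`` and ``w*(T+Δt)`` the
    percept difference is Gaussian, giving

        P(correct) = Φ( Δt / (w * sqrt(T² + (T+Δt)²)) ),

    mixed with chance at the lapse rate. Truncation of the percepts at zero
    is ignored here; its mass is O(Φ(-1/w)), negligible for w < 0.3.
    """
    if standard_T <= 0 or noise_coeff <= 0:
        raise ValueError("standard_T and noise_coeff must be strictly positive")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    sd = noise_coeff * math.hypot(standard_T, standard_T + delta)
    p = 0.5 * (1.0 + math.erf(delta / sd / math.sqrt(2.0)))
    return lapse_rate * 0.5 + (1.0 - lapse_rate) * p


def delta_at_accuracy(
    p_target: float, standard_T: float, noise_coeff: float, lapse_rate: float = 0.0
) -> float:
    """Invert the 2IFC psychometric function: the Δt with P(correct) = p_target.

    ``p_target`` must lie strictly between the chance-mixed floor and ceiling.
    """
    lo = lapse_rate * 0.5 + (1.0 - lapse_rate) * 0.5
    hi = lapse_rate * 0.5 + (1.0 - lapse_rate) * 1.0
    if not lo < p_target < hi:
        raise ValueError(f"p_target must lie in ({lo}, {hi})")
    f = lambda d: prob_correct_2ifc(d, standard_T, noise_coeff, lapse_rate) - p_target
    upper = standard_T
    while f(upper) < 0:
        upper *= 2.0
        if upper > 1e6 * standard_T:  # pragma: no cover - unreachable for valid p
            raise RuntimeError("failed to bracket the target accuracy")
    return brentq(f, 1e-12, upper)


def make_cohort(
    group: str,
    n: int,
    seed: int | np.random.SeedSequence,
    *,
    wf_start: float = 0.20,
    wf_asymptote: float = 0.13,
    tau_sessions: float = 1.5,
    lapse_rate: float = 0.02,
    jitter_cv: float = 0.10,
) -> list[ObserverParams]:
    """Generate ``n`` observers of one group with inter-individual jitter.

    Each observer's baseline noise coefficient is the group default scaled by
    a lognormal factor with coefficient of variation ``jitter_cv`` (one factor
    per observer, plus an independent 5%-CV per-condition factor). Improving
    conditions keep the default start:asymptote ratio so every jittered
    observer has the same fractional learning capacity.
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    improve = set(IMPROVING_CONDITIONS[group])
    ratio = wf_asymptote / wf_start

    def _lognormal(cv: float) -> float:
        if cv <= 0:
            return 1.0
        sigma = math.sqrt(math.log1p(cv * cv))
        return float(rng.lognormal(-0.5 * sigma * sigma, sigma))

    cohort = []
    for i in range(n):
        person = _lognormal(jitter_cv)
        learning: dict[Condition, LearningParams] = {}
        for cond in CONDITIONS:
            start = wf_start * person * _lognormal(0.05)
            if cond in improve:
                learning[cond] = LearningParams(start, start * ratio, tau_sessions)
            else:
                learning[cond] = LearningParams.flat(start)
        cohort.append(
            ObserverParams(
                participant=f"{group}{i + 1:02d}",
                group=group,
                learning=learning,
                lapse_rate=lapse_rate,
            )
        )
    return cohort
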