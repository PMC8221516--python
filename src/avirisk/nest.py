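"""Markov-chain breeding-season nest productivity model.

Each female progresses daily through nesting phases (laying, incubation,
nestling) inside a nest-initiation window.  Every active-nest day the
nest survives natural causes with probability ``daily_nest_survival``
and fails outright if the day's dietary pesticide concentration exceeds
the active phase's NOAEL (whole-nest failure; no per-egg effects).
Females renest after a fixed wait whenever the initiation window is
still open, and fledge ``clutch_size * prop_female`` female offspring
per successful brood.

Two evaluation routes are provided and must agree: a per-female Monte
Carlo simulation (:func:`simulate_season`) and an exact expectation by
forward propagation of the day-by-day state distribution
(:func:`enumerate_season_exact`).  Lognormal daily residue noise (the
exposure model's dietary stochasticity) is integrated analytically in
the exact route via the per-day exceedance probability
``Phi(log10(C_median / NOAEL) / sigma)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "Phase",
    "BreedingParams",
    "PhaseNOAELs",
    "FemaleState",
    "SeasonOutcome",
    "step_female_day",
    "simulate_season",
    "enumerate_season_exact",
    "calibrate_fixture",
]


class Phase(enum.Enum):
    WAITING = "waiting"
    LAYING = "laying"
    INCUBATING = "incubating"
    NESTLING = "nestling"
    WAIT_FAIL = "wait_fail"
    WAIT_SUCCESS = "wait_success"
    DONE = "done"


_ACTIVE = (Phase.LAYING, Phase.INCUBATING, Phase.NESTLING)


@dataclass(frozen=True)
class BreedingParams:
    """Species breeding-season parameters (all durations in days).

    ``season_start``/``season_end`` bound the nest-initiation window
    (days-of-year); nests started inside the window are allowed to run
    to completion beyond it.
    """

    season_start: int = 84
    season_end: int = 196
    laying_days: int = 4
    incubation_days: int = 14
    nestling_days: int = 16
    clutch_size: int = 4
    prop_female: float = 0.5
    daily_nest_survival: float = 0.98
    wait_after_failure: int = 3
    wait_after_success: int = 21
    nest_initiation_prob: float = 1.0

    def __post_init__(self) -> None:
        for name in ("laying_days", "incubation_days", "nestling_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("daily_nest_survival", "prop_female", "nest_initiation_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.season_end < self.season_start:
            raise ValueError("season_end before season_start")

    @property
    def cycle_days(self) -> int:
        """Hazard-exposed days per nesting attempt (laying + incubation + nestling)."""
        return self.laying_days + self.incubation_days + self.nestling_days

    @property
    def brood_fecundity(self) -> float:
        """Female offspring fledged per successful brood."""
        return self.clutch_size * self.prop_female

    def horizon(self) -> int:
        """Last simulation day: latest possible fledge of a window-initiated nest."""
        return self.season_end + self.cycle_days + 1


@dataclass(frozen=True)
class PhaseNOAELs:
    """Phase-specific no-adverse-effect dietary concentrations (mg a.i./kg diet)."""

    laying: float
    incubation: float
    nestling: float

    def __post_init__(self) -> None:
        if min(self.laying, self.incubation, self.nestling) <= 0:
            raise ValueError("NOAELs must be positive")

    @classmethod
    def uniform(cls, value: float) -> "PhaseNOAELs":
        return cls(laying=value, incubation=value, nestling=value)

    def for_phase(self, phase: Phase) -> float:
        return {
            Phase.LAYING: self.laying,
            Phase.INCUBATING: self.incubation,
            Phase.NESTLING: self.nestling,
        }[phase]


@dataclass(frozen=True)
class FemaleState:
    """One female's position in the breeding-season state machine."""

    day: int
    phase: Phase = Phase.WAITING
    days_in_phase: int = 0
    broods: int = 0
    natural_failures: int = 0
    pesticide_failures: int = 0


@dataclass(frozen=True)
class SeasonOutcome:
    """Season summary (per female, or Monte Carlo mean over females)."""

    successful_broods: float
    fecundity: float
    natural_failures: float
    pesticide_failures: float


def step_female_day(
    state: FemaleState,
    params: BreedingParams,
    dose_today: float,
    noaels: PhaseNOAELs,
    rng: np.random.Generator | None = None,
) -> FemaleState:
    """Advance one female by one day.

    Active-nest days: pesticide exceedance (dose_today > phase NOAEL)
    forces whole-nest failure; otherwise the nest survives natural
    causes with probability ``daily_nest_survival``; surviving the final
    nestling day fledges the brood.  Waiting phases count down fixed
    waits; a female that is available inside the initiation window
    necessarily (re)nests with the daily initiation probability, and is
    done for the season once the window closes.
    """
    phase, t, day = state.phase, state.days_in_phase, state.day
    nxt = dict(day=day + 1)
    if phase is Phase.DONE:
        return replace(state, **nxt)

    if phase in _ACTIVE:
        if dose_today > noaels.for_phase(phase):
            return replace(
                state,
                phase=Phase.WAIT_FAIL,
                days_in_phase=0,
                pesticide_failures=state.pesticide_failures + 1,
                **nxt,
            )
        survives = (
            params.daily_nest_survival >= 1.0
            or (rng is not None and rng.random() < params.daily_nest_survival)
        )
        if not survives:
            return replace(
                state,
                phase=Phase.WAIT_FAIL,
                days_in_phase=0,
                natural_failures=state.natural_failures + 1,
                **nxt,
            )
        t += 1
        if phase is Phase.LAYING and t >= params.laying_days:
            return replace(state, phase=Phase.INCUBATING, days_in_phase=0, **nxt)
        if phase is Phase.INCUBATING and t >= params.incubation_days:
            return replace(state, phase=Phase.NESTLING, days_in_phase=0, **nxt)
        if phase is Phase.NESTLING and t >= params.nestling_days:
            return replace(
                state,
                phase=Phase.WAIT_SUCCESS,
                days_in_phase=0,
                broods=state.broods + 1,
                **nxt,
            )
        return replace(state, days_in_phase=t, **nxt)

    if phase in (Phase.WAIT_FAIL, Phase.WAIT_SUCCESS):
        t += 1
        wait = (
            params.wait_after_failure
            if phase is Phase.WAIT_FAIL
            else params.wait_after_success
        )
        if t >= wait:
            return replace(state, phase=Phase.WAITING, days_in_phase=0, **nxt)
        return replace(state, days_in_phase=t, **nxt)

    if phase is Phase.WAITING:
        if day > params.season_end:
            return replace(state, phase=Phase.DONE, days_in_phase=0, **nxt)
        if day >= params.season_start:
            initiates = params.nest_initiation_prob >= 1.0 or (
                rng is not None and rng.random() < params.nest_initiation_prob
            )
            if initiates:
                return replace(state, phase=Phase.LAYING, days_in_phase=0, **nxt)
        return replace(state, **nxt)

    raise ValueError(f"unknown phase {phase!r}")


def _dose_at(dose_series: np.ndarray, day: int) -> float:
    return float(dose_series[day]) if 0 <= day < len(dose_series) else 0.0


def simulate_season(
    params: BreedingParams,
    dose_series: np.ndarray,
    noaels: PhaseNOAELs,
    n_females: int = 1000,
    rng: np.random.Generator | None = None,
    residue_sigma_log10: float = 0.0,
    death_day: int | None = None,
) -> SeasonOutcome:
    """Monte Carlo mean season outcome over ``n_females`` independent females.

    ``dose_series`` is the median daily dietary concentration indexed by
    day-of-year; with ``residue_sigma_log10 > 0`` each female-day draws
    an independent median-1 lognormal residue multiplier.  An optional
    ``death_day`` (acute mortality from the exposure model) discards
    broods fledged after that day.
    """
    if n_females < 1:
        raise ValueError("n_females must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    dose_series = np.asarray(dose_series, dtype=float)
    horizon = params.horizon()
    tot = np.zeros(3)  # broods, natural failures, pesticide failures
    for _ in range(n_females):
        state = FemaleState(day=params.season_start)
        while state.phase is not Phase.DONE and state.day <= horizon:
            dose = _dose_at(dose_series, state.day)
            if residue_sigma_log10 > 0.0 and dose > 0.0:
                dose *= 10.0 ** (residue_sigma_log10 * rng.standard_normal())
            prev_broods = state.broods
            state = step_female_day(state, params, dose, noaels, rng)
            if (
                death_day is not None
                and state.broods > prev_broods
                and state.day - 1 > death_day
            ):
                state = replace(state, broods=prev_broods)
        tot += (state.broods, state.natural_failures, state.pesticide_failures)
    broods, nat, pest = tot / n_females
    return SeasonOutcome(
        successful_broods=broods,
        fecundity=broods * params.brood_fecundity,
        natural_failures=nat,
        pesticide_failures=pest,
    )


def _exceedance_prob(
    conc: float, noael: float, sigma_log10: float
) -> float:
    """P(daily concentration exceeds the NOAEL) under median-1 lognormal noise."""
    if conc <= 0.0:
        return 0.0
    if sigma_log10 <= 0.0:
        return 1.0 if conc > noael else 0.0
    return float(norm.cdf(np.log10(conc / noael) / sigma_log10))


def enumerate_season_exact(
    params: BreedingParams,
    dose_series: np.ndarray,
    noaels: PhaseNOAELs,
    residue_sigma_log10: float = 0.0,
) -> SeasonOutcome:
    """Exact expected season outcome by dynamic programming.

    Propagates the full probability distribution over machine states
    (phase, days-in-phase) day by day, accumulating the expected number
    of fledged broods and of natural/pesticide failures.  The Monte
    Carlo estimate of :func:`simulate_season` converges to this value.
    """
    dose_series = np.asarray(dose_series, dtype=float)
    s = params.daily_nest_survival
    ip = params.nest_initiation_prob

    # state indexing
    states: list[tuple[Phase, int]] = [(Phase.WAITING, 0)]
    for ph, n in (
        (Phase.LAYING, params.laying_days),
        (Phase.INCUBATING, params.incubation_days),
        (Phase.NESTLING, params.nestling_days),
        (Phase.WAIT_FAIL, params.wait_after_failure),
        (Phase.WAIT_SUCCESS, params.wait_after_success),
    ):
        states += [(ph, t) for t in range(n)]
    states.append((Phase.DONE, 0))
    idx = {st: i for i, st in enumerate(states)}
    n_states = len(states)

    def advance(ph: Phase, t: int) -> tuple[Phase, int]:
        # surviving active day or completing one waiting day
        t += 1
        if ph is Phase.LAYING:
            return (Phase.INCUBATING, 0) if t >= params.laying_days else (ph, t)
        if ph is Phase.INCUBATING:
            return (Phase.NESTLING, 0) if t >= params.incubation_days else (ph, t)
        if ph is Phase.NESTLING:
            return (Phase.WAIT_SUCCESS, 0) if t >= params.nestling_days else (ph, t)
        if ph is Phase.WAIT_FAIL:
            return (Phase.WAITING, 0) if t >= params.wait_after_failure else (ph, t)
        if ph is Phase.WAIT_SUCCESS:
            return (Phase.WAITING, 0) if t >= params.wait_after_success else (ph, t)
        raise AssertionError(ph)

    prob = np.zeros(n_states)
    prob[idx[(Phase.WAITING, 0)]] = 1.0
    e_broods = e_nat = e_pest = 0.0

    for day in range(params.season_start, params.horizon() + 1):
        conc = _dose_at(dose_series, day)
        new = np.zeros(n_states)
        for i, (ph, t) in enumerate(states):
            p = prob[i]
            if p == 0.0:
                continue
            if ph is Phase.DONE:
                new[i] += p
            elif ph in _ACTIVE:
                p_pest = _exceedance_prob(conc, noaels.for_phase(ph), residue_sigma_log10)
                e_pest += p * p_pest
                e_nat += p * (1.0 - p_pest) * (1.0 - s)
                new[idx[(Phase.WAIT_FAIL, 0)]] += p * (p_pest + (1.0 - p_pest) * (1.0 - s))
                p_surv = p * (1.0 - p_pest) * s
                nxt = advance(ph, t)
                if nxt == (Phase.WAIT_SUCCESS, 0):
                    e_broods += p_surv
                new[idx[nxt]] += p_surv
            elif ph in (Phase.WAIT_FAIL, Phase.WAIT_SUCCESS):
                new[idx[advance(ph, t)]] += p
            else:  # WAITING
                if day > params.season_end:
                    new[idx[(Phase.DONE, 0)]] += p
                elif day >= params.season_start:
                    new[idx[(Phase.LAYING, 0)]] += p * ip
                    new[i] += p * (1.0 - ip)
                else:
                    new[i] += p
        prob = new

    return SeasonOutcome(
        successful_broods=e_broods,
        fecundity=e_broods * params.brood_fecundity,
        natural_failures=e_nat,
        pesticide_failures=e_pest,
    )


def calibrate_fixture(
    params: BreedingParams,
    target_fecundity: float,
    tol: float = 1e-4,
) -> float:
    """Daily nest survival at which unexposed seasonal fecundity hits the target.

    Bisection on ``daily_nest_survival`` in [0, 1] against the exact
    enumeration with zero exposure; raises if the target exceeds the
    maximum achievable fecundity (daily survival 1).
    """
    if target_fecundity < 0:
        raise ValueError("target fecundity must be non-negative")
    zero_dose = np.zeros(params.horizon() + 2)
    noaels = PhaseNOAELs.uniform(1.0)

    def fec(dns: float) -> float:
        p = replace(params, daily_nest_survival=dns)
        return enumerate_season_exact(p, zero_dose, noaels).fecundity

    if target_fecundity == 0.0:
        return 0.0
    f_max = fec(1.0)
    if target_fecundity > f_max + tol:
        raise ValueError(
            f"target fecundity {target_fecundity} exceeds maximum achievable {f_max:.4f}"
        )
    lo, hi = 0.0, 1.0
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        val = fec(mid)
        if abs(val - target_fecundity) <= tol:
            return mid
        if val < target_fecundity:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
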