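"""Nest productivity chain: state machine, exact enumeration, Monte Carlo
agreement, and fixture calibration."""

from dataclasses import replace

import numpy as np
import pytest

from avirisk.nest import (
    BreedingParams,
    FemaleState,
    Phase,
    PhaseNOAELs,
    calibrate_fixture,
    enumerate_season_exact,
    simulate_season,
    step_female_day,
)

TOY = BreedingParams(
    season_start=1,
    season_end=10,
    laying_days=1,
    incubation_days=2,
    nestling_days=1,
    clutch_size=2,
    prop_female=0.5,
    daily_nest_survival=0.8,
    wait_after_failure=1,
    wait_after_success=2,
    nest_initiation_prob=1.0,
)
NOAELS = PhaseNOAELs.uniform(4.62)


def brute_force_expected_broods(params, dose_series, noaels):
    """Independent oracle: recursive expectation over every fate sequence.

    Walks the season day by day, branching on nest survival; pesticide
    exceedance is deterministic given the dose series.
    """
    horizon = params.season_end + params.cycle_days + 1
    phase_days = {
        "laying": params.laying_days,
        "incubation": params.incubation_days,
        "nestling": params.nestling_days,
    }
    order = ["laying", "incubation", "nestling"]
    noael_of = {
        "laying": noaels.laying,
        "incubation": noaels.incubation,
        "nestling": noaels.nestling,
    }

    def dose(day):
        return dose_series[day] if 0 <= day < len(dose_series) else 0.0

    def go(day, mode, t):
        if day > horizon:
            return 0.0
        if mode == "done":
            return 0.0
        if mode in order:
            if dose(day) > noael_of[mode]:
                return go(day + 1, "wait_fail", 0)
            s = params.daily_nest_survival
            fail = (1 - s) * go(day + 1, "wait_fail", 0)
            t2 = t + 1
            if t2 >= phase_days[mode]:
                i = order.index(mode)
                if i == 2:
                    return fail + s * (1.0 + go(day + 1, "wait_success", 0))
                return fail + s * go(day + 1, order[i + 1], 0)
            return fail + s * go(day + 1, mode, t2)
        if mode in ("wait_fail", "wait_success"):
            wait = (
                params.wait_after_failure
                if mode == "wait_fail"
                else params.wait_after_success
            )
            if t + 1 >= wait:
                return go(day + 1, "waiting", 0)
            return go(day + 1, mode, t + 1)
        # waiting
        if day > params.season_end:
            return 0.0
        if day >= params.season_start:
            ip = params.nest_initiation_prob
            return ip * go(day + 1, "laying", 0) + (1 - ip) * go(day + 1, "waiting", 0)
        return go(day + 1, "waiting", 0)

    return go(params.season_start, "waiting", 0)


class TestStateMachine:
    def test_pesticide_exceedance_forces_whole_nest_failure(self, species):
        state = FemaleState(day=100, phase=Phase.INCUBATING, days_in_phase=5)
        out = step_female_day(state, species.breeding, dose_today=10.0, noaels=NOAELS)
        assert out.phase is Phase.WAIT_FAIL
        assert out.pesticide_failures == 1
        assert out.natural_failures == 0

    def test_certain_survival_never_fails(self):
        params = replace(TOY, daily_nest_survival=1.0)
        state = FemaleState(day=1, phase=Phase.LAYING)
        for _ in range(3):
            state = step_female_day(state, params, 0.0, NOAELS)
        assert state.natural_failures == 0 and state.pesticide_failures == 0

    def test_season_closes_for_waiting_female(self):
        state = FemaleState(day=TOY.season_end + 1, phase=Phase.WAITING)
        out = step_female_day(state, TOY, 0.0, NOAELS)
        assert out.phase is Phase.DONE


class TestExactEnumeration:
    def test_matches_brute_force_toy_season(self):
        dose = np.zeros(40)
        dose[4:7] = 10.0  # mid-season pulse above the NOAEL
        exact = enumerate_season_exact(TOY, dose, NOAELS)
        oracle = brute_force_expected_broods(TOY, dose, NOAELS)
        assert exact.successful_broods == pytest.approx(oracle, abs=1e-12)

    def test_matches_brute_force_unexposed(self):
        dose = np.zeros(40)
        exact = enumerate_season_exact(TOY, dose, NOAELS)
        oracle = brute_force_expected_broods(TOY, dose, NOAELS)
        assert exact.successful_broods == pytest.approx(oracle, abs=1e-12)

    def test_deterministic_brood_arithmetic(self, species):
        # daily survival 1 and no exposure: the window fits exactly 3 cycles
        params = replace(species.breeding, daily_nest_survival=1.0)
        out = enumerate_season_exact(params, np.zeros(300), NOAELS)
        assert out.fecundity == pytest.approx(3 * 4 * 0.5, abs=1e-12)

    def test_saturating_dose_zeroes_fecundity(self, species):
        dose = np.full(300, 1e4)
        out = enumerate_season_exact(species.breeding, dose, NOAELS)
        assert out.fecundity == 0.0
        assert out.pesticide_failures > 0

    def test_monotone_in_exposure(self, species):
        base = np.zeros(300)
        base[100:140] = 3.0
        higher = base * 2.0
        f_lo = enumerate_season_exact(
            species.breeding, base, NOAELS, residue_sigma_log10=0.23
        ).fecundity
        f_hi = enumerate_season_exact(
            species.breeding, higher, NOAELS, residue_sigma_log10=0.23
        ).fecundity
        f_none = enumerate_season_exact(species.breeding, np.zeros(300), NOAELS).fecundity
        assert f_hi <= f_lo <= f_none

    def test_fecundity_bounded_by_cycle_packing(self, species):
        window = species.breeding.season_end - species.breeding.season_start + 1
        max_broods = window // species.breeding.cycle_days + 1
        out = enumerate_season_exact(species.breeding, np.zeros(300), NOAELS)
        assert out.fecundity <= max_broods * species.breeding.brood_fecundity


class TestMonteCarlo:
    def test_mc_converges_to_exact_with_exposure(self, species):
        dose = np.zeros(300)
        dose[100:160] = 3.0  # below NOAEL at median; noise drives exceedance
        exact = enumerate_season_exact(
            species.breeding, dose, NOAELS, residue_sigma_log10=0.23
        ).fecundity
        rng = np.random.default_rng(11)
        means = [
            simulate_season(
                species.breeding,
                dose,
                NOAELS,
                n_females=400,
                rng=rng,
                residue_sigma_log10=0.23,
            ).fecundity
            for _ in range(10)
        ]
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - exact) < 3.0 * max(sem, 1e-3)

    def test_mc_converges_to_exact_toy(self):
        exact = enumerate_season_exact(TOY, np.zeros(40), NOAELS).fecundity
        rng = np.random.default_rng(12)
        means = [
            simulate_season(TOY, np.zeros(40), NOAELS, n_females=500, rng=rng).fecundity
            for _ in range(10)
        ]
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - exact) < 3.0 * max(sem, 1e-3)

    def test_reproducible_under_seed(self, species):
        dose = np.zeros(300)
        a = simulate_season(
            species.breeding, dose, NOAELS, n_females=50, rng=np.random.default_rng(3)
        )
        b = simulate_season(
            species.breeding, dose, NOAELS, n_females=50, rng=np.random.default_rng(3)
        )
        assert a == b

    def test_death_day_truncates_late_broods(self, species):
        params = replace(species.breeding, daily_nest_survival=1.0)
        full = simulate_season(params, np.zeros(300), NOAELS, n_females=1)
        early_death = simulate_season(
            params, np.zeros(300), NOAELS, n_females=1, death_day=130
        )
        assert full.successful_broods == 3
        assert early_death.successful_broods < full.successful_broods


class TestCalibration:
    def test_zero_target(self, species):
        assert calibrate_fixture(species.breeding, 0.0) == 0.0

    def test_max_achievable_target(self, species):
        dns = calibrate_fixture(species.breeding, 6.0)
        assert dns == pytest.approx(1.0, abs=1e-3)

    def test_unachievable_target_raises(self, species):
        with pytest.raises(ValueError):
            calibrate_fixture(species.breeding, 7.0)

    def test_recovers_packaged_fixture(self, species):
        dns = calibrate_fixture(species.breeding, 2.26)
        assert dns == pytest.approx(species.breeding.daily_nest_survival, abs=1e-4)
        check = enumerate_season_exact(
            replace(species.breeding, daily_nest_survival=dns), np.zeros(300), NOAELS
        )
        assert check.fecundity == pytest.approx(2.26, abs=1e-3)
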