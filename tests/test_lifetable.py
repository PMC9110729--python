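"""Age-stage schedules and demographic parameters against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from agestage.cohort import CohortDataset
from agestage.lifetable import (
    build_schedule,
    demographic_parameters,
    finite_rate,
    intrinsic_rate,
    life_expectancy,
    mean_generation_time,
    net_reproductive_rate,
    reproductive_value,
    solve_euler_lotka,
    curves_frame,
    UndefinedRateError,
)

from conftest import make_record, random_cohort


# -- brute-force oracles -----------------------------------------------------

def census_lx(cohort):
    """Daily head-count survival, independent of the schedule machinery."""
    records = cohort.active
    x_max = max(r.death_age for r in records) + 1
    return np.array(
        [sum(1 for r in records if x < r.death_age) / len(records) for x in range(x_max)]
    )


def egg_total_r0(cohort):
    """R0 as plain eggs laid divided by cohort size."""
    records = cohort.active
    return sum(sum(r.daily_fecundity.values()) for r in records) / len(records)


# -- schedule construction ---------------------------------------------------

class TestBuildSchedule:
    def test_single_egg_occupancy(self):
        cohort = CohortDataset("toy", [make_record("a", {"egg": 3})])
        sched = build_schedule(cohort)
        j = sched.stage_index("egg")
        assert list(sched.s[:, j]) == [1.0, 1.0, 1.0, 0.0]
        assert list(sched.l_x) == [1.0, 1.0, 1.0, 0.0]

    def test_lx_matches_daily_census(self):
        cohort = CohortDataset(
            "toy",
            [
                make_record("a", {"egg": 2}),
                make_record("b", {"egg": 3, "L1": 1}),
                make_record("c", {"egg": 3, "L1": 1}),
            ],
        )
        sched = build_schedule(cohort)
        np.testing.assert_allclose(sched.l_x, census_lx(cohort))

    @pytest.mark.parametrize("seed", range(8))
    def test_lx_census_oracle_random(self, seed):
        cohort = random_cohort(np.random.default_rng(seed))
        sched = build_schedule(cohort)
        np.testing.assert_allclose(sched.l_x, census_lx(cohort), atol=1e-12)
        assert sched.l_x[0] == 1.0
        assert np.all(np.diff(sched.l_x) <= 1e-12)
        # every s entry is a multiple of 1/N
        np.testing.assert_allclose(
            np.round(sched.s * sched.N), sched.s * sched.N, atol=1e-9
        )

    def test_adult_sex_curves_peak_at_survivor_fractions(self, urticae_counts_cohort):
        sched = build_schedule(urticae_counts_cohort)
        assert sched.s[:, sched.stage_index("adult_female")].max() == pytest.approx(0.5)
        assert sched.s[:, sched.stage_index("adult_male")].max() == pytest.approx(0.46)

    def test_all_excluded_cohort_errors(self):
        cohort = CohortDataset("toy", [make_record("a", {"egg": 2}, excluded=True)])
        with pytest.raises(ValueError, match="non-excluded"):
            build_schedule(cohort)


# -- scalar parameters -------------------------------------------------------

class TestNetReproductiveRate:
    def test_zero_without_fecundity(self):
        cohort = CohortDataset("toy", [make_record("a", {"egg": 4})])
        assert net_reproductive_rate(build_schedule(cohort)) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_per_individual_egg_totals(self, seed):
        cohort = random_cohort(np.random.default_rng(100 + seed))
        sched = build_schedule(cohort)
        assert net_reproductive_rate(sched) == pytest.approx(egg_total_r0(cohort), abs=1e-9)


class TestEulerLotka:
    def test_unit_pulse_gives_zero_rate(self):
        b = np.zeros(10)
        b[6] = 1.0
        assert solve_euler_lotka(b) == pytest.approx(0.0, abs=1e-13)

    def test_residual_below_tolerance(self):
        rng = np.random.default_rng(5)
        b = rng.random(40) * 0.5
        r = solve_euler_lotka(b)
        residual = abs(np.sum(np.exp(-r * (np.arange(40) + 1)) * b) - 1)
        assert residual < 1e-12

    def test_sign_matches_r0(self):
        b = np.zeros(15)
        b[10] = 2.5  # R0 > 1
        assert solve_euler_lotka(b) > 0
        b[10] = 0.4  # R0 < 1
        assert solve_euler_lotka(b) < 0

    def test_undefined_when_no_reproduction(self):
        with pytest.raises(UndefinedRateError):
            solve_euler_lotka(np.zeros(5))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.0, 3.0), min_size=3, max_size=60), st.integers(0, 10**6))
    def test_matches_independent_root_finder(self, values, bump_age):
        b = np.array(values)
        b[bump_age % len(b)] += 0.5  # guarantee some reproduction
        r = solve_euler_lotka(b)
        ages = np.arange(len(b)) + 1.0

        def residual(rr):
            return np.sum(np.exp(-rr * ages) * b) - 1.0

        # residual(-1) > 0 always (the bump contributes >= 0.5*e), residual(5)
        # is below zero for any schedule bounded by 3 eggs/day over 60 days
        oracle = brentq(residual, -1.0, 5.0, xtol=1e-13)
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_intrinsic_rate_on_random_cohorts(self):
        for seed in range(6):
            cohort = random_cohort(np.random.default_rng(200 + seed), n_max=8)
            sched = build_schedule(cohort)
            if net_reproductive_rate(sched) == 0:
                continue
            r = intrinsic_rate(sched)
            b = sched.l_x * sched.m_x
            residual = abs(np.sum(np.exp(-r * (np.arange(len(b)) + 1)) * b) - 1)
            assert residual < 1e-12


class TestDerivedRates:
    @pytest.mark.parametrize(
        "r,expected", [(0.118, 1.125), (0.047, 1.048), (0.0, 1.0)]
    )
    def test_finite_rate(self, r, expected):
        assert finite_rate(r) == pytest.approx(expected, abs=5e-4)

    def test_generation_time(self):
        assert mean_generation_time(math.e, 0.5) == pytest.approx(2.0)
        assert math.isnan(mean_generation_time(1.0, 0.0))
        with pytest.raises(UndefinedRateError):
            mean_generation_time(0.0, 0.1)

    def test_zero_reproduction_cohort_reports_undefined(self):
        cohort = CohortDataset("toy", [make_record("a", {"egg": 2, "L1": 3})])
        params = demographic_parameters(build_schedule(cohort))
        assert params.R0 == 0.0
        assert not params.defined
        assert math.isnan(params.r) and math.isnan(params.lam) and math.isnan(params.T)
        # e_xj is still available on such a cohort
        e = life_expectancy(build_schedule(cohort))
        assert e[0, 0] == pytest.approx(5.0)


# -- life expectancy ---------------------------------------------------------

class TestLifeExpectancy:
    def test_constant_lifespan(self):
        cohort = CohortDataset(
            "toy", [make_record(f"a{i}", {"egg": 4, "L1": 6}) for i in range(5)]
        )
        e = life_expectancy(build_schedule(cohort))
        assert e[0, 0] == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_first_cell_is_mean_lifespan(self, seed):
        cohort = random_cohort(np.random.default_rng(300 + seed))
        e = life_expectancy(build_schedule(cohort))
        oracle = np.mean([r.death_age for r in cohort.active])
        assert e[0, 0] == pytest.approx(oracle, abs=1e-9)

    def test_unoccupied_cells_are_nan(self):
        cohort = CohortDataset("toy", [make_record("a", {"egg": 2})])
        e = life_expectancy(build_schedule(cohort))
        assert math.isnan(e[0, 1])  # L1 never reached

    def test_calibrated_cohort_mean_longevity(self):
        # 50 individuals whose death ages average 38.7 days
        ages = [7] * 13 + [50] * 17 + [49] * 18 + [56, 56]
        assert np.mean(ages) == pytest.approx(38.7)
        individuals = []
        for i, a in enumerate(ages):
            if a == 7:
                individuals.append(make_record(f"x{i}", {"egg": 3, "L1": 4}))
            else:
                durations = {"egg": 3, "L1": 3, "L2": 3, "L3": 3, "L4": 5,
                             "prepupa": 1, "pupa": 4, "adult": a - 22}
                individuals.append(
                    make_record(f"x{i}", durations, sex="female" if i % 2 else "male")
                )
        cohort = CohortDataset("calib", individuals)
        e = life_expectancy(build_schedule(cohort))
        assert e[0, 0] == pytest.approx(38.7, abs=1e-9)


# -- reproductive value ------------------------------------------------------

def brute_force_v(cohort, sched, r):
    """Explicit double sum over per-individual trajectories."""
    records = cohort.active
    x_max = sched.n_ages
    v = np.full((x_max, len(sched.stages)), np.nan)
    for x in range(x_max):
        for j, stage in enumerate(sched.stages):
            members = []
            for rec in records:
                st_at = rec.stage_at(x)
                if st_at == "adult":
                    st_at = "adult_female" if rec.sex == "female" else "adult_male"
                if st_at == stage:
                    members.append(rec)
            if not members:
                continue
            acc = 0.0
            for rec in members:
                for age, eggs in rec.daily_fecundity.items():
                    if age >= x:
                        acc += math.exp(-r * (age + 1)) * eggs
            v[x, j] = math.exp(r * (x + 1)) * acc / len(members)
    return v


class TestReproductiveValue:
    @pytest.mark.parametrize("seed", [400, 403, 405, 406])
    def test_first_cell_equals_lambda(self, seed):
        cohort = random_cohort(np.random.default_rng(seed))
        sched = build_schedule(cohort)
        if net_reproductive_rate(sched) == 0:
            pytest.skip("no reproduction in this draw")
        r = intrinsic_rate(sched)
        v = reproductive_value(sched, r)
        assert v[0, 0] == pytest.approx(math.exp(r), rel=1e-12)

    @pytest.mark.parametrize("seed", [408, 409, 412, 413])
    def test_matches_explicit_double_sum(self, seed):
        cohort = random_cohort(np.random.default_rng(seed))
        sched = build_schedule(cohort)
        if net_reproductive_rate(sched) == 0:
            pytest.skip("no reproduction in this draw")
        r = intrinsic_rate(sched)
        v = reproductive_value(sched, r)
        oracle = brute_force_v(cohort, sched, r)
        np.testing.assert_allclose(v, oracle, atol=1e-9, equal_nan=True)

    def test_rises_toward_a_single_fecundity_pulse(self):
        # one female laying all eggs at one age: v increases with age up to
        # the pulse for the stages she passes through
        durations = {"egg": 3, "L1": 2, "L2": 2, "L3": 2, "L4": 2, "prepupa": 1,
                     "pupa": 2, "adult": 6}
        rec = make_record("f", durations, sex="female", fecundity={17: 12})
        cohort = CohortDataset("toy", [rec])
        sched = build_schedule(cohort)
        r = intrinsic_rate(sched)
        v = reproductive_value(sched, r)
        path = [np.nanmax(v[x]) for x in range(18)]
        assert all(b > a for a, b in zip(path, path[1:]))

    def test_undefined_without_growth_rate(self):
        cohort = CohortDataset("toy", [make_record("a", {"egg": 2})])
        sched = build_schedule(cohort)
        with pytest.raises(UndefinedRateError):
            reproductive_value(sched, math.nan)


class TestCurveExport:
    def test_tidy_frame_covers_all_quantities(self, urticae_counts_cohort):
        sched = build_schedule(urticae_counts_cohort)
        r = intrinsic_rate(sched)
        frame = curves_frame(
            sched,
            e_xj=life_expectancy(sched),
            v_xj=reproductive_value(sched, r),
        )
        assert set(frame["quantity"]) == {"s_xj", "f_xj", "e_xj", "v_xj", "l_x", "m_x"}
        lx = frame[frame.quantity == "l_x"].sort_values("age")["value"].to_numpy()
        np.testing.assert_allclose(lx, sched.l_x)
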