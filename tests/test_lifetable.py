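"""Life table core: tabulation, schedules, Euler-Lotka solver, identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agestage import (AgeSchedules, CohortError, CohortTable, StageOrder,
                      age_schedules, build_age_stage_matrix, compute_R0,
                      compute_T, compute_exj, compute_lambda, compute_lx,
                      compute_mx, compute_sxj, compute_vxj, diet15_config,
                      life_table, simulate_cohort, solve_r)
from conftest import make_individual

from _oracles import (R0_brute, euler_lotka_residual, lx_brute, mean_lifespan,
                      mx_brute, r_gridscan, sxj_brute, tally_counts)


# ---------------------------------------------------------------- tabulation

def test_counts_two_identical_individuals(tiny_order):
    inds = [make_individual(f"i{k}", "U", ["J", "J"]) for k in range(2)]
    cohort = CohortTable(inds, tiny_order)
    m = build_age_stage_matrix(cohort)
    assert m.counts[0, 0] == 2 and m.counts[1, 0] == 2
    assert m.counts.sum() == 4


def test_fecundity_cell_is_mean_eggs_per_occupant(tiny_order):
    inds = [make_individual("f", "F", ["J"] * 10 + ["AF"], {10: 50})]
    m = build_age_stage_matrix(CohortTable(inds, tiny_order))
    assert m.fecundity[10, 1] == 50.0


def test_empty_cohort_rejected(tiny_order):
    with pytest.raises(CohortError, match="empty cohort"):
        build_age_stage_matrix(CohortTable([], tiny_order))


def test_unknown_stage_names_individual(tiny_order):
    inds = [make_individual("odd", "U", ["J", "X"])]
    with pytest.raises(CohortError, match="X"):
        build_age_stage_matrix(CohortTable(inds, tiny_order))


def test_matrix_matches_tally_oracle(small_cohort):
    m = compute_sxj(build_age_stage_matrix(small_cohort))
    np.testing.assert_array_equal(m.counts, tally_counts(small_cohort))
    np.testing.assert_allclose(m.survival, sxj_brute(small_cohort), atol=1e-12)


# -------------------------------------------------------------- s_xj and l_x

def test_sxj_is_count_over_n01(tiny_order):
    inds = [make_individual(f"i{k}", "U", ["J", "J"] if k < 80 else ["J"])
            for k in range(100)]
    m = compute_sxj(build_age_stage_matrix(CohortTable(inds, tiny_order)))
    assert m.survival[1, 0] == pytest.approx(0.80)
    assert m.survival[0, 0] == 1.0  # all newborns start in stage 1


def test_sxj_requires_positive_n01(small_cohort):
    m = build_age_stage_matrix(small_cohort)
    with pytest.raises(CohortError):
        compute_sxj(m, 0)


def test_lx_sums_stages_and_is_monotone(small_cohort):
    m = compute_sxj(build_age_stage_matrix(small_cohort))
    lx = compute_lx(m)
    assert lx[0] == 1.0
    assert np.all(np.diff(lx) <= 1e-15)
    np.testing.assert_allclose(lx, lx_brute(small_cohort), atol=1e-12)
    # total stage occupancy is non-increasing in age too
    assert np.all(np.diff(m.survival.sum(axis=1)) <= 1e-15)


# ---------------------------------------------------------------------- m_x

def test_mx_weighted_average_and_zero_when_extinct(tiny_order):
    # 0.4 of the cohort are adult females laying 50, 0.4 adult males
    inds = ([make_individual(f"f{k}", "F", ["J", "AF"], {1: 50}) for k in range(4)]
            + [make_individual(f"m{k}", "M", ["J", "AM"]) for k in range(4)]
            + [make_individual(f"u{k}", "U", ["J"]) for k in range(2)])
    m = compute_sxj(build_age_stage_matrix(CohortTable(inds, tiny_order)))
    mx, lxmx = compute_mx(m)
    assert mx[1] == pytest.approx((0.4 * 50) / 0.8)
    assert lxmx[1] == pytest.approx(0.8 * 25)
    # ages with no survivors have mx defined as 0, not an error
    padded = np.append(m.survival.sum(axis=1), 0.0)
    assert mx.shape[0] == padded.shape[0] - 1


def test_mx_matches_brute_force(small_cohort):
    m = compute_sxj(build_age_stage_matrix(small_cohort))
    mx, _ = compute_mx(m)
    np.testing.assert_allclose(mx, mx_brute(small_cohort), atol=1e-12)


def test_reproductive_schedule_conserves_total_eggs(medium_cohort):
    sched = age_schedules(compute_sxj(build_age_stage_matrix(medium_cohort)))
    assert sched.lxmx.sum() == pytest.approx(
        medium_cohort.total_eggs / medium_cohort.n01, abs=1e-12)


# ----------------------------------------------------------------- R0, r, T, λ

def _sched(lx, mx):
    lx = np.asarray(lx, float)
    mx = np.asarray(mx, float)
    return AgeSchedules(lx=lx, mx=mx, lxmx=lx * mx)


def test_R0_direct_sum():
    assert compute_R0(_sched([1, 0.8, 0.5], [0, 10, 20])) == pytest.approx(18.0)
    assert compute_R0(_sched([1, 0.5], [0, 0])) == 0.0


def test_solve_r_zero_when_R0_is_one():
    assert abs(solve_r(_sched([1, 1], [0, 1]))) <= 1e-12


def test_solve_r_one_term_closed_form():
    # e^{-2r}·2 = 1  =>  r = ln(2)/2
    assert solve_r(_sched([1, 1], [0, 2])) == pytest.approx(math.log(2) / 2, abs=1e-10)


def test_solve_r_requires_reproduction():
    with pytest.raises(CohortError, match="no reproduction"):
        solve_r(_sched([1, 1], [0, 0]))


def test_solve_r_agrees_with_gridscan_oracle(medium_cohort):
    sched = age_schedules(compute_sxj(build_age_stage_matrix(medium_cohort)))
    r = solve_r(sched)
    assert r == pytest.approx(r_gridscan(list(sched.lxmx)), abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.floats(0, 50), min_size=2, max_size=40),
       st.integers(0, 30))
def test_solve_r_residual_and_sign_properties(fec, shift):
    lxmx = np.zeros(len(fec) + shift)
    lxmx[shift:] = fec
    if lxmx.sum() <= 0:
        return
    r = solve_r(AgeSchedules(lx=np.ones_like(lxmx), mx=lxmx, lxmx=lxmx))
    assert abs(euler_lotka_residual(r, list(lxmx))) <= 1e-12
    R0 = lxmx.sum()
    if abs(math.log(R0)) > 1e-9:
        assert math.copysign(1, r) == math.copysign(1, math.log(R0))
    # residual strictly decreasing around the root
    assert euler_lotka_residual(r - 0.01, list(lxmx)) > euler_lotka_residual(
        r + 0.01, list(lxmx))


def test_generation_time_formula_and_degenerate_cases():
    assert compute_T(18.0, 0.2) == pytest.approx(math.log(18) / 0.2)
    assert compute_T(math.e, 1.0) == pytest.approx(1.0)
    assert math.isnan(compute_T(1.0, 0.0))
    with pytest.raises(CohortError):
        compute_T(0.0, 0.1)


def test_T_round_trip_on_simulated_cohort(medium_cohort):
    sched = age_schedules(compute_sxj(build_age_stage_matrix(medium_cohort)))
    r = solve_r(sched)
    R0 = compute_R0(sched)
    T = compute_T(R0, r)
    assert math.exp(r * T) == pytest.approx(R0, abs=1e-9 * R0)


@pytest.mark.parametrize("r", [-1.0, -0.1, 0.0, 0.05, 0.5, math.log(2) / 2])
def test_lambda_is_exp_r(r):
    lam = compute_lambda(r)
    assert math.log(lam) == pytest.approx(r, abs=1e-15)
    assert compute_lambda(math.log(2) / 2) == pytest.approx(math.sqrt(2), abs=1e-12)


# ------------------------------------------------------------- e_xj and v_xj

def test_expectancy_certain_lifespan(tiny_order):
    inds = [make_individual(f"i{k}", "M", ["J"] * 20 + ["AM"] * 10)
            for k in range(5)]
    e = compute_exj(CohortTable(inds, tiny_order))
    assert e[0, 0] == pytest.approx(30.0)
    # last day of life: expectancy counts the current day
    assert e[29, 2] == pytest.approx(1.0)


def test_expectancy_at_birth_is_mean_lifespan(medium_cohort):
    e = compute_exj(medium_cohort)
    assert e[0, 0] == pytest.approx(mean_lifespan(medium_cohort), abs=1e-12)


def test_expectancy_bounded_by_remaining_window(small_cohort):
    e = compute_exj(small_cohort)
    width = e.shape[0]
    for x in range(width):
        vals = e[x][~np.isnan(e[x])]
        assert np.all(vals >= 0) and np.all(vals <= width - x)


def test_reproductive_value_at_birth_equals_lambda(medium_cohort):
    res = life_table(medium_cohort)
    assert res.vxj[0, 0] == pytest.approx(res.params.lam, abs=1e-9)


def test_reproductive_value_zero_without_future_reproduction(tiny_order):
    # males never reach the adult-female stage: v = 0 on their column
    inds = ([make_individual(f"m{k}", "M", ["J", "AM", "AM"]) for k in range(3)]
            + [make_individual("f", "F", ["J", "AF", "AF"], {1: 4, 2: 2})])
    cohort = CohortTable(inds, tiny_order)
    sched = age_schedules(compute_sxj(build_age_stage_matrix(cohort)))
    r = solve_r(sched)
    v = compute_vxj(cohort, r)
    assert v[1, 2] == pytest.approx(0.0)
    assert v[2, 2] == pytest.approx(0.0)
    assert v[0, 0] == pytest.approx(math.exp(r), abs=1e-9)


def test_reproductive_value_matches_hand_recursion(tiny_order):
    # lx=[1,1], mx=[0,2]: every individual is a female laying 2 eggs on day 1
    inds = [make_individual(f"f{k}", "F", ["J", "AF"], {1: 2}) for k in range(4)]
    cohort = CohortTable(inds, tiny_order)
    r = math.log(2) / 2
    v = compute_vxj(cohort, r)
    # hand evaluation: v_{1,AF} = e^{2r} · e^{-2r} · f = 2;  v_{0,1} = e^r
    assert v[1, 1] == pytest.approx(2.0, abs=1e-12)
    assert v[0, 0] == pytest.approx(math.exp(r), abs=1e-12)


def test_cells_never_occupied_are_flagged(small_cohort):
    res = life_table(small_cohort)
    occupied = res.matrix.counts > 0
    assert np.isnan(res.exj[~occupied]).all()
    assert np.isnan(res.vxj[~occupied]).all()
    assert np.all(res.vxj[occupied] >= -1e-12)


# ------------------------------------------------- whole-cohort brute force

def test_everything_matches_brute_force_on_small_cohorts():
    for seed in (1, 2, 3):
        cohort = simulate_cohort(diet15_config(n=30, seed=seed))
        m = compute_sxj(build_age_stage_matrix(cohort))
        sched = age_schedules(m)
        np.testing.assert_allclose(m.survival, sxj_brute(cohort), atol=1e-12)
        np.testing.assert_allclose(sched.lx, lx_brute(cohort), atol=1e-12)
        np.testing.assert_allclose(sched.mx, mx_brute(cohort), atol=1e-12)
        assert compute_R0(sched) == pytest.approx(R0_brute(cohort), abs=1e-12)
        if compute_R0(sched) > 0:
            assert solve_r(sched) == pytest.approx(
                r_gridscan(list(sched.lxmx)), abs=1e-9)
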