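"""PrR quantile ages, point estimate, permutation test, uncertainty sim."""

import itertools

import numpy as np
import pytest

from postrepro import SimConfig, generate_cohort
from postrepro.demography import (
    AgeSchedule,
    SurvivorshipCurve,
    exposure_schedule,
    fecundity_schedule,
    survivorship,
)
from postrepro.prr import (
    UndefinedStatisticError,
    compute_prr,
    fecundity_quantile_age,
    permutation_test,
    uncertainty_simulation,
)

from conftest import obs


def make_schedule(ages, m):
    ages = np.asarray(ages, dtype=int)
    m = np.asarray(m, dtype=float)
    return AgeSchedule(
        ages=ages,
        exposure=np.ones_like(m),
        females_observed=np.ones(len(m), dtype=int),
        births=np.zeros(len(m), dtype=int),
        fecundity=m,
        denominator="females_observed",
    )


def make_curve(grid, l):
    return SurvivorshipCurve(
        age_grid=np.asarray(grid, dtype=float),
        l=np.asarray(l, dtype=float),
        baseline_age=float(grid[0]),
    )


FLAT = make_curve([10.0, 30.0], [1.0, 1.0])


def brute_prr(curve, ages, m, weighting, n_fine=20_000):
    """Independent PrR: dense piecewise-constant fecundity density plus
    dense quadrature for T, no shared code with the implementation."""
    lo, hi = ages.min(), ages.max() + 1.0
    fine = np.linspace(lo, hi, n_fine, endpoint=False)
    dens = np.zeros(n_fine)
    for a, mi in zip(ages, m):
        mask = (fine >= a) & (fine < a + 1)
        w = mi * (curve.evaluate(a + 0.5) if weighting == "l_times_m" else 1.0)
        dens[mask] = w
    cum = np.cumsum(dens)
    cum = cum / cum[-1]
    step = (hi - lo) / n_fine

    def q_age(q):
        return fine[np.searchsorted(cum, q)] + step

    def T(x):
        omega = curve.age_grid[-1]
        g = np.linspace(x, omega, 200_001)
        return np.trapezoid(curve.evaluate(g), g)

    return T(q_age(0.95)) / T(q_age(0.05))


class TestQuantileAge:
    def test_single_atom_within_class(self):
        s = make_schedule([18, 19, 20, 21], [0, 0, 1.0, 0])
        for q in (0.05, 0.95):
            a = fecundity_quantile_age(FLAT, s, q, "m_only")
            assert 20.0 <= a < 21.0

    def test_uniform_schedule_median(self):
        s = make_schedule(range(10, 20), np.ones(10))
        assert fecundity_quantile_age(FLAT, s, 0.5, "m_only") == pytest.approx(15.0)

    def test_irregular_schedule_vs_dense_oracle(self):
        curve = make_curve(
            [10, 12, 12, 13.5, 13.5, 16], [1, 1, 0.7, 0.7, 0.4, 0.4]
        )
        ages = np.array([10, 11, 12, 13, 14])
        m = np.array([0.5, 0.05, 0.2, 0.1, 0.02])
        s = make_schedule(ages, m)
        for weighting in ("m_only", "l_times_m"):
            for q in (0.05, 0.5, 0.95):
                got = fecundity_quantile_age(curve, s, q, weighting)
                # independent dense cumulative interpolation
                lo = 10.0
                fine = np.linspace(lo, 15.0, 500_000, endpoint=False)
                dens = np.zeros_like(fine)
                for a, mi in zip(ages, m):
                    w = mi * (
                        curve.evaluate(a + 0.5) if weighting == "l_times_m" else 1.0
                    )
                    dens[(fine >= a) & (fine < a + 1)] = w
                cum = np.cumsum(dens) / np.sum(dens)
                expect = fine[np.searchsorted(cum, q)]
                assert got == pytest.approx(expect, abs=1e-3)

    def test_all_zero_fecundity_raises(self):
        s = make_schedule([10, 11], [0.0, 0.0])
        with pytest.raises(UndefinedStatisticError):
            fecundity_quantile_age(FLAT, s, 0.5)

    def test_bad_q_rejected(self):
        s = make_schedule([10, 11], [0.5, 0.5])
        with pytest.raises(ValueError):
            fecundity_quantile_age(FLAT, s, 1.5)


class TestComputePrr:
    def test_no_survival_past_age_M_gives_zero(self):
        # everyone dead at 18.5, before the 95% fecundity age (~18.93)
        curve = make_curve([10, 18.5, 18.5, 21], [1, 1, 0.0, 0.0])
        s = make_schedule([10, 15, 18], [0.1, 0.2, 0.7])
        r = compute_prr(curve, s, "m_only")
        assert r.prr == pytest.approx(0.0, abs=1e-9)

    def test_single_reproductive_class_near_one(self):
        # all fecundity at one age, survival far beyond it; B and M differ
        # only by the within-class interpolation
        curve = make_curve([10.0, 500.0], [1.0, 1.0])
        s = make_schedule([20], [1.0])
        r = compute_prr(curve, s, "m_only")
        assert r.age_B == pytest.approx(20.05)
        assert r.age_M == pytest.approx(20.95)
        assert r.prr > 0.99

    def test_invariants_on_random_cohorts(self):
        for seed in range(5):
            cohort = generate_cohort(SimConfig(n_females=40), seed=seed)
            s = fecundity_schedule(exposure_schedule(cohort))
            c = survivorship(cohort)
            r = compute_prr(c, s)
            assert 0.0 <= r.prr <= 1.0
            assert r.age_B <= r.age_M
            assert r.T_M <= r.T_B
            assert r.prr == pytest.approx(r.T_M / r.T_B)

    def test_matches_brute_force(self):
        curve = make_curve(
            [10, 12, 12, 13.5, 13.5, 16], [1, 1, 0.7, 0.7, 0.4, 0.4]
        )
        ages = np.array([10, 11, 12, 13, 14])
        m = np.array([0.5, 0.05, 0.2, 0.1, 0.02])
        s = make_schedule(ages, m)
        for weighting in ("m_only", "l_times_m"):
            got = compute_prr(curve, s, weighting).prr
            assert got == pytest.approx(
                brute_prr(curve, ages, m, weighting), abs=2e-3
            )


class TestPermutation:
    def test_constant_fecundity_p_is_one(self):
        s = make_schedule(range(10, 16), np.full(6, 0.3))
        curve = make_curve([10, 13, 13, 16], [1, 1, 0.6, 0.6])
        res = permutation_test(curve, s, 500, seed=4)
        assert res.p_value == 1.0
        assert np.allclose(res.null_prr, res.observed_prr)

    def test_matches_exhaustive_enumeration(self):
        curve = make_curve(
            [10, 12, 12, 13.5, 13.5, 16], [1, 1, 0.7, 0.7, 0.4, 0.4]
        )
        ages = np.array([10, 11, 12, 13, 14])
        m = np.array([0.5, 0.05, 0.2, 0.1, 0.02])
        s = make_schedule(ages, m)
        observed = brute_prr(curve, ages, m, "l_times_m")
        null = [
            brute_prr(curve, ages, np.array(perm), "l_times_m")
            for perm in itertools.permutations(m)
        ]
        p_exact = np.mean(np.asarray(null) >= observed - 1e-9)
        res = permutation_test(curve, s, 10_000, seed=17)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_value - p_exact) <= 3 * se + 2e-4

    def test_reproducible_from_seed(self):
        s = make_schedule(range(10, 20), np.linspace(1, 0.1, 10))
        r1 = permutation_test(FLAT, s, 200, seed=5)
        r2 = permutation_test(FLAT, s, 200, seed=5)
        assert np.array_equal(r1.null_prr, r2.null_prr)
        assert r1.p_value == r2.p_value

    def test_too_few_classes_rejected(self):
        s = make_schedule([10], [1.0])
        with pytest.raises(UndefinedStatisticError):
            permutation_test(FLAT, s, 100, seed=0)


class TestUncertainty:
    def test_zero_errors_degenerate(self):
        cohort = generate_cohort(SimConfig(n_females=30), seed=6)
        zeroed = type(cohort)(
            females=[
                type(f)(
                    female_id=f.female_id,
                    birth_date=f.birth_date,
                    age_error=0.0,
                    entry_date=f.entry_date,
                    exit_date=f.exit_date,
                    exit_fate=f.exit_fate,
                    entry_mode=f.entry_mode,
                )
                for f in cohort.females
            ],
            births=cohort.births,
        ).validate()
        res = uncertainty_simulation(
            zeroed, n_iterations=20, n_permutations=200, seed=1
        )
        s = fecundity_schedule(exposure_schedule(zeroed))
        c = survivorship(zeroed)
        point = compute_prr(c, s).prr
        assert res.sd_prr == 0.0
        assert np.allclose(res.prr_values, point)

    def test_larger_age_errors_widen_spread(self):
        base = generate_cohort(SimConfig(n_females=40), seed=8)

        def with_errors(factor):
            return type(base)(
                females=[
                    type(f)(
                        female_id=f.female_id,
                        birth_date=f.birth_date,
                        age_error=f.age_error * factor,
                        entry_date=f.entry_date,
                        exit_date=f.exit_date,
                        exit_fate=f.exit_fate,
                        entry_mode=f.entry_mode,
                    )
                    for f in base.females
                ],
                births=base.births,
            ).validate()

        small = with_errors(0.25)
        large = with_errors(1.0)
        sds_small, sds_large = [], []
        for rep in range(7):
            sds_small.append(
                uncertainty_simulation(
                    small, n_iterations=60, n_permutations=1, seed=100 + rep
                ).sd_prr
            )
            sds_large.append(
                uncertainty_simulation(
                    large, n_iterations=60, n_permutations=1, seed=100 + rep
                ).sd_prr
            )
        assert np.median(sds_large) >= np.median(sds_small)

    def test_mean_sd_consistent_with_values(self):
        cohort = generate_cohort(SimConfig(n_females=30), seed=12)
        res = uncertainty_simulation(
            cohort, n_iterations=30, n_permutations=50, seed=2
        )
        assert res.mean_prr == pytest.approx(float(np.mean(res.prr_values)))
        assert res.sd_prr == pytest.approx(float(np.std(res.prr_values, ddof=1)))
        assert len(res.p_values) == res.n_iterations
        assert np.all((res.p_values > 0) & (res.p_values <= 1))
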