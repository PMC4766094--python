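"""Cohort engine: probability conversions, transition rows, runs, life-years."""

import numpy as np
import pytest

from quitcea.errors import ConfigurationError, ModelConsistencyError
from quitcea.life_tables import DISEASES
from quitcea.markov import (
    CohortSpec, CohortTrace, DiseaseSurvivalSpec, MortalityTables, StrategySpec,
    Stratum, annual_death_probability_from_life_expectancy, build_transition_row,
    cause_specific_deaths, default_french_smoker_cohort,
    definitive_cessation_probability, full_coverage_strategy,
    life_years, no_coverage_strategy, participation_rate, run_cohort,
)


class TestCessationParameters:
    def test_multiplicative_construction(self):
        p = definitive_cessation_probability(0.026, (1.95, 1.39))
        assert p == pytest.approx(0.026 * 1.95 * 1.39)
        assert p == pytest.approx(0.0704, abs=5e-4)

    def test_odds_scale_is_lower(self):
        assert (definitive_cessation_probability(scale="odds")
                < definitive_cessation_probability(scale="multiplicative"))

    def test_participation(self):
        assert participation_rate() == pytest.approx(0.073)


class TestLifeExpectancyConversion:
    def test_boundary_values(self):
        assert annual_death_probability_from_life_expectancy(1.0) == 1.0
        assert annual_death_probability_from_life_expectancy(2.0) == 0.5
        assert annual_death_probability_from_life_expectancy(20.0) == 0.05
        with pytest.raises(ConfigurationError):
            annual_death_probability_from_life_expectancy(0.5)

    def test_geometric_lifetimes_have_mean_le(self):
        """Simulated geometric lifetimes with p = 1/LE average to LE."""
        rng = np.random.default_rng(0)
        p = annual_death_probability_from_life_expectancy(20.0)
        draws = rng.geometric(p, size=200_000)
        se = np.sqrt((1 - p) / p**2 / draws.size)
        assert abs(draws.mean() - 20.0) < 4 * se

    def test_exponential_mode(self):
        p = annual_death_probability_from_life_expectancy(2.0, "exponential")
        assert p == pytest.approx(1.0 - np.exp(-0.5))


class TestTransitionRows:
    def test_dead_is_absorbing(self, synthetic_tables):
        row = build_transition_row("D", "male", 40, 0, full_coverage_strategy(),
                                   synthetic_tables, DiseaseSurvivalSpec())
        assert row == {"D": 1.0}

    def test_zero_mortality_identity(self, zero_mortality_tables):
        strategy = StrategySpec(participation=0, attempt_cessation_prob=0,
                                natural_cessation_prob=0, n_attempts=0,
                                consult_cost=0, drug_cost=0)
        row = build_transition_row("S", "male", 40, 0, strategy,
                                   zero_mortality_tables, DiseaseSurvivalSpec())
        assert row["S"] == 1.0
        assert sum(row.values()) == 1.0

    def test_disease_row_uses_life_expectancy(self, synthetic_tables):
        row = build_transition_row("C", "male", 60, 0, full_coverage_strategy(),
                                   synthetic_tables, DiseaseSurvivalSpec(),
                                   age_at_diagnosis=58, status_at_diagnosis="current")
        assert row["D"] == pytest.approx(0.5)  # lung cancer: two-year LE
        assert row["C"] == pytest.approx(0.5)

    def test_row_oracle_equivalence(self, synthetic_tables):
        """Row assembly equals an independent, scalar re-implementation."""
        tables = synthetic_tables
        strategy = full_coverage_strategy()
        survival = DiseaseSurvivalSpec()
        rng = np.random.default_rng(17)
        for _ in range(50):
            gender = ("male", "female")[rng.integers(2)]
            age = int(rng.integers(15, 100))
            cycle = int(rng.integers(0, 8))
            participant = bool(rng.integers(2))
            row = build_transition_row("S", gender, age, cycle, strategy, tables,
                                       survival, participant=participant)
            gi = ("male", "female").index(gender)
            ai = age - 15
            cess = (strategy.attempt_cessation_prob
                    if participant and strategy.is_attempt_cycle(cycle)
                    else strategy.natural_cessation_prob)
            expected = {
                "C": tables.disease.probs[gi, ai, 1, 0],
                "O": tables.disease.probs[gi, ai, 1, 1],
                "V": tables.disease.probs[gi, ai, 1, 2],
                "D": tables.residual[gi, ai, 1],
                "F1": cess,
            }
            expected["S"] = 1.0 - sum(expected.values())
            for key, val in expected.items():
                assert row[key] == pytest.approx(val, abs=1e-15)
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

            d = int(rng.integers(1, 20))
            frow = build_transition_row("F", gender, age, cycle, strategy, tables,
                                        survival, years_since_quit=d)
            assert sum(frow.values()) == pytest.approx(1.0, abs=1e-12)
            nxt = f"F{min(d + 1, tables.tunnel_length)}"
            assert nxt in frow  # tunnel advances one year per cycle

    def test_overallocation_raises(self, synthetic_tables):
        bad = synthetic_tables.disease.copy()
        bad.probs[0, 84, 1, :] = 0.4  # age 99: disease sum 1.2 on its own
        tables = MortalityTables(disease=bad, all_cause=synthetic_tables.all_cause,
                                 rr=synthetic_tables.rr)
        with pytest.raises(ModelConsistencyError):
            build_transition_row("S", "male", 99, 0, full_coverage_strategy(),
                                 tables, DiseaseSurvivalSpec())


class TestRunCohort:
    def test_zero_mortality_conserves_cohort(self, zero_mortality_tables):
        cohort = default_french_smoker_cohort()
        trace = run_cohort(cohort, full_coverage_strategy(), zero_mortality_tables,
                           horizon=10)
        alive = trace.alive().sum(axis=0)
        np.testing.assert_allclose(alive[:10], 1000.0, rtol=1e-12)
        assert trace.occ_d[:, :10].sum() == 0.0

    def test_arm_symmetry_without_extra_effect(self, base_inputs):
        """An arm whose attempts carry only the natural rate matches the
        natural-only comparator in effect (costs may differ)."""
        full_like = full_coverage_strategy(attempt_cessation_prob=0.026)
        trace_a = run_cohort(base_inputs.cohort, full_like, base_inputs.tables)
        trace_b = run_cohort(base_inputs.cohort, no_coverage_strategy(), base_inputs.tables)
        assert life_years(trace_a, 0.0) == pytest.approx(life_years(trace_b, 0.0), rel=1e-12)

    def test_conservation_and_monotone_death(self, base_inputs):
        trace = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        weights = np.array([s.weight for s in base_inputs.cohort.strata])
        total = trace.alive() + trace.occ_d
        np.testing.assert_allclose(
            total, np.broadcast_to(weights[:, None], total.shape), rtol=1e-9)
        assert np.all(np.diff(trace.occ_d, axis=1) >= -1e-9)

    def test_scale_equivariance(self, base_inputs):
        """Doubling stratum weights doubles life-years."""
        doubled = base_inputs.cohort.scaled(2.0)
        t1 = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        t2 = run_cohort(doubled, base_inputs.full, base_inputs.tables)
        assert life_years(t2, 0.03) == pytest.approx(2 * life_years(t1, 0.03), rel=1e-12)

    def test_more_effective_cessation_gains_life_years(self, base_inputs):
        lys = []
        for p in (0.03, 0.0704, 0.15):
            strat = full_coverage_strategy(attempt_cessation_prob=p)
            lys.append(life_years(run_cohort(base_inputs.cohort, strat,
                                             base_inputs.tables), 0.0))
        assert lys[0] <= lys[1] <= lys[2]

    def test_everyone_starts_smoking(self, base_inputs):
        trace = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        assert (trace.occ_s_part[:, 0] + trace.occ_s_non[:, 0]).sum() == pytest.approx(1000.0)
        assert trace.occ_f[:, 0].sum() == 0.0

    def test_lifetime_run_ends_dead(self, base_inputs):
        trace = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        assert trace.occ_d[:, -1].sum() == pytest.approx(1000.0)

    def test_attempt_schedule(self, base_inputs):
        """Covered attempts land at cycles 0, f, 2f, ... while smoking."""
        trace = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        attempt_cycles = np.nonzero(trace.attempts.sum(axis=0))[0]
        np.testing.assert_array_equal(attempt_cycles, [0, 2, 4, 6])
        assert trace.attempts[:, 0].sum() == pytest.approx(73.0)  # 7.3% of 1,000
        # re-attempts only among those still smoking: counts strictly decrease
        totals = trace.attempts.sum(axis=0)[[0, 2, 4, 6]]
        assert np.all(np.diff(totals) < 0)


class TestLifeYears:
    def test_all_dead_at_start_is_zero(self, base_inputs):
        trace = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables,
                           horizon=2)
        dead = CohortTrace(
            cohort=trace.cohort, strategy=trace.strategy,
            occ_s_part=np.zeros_like(trace.occ_s_part),
            occ_s_non=np.zeros_like(trace.occ_s_non),
            occ_f=np.zeros_like(trace.occ_f), occ_dis=np.zeros_like(trace.occ_dis),
            occ_d=np.zeros_like(trace.occ_d) + 1000.0 / trace.occ_d.shape[0],
            inc=trace.inc, deaths=trace.deaths, attempts=trace.attempts, snapshots={})
        assert life_years(dead, 0.0) == 0.0

    def test_two_cycles_alive_counts_two_years_each(self, zero_mortality_tables):
        cohort = default_french_smoker_cohort()
        trace = run_cohort(cohort, no_coverage_strategy(), zero_mortality_tables,
                           horizon=2)
        assert life_years(trace, 0.0) == pytest.approx(2000.0)

    def test_discounting_shrinks_life_years(self, base_inputs):
        trace = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        assert life_years(trace, 0.06) < life_years(trace, 0.03) < life_years(trace, 0.0)


class TestCauseSpecificDeaths:
    def test_identical_traces_avoid_nothing(self, base_inputs):
        trace = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        avoided = cause_specific_deaths(trace, trace)
        assert all(v == 0.0 for v in avoided.values())

    def test_constructed_difference(self, base_inputs):
        t1 = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        t2 = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        t1.deaths = t1.deaths.copy()
        t1.deaths[0, 5, 0] += 1.0  # one extra lung-cancer death in arm A
        avoided = cause_specific_deaths(t1, t2)
        assert avoided["lung_cancer"] == pytest.approx(1.0)  # per 1,000 of 1,000
        assert avoided["copd"] == 0.0

    def test_subtraction_oracle(self, base_inputs):
        strat_hi = full_coverage_strategy(attempt_cessation_prob=0.15)
        t_comp = run_cohort(base_inputs.cohort, base_inputs.comparator, base_inputs.tables)
        t_full = run_cohort(base_inputs.cohort, strat_hi, base_inputs.tables)
        avoided = cause_specific_deaths(t_comp, t_full)
        for ci, cause in enumerate(DISEASES):
            expected = (t_comp.deaths[:, :, ci].sum() - t_full.deaths[:, :, ci].sum())
            assert avoided[cause] == pytest.approx(expected)  # cohort size is 1,000

    def test_mismatched_cohorts_rejected(self, base_inputs, small_cohort):
        t1 = run_cohort(base_inputs.cohort, base_inputs.full, base_inputs.tables)
        t2 = run_cohort(small_cohort, base_inputs.full, base_inputs.tables)
        with pytest.raises(ConfigurationError):
            cause_specific_deaths(t1, t2)


class TestStrategyValidation:
    def test_probability_bounds(self):
        with pytest.raises(ConfigurationError):
            StrategySpec(participation=1.5)
        with pytest.raises(ConfigurationError):
            StrategySpec(attempt_frequency_years=0)

    def test_cohort_bounds(self):
        with pytest.raises(ConfigurationError):
            Stratum("male", 80, 1.0)
        with pytest.raises(ConfigurationError):
            CohortSpec(())
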