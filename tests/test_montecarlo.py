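"""Lifetime simulator: determinism, accounting identities and limiting cases."""

import numpy as np
import pandas as pd
import pytest

from sealskip.montecarlo import (
    ALWAYS_BREED,
    cohens_d,
    run_cohort,
    simulate_individual,
    skip_count_distribution,
)
from sealskip.params import ModelParams, UncertainParam
from sealskip.sdp import solve
from sealskip.survival import pup_survival


def _sustainable_start(params: ModelParams) -> ModelParams:
    """Start females at 600 kg, where annual breeding is mass-sustaining."""
    return params.replace(
        init_mass_slope=UncertainParam(0.0, 0.0),
        init_mass_intercept=UncertainParam(600.0, 0.0),
    )


class TestSimulateIndividual:
    def test_deathless_limit(self, det_params):
        # no parameter noise, certain survival, good years, large female:
        # an annual breeder lives all ten years and attempts every year
        p = _sustainable_start(det_params).replace(s_max=1.0, x_cutoff=140.0)
        rec = simulate_individual(ALWAYS_BREED, p, 0)
        assert rec.age_at_death == 13
        assert rec.n_attempts == 10
        assert rec.n_skips == 0

    def test_declining_annual_breeder_starves(self, det_params):
        # from the regression-mean initial mass (426.8 kg) annual breeding
        # shrinks body mass every year until the post-lactation nadir crosses
        # the critical mass; certain survival cannot prevent starvation
        p = det_params.replace(s_max=1.0, x_cutoff=140.0)
        rec = simulate_individual(ALWAYS_BREED, p, 0)
        assert rec.age_at_death < 13
        assert not rec.years[-1].mother_survived

    def test_immediate_death_limit(self, det_params):
        p = det_params.replace(s_max=0.0)
        rec = simulate_individual(ALWAYS_BREED, p, 5)
        assert rec.age_at_death == 4
        assert len(rec.years) == 1
        assert rec.lifetime_reproductive_output <= 1

    def test_seed_reproducibility(self, default_params):
        policy = solve(default_params)
        a = simulate_individual(policy, default_params, 123)
        b = simulate_individual(policy, default_params, 123)
        assert a == b


class TestRunCohort:
    def test_summary_table_shape(self, default_params):
        s = run_cohort("annual", default_params, 25, 0)
        assert s.n == 25
        assert len(s.table) == 25
        assert set(s.table.columns) >= {"lro", "longevity", "attempts", "skips"}

    def test_bit_identical_under_seed(self, default_params):
        a = run_cohort("optimal", default_params, 40, 9)
        b = run_cohort("optimal", default_params, 40, 9)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert np.array_equal(a.wean_masses, b.wean_masses)

    def test_attempts_plus_skips_equal_years_alive(self, default_params):
        s = run_cohort("optimal", default_params, 60, 2, keep_records=True)
        for rec in s.records:
            years_alive = rec.age_at_death - default_params.age_first + 1
            assert rec.n_attempts + rec.n_skips == years_alive == len(rec.years)
            assert rec.lifetime_reproductive_output <= rec.n_attempts

    def test_optimal_dominates_annual(self, default_params):
        n = 400
        opt = run_cohort("optimal", default_params, n, 7)
        ann = run_cohort("annual", default_params, n, 8)
        assert opt.lro.mean() >= ann.lro.mean()

    def test_degenerate_variance_gives_identical_individuals(self, det_params):
        # no parameter noise, certain survival, no bad years, and a single
        # pup-mass intercept (so pup sex is inconsequential): every female's
        # mass trajectory, decisions and lifespan coincide exactly
        p = _sustainable_start(det_params).replace(
            s_max=1.0,
            x_cutoff=140.0,
            pup_intercept_high=UncertainParam(47.8, 0.0),
        )
        s = run_cohort("optimal", p, 15, 4)
        assert s.table[["longevity", "attempts", "skips"]].nunique().max() == 1
        assert np.allclose(s.wean_masses, s.wean_masses[0])

    def test_annual_cohort_never_skips(self, default_params):
        s = run_cohort("annual", default_params, 30, 1)
        hist = skip_count_distribution(s)
        assert hist.index.tolist() == [0]
        assert hist.sum() == 30

    def test_unknown_strategy(self, default_params):
        with pytest.raises(ValueError):
            run_cohort("sometimes", default_params, 5, 0)

    def test_n_one_summary(self, default_params):
        s = run_cohort("annual", default_params, 1, 0)
        desc = s.describe()
        assert np.isnan(desc.loc["lro", "sd"])
        assert desc.loc["lro", "mean"] == s.table.lro.iloc[0]

    def test_pup_survival_frequencies_match_step_function(self, det_params):
        # empirical first-year survival per weaning-mass bin vs the step
        # probabilities, within binomial error (deterministic parameters so
        # the bin probabilities are exact)
        p = _sustainable_start(det_params).replace(s_max=1.0, x_cutoff=140.0)
        s = run_cohort("annual", p, 400, 3, keep_records=True)
        outcomes: dict[float, list[bool]] = {}
        for rec in s.records:
            for yr in rec.years:
                if yr.pup_born:
                    prob = pup_survival(yr.wean_mass, p)
                    outcomes.setdefault(prob, []).append(yr.pup_survived)
        assert outcomes
        for prob, flags in outcomes.items():
            k = len(flags)
            if k < 30:
                continue
            se = np.sqrt(prob * (1 - prob) / k)
            assert abs(np.mean(flags) - prob) <= max(4 * se, 1e-12)


class TestCohensD:
    def test_unit_effect_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 20000)
        b = rng.normal(0.0, 1.0, 20000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_identical_cohorts_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(x, x) == 0.0

    def test_antisymmetry(self):
        a = np.array([1.0, 2.0, 5.0])
        b = np.array([0.5, 1.0, 2.0])
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_exact_value(self):
        # means one apart, both sample SD 1, equal n -> d = 1
        a = np.array([0.0, 2.0]) + 1.0
        b = np.array([0.0, 2.0])
        assert cohens_d(a, b) == pytest.approx(1.0 / np.sqrt(2))  # sd = sqrt(2)
        a = np.array([1.0, 2.0, 3.0]) + 1.0
        b = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])
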