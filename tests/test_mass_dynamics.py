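"""Annual mass budget: hand-computed values and structural properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sealskip.mass_dynamics import (
    annual_transition,
    breeding_loss,
    expected_pup_birth_mass,
    foraging_gain,
    initial_mass,
    molt_loss,
    pup_birth_mass,
    wean_mass,
)
from sealskip.params import ModelParams

P = ModelParams()


class TestPupBirthMass:
    def test_low_intercept_branch(self):
        # female pup of a 380-kg mother
        expected = 47.8 - 107 * np.exp(-0.0055 * 380)
        assert pup_birth_mass(380.0, P, sex_draw=0.9) == pytest.approx(expected)
        assert expected == pytest.approx(34.565, abs=5e-3)

    def test_high_intercept_branch(self):
        expected = 52.6 - 107 * np.exp(-0.0055 * 380)
        assert pup_birth_mass(380.0, P, sex_draw=0.2) == pytest.approx(expected)
        assert expected == pytest.approx(39.365, abs=5e-3)

    def test_small_mother_always_low_branch(self):
        assert pup_birth_mass(300.0, P, 0.1) == pup_birth_mass(300.0, P, 0.9)

    def test_negative_extrapolation_floored(self):
        # at the critical mass the regression goes negative: pup fails
        assert pup_birth_mass(140.0, P, 0.5) == 0.0

    def test_expected_is_branch_average(self):
        low = pup_birth_mass(380.0, P, 1.0)
        high = pup_birth_mass(380.0, P, 0.0)
        assert expected_pup_birth_mass(380.0, P) == pytest.approx((low + high) / 2)
        assert expected_pup_birth_mass(380.0, P) == pytest.approx(36.965, abs=5e-3)

    def test_expected_below_threshold_single_branch(self):
        assert expected_pup_birth_mass(300.0, P) == pup_birth_mass(300.0, P, 0.7)

    def test_expected_within_branch_interval(self):
        x = P.x_max
        low, high = pup_birth_mass(x, P, 1.0), pup_birth_mass(x, P, 0.0)
        assert low <= expected_pup_birth_mass(x, P) <= high


class TestStageComponents:
    def test_breeding_loss_values(self):
        assert breeding_loss(500.0, P) == pytest.approx((0.013 * 500 + 2.48) * 22.1)
        assert breeding_loss(500.0, P) == pytest.approx(198.458)
        assert breeding_loss(0.0, P) == pytest.approx(2.48 * 22.1)

    def test_breeding_loss_monotone(self):
        assert breeding_loss(600.0, P) > breeding_loss(300.0, P)

    @pytest.mark.parametrize(
        "m, period, breeder, bad, expected",
        [
            (400.0, "postbreed", True, False, 146.8),
            (400.0, "postbreed", False, False, 200.0),
            (400.0, "postmolt", True, False, 266.4),
            (400.0, "postmolt", True, True, 0.75 * 266.4),
            (400.0, "postbreed", True, True, 0.75 * 146.8),
        ],
    )
    def test_foraging_gain(self, m, period, breeder, bad, expected):
        assert foraging_gain(m, period, breeder, bad, P) == pytest.approx(expected)

    def test_nonbreeder_gains_more(self):
        for m in (0.0, 200.0, 800.0):
            assert foraging_gain(m, "postbreed", False, False, P) >= foraging_gain(
                m, "postbreed", True, False, P
            )

    def test_unknown_period_rejected(self):
        with pytest.raises(ValueError):
            foraging_gain(400.0, "winter", True, False, P)

    def test_molt_loss_values(self):
        assert molt_loss(500.0, P) == pytest.approx((0.0396 * 500 + 1.92) * 4.58)
        assert molt_loss(500.0, P) == pytest.approx(99.4776)
        assert molt_loss(0.0, P) == pytest.approx(1.92 * 4.58)
        assert molt_loss(600.0, P) > molt_loss(500.0, P)

    def test_molt_duration_floored_at_zero(self):
        neg = P.replace(molt_days_intercept=P.molt_days_intercept.__class__(-50.0, 0.0))
        assert molt_loss(0.0, neg) == 0.0

    def test_wean_mass_values(self):
        assert wean_mass(500.0, P) == pytest.approx(116.957)
        assert wean_mass(1000.0, P) == 160.0  # cap engages
        assert wean_mass(0.0, P) == pytest.approx(31.457)

    def test_initial_mass_point_estimates(self):
        assert initial_mass(4, P.with_means()) == pytest.approx(426.8)
        assert initial_mass(13, P.with_means()) == pytest.approx(608.6)

    def test_initial_mass_sampling_mean(self):
        rng = np.random.default_rng(3)
        n = 10_000
        draws = np.array([initial_mass(4, P, rng) for _ in range(n)])
        sd = np.hypot(4 * P.init_mass_slope.sd, P.init_mass_intercept.sd)
        assert abs(draws.mean() - 426.8) < 3 * sd / np.sqrt(n)


class TestAnnualTransition:
    def test_nonbreeder_stage_chain(self):
        # sequential evaluation at point estimates from 400 kg:
        # +200 (non-breeder trip), molt 25.68 d at 4.58 kg/d, +0.666x post-molt
        t = annual_transition(400.0, breed=False, bad_year=False, params=P)
        assert t.postbreed_gain == pytest.approx(200.0)
        assert t.molt_loss == pytest.approx(117.6144)
        assert t.postmolt_gain == pytest.approx(0.666 * 482.3856)
        assert t.end_mass == pytest.approx(803.654, abs=1e-3)
        assert not t.died_of_starvation

    def test_breeder_at_critical_mass_starves(self):
        t = annual_transition(140.0, breed=True, bad_year=False, params=P, sex_draw=0.7)
        assert t.died_of_starvation
        assert t.starved_before_weaning()

    def test_deterministic(self):
        a = annual_transition(500.0, True, False, P, sex_draw=0.3)
        b = annual_transition(500.0, True, False, P, sex_draw=0.3)
        assert a == b

    def test_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            annual_transition(100.0, False, False, P)
        with pytest.raises(ValueError):
            annual_transition(2000.0, False, False, P)

    @given(
        x=st.floats(min_value=140.0, max_value=1060.0),
        breed=st.booleans(),
        bad=st.booleans(),
        sex=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_stage_components_reconstruct_end_mass(self, x, breed, bad, sex):
        t = annual_transition(x, breed, bad, P, sex_draw=sex)
        if breed:
            raw = (
                x
                - t.pup_birth_mass
                - t.breeding_loss
                + t.postbreed_gain
                - t.molt_loss
                + t.postmolt_gain
            )
        else:
            raw = x + t.postbreed_gain - t.molt_loss + t.postmolt_gain
        assert t.end_mass == pytest.approx(min(raw, P.x_max), abs=1e-9)

    @pytest.mark.parametrize("breed", [True, False])
    @pytest.mark.parametrize("bad", [True, False])
    def test_end_mass_monotone_in_start_mass(self, breed, bad):
        masses = np.arange(140.0, 1060.1, 10.0)
        ends = [
            annual_transition(x, breed, bad, P, sex_draw=None).end_mass
            for x in masses
        ]
        assert np.all(np.diff(ends) >= -1e-9)

    def test_bad_year_dominated_by_good(self):
        for x in np.arange(140.0, 1060.1, 10.0):
            for breed in (True, False):
                good = annual_transition(x, breed, False, P, sex_draw=None)
                bad = annual_transition(x, breed, True, P, sex_draw=None)
                assert bad.end_mass <= good.end_mass + 1e-9
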