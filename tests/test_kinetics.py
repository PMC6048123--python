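"""Bell kinetics: rates, survival, waiting-time sampling, calibration."""

import math

import numpy as np
import pytest
from scipy import stats

from pilusmech import (
    CENSORED,
    BellParams,
    ConstantForce,
    LinearRamp,
    TabulatedSchedule,
    builtin_domain,
    calibrate_bell,
    draw_waiting_time,
    rate_at_force,
    refold_probability,
    survival_probability,
)
from pilusmech.kinetics import (
    RefoldingCondition,
    ramp_rupture_cdf,
    ramp_rupture_quantile,
    ramp_mean_rupture_force,
    solve_ramp_k0,
)
from pilusmech.registry import build_construct
from pilusmech.simulate import Protocol, mean_fx_rupture_force


class TestRate:
    def test_zero_force_gives_intrinsic_rate(self):
        p = BellParams(0.01, 0.2)
        assert rate_at_force(0.0, p) == pytest.approx(0.01)

    def test_zero_distance_is_force_independent(self):
        p = BellParams(0.01, 0.0)
        assert rate_at_force(500.0, p) == pytest.approx(0.01)

    def test_exponential_force_dependence(self):
        p = BellParams(0.01, 0.2)
        assert rate_at_force(100.0, p, 4.114) == pytest.approx(1.29, abs=0.01)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            BellParams(0.0, 0.2)
        with pytest.raises(ValueError):
            BellParams(0.01, -0.1)


class TestSurvival:
    def test_unit_at_zero_time(self):
        assert survival_probability(100.0, 0.0, BellParams(1.0, 0.1)) == 1.0

    def test_oxidized_fimg_five_seconds(self):
        # k(300 pN) = 0.94/s barely survives a 5 s pulse
        p = BellParams(0.94, 0.0)
        assert survival_probability(300.0, 5.0, p) == pytest.approx(0.00909,
                                                                    abs=2e-4)

    def test_refolding_timescale(self):
        p = BellParams(0.021, 0.0)
        assert survival_probability(0.0, 45.0, p) == pytest.approx(0.389, abs=1e-3)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(100.0, -1.0, BellParams(1.0, 0.1))


class TestWaitingTimes:
    def test_constant_force_mean(self, rng):
        p = BellParams(1.0, 0.0)
        sched = ConstantForce(force=10.0, duration=1e9)
        draws = np.array([draw_waiting_time(sched, p, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.01)

    def test_negligible_rate_always_censored(self, rng):
        p = BellParams(1e-300, 0.0)
        sched = ConstantForce(force=10.0, duration=100.0)
        assert draw_waiting_time(sched, p, rng) == CENSORED

    def test_constant_force_matches_survival(self, rng):
        p = BellParams(0.5, 0.1)
        k = rate_at_force(50.0, p)
        sched = ConstantForce(force=50.0, duration=1e9)
        draws = np.array([draw_waiting_time(sched, p, rng) for _ in range(10_000)])
        res = stats.kstest(draws, "expon", args=(0, 1.0 / k))
        assert res.pvalue > 0.01

    def test_linear_ramp_matches_closed_form(self, rng):
        p = BellParams(1e-4, 0.25)
        sched = LinearRamp(start_force=0.0, load_rate=10.0, duration=1e5)
        times = np.array([draw_waiting_time(sched, p, rng) for _ in range(10_000)])
        forces = 10.0 * times
        res = stats.kstest(forces, lambda f: ramp_rupture_cdf(f, p, 10.0, 0.0))
        assert res.pvalue > 0.01

    def test_tabulated_schedule_agrees_with_ramp(self, rng):
        p = BellParams(1e-4, 0.25)
        t = np.linspace(0.0, 40.0, 2001)
        tab = TabulatedSchedule(t, 10.0 * t)
        draws = np.array([draw_waiting_time(tab, p, rng) for _ in range(5_000)])
        draws = draws[np.isfinite(draws)]
        res = stats.kstest(10.0 * draws,
                           lambda f: ramp_rupture_cdf(f, p, 10.0, 0.0))
        assert res.pvalue > 0.01

    def test_censoring_beyond_schedule(self, rng):
        p = BellParams(1e-9, 0.0)
        assert draw_waiting_time(ConstantForce(10.0, 1.0), p, rng) == CENSORED


class TestRampClosedForms:
    def test_quantile_inverts_cdf(self):
        p = BellParams(1e-4, 0.25)
        u = np.linspace(0.01, 0.99, 25)
        f = ramp_rupture_quantile(u, p, 10.0, 0.0)
        assert np.allclose(ramp_rupture_cdf(f, p, 10.0, 0.0), u, atol=1e-9)

    def test_solve_k0_round_trip(self):
        k0 = solve_ramp_k0(281.0, 0.19, 10.0)
        mean = ramp_mean_rupture_force(BellParams(k0, 0.19), 10.0)
        assert mean == pytest.approx(281.0, rel=1e-4)


class TestCalibration:
    def test_ramp_calibration_reproduced_by_sampling(self, rng):
        protocol = Protocol.force_ramp()
        params = calibrate_bell(281.0, protocol, dx_prior=0.19)
        draws = ramp_rupture_quantile(rng.random(20_000), params, 10.0, -10.0)
        observed = draws[draws < 400.0]
        assert observed.mean() == pytest.approx(281.0, rel=0.02)

    def test_force_extension_calibration_round_trip(self):
        # I91 handle: target ~200 pN at 400 nm/s with the conventional dx
        construct = build_construct("I91x2-FimG-I91x2")
        protocol = Protocol.force_extension(400.0)
        params = calibrate_bell(
            200.0, protocol, dx_prior=0.25, construct=construct, domain="I91",
            n_events=2000, seed=0,
        )
        mean = mean_fx_rupture_force(
            construct, protocol, "I91", params, n_events=2000, seed=99
        )
        assert 196.0 <= mean <= 204.0

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_bell(-5.0, Protocol.force_ramp(), 0.2)


class TestRefoldProbability:
    def setup_method(self):
        self.cond = RefoldingCondition("ox_alone", fold_rate=0.021,
                                       fold_plateau=1.0)

    def test_zero_quench(self):
        assert refold_probability(0.0, self.cond) == 0.0

    def test_full_plateau_45s(self):
        assert refold_probability(45.0, self.cond) == pytest.approx(0.611,
                                                                    abs=1e-3)

    def test_partial_plateau(self):
        cond = RefoldingCondition("ox_alone", fold_rate=0.04, fold_plateau=0.7)
        assert refold_probability(60.0, cond) == pytest.approx(0.636, abs=1e-3)

    def test_monotone_and_bounded(self):
        cond = RefoldingCondition("ox_FimC", fold_rate=0.021, fold_plateau=0.85)
        times = np.linspace(0, 300, 50)
        probs = [refold_probability(t, cond) for t in times]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert max(probs) <= cond.fold_plateau

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            RefoldingCondition("bogus", 0.02, 0.5)


def test_shipped_redox_rate_ratio_at_300pn():
    """Reduced FimG unfolds ~30x faster than oxidized at 300 pN."""
    g = builtin_domain("FimG")
    ratio = rate_at_force(300.0, g.bell_red) / rate_at_force(300.0, g.bell_ox)
    assert ratio == pytest.approx(29.9 / 0.94, rel=1e-3)
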