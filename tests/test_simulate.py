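"""Simulator: trace morphology, event statistics, noise, ground-truth logs."""

import numpy as np
import pytest

from pilusmech import (
    BellParams,
    NoiseModel,
    Protocol,
    add_noise,
    build_construct,
    builtin_condition,
    default_quaternary_model,
    parse_pulses,
    refold_probability,
    simulate_force_clamp,
    simulate_force_extension,
    simulate_force_ramp,
)
from pilusmech.registry import QuaternaryStepModel
from pilusmech.simulate import (
    CLEAN,
    mean_fx_rupture_force,
    refold_3pulse_protocol,
)


class TestProtocol:
    def test_pulse_grammar(self):
        assert parse_pulses("160:2,300:20,0:45") == ((160, 2), (300, 20), (0, 45))

    def test_bad_pulse_token(self):
        with pytest.raises(ValueError, match="position"):
            parse_pulses("160:2,banana")

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            Protocol(mode="squeeze")
        with pytest.raises(ValueError):
            Protocol.force_clamp([(160, -1)])


class TestForceExtension:
    def test_sawtooth_event_structure(self):
        """Every FimA pull shows 5 unfolding peaks then detachment."""
        c = build_construct("I91x2-FimA-I91x2")
        proto = Protocol.force_extension(400.0)
        for seed in range(10):
            tr = simulate_force_extension(c.copy(), proto, CLEAN, seed=seed)
            kinds = [e.kind for e in tr.events]
            assert kinds.count("unfold") == 5
            assert kinds[-1] == "detach"
            # unfold-before-detach ordering
            assert all(k == "unfold" for k in kinds[:-1])

    def test_inert_domains_give_single_wlc_curve(self):
        from dataclasses import replace

        c = build_construct("I91x2-FimA-I91x2")
        frozen = BellParams(1e-300, 0.1)
        for d in c.domains:
            d.spec = replace(d.spec, bell_ox=frozen, bell_red=frozen)
        tr = simulate_force_extension(c, Protocol.force_extension(), CLEAN, seed=0)
        assert sum(e.kind == "unfold" for e in tr.events) == 0
        before_detach = tr.time < tr.events[-1].time
        assert np.all(np.diff(tr.force[before_detach]) >= -1e-9)

    def test_calibrated_fima_mean_force(self):
        """Ground-truth FimA rupture forces average to the calibration target."""
        c = build_construct("I91x2-FimA-I91x2")
        mean = mean_fx_rupture_force(c, Protocol.force_extension(), "FimA",
                                     n_events=2000, seed=42)
        assert mean == pytest.approx(527.0, rel=0.02)

    def test_seed_reproducibility(self):
        c = build_construct("I91x2-FimG-I91x2")
        proto = Protocol.force_extension()
        a = simulate_force_extension(c.copy(), proto, seed=7)
        b = simulate_force_extension(c.copy(), proto, seed=7)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.extension, b.extension)
        assert a.metadata["seed"] == 7


class TestForceRamp:
    def test_tip_fibrillum_step_count(self):
        """All eight rupturing units (4 I91 + FimF + FimG + FimH_L + FimH_P)
        unfold within the -10..400 pN ramp."""
        c = build_construct("I91x2-FimF-FimG-FimH-I91x2")
        proto = Protocol.force_ramp()
        counts = []
        for seed in range(20):
            tr = simulate_force_ramp(c.copy(), proto, None, CLEAN, seed=seed)
            counts.append(sum(e.kind == "unfold" for e in tr.events))
        assert np.mean(counts) == pytest.approx(8.0, abs=0.2)

    def test_no_quaternary_when_disabled(self):
        c = build_construct("I91x2-FimF-FimG-FimH-I91x2")
        quat = QuaternaryStepModel(occurrence_prob=0.0)
        for seed in range(10):
            tr = simulate_force_ramp(c.copy(), Protocol.force_ramp(), quat,
                                     CLEAN, seed=seed)
            assert not any(e.kind == "quaternary_step" for e in tr.events)

    def test_quaternary_trace_fraction(self):
        c = build_construct("I91x2-FimF-FimG-FimH-I91x2")
        quat = default_quaternary_model()
        rng = np.random.default_rng(2)
        n = 300
        hits = 0
        for _ in range(n):
            tr = simulate_force_ramp(c.copy(), Protocol.force_ramp(), quat,
                                     rng=rng, events_only=True)
            hits += any(e.kind == "quaternary_step" for e in tr.events)
        # binomial 95% CI around the 50% occurrence probability
        assert abs(hits / n - 0.5) < 2.5 * np.sqrt(0.25 / n)

    def test_extension_is_a_staircase(self):
        c = build_construct("I91x2-FimF-FimG-FimH-I91x2")
        tr = simulate_force_ramp(c.copy(), Protocol.force_ramp(), None, CLEAN,
                                 seed=3)
        for e in tr.events:
            i = np.searchsorted(tr.time, e.time)
            if 1 < i < len(tr.time) - 1:
                jump = tr.extension[i] - tr.extension[i - 1]
                assert jump == pytest.approx(e.size, abs=1.0)


class TestForceClamp:
    def test_oxidized_fimg_staircase(self):
        cond = builtin_condition("ox_alone")
        c = build_construct("I91x2-FimG-I91x2")
        proto = Protocol.force_clamp([(160, 2), (300, 20)])
        tr = simulate_force_clamp(c.copy(), proto, cond, CLEAN, seed=1)
        at160 = [e for e in tr.events if e.force == 160 and e.kind == "unfold"]
        at300 = [e for e in tr.events if e.force == 300 and e.kind == "unfold"]
        assert len(at160) == 4 and len(at300) == 1
        assert np.mean([e.size for e in at160]) == pytest.approx(25.0, abs=2.0)
        assert at300[0].size == pytest.approx(33.0, abs=2.0)

    def test_reduced_fimg_single_45nm_step(self):
        cond = builtin_condition("red_alone")
        c = build_construct("I91x2-FimG-I91x2")
        proto = Protocol.force_clamp([(160, 2), (300, 20)])
        tr = simulate_force_clamp(c.copy(), proto, cond, CLEAN, seed=1)
        fimg = [e for e in tr.events if e.domain == "FimG"]
        assert len(fimg) == 1
        assert fimg[0].size == pytest.approx(45.0, abs=2.0)

    def test_pulsewise_extension_conservation(self):
        """Within each force pulse the net (noise-free) extension change
        equals the summed event sizes of that pulse."""
        cond = builtin_condition("red_DsbA")
        c = build_construct("I91x2-FimG-I91x2")
        proto = Protocol.force_clamp(
            [(160, 2), (300, 5), (100, 2), (0, 45), (160, 2), (300, 5), (100, 2)]
        )
        for seed in range(10):
            tr = simulate_force_clamp(c.copy(), proto, cond, CLEAN, seed=seed)
            t0 = 0.0
            for f_pulse, dur in proto.pulses:
                sel = (tr.time >= t0) & (tr.time < t0 + dur)
                if f_pulse > 0 and np.any(sel):
                    tt = tr.time[sel]
                    net = tr.extension[sel][-1] - tr.extension[sel][0]
                    total = sum(
                        e.size
                        for e in tr.events
                        if e.kind in ("unfold", "reduce")
                        and tt[0] < e.time <= tt[-1]
                    )
                    assert net == pytest.approx(total, abs=1e-9)
                t0 += dur

    def test_refolding_fraction_matches_model(self):
        """Fraction of traces whose FimG refolds in a 45 s quench follows the
        plateaued-exponential refolding probability."""
        cond = builtin_condition("red_alone")
        c = build_construct("I91x2-FimG-I91x2")
        proto = Protocol.force_clamp([(160, 2), (300, 5), (0, 45), (300, 5)])
        rng = np.random.default_rng(5)
        n, hits = 300, 0
        for _ in range(n):
            tr = simulate_force_clamp(c.copy(), proto, cond, CLEAN, rng=rng)
            hits += any(
                e.kind == "refold" and e.domain == "FimG" for e in tr.events
            )
        expected = refold_probability(45.0, cond)
        assert abs(hits / n - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_dsba_redox_chemistry(self):
        """red_DsbA traces show reduction steps at 100 pN and reoxidation
        during quenches at the configured probabilities."""
        cond = builtin_condition("red_DsbA")
        c = build_construct("I91x2-FimG-I91x2")
        proto = Protocol.force_clamp(
            [(160, 2), (300, 5), (100, 2), (0, 45), (160, 2), (300, 5), (100, 2)]
        )
        rng = np.random.default_rng(11)
        n = 200
        reduces = oxidizes = refolds = 0
        for _ in range(n):
            tr = simulate_force_clamp(c.copy(), proto, cond, CLEAN, rng=rng)
            kinds = [e.kind for e in tr.events if e.domain == "FimG"]
            reduces += "reduce" in kinds
            oxidizes += "oxidize" in kinds
            refolds += "refold" in kinds
        # starts reduced: first reduction requires a prior oxidation
        assert reduces <= oxidizes
        assert refolds > 0 and oxidizes > 0

    def test_missing_quench_warns(self):
        cond = builtin_condition("ox_alone")
        c = build_construct("I91x2-FimG-I91x2")
        with pytest.warns(UserWarning, match="quench"):
            simulate_force_clamp(
                c, Protocol.force_clamp([(160, 2), (300, 20)]), cond, CLEAN,
                seed=0,
            )


class TestNoise:
    def test_zero_noise_is_identity(self, rng):
        c = build_construct("I91x2-FimG-I91x2")
        tr = simulate_force_extension(c, Protocol.force_extension(), CLEAN, seed=2)
        out = add_noise(tr, CLEAN, rng)
        assert np.array_equal(out.force, tr.force)
        assert np.array_equal(out.extension, tr.extension)

    def test_flat_segment_recovers_sd(self, rng):
        from pilusmech.simulate import Trace

        n = 10_000
        tr = Trace(np.arange(n) / 1000.0, np.zeros(n), np.full(n, 100.0),
                   {"mode": "force_clamp"}, [])
        noisy = add_noise(tr, NoiseModel(extension_sd=0.5), rng)
        assert 0.45 < np.std(noisy.extension) < 0.55

    def test_noise_leaves_event_log_untouched(self, rng):
        c = build_construct("I91x2-FimG-I91x2")
        tr = simulate_force_extension(c, Protocol.force_extension(), CLEAN, seed=2)
        noisy = add_noise(tr, NoiseModel(), rng)
        assert noisy.events == tr.events

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(force_sd=-1.0)


def test_refold_protocol_shape():
    proto = refold_3pulse_protocol(quench=30.0)
    assert proto.pulses == ((160, 2), (300, 20), (0, 30.0), (160, 2), (300, 20))
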