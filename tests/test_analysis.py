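"""Blind analysis pipeline: detection, fitting, classification, kinetics."""

import numpy as np
import pytest

from pilusmech import (
    Protocol,
    build_construct,
    default_quaternary_model,
    detect_fx_peaks,
    detect_steps,
    fit_refolding_curve,
    fit_wlc_peaks,
    hierarchy_report,
    refolding_probability,
    simulate_force_extension,
    simulate_force_ramp,
    summed_trace_rate,
)
from pilusmech.analysis import StepEvent, classify_fx_peak, classify_step
from pilusmech.simulate import CLEAN, NoiseModel, Trace


def staircase_trace(levels, dwell=1.2, fs=1000.0, force=300.0, noise=0.0,
                    rng=None):
    """Synthetic clamp staircase: ``levels[i]`` nm added at (i+1)*dwell s."""
    n = int(round((len(levels) + 1) * dwell * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for i, lv in enumerate(levels):
        x[t >= (i + 1) * dwell] += lv
    if noise and rng is not None:
        x = x + rng.normal(0, noise, n)
    return Trace(t, x, np.full(n, force), {"mode": "force_clamp"}, [])


class TestDetectFxPeaks:
    def test_clean_fimg_trace_structure(self):
        c = build_construct("I91x2-FimG-I91x2")
        tr = simulate_force_extension(c, Protocol.force_extension(), CLEAN, seed=0)
        peaks = detect_fx_peaks(tr)
        assert len(peaks) == 6
        assert sum(p.is_detachment for p in peaks) == 1
        assert peaks[-1].is_detachment

    def test_flat_trace_yields_nothing(self):
        n = 2000
        tr = Trace(np.arange(n) / 1e3, np.zeros(n), np.zeros(n),
                   {"mode": "force_extension"}, [])
        assert detect_fx_peaks(tr) == []

    def test_recall_at_default_noise(self):
        """>= 95% of true ruptures recovered at 10 pN force noise."""
        c = build_construct("I91x2-FimG-I91x2")
        proto = Protocol.force_extension()
        noise = NoiseModel()
        found = total = 0
        for seed in range(50):
            tr = simulate_force_extension(c.copy(), proto, noise, seed=seed)
            truth = [e for e in tr.events if e.kind == "unfold"]
            peaks = [p for p in detect_fx_peaks(tr) if not p.is_detachment]
            total += len(truth)
            for e in truth:
                if any(abs(p.peak_force - e.force) < 50.0 for p in peaks):
                    found += 1
        assert found / total >= 0.95


class TestWlcFitting:
    @pytest.fixture(scope="class")
    def fitted_increments(self):
        c = build_construct("I91x2-FimG-I91x2")
        proto = Protocol.force_extension()
        noise = NoiseModel()
        i91, fimg = [], []
        for seed in range(30):
            tr = simulate_force_extension(c.copy(), proto, noise, seed=seed)
            peaks = detect_fx_peaks(tr)
            for fit in fit_wlc_peaks(tr, peaks):
                if fit.is_detachment or fit.delta_lc is None:
                    continue
                label = classify_fx_peak(fit.peak_force, fit.delta_lc,
                                         candidates=["I91", "FimG"])
                if label == "I91":
                    i91.append(fit.delta_lc)
                elif label == "FimG":
                    fimg.append(fit.delta_lc)
        return np.array(i91), np.array(fimg)

    def test_i91_contour_increment(self, fitted_increments):
        i91, _ = fitted_increments
        assert np.mean(i91) == pytest.approx(28.0, abs=1.0)

    def test_fimg_contour_increment(self, fitted_increments):
        _, fimg = fitted_increments
        assert np.mean(fimg) == pytest.approx(40.0, abs=2.0)

    def test_single_peak_has_no_increment(self):
        c = build_construct("I91x2-FimG-I91x2")
        tr = simulate_force_extension(c, Protocol.force_extension(), CLEAN, seed=0)
        peaks = detect_fx_peaks(tr)[:1]
        fits = fit_wlc_peaks(tr, peaks)
        assert len(fits) == 1 and fits[0].delta_lc is None

    def test_no_peaks_rejected(self):
        c = build_construct("I91x2-FimG-I91x2")
        tr = simulate_force_extension(c, Protocol.force_extension(), CLEAN, seed=0)
        with pytest.raises(ValueError):
            fit_wlc_peaks(tr, [])


class TestDetectSteps:
    def test_exact_on_clean_staircase(self):
        levels = [25.0, 25.0, 25.0, 25.0, 33.0]
        steps = detect_steps(staircase_trace(levels), min_step=3.0)
        assert [round(s.size, 9) for s in steps] == levels

    def test_min_step_filters_everything(self):
        steps = detect_steps(staircase_trace([25.0, 33.0]), min_step=50.0)
        assert steps == []

    def test_flat_trace(self):
        assert detect_steps(staircase_trace([])) == []

    def test_quaternary_recall_on_simulated_ramps(self):
        """6 nm quaternary steps above the analysis force floor are found."""
        c = build_construct("I91x2-FimF-FimG-FimH-I91x2")
        quat = default_quaternary_model()
        noise = NoiseModel()
        found = total = 0
        for seed in range(50):
            tr = simulate_force_ramp(c.copy(), Protocol.force_ramp(), quat,
                                     noise, seed=seed)
            truth = [e for e in tr.events
                     if e.kind == "quaternary_step" and 40.0 < e.force < 180.0]
            steps = detect_steps(tr)
            total += len(truth)
            for e in truth:
                if any(abs(s.time - e.time) < 0.5 and abs(s.size - e.size) < 3.0
                       for s in steps):
                    found += 1
        assert total > 10
        assert found / total >= 0.9


class TestClassifyStep:
    @pytest.mark.parametrize(
        "size,force,expected",
        [
            (37.0, 280.0, "FimF"),
            (33.0, 60.0, "FimH_L"),
            (6.0, 82.0, "quaternary_step"),
            (32.0, 238.0, "FimH_P"),
            (25.0, 115.0, "I91"),
            (80.0, 300.0, "unassigned"),
        ],
    )
    def test_paper_signatures(self, size, force, expected):
        assert classify_step(StepEvent(0.0, size, force)) == expected


class TestSummedTraceRate:
    @staticmethod
    def exponential_traces(k, rng, n=200, dur=20.0, fs=1000.0, noise=0.5):
        traces = []
        for _ in range(n):
            tau = rng.exponential(1.0 / k)
            m = int(dur * fs)
            t = np.arange(m) / fs
            x = np.where(t >= tau, 33.0, 0.0) + rng.normal(0, noise, m)
            traces.append(Trace(t, x, np.full(m, 300.0),
                                {"mode": "force_clamp"}, []))
        return traces

    def test_unbiased_over_replicates(self, rng):
        """Mean fitted rate over replicate campaigns is within 5% of truth."""
        rates = [
            summed_trace_rate(self.exponential_traces(0.94, rng), 300.0,
                              n_boot=5, rng=rng).rate
            for _ in range(20)
        ]
        assert np.mean(rates) == pytest.approx(0.94, rel=0.05)

    def test_deterministic_step_rejected(self):
        traces = [staircase_trace([33.0], dwell=4.0, fs=1000.0)
                  for _ in range(20)]
        with pytest.warns(UserWarning, match="step"):
            fit = summed_trace_rate(traces, 300.0, n_boot=2)
        assert np.isnan(fit.rate) and fit.flag == "step_function"

    def test_few_traces_warns_but_fits(self, rng):
        traces = self.exponential_traces(1.0, rng, n=5)
        with pytest.warns(UserWarning, match="traces"):
            fit = summed_trace_rate(traces, 300.0, n_boot=2, rng=rng)
        assert fit.rate > 0


class TestRefoldingProbability:
    def test_half(self):
        p, sd = refolding_probability(7, 14)
        assert p == 0.5 and sd == pytest.approx(0.134, abs=1e-3)

    def test_extremes_have_zero_sd(self):
        assert refolding_probability(0, 20) == (0.0, 0.0)
        assert refolding_probability(14, 14) == (1.0, 0.0)

    def test_sd_scales_with_sqrt_n(self):
        _, sd1 = refolding_probability(10, 20)
        _, sd2 = refolding_probability(40, 80)
        assert sd1 / sd2 == pytest.approx(2.0)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            refolding_probability(0, 0)


class TestFitRefoldingCurve:
    def test_exact_points_recover_exactly(self):
        t = np.array([10.0, 30.0, 45.0, 60.0])
        p = 0.8 * (1 - np.exp(-0.021 * t))
        fit = fit_refolding_curve([(ti, pi, 20) for ti, pi in zip(t, p)])
        assert fit.rate == pytest.approx(0.021, rel=1e-3)
        assert fit.plateau == pytest.approx(0.8, rel=1e-3)

    def test_recovery_from_binomial_sampling(self, rng):
        t = np.array([10.0, 30.0, 45.0, 60.0])
        n = np.array([28, 24, 17, 25])
        p = 0.8 * (1 - np.exp(-0.04 * t))
        y = rng.binomial(n, p) / n
        fit = fit_refolding_curve(list(zip(t, y, n)))
        assert abs(fit.rate - 0.04) <= 0.5 * 0.04

    def test_flat_points_unidentifiable(self):
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_refolding_curve([(10, 0.3, 20), (30, 0.3, 20),
                                       (60, 0.3, 20)])
        assert fit.flag == "unidentifiable"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_refolding_curve([(10, 0.1, 20), (30, 0.2, 20)])


class TestHierarchyReport:
    @staticmethod
    def synthetic_events(rng, means, n=30):
        events = []
        for name, (force, size) in means.items():
            for _ in range(n):
                events.append((name, rng.normal(force, 10), rng.normal(size, 1)))
        return events

    MEANS = {
        "FimA": (527, 42),
        "FimF": (281, 37),
        "FimG": (261, 33),
        "FimH_P": (238, 32),
        "FimH_L": (62, 33),
    }

    def test_paper_means_are_ordered(self, rng):
        table, ordered = hierarchy_report(self.synthetic_events(rng, self.MEANS))
        assert ordered
        assert list(table.index)[0] == "FimA"

    def test_empty_input(self):
        table, ordered = hierarchy_report([])
        assert table.empty and not ordered

    def test_shuffled_labels_break_ordering(self, rng):
        means = dict(self.MEANS)
        means["FimA"], means["FimH_L"] = means["FimH_L"], means["FimA"]
        _, ordered = hierarchy_report(self.synthetic_events(rng, means))
        assert not ordered

    def test_sparse_domains_do_not_qualify(self, rng):
        events = self.synthetic_events(rng, self.MEANS, n=3)
        _, ordered = hierarchy_report(events, min_events=5)
        assert not ordered
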