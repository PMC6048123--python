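"""Closed-loop recovery campaigns: simulate -> analyse blind -> compare.

The raw AFM data behind the published numbers are not deposited, so the
package validates itself in closed loop: the simulator is parameterised by
the registry (whose targets are the printed values), synthetic campaigns are
generated at the published protocol settings and sample sizes, and the blind
analysis pipeline must recover the registry targets.  Each function here
runs one such campaign from scratch and returns the measured quantities.

Seeding: every campaign derives independent child seeds from the single seed
it is given, so one integer reproduces the whole suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import analysis as an
from . import registry as reg
from . import simulate as sim

__all__ = [
    "released_contour_total",
    "fx_force_recovery",
    "contour_increment_recovery",
    "clamp_rate_recovery",
    "clamp_rate_ratio",
    "refolding_rate_recovery",
    "ramp_recovery",
    "hierarchy_campaign",
    "recovery_suite",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def released_contour_total(domain: str = "FimG") -> float:
    """Observed released length of one unfolded, reduced domain (nm):
    oxidized unfolding step plus disulfide-reduction step."""
    construct = reg.Construct([reg.DomainState(reg.builtin_domain(domain))])
    construct.domains[0].fold_state = reg.UNFOLDED
    construct.domains[0].redox_state = reg.REDUCED
    return reg.released_contour(construct, mode="observed")


def fx_force_recovery(
    seed: int,
    n_traces: int = 2000,
    construct_spec: str = "I91x2-FimA-I91x2",
    domain: str = "FimA",
    velocity: float = 400.0,
) -> dict:
    """Mean rupture force of ``domain`` recovered by blind peak detection
    from simulated force-extension traces."""
    construct = reg.build_construct(construct_spec)
    present = sorted({d.spec.name for d in construct.domains})
    protocol = sim.Protocol.force_extension(velocity)
    noise = sim.NoiseModel()
    forces: list[float] = []
    for s in _child_seeds(seed, n_traces):
        tr = sim.simulate_force_extension(construct.copy(), protocol, noise, seed=s)
        for pk in an.detect_fx_peaks(tr):
            if pk.is_detachment:
                continue
            if an.classify_fx_peak(pk.peak_force, candidates=present) == domain:
                forces.append(pk.peak_force)
    return {
        "mean_force": float(np.mean(forces)),
        "sem": float(np.std(forces, ddof=1) / math.sqrt(len(forces))),
        "n_events": len(forces),
        "n_traces": n_traces,
    }


def contour_increment_recovery(
    seed: int,
    n_traces: int = 100,
    construct_spec: str = "I91x2-FimG-I91x2",
    fim_domain: str = "FimG",
    velocity: float = 400.0,
) -> dict:
    """Mean contour-length increments from blind WLC fitting of simulated
    force-extension traces (fixed persistence length, contour free)."""
    construct = reg.build_construct(construct_spec)
    present = sorted({d.spec.name for d in construct.domains})
    protocol = sim.Protocol.force_extension(velocity)
    noise = sim.NoiseModel()
    i91: list[float] = []
    fim: list[float] = []
    for s in _child_seeds(seed, n_traces):
        tr = sim.simulate_force_extension(construct.copy(), protocol, noise, seed=s)
        peaks = an.detect_fx_peaks(tr)
        if not peaks:
            continue
        fits = an.fit_wlc_peaks(tr, peaks)
        for fit in fits:
            if fit.is_detachment or fit.delta_lc is None:
                continue
            label = an.classify_fx_peak(fit.peak_force, fit.delta_lc,
                                        candidates=present)
            if label == "I91":
                i91.append(fit.delta_lc)
            elif label == fim_domain:
                fim.append(fit.delta_lc)
    return {
        "i91_delta_lc": float(np.mean(i91)),
        "fim_delta_lc": float(np.mean(fim)),
        "fim_domain": fim_domain,
        "n_i91": len(i91),
        "n_fim": len(fim),
        "n_traces": n_traces,
    }


def clamp_rate_recovery(
    seed: int,
    condition: str = "ox_alone",
    n_traces: int = 200,
    force: float = 300.0,
) -> an.KineticFit:
    """Summed-trace unfolding rate of FimG at constant force.

    Simulates the unfolding pulses of the published clamp protocol (160 pN
    fingerprint pulse then the high-force pulse) and fits the normalised
    summed extension at ``force`` to a single exponential.
    """
    import warnings

    construct = reg.build_construct("I91x2-FimG-I91x2")
    protocol = sim.Protocol.force_clamp([(160, 2), (force, 20)])
    cond = reg.builtin_condition(condition)
    noise = sim.NoiseModel()
    with warnings.catch_warnings():
        # the unfolding pulses deliberately omit the quench
        warnings.simplefilter("ignore", UserWarning)
        traces = [
            sim.simulate_force_clamp(construct.copy(), protocol, cond, noise, seed=s)
            for s in _child_seeds(seed, n_traces)
        ]
    return an.summed_trace_rate(traces, force, rng=np.random.default_rng(seed))


def clamp_rate_ratio(seed: int, n_traces: int = 200) -> dict:
    """Reduced/oxidized FimG unfolding-rate ratio at 300 pN."""
    s_ox, s_red = _child_seeds(seed, 2)
    fit_ox = clamp_rate_recovery(s_ox, "ox_alone", n_traces)
    fit_red = clamp_rate_recovery(s_red, "red_alone", n_traces)
    return {
        "rate_ox": fit_ox.rate,
        "rate_red": fit_red.rate,
        "ratio": fit_red.rate / fit_ox.rate,
        "n_traces": n_traces,
    }


def refolding_rate_recovery(
    seed: int,
    condition: str = "ox_alone",
    quench_times: tuple = (10.0, 30.0, 45.0, 60.0),
    n_per_time: tuple = (22, 18, 15, 11),
    model: str = "plateaued_exponential",
) -> dict:
    """Refolding rate from a simulated quench-time campaign.

    For each quench time, runs the published number of 3-pulse clamp traces,
    scores refolding blindly from the probe pulse, and fits the plateaued
    exponential to probability vs quench time.
    """
    cond = reg.builtin_condition(condition)
    construct = reg.build_construct("I91x2-FimG-I91x2")
    noise = sim.NoiseModel()
    points = []
    seeds = _child_seeds(seed, len(quench_times))
    for dt, n, s in zip(quench_times, n_per_time, seeds):
        protocol = sim.refold_3pulse_protocol(quench=dt)
        successes = 0
        for ts in _child_seeds(s, n):
            tr = sim.simulate_force_clamp(
                construct.copy(), protocol, cond, noise, seed=ts
            )
            if an.refolded_in_probe(tr):
                successes += 1
        p, sd = an.refolding_probability(successes, n)
        points.append((dt, p, n))
    fit = an.fit_refolding_curve(points, model=model)
    return {"points": points, "rate": fit.rate, "rate_se": fit.rate_se,
            "plateau": fit.plateau}


def ramp_recovery(
    seed: int,
    n_traces: int = 200,
    construct_spec: str = "I91x2-FimF-FimG-FimH-I91x2",
    min_force: float = 30.0,
) -> dict:
    """Force-ramp campaign on the tip-fibrillum polyprotein.

    Blind step detection and (size, force) classification; reports the mean
    rupture force per classified domain and the fraction of traces showing
    at least one quaternary step.  Steps below ``min_force`` are dropped as
    low-force baseline artefacts of the stretching backbone.
    """
    construct = reg.build_construct(construct_spec)
    multiplicities: dict[str, int] = {}
    for d in construct.domains:
        multiplicities[d.spec.name] = multiplicities.get(d.spec.name, 0) + 1
    protocol = sim.Protocol.force_ramp()
    quat = reg.default_quaternary_model()
    noise = sim.NoiseModel()
    classified: list[tuple[str, float, float]] = []
    traces_with_quaternary = 0
    for s in _child_seeds(seed, n_traces):
        tr = sim.simulate_force_ramp(construct.copy(), protocol, quat, noise, seed=s)
        steps = [
            st for st in an.detect_steps(tr) if st.force_at_step >= min_force
        ]
        labels = an.classify_trace_steps(steps, multiplicities)
        found_quat = False
        for step, label in zip(steps, labels):
            if label == "unassigned":
                continue
            if label == "quaternary_step":
                found_quat = True
            classified.append((label, step.force_at_step, step.size))
        if found_quat:
            traces_with_quaternary += 1
    forces: dict[str, list[float]] = {}
    for label, force, _ in classified:
        forces.setdefault(label, []).append(force)
    mean_forces = {k: float(np.mean(v)) for k, v in forces.items()}
    return {
        "mean_forces": mean_forces,
        "counts": {k: len(v) for k, v in forces.items()},
        "quaternary_fraction": traces_with_quaternary / n_traces,
        "events": classified,
        "n_traces": n_traces,
    }


def hierarchy_campaign(
    seed: int,
    n_ramp: int = 150,
    n_fx: int = 12,
) -> tuple:
    """Full campaign for the mechanical hierarchy.

    FimF/FimG/FimH forces come from a force-ramp campaign on the tip
    fibrillum; FimA — too strong to survive alongside the others — from its
    own force-extension campaign.  Returns the per-domain table and the
    strict-ordering flag.
    """
    s_ramp, s_fx = _child_seeds(seed, 2)
    events = list(ramp_recovery(s_ramp, n_ramp)["events"])
    events = [e for e in events if e[0] in reg.HIERARCHY]

    construct = reg.build_construct("I91x2-FimA-I91x2")
    protocol = sim.Protocol.force_extension()
    noise = sim.NoiseModel()
    for s in _child_seeds(s_fx, n_fx):
        tr = sim.simulate_force_extension(construct.copy(), protocol, noise, seed=s)
        peaks = an.detect_fx_peaks(tr)
        if not peaks:
            continue
        fits = an.fit_wlc_peaks(tr, peaks)
        for fit in fits:
            if fit.is_detachment or fit.delta_lc is None:
                continue
            if an.classify_fx_peak(fit.peak_force, fit.delta_lc,
                                   candidates=["I91", "FimA"]) == "FimA":
                events.append(("FimA", fit.peak_force, fit.delta_lc))
    return an.hierarchy_report(events)


@dataclass
class RecoveryResult:
    name: str
    measured: float
    target: float
    tolerance: float  # relative
    n: int

    @property
    def passed(self) -> bool:
        return abs(self.measured - self.target) <= self.tolerance * abs(self.target)


def recovery_suite(seed: int = 1, fast: bool = False) -> list[RecoveryResult]:
    """Run the full closed-loop recovery suite and score it against the
    registry targets.  ``fast`` shrinks the campaigns ~10x for smoke runs."""
    k = 10 if fast else 1
    s = _child_seeds(seed, 6)
    out: list[RecoveryResult] = []

    out.append(
        RecoveryResult("FimG reduced total release (nm)",
                       released_contour_total("FimG"), 45.0, 0.0, 1)
    )
    fx = fx_force_recovery(s[0], n_traces=2000 // k)
    out.append(
        RecoveryResult("FimA FX mean force (pN)", fx["mean_force"], 527.0, 0.02,
                       fx["n_events"])
    )
    inc = contour_increment_recovery(s[1], n_traces=100 // k)
    out.append(
        RecoveryResult("I91 delta_Lc (nm)", inc["i91_delta_lc"], 28.0, 1.0 / 28.0,
                       inc["n_i91"])
    )
    out.append(
        RecoveryResult("FimG delta_Lc (nm)", inc["fim_delta_lc"], 40.0, 2.0 / 40.0,
                       inc["n_fim"])
    )
    rates = clamp_rate_ratio(s[2], n_traces=200 // k)
    out.append(
        RecoveryResult("FimG ox rate at 300 pN (1/s)", rates["rate_ox"], 0.94, 0.10,
                       rates["n_traces"])
    )
    out.append(
        RecoveryResult("FimG red/ox rate ratio", rates["ratio"], 30.0, 0.25,
                       rates["n_traces"])
    )
    ramp = ramp_recovery(s[3], n_traces=200 // k)
    out.append(
        RecoveryResult("FimF ramp mean force (pN)",
                       ramp["mean_forces"].get("FimF", math.nan), 281.0, 0.05,
                       ramp["counts"].get("FimF", 0))
    )
    out.append(
        RecoveryResult("quaternary-step trace fraction",
                       ramp["quaternary_fraction"], 0.5, 0.2, ramp["n_traces"])
    )
    refold = refolding_rate_recovery(s[4])
    out.append(
        RecoveryResult("FimG refolding rate (1/s)", refold["rate"], 0.021,
                       0.008 / 0.021, sum(n for _, _, n in refold["points"]))
    )
    return out
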