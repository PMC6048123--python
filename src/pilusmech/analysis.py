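"""Blind trace analysis: peak/step detection, WLC fitting, kinetics.

Every operation here consumes only the observable channels (time, extension,
force); ground-truth event logs are used exclusively by the test suite to
score the pipeline.

The analysis chain mirrors standard AFM practice:

* sawtooth force-extension traces -> rupture peaks -> per-peak WLC fits with
  a shared fixed persistence length -> contour-length increments as the
  difference between consecutive fitted contours;
* staircase (ramp / clamp) traces -> change-point detection on the extension
  channel (binary segmentation, L2 cost) -> step sizes and forces;
* (size, force) classification of steps against the domain registry;
* summed-trace kinetics at constant force; refolding probabilities with
  binomial errors and plateaued-exponential rate fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .registry import HIERARCHY, load_registry
from .simulate import Trace
from .wlc import KBT_ROOM, WLCParams, wlc_force

__all__ = [
    "PeakFit",
    "PeakSegment",
    "StepEvent",
    "KineticFit",
    "detect_fx_peaks",
    "fit_wlc_peaks",
    "classify_fx_peak",
    "detect_steps",
    "classify_step",
    "pulse_segments",
    "summed_trace_rate",
    "refolding_probability",
    "refolded_in_probe",
    "fit_refolding_curve",
    "hierarchy_report",
]


@dataclass
class PeakSegment:
    """One detected rupture peak of a sawtooth trace (sample indices)."""

    start: int
    end: int  # index of the last sample before the force drop
    peak_force: float
    peak_position: float  # extension at rupture, nm
    is_detachment: bool = False


@dataclass
class PeakFit:
    """WLC fit of one peak: fitted contour and the increment released by the
    rupture at this peak (difference to the *next* peak's fitted contour)."""

    peak_force: float
    peak_position: float
    fitted_contour: float
    delta_lc: Optional[float]
    fit_residual: float
    is_detachment: bool = False


@dataclass
class StepEvent:
    """One detected staircase step."""

    time: float
    size: float
    force_at_step: float


@dataclass
class KineticFit:
    """Fitted first-order rate (1/s) with its standard error."""

    rate: float
    rate_se: float
    model: str = "single_exponential"
    plateau: Optional[float] = None
    plateau_se: Optional[float] = None
    flag: Optional[str] = None


# ---------------------------------------------------------------------------
# Force-extension peaks
# ---------------------------------------------------------------------------


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(y) < window:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")[: len(y)]


def detect_fx_peaks(
    trace: Trace,
    min_force: float = 80.0,
    min_drop: float = 40.0,
    smooth_window: int = 7,
    drop_span: int = 6,
) -> list[PeakSegment]:
    """Detect rupture peaks in a sawtooth force-extension trace.

    A rupture is a drop of at least ``min_drop`` pN within ``drop_span``
    samples of the smoothed force, from a level of at least ``min_force``.
    The peak force is read by extrapolating a linear fit of the pre-drop rise
    to the rupture instant, which is unbiased under additive force noise.
    The final peak is flagged as the detachment candidate.
    """
    f = np.asarray(trace.force, dtype=float)
    x = np.asarray(trace.extension, dtype=float)
    n = len(f)
    if n < 2 * drop_span:
        return []
    fs = _smooth(f, smooth_window)
    drop = fs[:-drop_span] - fs[drop_span:]
    cand = np.flatnonzero((drop > min_drop) & (fs[:-drop_span] > min_force))
    if cand.size == 0:
        return []
    # cluster contiguous candidates; rupture index = local force max in cluster
    splits = np.flatnonzero(np.diff(cand) > drop_span) + 1
    clusters = np.split(cand, splits)
    peaks: list[PeakSegment] = []
    prev_end = 0
    for cl in clusters:
        lo, hi = max(cl[0] - 2, 1), min(cl[-1] + drop_span, n - 1)
        # rupture sits at the sharpest raw drop within the cluster window;
        # the true rupture instant is between idx and idx+1
        idx = lo + int(np.argmin(np.diff(f[lo : hi + 1])))
        # pre-drop linear extrapolation to the rupture instant (idx + 0.5)
        w = min(25, idx - prev_end)
        if w >= 5:
            tt = np.arange(w, dtype=float)
            coef = np.polyfit(tt, f[idx - w + 1 : idx + 1], 1)
            peak_force = float(np.polyval(coef, w - 0.5))
        else:
            peak_force = float(fs[idx])
        peaks.append(PeakSegment(prev_end, idx, peak_force, float(x[idx])))
        prev_end = idx + drop_span
    # the last peak of a complete pull is the detachment: force stays low after
    tail = fs[min(peaks[-1].end + drop_span, n - 1) :]
    if tail.size == 0 or float(np.median(tail)) < min_force:
        peaks[-1].is_detachment = True
    return peaks


def fit_wlc_peaks(
    trace: Trace,
    peaks: Sequence[PeakSegment],
    fixed_persistence: float = 0.4,
    thermal_energy: float = KBT_ROOM,
    fit_fmin: float = 20.0,
) -> list[PeakFit]:
    """Fit each peak's rising flank with a WLC (contour free, p fixed).

    The contour-length increment released by the rupture at peak ``i`` is the
    difference between the contours fitted to peaks ``i+1`` and ``i`` (the
    fits "in the asymptote" bracket the unfolding).  The detachment segment
    is fitted too — it provides the final contour — but is excluded from
    force statistics downstream.  Non-convergent peaks are flagged with a
    NaN contour and skipped in the increments.
    """
    if not peaks:
        raise ValueError("need at least one peak to fit")
    f = np.asarray(trace.force, dtype=float)
    x = np.asarray(trace.extension, dtype=float)
    fits: list[PeakFit] = []
    for pk in peaks:
        sel = slice(pk.start, pk.end + 1)
        xx, ff = x[sel], f[sel]
        keep = ff > max(fit_fmin, 0.08 * pk.peak_force)
        xx, ff = xx[keep], ff[keep]
        if xx.size < 8:
            fits.append(
                PeakFit(pk.peak_force, pk.peak_position, math.nan, None,
                        math.nan, pk.is_detachment)
            )
            continue
        x_max = float(xx.max())
        pars = Parameters()
        pars.add("lc", value=x_max / 0.92, min=x_max * 1.0001, max=x_max * 2.5)

        def residual(p, xx=xx, ff=ff):
            w = WLCParams(fixed_persistence, p["lc"].value, thermal_energy)
            return wlc_force(np.clip(xx, 0, w.contour_length * (1 - 1e-9)), w) - ff

        try:
            out = minimize(residual, pars, method="leastsq")
            lc = float(out.params["lc"].value)
            resid = float(np.sqrt(np.mean(out.residual**2)))
        except Exception:
            lc, resid = math.nan, math.nan
        fits.append(
            PeakFit(pk.peak_force, pk.peak_position, lc, None, resid,
                    pk.is_detachment)
        )
    for i in range(len(fits) - 1):
        a, b = fits[i].fitted_contour, fits[i + 1].fitted_contour
        if math.isfinite(a) and math.isfinite(b) and b > a:
            fits[i].delta_lc = b - a
    return fits


def classify_fx_peak(
    peak_force: float,
    delta_lc: Optional[float] = None,
    candidates: Optional[Sequence[str]] = None,
    overrides: Optional[dict] = None,
    force_scale: float = 60.0,
    size_scale: float = 2.5,
    cutoff: float = 4.0,
) -> str:
    """Assign a force-extension rupture to a domain by (force, delta_Lc).

    Nearest class in scaled coordinates against the registry's
    force-extension means; returns ``"unassigned"`` beyond ``cutoff``.
    ``candidates`` restricts the classes to the domains actually present in
    the pulled construct (known to the experimenter) — without it, the low
    tail of a strong domain can leak into an absent neighbouring class.
    """
    reg = load_registry(overrides)["domains"]
    if candidates is not None:
        reg = {k: v for k, v in reg.items() if k in set(candidates)}
    best, best_d = "unassigned", cutoff
    for name, t in reg.items():
        d = abs(peak_force - t["mean_force_fx"]) / force_scale
        if delta_lc is not None:
            d = math.hypot(d, (delta_lc - t["delta_lc_ox"]) / size_scale)
        if d < best_d:
            best, best_d = name, d
    return best


# ---------------------------------------------------------------------------
# Staircase step detection (change-point)
# ---------------------------------------------------------------------------


def _binseg(y: np.ndarray, min_size: int, penalty: float) -> list[int]:
    """Penalised binary segmentation with an L2 cost.

    Returns the sorted interior breakpoints.  A split of segment [a, b) at s
    is accepted when it lowers sum((y - segment mean)^2) by more than
    ``penalty``; candidate splits keep both sides at least ``min_size`` long.
    """
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(a: int, b: int) -> float:
        s, q = c1[b] - c1[a], c2[b] - c2[a]
        return q - s * s / (b - a)

    breaks: list[int] = []
    stack = [(0, len(y))]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_size:
            continue
        s = np.arange(a + min_size, b - min_size + 1)
        sl = c1[s] - c1[a]
        ql = c2[s] - c2[a]
        left = ql - sl * sl / (s - a)
        sr = c1[b] - c1[s]
        qr = c2[b] - c2[s]
        right = qr - sr * sr / (b - s)
        tot = left + right
        i = int(np.argmin(tot))
        if sse(a, b) - tot[i] > penalty:
            split = int(s[i])
            breaks.append(split)
            stack.append((a, split))
            stack.append((split, b))
    return sorted(breaks)


def _decimate(t, x, f, factor: int):
    n = (len(t) // factor) * factor
    shape = (-1, factor)
    return (
        t[:n].reshape(shape).mean(axis=1),
        x[:n].reshape(shape).mean(axis=1),
        f[:n].reshape(shape).mean(axis=1),
    )


def _steps_in_segment(
    t: np.ndarray,
    x: np.ndarray,
    f: np.ndarray,
    min_step: float,
    min_size: int,
    penalty_factor: float,
) -> list[StepEvent]:
    n = len(x)
    if n < 2 * min_size:
        return []
    diffs = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / math.sqrt(2)
    penalty = max(sigma**2, 1e-12) * penalty_factor * math.log(max(n, 2))
    breaks = _binseg(x, min_size, penalty)
    if not breaks:
        return []
    bounds = [0] + breaks + [n]
    means = [float(np.mean(x[bounds[i] : bounds[i + 1]])) for i in range(len(bounds) - 1)]
    out: list[StepEvent] = []
    for j, bp in enumerate(breaks):
        size = means[j + 1] - means[j]
        if size >= min_step:
            out.append(StepEvent(float(t[bp]), float(size), float(f[bp])))
    return out


def detect_steps(
    trace: Trace,
    min_step: float = 3.0,
    min_size: int = 20,
    penalty_factor: float = 6.0,
    max_samples: int = 20000,
) -> list[StepEvent]:
    """Detect upward extension steps in a clamp or ramp trace.

    The extension channel is segmented piecewise-constant by penalised binary
    segmentation (L2 cost, minimum segment length ``min_size`` samples); a
    step is a boundary whose level difference is at least ``min_step`` nm,
    with the force read from the force channel at the boundary.  Clamp
    traces are segmented within each constant-force pulse.  Long traces are
    block-averaged down to at most ``max_samples`` samples first.
    """
    t = np.asarray(trace.time, dtype=float)
    x = np.asarray(trace.extension, dtype=float)
    f = np.asarray(trace.force, dtype=float)
    mode = trace.metadata.get("mode", "")

    out: list[StepEvent] = []
    if mode == "force_clamp":
        for a, b, level in pulse_segments(trace):
            if level <= 0:
                continue
            tt, xx, ff = t[a:b], x[a:b], f[a:b]
            factor = max(1, math.ceil(len(xx) / max_samples))
            if factor > 1:
                tt, xx, ff = _decimate(tt, xx, ff, factor)
            out.extend(
                _steps_in_segment(tt, xx, ff, min_step, min_size, penalty_factor)
            )
    else:
        sel = f > 0 if mode == "force_ramp" else np.ones_like(f, bool)
        tt, xx, ff = t[sel], x[sel], f[sel]
        factor = max(1, math.ceil(len(xx) / max_samples))
        if factor > 1:
            tt, xx, ff = _decimate(tt, xx, ff, factor)
        out = _steps_in_segment(tt, xx, ff, min_step, min_size, penalty_factor)
    return out


def pulse_segments(trace: Trace) -> list[tuple[int, int, float]]:
    """Split a clamp trace into constant-force pulses.

    Returns ``(start, stop, force_level)`` index triples (stop exclusive).
    """
    f = np.asarray(trace.force, dtype=float)
    # the commanded force is piecewise constant; changes exceed any noise
    change = np.flatnonzero(np.abs(np.diff(f)) > 1.0) + 1
    bounds = np.concatenate([[0], change, [len(f)]])
    return [
        (int(a), int(b), float(np.median(f[a:b])))
        for a, b in zip(bounds[:-1], bounds[1:])
        if b - a >= 2
    ]


def classify_step(
    step: StepEvent,
    overrides: Optional[dict] = None,
    size_scale: float = 1.5,
    force_scale: float = 25.0,
    cutoff: float = 3.5,
) -> str:
    """Classify a ramp/clamp step by its joint (size, force) signature.

    Force regimes resolve size-degenerate classes: below 100 pN only FimH_L
    and the quaternary steps occur, between 100 and 200 pN the I91
    fingerprint, above 200 pN the pilin-domain ruptures (FimF/FimG/FimH_P).
    Within a regime the nearest class in scaled coordinates wins; anything
    farther than ``cutoff`` is ``"unassigned"``.
    """
    regdata = load_registry(overrides)
    domains = regdata["domains"]
    quat = regdata["quaternary"]
    force = step.force_at_step
    if force < 100.0:
        candidates = {
            "quaternary_step": (quat["step_size"], quat["mean_force"]),
            "FimH_L": (domains["FimH_L"]["step_ramp"],
                       domains["FimH_L"]["mean_force_ramp"]),
        }
    elif force < 200.0:
        # quaternary steps stay a candidate here: their 6 nm size is
        # unambiguous against the 25 nm I91 fingerprint
        candidates = {
            "I91": (domains["I91"]["step_ramp"], domains["I91"]["mean_force_ramp"]),
            "quaternary_step": (quat["step_size"], quat["mean_force"]),
        }
    else:
        candidates = {
            name: (domains[name]["step_ramp"], domains[name]["mean_force_ramp"])
            for name in ("FimF", "FimG", "FimH_P")
        }
    best, best_d = "unassigned", cutoff
    for name, (size_mean, force_mean) in candidates.items():
        d = math.hypot(
            (step.size - size_mean) / size_scale, (force - force_mean) / force_scale
        )
        if d < best_d:
            best, best_d = name, d
    return best


def classify_trace_steps(
    steps: Sequence[StepEvent],
    multiplicities: dict[str, int],
    overrides: Optional[dict] = None,
    size_scale: float = 1.5,
    force_scale: float = 25.0,
    cutoff: float = 3.5,
) -> list[str]:
    """Jointly classify all steps of one trace under multiplicity constraints.

    The per-step rule of :func:`classify_step` lets the tails of overlapping
    neighbours leak into each other (each class keeps its away-from-neighbour
    side, biasing class means) and can assign one domain twice in a trace.
    Since the experimenter knows the construct, each domain class may be used
    at most as often as it occurs in it; the globally cheapest assignment
    (Hungarian algorithm on the same scaled (size, force) distances, with
    unlimited quaternary and "unassigned" slots at ``cutoff`` cost) removes
    both artefacts.
    """
    from scipy.optimize import linear_sum_assignment

    if not steps:
        return []
    regdata = load_registry(overrides)
    domains = regdata["domains"]
    quat = regdata["quaternary"]

    def regime_ok(name: str, force: float) -> bool:
        if name == "quaternary_step":
            return force < 200.0
        if name == "FimH_L":
            return force < 100.0
        if name == "I91":
            return 100.0 <= force < 200.0
        return force >= 200.0

    def centre(name: str) -> tuple[float, float]:
        if name == "quaternary_step":
            return quat["step_size"], quat["mean_force"]
        return domains[name]["step_ramp"], domains[name]["mean_force_ramp"]

    slots: list[str] = []
    for name, count in multiplicities.items():
        if name in domains:
            slots.extend([name] * count)
    slots.extend(["quaternary_step"] * len(steps))
    slots.extend(["unassigned"] * len(steps))

    big = 1e6
    cost = np.full((len(steps), len(slots)), big)
    for i, s in enumerate(steps):
        for j, name in enumerate(slots):
            if name == "unassigned":
                cost[i, j] = cutoff
            elif regime_ok(name, s.force_at_step):
                size_mean, force_mean = centre(name)
                d = math.hypot(
                    (s.size - size_mean) / size_scale,
                    (s.force_at_step - force_mean) / force_scale,
                )
                if d < cutoff:
                    cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    labels = ["unassigned"] * len(steps)
    for i, j in zip(rows, cols):
        if cost[i, j] < cutoff:
            labels[i] = slots[j]
    return labels


# ---------------------------------------------------------------------------
# Constant-force kinetics from summed traces
# ---------------------------------------------------------------------------


def _normalise_pulse(x: np.ndarray, min_range: float = 5.0) -> Optional[np.ndarray]:
    """Map a single-staircase pulse onto [0, 1] using its two occupancy levels.

    Levels are estimated from the sample histogram (medians of the lower and
    upper halves split at mid-range), which stays unbiased however early or
    late the step occurs.  Pulses with no step (< ``min_range`` nm span)
    cannot be normalised and return ``None``: the domain either unfolded
    before this pulse or survived it, so the pulse carries no dwell-time
    information.
    """
    s = _smooth(x, 9)
    lo, hi = float(np.min(s)), float(np.max(s))
    if hi - lo < min_range:
        return None
    mid = 0.5 * (lo + hi)
    base = float(np.median(x[s < mid]))
    top = float(np.median(x[s >= mid]))
    if top - base < min_range:
        return None
    return np.clip((x - base) / (top - base), 0.0, 1.0)


def summed_trace_rate(
    traces: Sequence[Trace],
    force: float,
    pulse_index: int = 0,
    align: str = "pulse_start",
    n_boot: int = 50,
    rng: Optional[np.random.Generator] = None,
    max_points: int = 2000,
) -> KineticFit:
    """Unfolding rate from the normalised summed extension at constant force.

    Each trace's ``pulse_index``-th pulse at ``force`` is normalised to
    [0, 1], the traces are averaged on a common pulse-relative time grid
    (aligned to the pulse start, or to each trace's first extension movement
    with ``align="first_step"``), and the mean curve is fitted to
    ``1 - exp(-t/tau)``; returns ``1/tau`` with a bootstrap-over-traces SE.
    """
    if align not in ("pulse_start", "first_step"):
        raise ValueError("align must be 'pulse_start' or 'first_step'")
    if len(traces) < 10:
        warnings.warn(
            f"only {len(traces)} traces; the summed-trace fit is noisy below 10",
            stacklevel=2,
        )
    rng = np.random.default_rng(0) if rng is None else rng

    curves = []
    t_rel = None
    for tr in traces:
        matches = [
            (a, b) for a, b, lvl in pulse_segments(tr) if abs(lvl - force) < 1.0
        ]
        if pulse_index >= len(matches):
            continue
        a, b = matches[pulse_index]
        u = _normalise_pulse(np.asarray(tr.extension[a:b], dtype=float))
        if u is None:
            continue
        if align == "first_step":
            idx = np.flatnonzero(u > 0.5)
            shift = idx[0] if idx.size else 0
            u = u[shift:]
        tt = np.asarray(tr.time[a : a + len(u)], dtype=float) - tr.time[a]
        if t_rel is None or len(tt) < len(t_rel):
            t_rel = tt
        curves.append(u)
    if not curves:
        raise ValueError(f"no pulses found at {force} pN")
    n = len(t_rel)
    mat = np.vstack([c[:n] for c in curves])
    # thin the grid for the fit but keep the early rise at full resolution:
    # fast unfolders concentrate their information in the first fraction of
    # the pulse
    stride = max(1, n // max_points)
    head = min(n, max_points)
    idx = np.unique(np.concatenate([np.arange(head), np.arange(head, n, stride)]))
    t_fit = t_rel[idx]
    mat = mat[:, idx]
    mean_curve = mat.mean(axis=0)

    # degenerate case: an identical, deterministic step in every trace
    jump = np.flatnonzero(np.diff(mean_curve > 0.5))
    if jump.size == 1:
        j = jump[0]
        lo = mean_curve[max(j - 3, 0)]
        hi = mean_curve[min(j + 3, len(mean_curve) - 1)]
        if lo < 0.1 and hi > 0.9:
            warnings.warn(
                "summed curve is a step function; exponential fit rejected",
                stacklevel=2,
            )
            return KineticFit(math.nan, math.nan, flag="step_function")

    def fit_rate(curve: np.ndarray) -> float:
        target = 1.0 - 1.0 / math.e
        above = np.flatnonzero(curve >= target)
        k_init = 1.0 / max(t_fit[above[0]], t_fit[1]) if above.size else 0.1
        pars = Parameters()
        pars.add("k", value=k_init, min=1e-6)
        out = minimize(
            lambda p: (1.0 - np.exp(-p["k"].value * t_fit)) - curve,
            pars,
            method="leastsq",
        )
        return float(out.params["k"].value)

    rate = fit_rate(mean_curve)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(curves), len(curves))
        boots.append(fit_rate(mat[idx].mean(axis=0)))
    return KineticFit(rate, float(np.std(boots, ddof=1)), "single_exponential")


# ---------------------------------------------------------------------------
# Refolding statistics
# ---------------------------------------------------------------------------


def refolding_probability(successes: int, trials: int) -> tuple[float, float]:
    """Refolding probability with the SD of a binomial distribution."""
    if trials <= 0:
        raise ValueError("trials must be > 0")
    if not (0 <= successes <= trials):
        raise ValueError("successes must be in [0, trials]")
    p = successes / trials
    return p, math.sqrt(p * (1.0 - p) / trials)


def refolded_in_probe(
    trace: Trace,
    probe_force: float = 300.0,
    min_step: float = 20.0,
    **detect_kw,
) -> bool:
    """Did the subject domain refold during the quench?

    True when the probe pulse (the occurrence of ``probe_force`` *after* the
    longest quench) contains a step of at least ``min_step`` nm — the domain
    unfolded again, so it must have folded during the quench.
    """
    segs = pulse_segments(trace)
    quenches = [i for i, (_, _, lvl) in enumerate(segs) if lvl <= 0.5]
    if not quenches:
        raise ValueError("trace has no quench segment")
    q = quenches[-1]
    t_after = trace.time[segs[q][1] - 1]
    steps = detect_steps(trace, min_step=min_step, **detect_kw)
    return any(
        s.time > t_after and abs(s.force_at_step - probe_force) < 25.0 for s in steps
    )


def fit_refolding_curve(
    points: Iterable[tuple[float, float, int]],
    model: str = "plateaued_exponential",
    eps: float = 0.01,
) -> KineticFit:
    """Fit refolding probability vs quench time.

    ``points`` are ``(quench_time, probability, n_trials)`` triples.  The
    model is ``P_inf * (1 - exp(-k t))`` (plateau free) or ``1 - exp(-k t)``.
    Weighted least squares with weights ``n / (p (1 - p) + eps)`` — the
    inverse binomial variance, regularised so the endpoints keep finite
    weight.  Returns the rate and its standard error.
    """
    pts = sorted(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 quench times")
    t = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    n = np.array([p[2] for p in pts], dtype=float)
    if np.allclose(y, y[0]):
        warnings.warn("all probabilities equal; rate unidentifiable", stacklevel=2)
        return KineticFit(math.nan, math.nan, model, flag="unidentifiable")
    w = np.sqrt(n / (y * (1.0 - y) + eps))

    pars = Parameters()
    t_scale = float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
    pars.add("k", value=1.0 / t_scale, min=1e-6)
    free_plateau = model == "plateaued_exponential"
    pars.add("plateau", value=min(max(y.max(), 0.05), 1.0), min=1e-3, max=1.0,
             vary=free_plateau)

    def residual(p):
        mdl = p["plateau"].value * (1.0 - np.exp(-p["k"].value * t))
        return w * (mdl - y)

    out = minimize(residual, pars, method="leastsq")
    k = float(out.params["k"].value)
    k_se = float(out.params["k"].stderr) if out.params["k"].stderr else math.nan
    plateau = float(out.params["plateau"].value)
    p_se = (
        float(out.params["plateau"].stderr)
        if free_plateau and out.params["plateau"].stderr
        else None
    )
    return KineticFit(k, k_se, model, plateau, p_se)


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------


def hierarchy_report(
    events: Iterable[tuple[str, float, float]],
    order: Sequence[str] = HIERARCHY,
    min_events: int = 5,
) -> tuple[pd.DataFrame, bool]:
    """Per-domain force/size statistics and the mechanical-hierarchy flag.

    ``events`` are ``(domain, force, size)`` triples from classified ruptures
    across experiments.  Returns a table (mean +/- SEM force, mean +/- SD
    size, n) and a flag that is True iff every domain of ``order`` has at
    least ``min_events`` events and their mean forces are strictly
    decreasing along ``order``.
    """
    rows = list(events)
    if not rows:
        return (
            pd.DataFrame(
                columns=["n", "mean_force", "sem_force", "mean_size", "sd_size"]
            ),
            False,
        )
    df = pd.DataFrame(rows, columns=["domain", "force", "size"])
    g = df.groupby("domain")
    table = pd.DataFrame(
        {
            "n": g.size(),
            "mean_force": g["force"].mean(),
            "sem_force": g["force"].sem(),
            "mean_size": g["size"].mean(),
            "sd_size": g["size"].std(),
        }
    )
    present = [d for d in order if d in table.index and table.loc[d, "n"] >= min_events]
    ordered = False
    if len(present) == len(order):
        forces = [table.loc[d, "mean_force"] for d in order]
        ordered = all(a > b for a, b in zip(forces[:-1], forces[1:]))
    # strongest first in the report
    table = table.sort_values("mean_force", ascending=False)
    return table, ordered
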