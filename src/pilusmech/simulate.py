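"""Synthetic AFM trace generator for pilus polyprotein constructs.

Three experiment modes are simulated, matching the measurement protocols:

* force-extension: the cantilever base retracts at constant velocity; the
  force follows the quasi-static equilibrium of the cantilever spring in
  series with the WLC of the currently liberated contour.  Unfolding events
  are sampled from the Bell hazard along the resulting nonlinear force
  schedule, each adding its contour-length increment; the trace ends with a
  detachment event at a high force.
* force-ramp: the feedback raises the force linearly; each rupture appears as
  an extension step.  Rupture forces follow the closed-form Bell-ramp
  distribution; quaternary inter-domain steps are inserted stochastically.
* force-clamp: pulses of constant force produce staircases of observed step
  sizes; 0 pN quenches allow refolding (chaperone-condition dependent) and
  DsbA redox chemistry (reduction under low force, reoxidation on folding).

Every trace carries a ground-truth event log so the blind analysis pipeline
can be validated against what actually happened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np

from . import registry as reg
from .kinetics import BellParams, RefoldingCondition, refold_probability
from .registry import Construct, DomainState, QuaternaryStepModel, load_registry
from .wlc import KBT_ROOM, WLCParams, wlc_extension

__all__ = [
    "Protocol",
    "NoiseModel",
    "Event",
    "Trace",
    "parse_pulses",
    "refold_3pulse_protocol",
    "oxfold_4pulse_protocol",
    "fimh_4pulse_protocol",
    "simulate_force_extension",
    "simulate_force_ramp",
    "simulate_force_clamp",
    "add_noise",
    "mean_fx_rupture_force",
]

_PHYS = load_registry()["physics"]
_NOISE = load_registry()["noise"]

#: quenches at least this long refold every I91 handle (their fast,
#: well-characterised folding is not the object of study here)
I91_REFOLD_MIN_QUENCH = 10.0

#: pulses within this window of 100 pN allow enzymatic disulfide reduction
REDUCTION_FORCE_WINDOW = (50.0, 150.0)


@dataclass(frozen=True)
class Protocol:
    """Declarative description of one AFM experiment."""

    mode: str  # force_extension | force_ramp | force_clamp
    velocity: float = 400.0  # nm/s (force_extension)
    cantilever_stiffness: float = _PHYS["cantilever_stiffness"]  # pN/nm
    load_rate: float = 10.0  # pN/s (force_ramp)
    force_range: tuple[float, float] = (-10.0, 400.0)  # pN (force_ramp)
    pulses: tuple[tuple[float, float], ...] = ()  # (force pN, duration s)
    detachment_force: float = _PHYS["detachment_force"]
    detachment_sd: float = _PHYS["detachment_sd"]

    def __post_init__(self) -> None:
        if self.mode not in ("force_extension", "force_ramp", "force_clamp"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "force_extension" and not (self.velocity > 0):
            raise ValueError("velocity must be > 0")
        if self.mode == "force_ramp" and not (self.load_rate > 0):
            raise ValueError("load_rate must be > 0")
        if self.mode == "force_clamp":
            if not self.pulses:
                raise ValueError("force_clamp protocol needs pulses")
            for f, d in self.pulses:
                if d <= 0:
                    raise ValueError("pulse durations must be > 0")
                if f < 0:
                    raise ValueError("pulse forces must be >= 0")

    @classmethod
    def force_extension(cls, velocity: float = 400.0, **kw) -> "Protocol":
        return cls(mode="force_extension", velocity=velocity, **kw)

    @classmethod
    def force_ramp(
        cls,
        load_rate: float = 10.0,
        force_range: tuple[float, float] = (-10.0, 400.0),
        **kw,
    ) -> "Protocol":
        return cls(mode="force_ramp", load_rate=load_rate, force_range=force_range, **kw)

    @classmethod
    def force_clamp(cls, pulses, **kw) -> "Protocol":
        return cls(mode="force_clamp", pulses=tuple(tuple(p) for p in pulses), **kw)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "velocity": self.velocity,
            "cantilever_stiffness": self.cantilever_stiffness,
            "load_rate": self.load_rate,
            "force_range": list(self.force_range),
            "pulses": [list(p) for p in self.pulses],
            "detachment_force": self.detachment_force,
            "detachment_sd": self.detachment_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            mode=d["mode"],
            velocity=d.get("velocity", 400.0),
            cantilever_stiffness=d.get(
                "cantilever_stiffness", _PHYS["cantilever_stiffness"]
            ),
            load_rate=d.get("load_rate", 10.0),
            force_range=tuple(d.get("force_range", (-10.0, 400.0))),
            pulses=tuple(tuple(p) for p in d.get("pulses", ())),
            detachment_force=d.get("detachment_force", _PHYS["detachment_force"]),
            detachment_sd=d.get("detachment_sd", _PHYS["detachment_sd"]),
        )


def parse_pulses(text: str) -> tuple[tuple[float, float], ...]:
    """Parse a pulse schedule mini-grammar, e.g. ``"160:2,300:20,0:45"``.

    Each ``force:duration`` pair is one pulse; 0-force segments are quenches.
    """
    pulses = []
    for i, tok in enumerate(text.split(",")):
        try:
            f_s, d_s = tok.split(":")
            pulses.append((float(f_s), float(d_s)))
        except ValueError as exc:
            raise ValueError(f"bad pulse token {tok!r} (position {i}): {exc}") from None
    return tuple(pulses)


def refold_3pulse_protocol(quench: float = 45.0) -> Protocol:
    """160 pN (2 s) + 300 pN (20 s), quench, then the same probe pulses."""
    return Protocol.force_clamp(
        [(160, 2), (300, 20), (0, quench), (160, 2), (300, 20)]
    )


def oxfold_4pulse_protocol(quench: float = 45.0) -> Protocol:
    """160 pN (2 s) + 300 pN (5 s) + 100 pN (2 s), quench, then probe."""
    return Protocol.force_clamp(
        [(160, 2), (300, 5), (100, 2), (0, quench), (160, 2), (300, 5), (100, 2)]
    )


def fimh_4pulse_protocol(quench: float = 10.0) -> Protocol:
    """60 pN (5 s) + 160 pN (3 s) + 250 pN (7 s), quench, then probe."""
    return Protocol.force_clamp(
        [(60, 5), (160, 3), (250, 7), (0, quench), (60, 5), (160, 3), (250, 7)]
    )


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise on the observable channel."""

    force_sd: float = _NOISE["force_sd"]
    extension_sd: float = _NOISE["extension_sd"]
    sampling_rate: float = _NOISE["sampling_rate"]

    def __post_init__(self) -> None:
        if self.force_sd < 0 or self.extension_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")

    def to_dict(self) -> dict:
        return {
            "force_sd": self.force_sd,
            "extension_sd": self.extension_sd,
            "sampling_rate": self.sampling_rate,
        }


CLEAN = NoiseModel(force_sd=0.0, extension_sd=0.0)


@dataclass
class Event:
    """Ground-truth simulator event."""

    time: float
    kind: str  # unfold | reduce | refold | oxidize | quaternary_step | detach
    domain: str
    size: float
    force: float
    note: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "kind": self.kind,
            "domain": self.domain,
            "size": self.size,
            "force": self.force,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(
            d["time"], d["kind"], d["domain"], d["size"], d["force"], d.get("note")
        )


@dataclass
class Trace:
    """Simulated (or loaded) time series plus metadata and ground truth."""

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.time)
        if len(self.extension) != n or len(self.force) != n:
            raise ValueError("time/extension/force must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def _resolve_rng(rng, seed):
    if rng is not None:
        return rng, None if seed is None else int(seed)
    return np.random.default_rng(seed), None if seed is None else int(seed)


def _base_metadata(mode, construct, protocol, noise, seed) -> dict:
    return {
        "mode": mode,
        "construct": construct.spec_string or "custom",
        "protocol": protocol.to_dict(),
        "noise": noise.to_dict(),
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# Force-extension mode
# ---------------------------------------------------------------------------


@dataclass
class _Unit:
    """One independently rupturing element in the event engine."""

    name: str
    bell: BellParams
    size: float  # contour (FX) or observed step (ramp/clamp), nm
    note: Optional[str] = None
    activates: Optional["_Unit"] = None  # serial successor (intermediate path)


class _FxTables:
    """Per-run cache of x(F) / z(F) grids keyed by contour length."""

    def __init__(self, stiffness: float, persistence: float, kbt: float):
        self.kc = stiffness
        self.p = persistence
        self.kbt = kbt
        self.f_grid = np.linspace(0.0, 1600.0, 2048)
        self._x: dict[float, np.ndarray] = {}
        self._rate: dict[BellParams, np.ndarray] = {}

    def x_of_f(self, lc: float) -> np.ndarray:
        key = round(lc, 6)
        if key not in self._x:
            params = WLCParams(self.p, lc, self.kbt)
            self._x[key] = wlc_extension(self.f_grid, params)
        return self._x[key]

    def z_of_f(self, lc: float) -> np.ndarray:
        return self.x_of_f(lc) + self.f_grid / self.kc

    def rate_of_f(self, bell: BellParams) -> np.ndarray:
        if bell not in self._rate:
            self._rate[bell] = bell.intrinsic_rate * np.exp(
                self.f_grid * bell.distance_to_transition / self.kbt
            )
        return self._rate[bell]


def _expand_units(construct: Construct, rng, mode: str) -> list[_Unit]:
    units: list[_Unit] = []
    for d in construct.domains:
        spec = d.spec
        if d.fold_state != reg.FOLDED:
            continue
        bell = spec.bell(d.redox_state)
        if mode == "force_extension":
            inter = spec.intermediate
            if inter is not None and rng.random() < inter.occurrence_prob:
                rest = _Unit(spec.name, inter.bell_remainder, inter.remainder,
                             note="remainder")
                first = _Unit(spec.name, inter.bell_step, inter.step,
                              note="intermediate", activates=rest)
                units.append(first)
                continue
            size = (
                spec.delta_lc_red
                if d.redox_state == reg.REDUCED and spec.delta_lc_red is not None
                else spec.delta_lc_ox
            )
            units.append(_Unit(spec.name, bell, size))
        else:
            units.append(_Unit(spec.name, bell, spec.step_ramp))
    return units


def _fx_events(
    construct: Construct,
    protocol: Protocol,
    rng: np.random.Generator,
    tables: _FxTables,
) -> list[Event]:
    v = protocol.velocity
    f_grid = tables.f_grid
    detach_force = max(
        300.0, rng.normal(protocol.detachment_force, protocol.detachment_sd)
    )
    units = _expand_units(construct, rng, "force_extension")
    lc = construct.linker_slack
    z_cur = 0.0
    events: list[Event] = []

    while True:
        z_of_f = tables.z_of_f(lc)
        f_start = float(np.interp(z_cur, z_of_f, f_grid))
        if not units:
            t_det = float(np.interp(detach_force, f_grid, z_of_f)) / v
            events.append(Event(t_det, "detach", "tether", 0.0, detach_force))
            break
        k_tot = np.zeros_like(f_grid)
        for u in units:
            k_tot += tables.rate_of_f(u.bell)
        # cumulative hazard along the schedule: dt = dz/v
        seg = 0.5 * (k_tot[1:] + k_tot[:-1]) * np.diff(z_of_f) / v
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        cum_start = float(np.interp(f_start, f_grid, cum))
        cum_detach = float(np.interp(detach_force, f_grid, cum))
        target = cum_start + rng.exponential()
        if target >= cum_detach:
            t_det = float(np.interp(detach_force, f_grid, z_of_f)) / v
            events.append(Event(t_det, "detach", "tether", 0.0, detach_force))
            break
        f_star = float(np.interp(target, cum, f_grid))
        z_star = float(np.interp(f_star, f_grid, z_of_f))
        weights = np.array(
            [
                u.bell.intrinsic_rate
                * math.exp(f_star * u.bell.distance_to_transition / tables.kbt)
                for u in units
            ]
        )
        idx = int(rng.choice(len(units), p=weights / weights.sum()))
        u = units.pop(idx)
        events.append(Event(z_star / v, "unfold", u.name, u.size, f_star, u.note))
        if u.activates is not None:
            units.append(u.activates)
        lc += u.size
        z_cur = z_star
    return events


def simulate_force_extension(
    construct: Construct,
    protocol: Protocol,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    events_only: bool = False,
    persistence_length: float = _PHYS["persistence_length"],
    thermal_energy: float = KBT_ROOM,
) -> Trace:
    """Simulate one sawtooth force-extension pull of ``construct``."""
    if protocol.mode != "force_extension":
        raise ValueError("protocol mode must be force_extension")
    noise = NoiseModel() if noise is None else noise
    rng, seed = _resolve_rng(rng, seed)
    tables = _FxTables(protocol.cantilever_stiffness, persistence_length, thermal_energy)
    events = _fx_events(construct, protocol, rng, tables)

    meta = _base_metadata("force_extension", construct, protocol, noise, seed)
    if events_only:
        return Trace(np.zeros(1), np.zeros(1), np.zeros(1), meta, events)

    fs = noise.sampling_rate
    v = protocol.velocity
    t_end = events[-1].time + 0.05
    t = np.arange(0.0, t_end, 1.0 / fs)
    z = v * t
    ext = np.zeros_like(t)
    force = np.zeros_like(t)
    bounds = [0.0] + [e.time for e in events]
    lc = construct.linker_slack
    f_grid = tables.f_grid
    for i, e in enumerate(events):
        sel = (t >= bounds[i]) & (t < bounds[i + 1] + 0.5 / fs)
        if np.any(sel):
            z_of_f = tables.z_of_f(lc)
            force[sel] = np.interp(z[sel], z_of_f, f_grid)
            ext[sel] = np.interp(z[sel], z_of_f, tables.x_of_f(lc))
        if e.kind == "unfold":
            lc += e.size
    after = t >= events[-1].time
    force[after] = 0.0
    ext[after] = z[after]  # free cantilever travels with the base

    trace = Trace(t, ext, force, meta, events)
    return add_noise(trace, noise, rng)


def mean_fx_rupture_force(
    construct: Construct,
    protocol: Protocol,
    domain: str,
    candidate: Optional[BellParams] = None,
    n_events: int = 2000,
    seed: int = 0,
    persistence_length: float = _PHYS["persistence_length"],
    thermal_energy: float = KBT_ROOM,
) -> float:
    """Mean simulated rupture force of ``domain`` (event-level, no rendering).

    Used by the calibration loop; with a fixed ``seed`` this is a
    deterministic, monotone function of the candidate intrinsic rate.
    """
    work = construct.copy()
    if candidate is not None:
        for d in work.domains:
            if d.spec.name == domain:
                d.spec = dc_replace(d.spec, bell_ox=candidate, bell_red=candidate)
    rng = np.random.default_rng(seed)
    tables = _FxTables(protocol.cantilever_stiffness, persistence_length, thermal_energy)
    forces: list[float] = []
    n_traces = 0
    while len(forces) < n_events and n_traces < 20 * n_events:
        events = _fx_events(work, protocol, rng, tables)
        n_traces += 1
        forces.extend(
            e.force
            for e in events
            if e.kind == "unfold" and e.domain == domain and e.note is None
        )
    if not forces:
        raise ValueError(f"no rupture events observed for {domain}")
    return float(np.mean(forces))


# ---------------------------------------------------------------------------
# Force-ramp mode
# ---------------------------------------------------------------------------


def simulate_force_ramp(
    construct: Construct,
    protocol: Protocol,
    quaternary: Optional[QuaternaryStepModel] = None,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    events_only: bool = False,
    persistence_length: float = _PHYS["persistence_length"],
    thermal_energy: float = KBT_ROOM,
) -> Trace:
    """Simulate one extension-vs-time staircase under a linear force ramp.

    Force is controlled, so domain ruptures are independent draws from the
    closed-form Bell-ramp distribution; ruptures beyond the end of the ramp
    are censored (the domain simply never unfolds in the trace).
    """
    if protocol.mode != "force_ramp":
        raise ValueError("protocol mode must be force_ramp")
    noise = NoiseModel() if noise is None else noise
    rng, seed = _resolve_rng(rng, seed)
    f0, fmax = protocol.force_range
    r = protocol.load_rate

    events: list[Event] = []
    for u in _expand_units(construct, rng, "force_ramp"):
        a = u.bell.distance_to_transition / thermal_energy
        k0 = u.bell.intrinsic_rate
        e_var = rng.exponential()
        if a == 0:
            f_rupt = f0 + e_var * r / k0
        else:
            f_rupt = math.log(math.exp(a * f0) + r * a * e_var / k0) / a
        if f_rupt >= fmax:
            continue  # censored: survives the ramp
        size = max(rng.normal(u.size, 1.0), 1.0)
        events.append(Event((f_rupt - f0) / r, "unfold", u.name, size, f_rupt))

    if quaternary is not None and rng.random() < quaternary.occurrence_prob:
        count = int(rng.integers(1, quaternary.max_count + 1))
        for _ in range(count):
            fq = float(
                np.clip(
                    rng.normal(quaternary.mean_force, quaternary.force_sd),
                    20.0,
                    min(180.0, fmax - 1.0),
                )
            )
            size = max(rng.normal(quaternary.step_size, quaternary.step_sd), 1.0)
            events.append(
                Event((fq - f0) / r, "quaternary_step", "quaternary", size, fq)
            )
    events.sort(key=lambda e: e.time)

    meta = _base_metadata("force_ramp", construct, protocol, noise, seed)
    if events_only:
        return Trace(np.zeros(1), np.zeros(1), np.zeros(1), meta, events)

    fs = noise.sampling_rate
    duration = (fmax - f0) / r
    t = np.arange(0.0, duration, 1.0 / fs)
    force = f0 + r * t
    params = WLCParams(persistence_length, construct.linker_slack, thermal_energy)
    fg = np.linspace(0.0, fmax, 1024)
    xg = wlc_extension(fg, params)
    ext = np.where(force > 0, np.interp(np.clip(force, 0, None), fg, xg), 0.0)
    for e in events:
        ext[t >= e.time] += e.size

    trace = Trace(t, ext, force, meta, events)
    return add_noise(trace, noise, rng)


# ---------------------------------------------------------------------------
# Force-clamp mode
# ---------------------------------------------------------------------------


def _is_subject(d: DomainState) -> bool:
    """Domains whose refolding is governed by the chaperone condition
    (everything except the I91 fingerprint handles)."""
    return d.spec.name != "I91"


def simulate_force_clamp(
    construct: Construct,
    protocol: Protocol,
    cond: RefoldingCondition,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    persistence_length: float = _PHYS["persistence_length"],
    thermal_energy: float = KBT_ROOM,
) -> Trace:
    """Simulate one multi-pulse force-clamp trace under a chaperone condition.

    The condition's label sets the initial redox state of the disulfide
    domains (``red_*`` labels start reduced).  During force pulses each
    folded domain unfolds with constant-force Bell kinetics, producing its
    observed step; ~100 pN pulses allow DsbA reduction of unfolded oxidized
    domains; 0 pN quenches allow refolding (plateaued-exponential success
    probability) and, with DsbA present, reoxidation.
    """
    if protocol.mode != "force_clamp":
        raise ValueError("protocol mode must be force_clamp")
    noise = NoiseModel() if noise is None else noise
    rng, seed = _resolve_rng(rng, seed)
    work = construct.copy()
    if cond.starts_reduced:
        work.set_redox(reg.REDUCED)
    has_quench = any(f == 0 for f, _ in protocol.pulses)
    if not has_quench and cond.fold_rate > 0:
        import warnings

        warnings.warn(
            "protocol has no 0 pN quench but the condition expects refolding",
            stacklevel=2,
        )

    fs = noise.sampling_rate
    params = WLCParams(persistence_length, work.linker_slack, thermal_energy)
    events: list[Event] = []
    seg_t: list[np.ndarray] = []
    seg_x: list[np.ndarray] = []
    seg_f: list[np.ndarray] = []
    t0 = 0.0
    released_total = 0.0

    for f_pulse, dur in protocol.pulses:
        pulse_events: list[Event] = []
        if f_pulse > 0:
            for d in work.domains:
                if d.fold_state == reg.FOLDED:
                    k = d.spec.bell(d.redox_state).intrinsic_rate * math.exp(
                        f_pulse
                        * d.spec.bell(d.redox_state).distance_to_transition
                        / thermal_energy
                    )
                    if k <= 0:
                        continue
                    tau = rng.exponential(1.0 / k)
                    if tau < dur:
                        size = max(
                            rng.normal(d.spec.clamp_step(d.redox_state), 0.5), 1.0
                        )
                        d.fold_state = reg.UNFOLDED
                        d.released += size
                        pulse_events.append(
                            Event(t0 + tau, "unfold", d.spec.name, size, f_pulse)
                        )
            lo, hi = REDUCTION_FORCE_WINDOW
            if cond.reduction_prob > 0 and lo <= f_pulse <= hi:
                for d in work.domains:
                    if (
                        d.fold_state == reg.UNFOLDED
                        and d.redox_state == reg.OXIDIZED
                        and d.spec.reduction_step is not None
                        and rng.random() < cond.reduction_prob
                    ):
                        size = max(rng.normal(d.spec.reduction_step, 0.5), 1.0)
                        d.redox_state = reg.REDUCED
                        d.released += size
                        pulse_events.append(
                            Event(
                                t0 + rng.uniform(0, dur),
                                "reduce",
                                d.spec.name,
                                size,
                                f_pulse,
                            )
                        )
        else:  # quench
            for d in work.domains:
                if d.fold_state != reg.UNFOLDED:
                    continue
                if d.spec.name == "I91":
                    if dur >= I91_REFOLD_MIN_QUENCH:
                        t_fold = t0 + min(1.0, 0.5 * dur)
                        pulse_events.append(
                            Event(t_fold, "refold", "I91", d.released, 0.0)
                        )
                        d.fold_state = reg.FOLDED
                        d.released = 0.0
                elif _is_subject(d):
                    if rng.random() < refold_probability(dur, cond):
                        kf = max(cond.fold_rate, 1e-9)
                        u = rng.random()
                        t_fold = t0 - math.log(
                            1.0 - u * (1.0 - math.exp(-kf * dur))
                        ) / kf
                        pulse_events.append(
                            Event(t_fold, "refold", d.spec.name, d.released, 0.0)
                        )
                        d.fold_state = reg.FOLDED
                        d.released = 0.0
                        if (
                            d.redox_state == reg.REDUCED
                            and cond.has_dsba
                            and rng.random() < cond.oxidation_prob
                        ):
                            d.redox_state = reg.OXIDIZED
                            pulse_events.append(
                                Event(
                                    min(t_fold + 0.5, t0 + dur),
                                    "oxidize",
                                    d.spec.name,
                                    0.0,
                                    0.0,
                                )
                            )

        pulse_events.sort(key=lambda e: e.time)
        events.extend(pulse_events)

        n = max(int(round(dur * fs)), 2)
        tt = t0 + np.arange(n) / fs
        ff = np.full(n, float(f_pulse))
        if f_pulse > 0:
            base = float(wlc_extension(f_pulse, params))
            xx = np.full(n, base + released_total)
            for e in pulse_events:
                if e.kind in ("unfold", "reduce"):
                    xx[tt >= e.time] += e.size
                    released_total += e.size
        else:
            xx = np.zeros(n)
            for e in pulse_events:
                if e.kind == "refold":
                    released_total -= e.size
        seg_t.append(tt)
        seg_x.append(xx)
        seg_f.append(ff)
        t0 += dur

    meta = _base_metadata("force_clamp", work, protocol, noise, seed)
    meta["condition"] = cond.label
    trace = Trace(
        np.concatenate(seg_t),
        np.concatenate(seg_x),
        np.concatenate(seg_f),
        meta,
        events,
    )
    return add_noise(trace, noise, rng)


# ---------------------------------------------------------------------------


def add_noise(trace: Trace, noise: NoiseModel, rng: np.random.Generator) -> Trace:
    """Add Gaussian noise to the observable channel of a trace.

    Force-extension traces are noisy in force; clamp traces in extension;
    ramp traces carry force noise (the feedback error) and extension noise
    (the observable staircase).  The ground-truth event log is untouched.
    """
    mode = trace.metadata.get("mode", "force_extension")
    force = trace.force.copy()
    ext = trace.extension.copy()
    n = len(trace.time)
    if mode in ("force_extension", "force_ramp") and noise.force_sd > 0:
        force = force + rng.normal(0.0, noise.force_sd, n)
    if mode in ("force_clamp", "force_ramp") and noise.extension_sd > 0:
        ext = ext + rng.normal(0.0, noise.extension_sd, n)
    return Trace(trace.time.copy(), ext, force, dict(trace.metadata), trace.events)
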