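"""Two-state force-dependent unfolding/refolding kinetics.

Unfolding is modelled with the Bell law, k(F) = k0 * exp(F * dx / kBT): a
single exponential barrier whose height decreases linearly with force.  This
is the minimal model consistent with the single-exponential unfolding
observed at constant force, and it admits closed forms both at constant force
and under a linear force ramp, which the calibration and the test oracles
exploit.

Waiting times under an arbitrary force schedule are sampled by integrating
the hazard k(F(t)) and inverting the cumulative hazard at an Exp(1) variate.

Refolding at zero force is modelled as a plateaued exponential,
P(dt) = P_inf * (1 - exp(-k_fold * dt)): chaperone conditions change the
plateau P_inf (how often folding succeeds at all) without necessarily
changing the rate, which is exactly the FimC phenomenology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .wlc import KBT_ROOM

__all__ = [
    "CENSORED",
    "BellParams",
    "RefoldingCondition",
    "rate_at_force",
    "survival_probability",
    "ConstantForce",
    "LinearRamp",
    "TabulatedSchedule",
    "draw_waiting_time",
    "ramp_rupture_quantile",
    "ramp_rupture_cdf",
    "ramp_mean_rupture_force",
    "solve_ramp_k0",
    "calibrate_bell",
    "refold_probability",
]

#: sentinel returned when no event occurs within a finite schedule
CENSORED = math.inf

CONDITION_LABELS = (
    "ox_alone",
    "ox_FimC",
    "red_alone",
    "red_FimC",
    "red_DsbA",
    "red_FimC_DsbA",
)


@dataclass(frozen=True)
class BellParams:
    """Bell-model kinetic parameters: intrinsic rate k0 (1/s) and
    distance to the transition state dx (nm)."""

    intrinsic_rate: float
    distance_to_transition: float

    def __post_init__(self) -> None:
        if not (self.intrinsic_rate > 0):
            raise ValueError("intrinsic_rate must be > 0")
        if self.distance_to_transition < 0:
            raise ValueError("distance_to_transition must be >= 0")


@dataclass(frozen=True)
class RefoldingCondition:
    """Per-condition refolding kinetics and redox chemistry.

    ``fold_rate`` (1/s) and ``fold_plateau`` parameterise the plateaued
    exponential refolding probability; ``oxidation_prob`` is the probability
    that DsbA reforms the disulfide during a quench in which the domain
    folded; ``reduction_prob`` is the probability per low-force (~100 pN)
    pulse that reduced DsbA cleaves the disulfide of the unfolded domain.
    """

    label: str
    fold_rate: float
    fold_plateau: float
    oxidation_prob: float = 0.0
    reduction_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValueError(
                f"unknown condition {self.label!r}; valid: {CONDITION_LABELS}"
            )
        if self.fold_rate < 0:
            raise ValueError("fold_rate must be >= 0")
        for name in ("fold_plateau", "oxidation_prob", "reduction_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def starts_reduced(self) -> bool:
        return self.label.startswith("red")

    @property
    def has_dsba(self) -> bool:
        return "DsbA" in self.label


def rate_at_force(force, params: BellParams, thermal_energy: float = KBT_ROOM):
    """Bell rate k(F) = k0 * exp(F * dx / kBT), 1/s."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    out = params.intrinsic_rate * np.exp(
        f * params.distance_to_transition / thermal_energy
    )
    return float(out) if np.ndim(force) == 0 else out


def survival_probability(
    force: float,
    duration: float,
    params: BellParams,
    thermal_energy: float = KBT_ROOM,
) -> float:
    """Probability of remaining folded for ``duration`` s at constant force."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    return float(np.exp(-rate_at_force(force, params, thermal_energy) * duration))


# ---------------------------------------------------------------------------
# Force schedules and waiting-time sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantForce:
    force: float
    duration: float


@dataclass(frozen=True)
class LinearRamp:
    """Force increasing linearly from ``start_force`` at ``load_rate`` pN/s."""

    start_force: float
    load_rate: float
    duration: float

    def force_at(self, t):
        return self.start_force + self.load_rate * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class TabulatedSchedule:
    """Piecewise-linear force-vs-time table (e.g. constant-velocity pulling)."""

    time: np.ndarray = field(repr=False)
    force: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if t.shape != f.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("time and force must be matching 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)


def _ramp_log_cumhaz_coeff(params: BellParams, rate: float, kbt: float) -> float:
    return params.distance_to_transition / kbt


def _ramp_cumulative_hazard(f, f0, params: BellParams, rate: float, kbt: float):
    """Cumulative hazard accumulated while ramping from f0 to f at `rate`."""
    a = params.distance_to_transition / kbt
    k0 = params.intrinsic_rate
    f = np.asarray(f, dtype=float)
    if a == 0:
        return k0 * (f - f0) / rate
    return (k0 / (rate * a)) * (np.exp(a * f) - np.exp(a * f0))


def draw_waiting_time(
    schedule,
    params: BellParams,
    rng: np.random.Generator,
    thermal_energy: float = KBT_ROOM,
) -> float:
    """Sample the unfolding time under a force schedule.

    Returns the waiting time (s) from the start of the schedule, or
    :data:`CENSORED` (``math.inf``) if the domain survives the whole
    schedule.  Sampling inverts the cumulative hazard at an Exp(1) variate;
    constant and linear-ramp schedules use closed forms, tabulated schedules
    use trapezoid integration of the hazard.
    """
    target = rng.exponential()
    kbt = thermal_energy

    if isinstance(schedule, ConstantForce):
        k = rate_at_force(max(schedule.force, 0.0), params, kbt)
        if k <= 0:
            return CENSORED
        t = target / k
        return t if t < schedule.duration else CENSORED

    if isinstance(schedule, LinearRamp):
        a = params.distance_to_transition / kbt
        k0 = params.intrinsic_rate
        r = schedule.load_rate
        f0 = schedule.start_force
        f_end = f0 + r * schedule.duration
        total = float(_ramp_cumulative_hazard(f_end, f0, params, r, kbt))
        if total <= target:
            return CENSORED
        if a == 0:
            f_star = f0 + target * r / k0
        else:
            f_star = np.log(np.exp(a * f0) + r * a * target / k0) / a
        return float((f_star - f0) / r)

    if isinstance(schedule, TabulatedSchedule):
        k = rate_at_force(np.clip(schedule.force, 0.0, None), params, kbt)
        dt = np.diff(schedule.time)
        seg = 0.5 * (k[1:] + k[:-1]) * dt
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if cum[-1] <= target:
            return CENSORED
        idx = int(np.searchsorted(cum, target) - 1)
        frac = (target - cum[idx]) / (cum[idx + 1] - cum[idx])
        return float(
            schedule.time[idx] + frac * (schedule.time[idx + 1] - schedule.time[idx])
        )

    raise TypeError(f"unsupported schedule type: {type(schedule).__name__}")


# ---------------------------------------------------------------------------
# Linear-ramp closed forms (analytic oracles + calibration)
# ---------------------------------------------------------------------------


def ramp_rupture_cdf(
    f,
    params: BellParams,
    load_rate: float,
    start_force: float = 0.0,
    thermal_energy: float = KBT_ROOM,
):
    """CDF of the rupture force under a linear force ramp."""
    lam = _ramp_cumulative_hazard(f, start_force, params, load_rate, thermal_energy)
    return 1.0 - np.exp(-lam)


def ramp_rupture_quantile(
    u,
    params: BellParams,
    load_rate: float,
    start_force: float = 0.0,
    thermal_energy: float = KBT_ROOM,
):
    """Inverse CDF: rupture force at probability ``u`` under a linear ramp."""
    a = params.distance_to_transition / thermal_energy
    k0 = params.intrinsic_rate
    target = -np.log1p(-np.asarray(u, dtype=float))
    if a == 0:
        return start_force + target * load_rate / k0
    return np.log(np.exp(a * start_force) + load_rate * a * target / k0) / a


def ramp_mean_rupture_force(
    params: BellParams,
    load_rate: float,
    start_force: float = -10.0,
    max_force: float = 400.0,
    thermal_energy: float = KBT_ROOM,
    truncated: bool = True,
    n_grid: int = 4001,
) -> float:
    """Mean rupture force under a linear ramp, by quadrature.

    With ``truncated=True`` the mean is conditional on rupture before
    ``max_force`` (events past the end of the ramp are never observed), which
    is what a measured mean over detected steps estimates.
    """
    f = np.linspace(start_force, max_force, n_grid)
    lam = _ramp_cumulative_hazard(f, start_force, params, load_rate, thermal_energy)
    surv = np.exp(-lam)
    k = rate_at_force(np.clip(f, 0.0, None), params, thermal_energy)
    pdf = k * surv / load_rate
    num = np.trapezoid(f * pdf, f)
    den = np.trapezoid(pdf, f)
    if den <= 0:
        raise ValueError("rupture probability is zero on the ramp")
    if not truncated:
        den = 1.0
    return float(num / den)


def solve_ramp_k0(
    target_mean_force: float,
    dx: float,
    load_rate: float,
    start_force: float = -10.0,
    max_force: float = 400.0,
    thermal_energy: float = KBT_ROOM,
) -> float:
    """Solve for k0 so that the ramp mean rupture force equals the target."""
    from scipy.optimize import brentq

    def objective(log10_k0: float) -> float:
        p = BellParams(10.0**log10_k0, dx)
        return (
            ramp_mean_rupture_force(
                p, load_rate, start_force, max_force, thermal_energy
            )
            - target_mean_force
        )

    lo, hi = -24.0, 3.0
    if objective(lo) < 0 or objective(hi) > 0:
        raise ValueError(
            f"ramp mean force {target_mean_force} pN not bracketable with dx={dx}"
        )
    root = brentq(objective, lo, hi, xtol=1e-6)
    return float(10.0**root)


# ---------------------------------------------------------------------------
# Calibration to printed mean rupture forces
# ---------------------------------------------------------------------------


def calibrate_bell(
    target_mean_force: float,
    protocol,
    dx_prior: float,
    *,
    construct=None,
    domain: str | None = None,
    n_events: int = 2000,
    seed: int = 0,
    thermal_energy: float = KBT_ROOM,
) -> BellParams:
    """Calibrate k0 (dx fixed at ``dx_prior``) to a printed mean rupture force.

    The paper reports mean unfolding forces but never the underlying kinetic
    parameters, so k0 is solved by monotone root-finding such that the
    simulated mean rupture force under ``protocol`` equals the target.

    * force-ramp protocols use the closed-form ramp distribution;
    * force-extension protocols run the event-level Monte-Carlo simulator on
      ``construct`` (with the named ``domain``'s parameters replaced by the
      candidate) using common random numbers, so the objective is a
      deterministic, monotone function of k0.
    """
    if target_mean_force <= 0:
        raise ValueError("target mean force must be > 0")

    mode = getattr(protocol, "mode", None)
    if mode == "force_ramp":
        f0, fmax = protocol.force_range
        k0 = solve_ramp_k0(
            target_mean_force,
            dx_prior,
            protocol.load_rate,
            start_force=f0,
            max_force=fmax,
            thermal_energy=thermal_energy,
        )
        return BellParams(k0, dx_prior)

    if mode == "force_extension":
        if construct is None or domain is None:
            raise ValueError(
                "force-extension calibration needs a construct and a domain name"
            )
        from scipy.optimize import brentq

        from .simulate import mean_fx_rupture_force

        def objective(log10_k0: float) -> float:
            candidate = BellParams(10.0**log10_k0, dx_prior)
            mean = mean_fx_rupture_force(
                construct,
                protocol,
                domain,
                candidate,
                n_events=n_events,
                seed=seed,
            )
            return mean - target_mean_force

        lo, hi = -12.0, 2.0
        f_lo, f_hi = objective(lo), objective(hi)
        if f_lo < 0 or f_hi > 0:
            raise ValueError(
                f"target {target_mean_force} pN not bracketable for {domain} "
                f"with dx={dx_prior} (mean range [{f_hi + target_mean_force:.0f}, "
                f"{f_lo + target_mean_force:.0f}] pN)"
            )
        root = brentq(objective, lo, hi, xtol=2e-3)
        return BellParams(10.0**root, dx_prior)

    raise ValueError(f"cannot calibrate against protocol mode {mode!r}")


def refold_probability(quench_time: float, cond: RefoldingCondition) -> float:
    """Plateaued-exponential refolding probability after a 0 pN quench."""
    if quench_time < 0:
        raise ValueError("quench_time must be >= 0")
    return float(cond.fold_plateau * (1.0 - math.exp(-cond.fold_rate * quench_time)))
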