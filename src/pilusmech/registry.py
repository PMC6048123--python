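"""Registry of per-domain mechanical/kinetic parameters and polyprotein constructs.

The registry encodes the measured properties of the titin I91 fingerprint and
the five pilus (sub)domains — FimA, FimF, FimG, FimH_P, FimH_L — in both
redox states: contour-length increments, mean unfolding forces in
force-extension and force-ramp modes, observed force-clamp step sizes, the
disulfide reduction step, and the calibrated Bell kinetic parameters.

Values ship in ``data/registry.toml`` (human-readable; user overrides merge
over the defaults).  Bell parameters are calibrated — not printed anywhere —
such that simulated campaigns reproduce the measured mean rupture forces and
300 pN unfolding rates; ``scripts/calibrate_registry.py`` regenerates them.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

from .kinetics import BellParams, RefoldingCondition

__all__ = [
    "IntermediateSpec",
    "DomainSpec",
    "DomainState",
    "Construct",
    "QuaternaryStepModel",
    "builtin_domain",
    "builtin_condition",
    "default_quaternary_model",
    "domain_names",
    "build_construct",
    "released_contour",
    "load_registry",
]

FOLDED, UNFOLDED = "folded", "unfolded"
OXIDIZED, REDUCED, NO_REDOX = "oxidized", "reduced", "n/a"

#: mechanical hierarchy, strongest first
HIERARCHY = ("FimA", "FimF", "FimG", "FimH_P", "FimH_L")


@dataclass(frozen=True)
class IntermediateSpec:
    """Optional two-stage unfolding pathway (FimH_L): a small step followed by
    the rupture of the remaining fold, each with its own kinetics."""

    step: float
    force: float
    remainder: float
    remainder_force: float
    occurrence_prob: float
    bell_step: BellParams
    bell_remainder: BellParams


@dataclass(frozen=True)
class DomainSpec:
    """Mechanical/kinetic parameter bundle for one domain (both redox states).

    Lengths in nm, forces in pN, rates in 1/s.  ``delta_lc_*`` are WLC
    contour-length increments; ``step_fc`` / ``step_ramp`` are the observed
    extension steps at the force-clamp / force-ramp working forces;
    ``reduction_step`` is the extra observed length released when the
    disulfide of the unfolded, oxidized domain is cleaved under load.
    """

    name: str
    delta_lc_ox: float
    bell_ox: BellParams
    mean_force_fx: float
    step_fc: float
    step_ramp: float
    size_sd: float = 1.0
    has_disulfide: bool = False
    delta_lc_red: Optional[float] = None
    bell_red: Optional[BellParams] = None
    reduction_step: Optional[float] = None
    step_fc_red: Optional[float] = None
    mean_force_ramp: Optional[float] = None
    intermediate: Optional[IntermediateSpec] = None
    supplementary_estimate: bool = False

    def __post_init__(self) -> None:
        for attr in ("delta_lc_ox", "step_fc", "step_ramp", "mean_force_fx"):
            if not (getattr(self, attr) > 0):
                raise ValueError(f"{self.name}: {attr} must be > 0")
        if self.delta_lc_red is not None and not (
            self.delta_lc_red > self.delta_lc_ox
        ):
            raise ValueError(f"{self.name}: delta_lc_red must exceed delta_lc_ox")
        if self.step_fc > self.delta_lc_ox:
            raise ValueError(f"{self.name}: step_fc cannot exceed delta_lc_ox")

    def bell(self, redox: str) -> BellParams:
        if redox == REDUCED and self.bell_red is not None:
            return self.bell_red
        return self.bell_ox

    def clamp_step(self, redox: str) -> float:
        if redox == REDUCED and self.step_fc_red is not None:
            return self.step_fc_red
        return self.step_fc


@dataclass
class DomainState:
    """One domain inside a construct, with its mutable fold/redox state."""

    spec: DomainSpec
    fold_state: str = FOLDED
    redox_state: str = OXIDIZED
    #: observed length currently released by this domain (nm); maintained by
    #: the simulator so refolding can return exactly what was taken out
    released: float = 0.0

    def __post_init__(self) -> None:
        if not self.spec.has_disulfide:
            self.redox_state = NO_REDOX


@dataclass
class Construct:
    """Ordered polyprotein: I91 handles plus the Fim domains under study."""

    domains: list[DomainState]
    linker_slack: float = 25.0  # folded-construct baseline contour, nm
    spec_string: str = ""

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("a construct needs at least one domain")

    def copy(self) -> "Construct":
        return Construct(
            [
                DomainState(d.spec, d.fold_state, d.redox_state, d.released)
                for d in self.domains
            ],
            self.linker_slack,
            self.spec_string,
        )

    def set_redox(self, redox: str) -> "Construct":
        """Set the redox state of every disulfide-bearing domain in place."""
        for d in self.domains:
            if d.spec.has_disulfide:
                d.redox_state = redox
        return self


@dataclass(frozen=True)
class QuaternaryStepModel:
    """Repetitive small inter-domain steps seen in about half the force-ramp
    traces of the tip fibrillum (6 +/- 1 nm around 82 pN)."""

    occurrence_prob: float = 0.5
    step_size: float = 6.0
    step_sd: float = 1.0
    mean_force: float = 82.0
    force_sd: float = 20.0
    max_count: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.occurrence_prob <= 1.0):
            raise ValueError("occurrence_prob must be in [0, 1]")
        if not (self.step_size > 0):
            raise ValueError("step_size must be > 0")


# ---------------------------------------------------------------------------
# Registry loading
# ---------------------------------------------------------------------------

_REGISTRY_CACHE: dict | None = None


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_registry(overrides: dict | None = None, path=None) -> dict:
    """Load the parameter registry (shipped TOML, optionally overridden)."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        src = (
            resources.files("pilusmech").joinpath("data/registry.toml")
            if path is None
            else path
        )
        with open(str(src), "rb") if path is not None else src.open("rb") as fh:
            _REGISTRY_CACHE = tomllib.load(fh)
    data = _REGISTRY_CACHE
    if overrides:
        data = _deep_merge(data, overrides)
    return data


def _bell_from(table: dict) -> BellParams:
    return BellParams(table["k0"], table["dx"])


def _domain_from_table(name: str, t: dict) -> DomainSpec:
    inter = None
    if "intermediate" in t:
        i = t["intermediate"]
        inter = IntermediateSpec(
            step=i["step"],
            force=i["force"],
            remainder=i["remainder"],
            remainder_force=i["remainder_force"],
            occurrence_prob=i["occurrence_prob"],
            bell_step=_bell_from(i["bell_step"]),
            bell_remainder=_bell_from(i["bell_remainder"]),
        )
    return DomainSpec(
        name=name,
        delta_lc_ox=t["delta_lc_ox"],
        bell_ox=_bell_from(t["bell_ox"]),
        mean_force_fx=t["mean_force_fx"],
        step_fc=t["step_fc"],
        step_ramp=t["step_ramp"],
        size_sd=t.get("size_sd", 1.0),
        has_disulfide=t.get("has_disulfide", False),
        delta_lc_red=t.get("delta_lc_red"),
        bell_red=_bell_from(t["bell_red"]) if "bell_red" in t else None,
        reduction_step=t.get("reduction_step"),
        step_fc_red=t.get("step_fc_red"),
        mean_force_ramp=t.get("mean_force_ramp"),
        intermediate=inter,
        supplementary_estimate=t.get("supplementary_estimate", False),
    )


def domain_names(overrides: dict | None = None) -> tuple[str, ...]:
    return tuple(load_registry(overrides)["domains"].keys())


def builtin_domain(name: str, overrides: dict | None = None) -> DomainSpec:
    """Return the shipped parameter set for one of the known domains."""
    reg = load_registry(overrides)["domains"]
    if name not in reg:
        raise KeyError(
            f"unknown domain {name!r}; valid names: {', '.join(sorted(reg))}"
        )
    return _domain_from_table(name, reg[name])


def builtin_condition(label: str, overrides: dict | None = None) -> RefoldingCondition:
    """Return the shipped refolding/redox condition for a label such as
    ``red_FimC_DsbA``."""
    reg = load_registry(overrides)["conditions"]
    if label not in reg:
        raise KeyError(
            f"unknown condition {label!r}; valid labels: {', '.join(sorted(reg))}"
        )
    t = reg[label]
    return RefoldingCondition(
        label=label,
        fold_rate=t["fold_rate"],
        fold_plateau=t["fold_plateau"],
        oxidation_prob=t.get("oxidation_prob", 0.0),
        reduction_prob=t.get("reduction_prob", 0.0),
    )


def default_quaternary_model(overrides: dict | None = None) -> QuaternaryStepModel:
    t = load_registry(overrides)["quaternary"]
    return QuaternaryStepModel(
        occurrence_prob=t["occurrence_prob"],
        step_size=t["step_size"],
        step_sd=t["step_sd"],
        mean_force=t["mean_force"],
        force_sd=t["force_sd"],
        max_count=t["max_count"],
    )


# ---------------------------------------------------------------------------
# Construct parsing and bookkeeping
# ---------------------------------------------------------------------------


def build_construct(
    spec_string: str,
    overrides: dict | None = None,
    linker_slack: float = 25.0,
) -> Construct:
    """Parse a construct spec such as ``"I91x2-FimG-I91x2"``.

    Tokens are domain names optionally suffixed ``xN`` for repeats; ``FimH``
    expands to its lectin and pilin subdomains (``FimH_L`` + ``FimH_P``) in
    series.  All domains start folded; disulfide domains start oxidized.
    """
    if not spec_string or not spec_string.strip():
        raise ValueError("empty construct spec")
    known = set(domain_names(overrides))
    states: list[DomainState] = []
    pos = 0
    for token in spec_string.split("-"):
        name, _, count_s = token.partition("x")
        count = 1
        if count_s:
            if not count_s.isdigit() or int(count_s) < 1:
                raise ValueError(
                    f"bad repeat count {count_s!r} at position {pos} in "
                    f"{spec_string!r}"
                )
            count = int(count_s)
        if name == "FimH":
            expansion = ["FimH_L", "FimH_P"]
        elif name in known:
            expansion = [name]
        else:
            raise ValueError(
                f"unknown domain {name!r} at position {pos} in {spec_string!r}"
            )
        for _ in range(count):
            for sub in expansion:
                states.append(DomainState(builtin_domain(sub, overrides)))
        pos += len(token) + 1
    return Construct(states, linker_slack=linker_slack, spec_string=spec_string)


def released_contour(construct: Construct, mode: str = "observed") -> float:
    """Total released length of the construct's unfolded domains (nm).

    ``mode="observed"`` (default) sums the observed force-clamp steps: the
    oxidized unfolding step plus, for reduced domains, the disulfide
    reduction step — e.g. an unfolded, reduced FimG gives 33 + 12 = 45 nm.
    ``mode="contour"`` sums WLC contour-length increments instead.
    """
    if mode not in ("observed", "contour"):
        raise ValueError("mode must be 'observed' or 'contour'")
    total = 0.0
    for d in construct.domains:
        if d.fold_state != UNFOLDED:
            continue
        spec = d.spec
        if mode == "contour":
            if d.redox_state == REDUCED and spec.delta_lc_red is not None:
                total += spec.delta_lc_red
            else:
                total += spec.delta_lc_ox
        else:
            total += spec.step_fc
            if d.redox_state == REDUCED and spec.reduction_step is not None:
                total += spec.reduction_step
    return total
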