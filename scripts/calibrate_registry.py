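"""Regenerate the calibrated Bell parameters in the shipped registry.

The published record gives mean unfolding forces (force-extension at
400 nm/s, force-ramp at 10 pN/s) and two 300 pN rates (oxidized/reduced
FimG), but never the underlying (k0, dx).  This script solves for them:

* I91:     k0 from the 200 pN force-extension mean, dx fixed at 0.25 nm;
* FimA:    k0 from the 527 pN force-extension mean, dx fixed at 0.15 nm;
* FimG ox: (k0, dx) jointly from the 261 pN ramp mean and k(300) = 0.94/s;
* FimG red: k0 from k(300) = 29.9/s, dx fixed at 0.20 nm;
* FimF, FimH_P, FimH_L: (k0, dx) jointly from their ramp and FX means;
* FimH_L intermediate pathway: k0 of both barriers from the 98 / 107 pN
  intermediate means, dx fixed at the FimH_L value;
* reduced FimA/FimF/FimH_P: 30x the oxidized rate at 300 pN (the measured
  FimG ratio), same dx.

Run from the repository root:  python scripts/calibrate_registry.py
The script edits src/pilusmech/data/registry.toml in place and prints the
verification table.
"""

from __future__ import annotations

import math
import re
import sys
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from pilusmech.kinetics import (
    BellParams,
    ramp_mean_rupture_force,
    solve_ramp_k0,
)
from pilusmech.registry import build_construct, load_registry
from pilusmech.simulate import Protocol, mean_fx_rupture_force
from pilusmech.wlc import KBT_ROOM

TOML = Path(__file__).resolve().parents[1] / "src/pilusmech/data/registry.toml"
FX = Protocol.force_extension(400.0)
SEED = 12345
N_EVENTS = 2000


def fx_mean(construct_spec: str, domain: str, bell: BellParams, note=None) -> float:
    construct = build_construct(construct_spec, overrides=OVERRIDES)
    return mean_fx_rupture_force(
        construct, FX, domain, bell, n_events=N_EVENTS, seed=SEED
    )


OVERRIDES: dict = {"domains": {}}


def set_override(domain: str, table: str, bell: BellParams) -> None:
    OVERRIDES["domains"].setdefault(domain, {})[table] = {
        "k0": bell.intrinsic_rate,
        "dx": bell.distance_to_transition,
    }


def solve_fx_k0(construct_spec: str, domain: str, target: float, dx: float) -> BellParams:
    def objective(log10_k0: float) -> float:
        return fx_mean(construct_spec, domain, BellParams(10.0**log10_k0, dx)) - target

    root = brentq(objective, -12.0, 1.0, xtol=2e-3)
    return BellParams(10.0**root, dx)


def solve_joint(construct_spec: str, domain: str, fx_target: float,
                ramp_target: float) -> BellParams:
    """(k0, dx) from the ramp mean (analytic) and the FX mean (Monte Carlo)."""

    def bell_at(dx: float) -> BellParams:
        return BellParams(solve_ramp_k0(ramp_target, dx, 10.0), dx)

    def objective(dx: float) -> float:
        return fx_mean(construct_spec, domain, bell_at(dx)) - fx_target

    root = brentq(objective, 0.05, 0.60, xtol=5e-4)
    return bell_at(root)


def main() -> None:
    reg = load_registry()["domains"]
    results: dict[tuple[str, str], BellParams] = {}

    # --- I91 fingerprint: FX mean 200 pN, conventional dx ---------------
    i91 = solve_fx_k0("I91x2-FimG-I91x2", "I91", reg["I91"]["mean_force_fx"], 0.25)
    set_override("I91", "bell_ox", i91)
    results[("I91", "bell_ox")] = i91

    # --- FimG: ramp mean + 300 pN rate jointly --------------------------
    rate300 = reg["FimG"]["rate_300_ox"]
    ramp_target = reg["FimG"]["mean_force_ramp"]

    def fimg_bell(dx: float) -> BellParams:
        return BellParams(rate300 * math.exp(-300.0 * dx / KBT_ROOM), dx)

    dx_g = brentq(
        lambda dx: ramp_mean_rupture_force(fimg_bell(dx), 10.0) - ramp_target,
        0.02, 0.60, xtol=1e-5,
    )
    g_ox = fimg_bell(dx_g)
    set_override("FimG", "bell_ox", g_ox)
    results[("FimG", "bell_ox")] = g_ox
    g_red = BellParams(
        reg["FimG"]["rate_300_red"] * math.exp(-300.0 * 0.20 / KBT_ROOM), 0.20
    )
    set_override("FimG", "bell_red", g_red)
    results[("FimG", "bell_red")] = g_red

    # --- FimA: FX only ---------------------------------------------------
    fima = solve_fx_k0("I91x2-FimA-I91x2", "FimA", reg["FimA"]["mean_force_fx"], 0.15)
    set_override("FimA", "bell_ox", fima)
    results[("FimA", "bell_ox")] = fima

    # --- FimF / FimH_P / FimH_L: joint FX + ramp ------------------------
    for name, cs in (
        ("FimF", "I91x2-FimF-I91x2"),
        ("FimH_P", "I91x2-FimH-I91x2"),
        ("FimH_L", "I91x2-FimH-I91x2"),
    ):
        bell = solve_joint(cs, name, reg[name]["mean_force_fx"],
                           reg[name]["mean_force_ramp"])
        set_override(name, "bell_ox", bell)
        results[(name, "bell_ox")] = bell

    # --- reduced states: 30x oxidized rate at 300 pN, same dx -----------
    for name in ("FimA", "FimF", "FimH_P"):
        ox = results[(name, "bell_ox")]
        red = BellParams(30.0 * ox.intrinsic_rate, ox.distance_to_transition)
        set_override(name, "bell_red", red)
        results[(name, "bell_red")] = red

    # --- FimH_L intermediate pathway -------------------------------------
    inter = reg["FimH_L"]["intermediate"]
    dx_l = results[("FimH_L", "bell_ox")].distance_to_transition
    OVERRIDES["domains"].setdefault("FimH_L", {})["intermediate"] = {
        "occurrence_prob": 1.0
    }

    def inter_mean(which: str, bell: BellParams, note: str) -> float:
        OVERRIDES["domains"]["FimH_L"]["intermediate"][which] = {
            "k0": bell.intrinsic_rate, "dx": bell.distance_to_transition
        }
        construct = build_construct("I91x2-FimH-I91x2", overrides=OVERRIDES)
        from pilusmech.simulate import _FxTables, _fx_events
        from pilusmech.registry import load_registry as lr

        phys = lr()["physics"]
        rng = np.random.default_rng(SEED)
        tables = _FxTables(FX.cantilever_stiffness, phys["persistence_length"],
                           KBT_ROOM)
        forces = []
        while len(forces) < N_EVENTS // 2:
            for e in _fx_events(construct.copy(), FX, rng, tables):
                if e.kind == "unfold" and e.domain == "FimH_L" and e.note == note:
                    forces.append(e.force)
        return float(np.mean(forces))

    k_step = brentq(
        lambda lg: inter_mean("bell_step", BellParams(10.0**lg, dx_l),
                              "intermediate") - inter["force"],
        -8.0, 1.0, xtol=5e-3,
    )
    b_step = BellParams(10.0**k_step, dx_l)
    OVERRIDES["domains"]["FimH_L"]["intermediate"]["bell_step"] = {
        "k0": b_step.intrinsic_rate, "dx": dx_l
    }
    results[("FimH_L", "intermediate.bell_step")] = b_step
    k_rem = brentq(
        lambda lg: inter_mean("bell_remainder", BellParams(10.0**lg, dx_l),
                              "remainder") - inter["remainder_force"],
        -8.0, 2.0, xtol=5e-3,
    )
    b_rem = BellParams(10.0**k_rem, dx_l)
    results[("FimH_L", "intermediate.bell_remainder")] = b_rem

    # --- implied I91 ramp mean (classifier prior) ------------------------
    i91_ramp = ramp_mean_rupture_force(i91, 10.0)

    # --- report ----------------------------------------------------------
    print(f"{'domain':28s} {'k0 (1/s)':>12s} {'dx (nm)':>8s}")
    for (name, table), bell in results.items():
        print(f"{name + '.' + table:28s} {bell.intrinsic_rate:12.4e} "
              f"{bell.distance_to_transition:8.4f}")
    print(f"implied I91 ramp mean: {i91_ramp:.1f} pN")
    print(f"implied FimG FX mean:  "
          f"{fx_mean('I91x2-FimG-I91x2', 'FimG', results[('FimG','bell_ox')]):.1f} pN")

    # --- patch the TOML ---------------------------------------------------
    text = TOML.read_text()

    def patch_section(text: str, section: str, bell: BellParams) -> str:
        pat = re.compile(
            rf"(\[{re.escape(section)}\]\nk0 = )[-0-9.e+]+(\ndx = )[-0-9.e+]+"
        )
        repl = rf"\g<1>{bell.intrinsic_rate:.8e}\g<2>{bell.distance_to_transition:.6f}"
        new, n = pat.subn(repl, text)
        if n != 1:
            sys.exit(f"could not patch section [{section}]")
        return new

    for (name, table), bell in results.items():
        text = patch_section(text, f"domains.{name}.{table}", bell)
    text = re.sub(
        r"(mean_force_ramp = )[-0-9.e+]+(   # model-implied)",
        rf"\g<1>{i91_ramp:.1f}\g<2>",
        text,
    )
    TOML.write_text(text)
    print(f"patched {TOML}")


if __name__ == "__main__":
    main()
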