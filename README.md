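# pilusmech

Mechanics and chaperone-assisted folding of *E. coli* type 1 pilus domains,
as seen by single-molecule AFM force spectroscopy — a stochastic simulator of
the experiments plus the blind trace-analysis pipeline, validated against
each other in closed loop.

## The scientific problem

Uropathogenic *E. coli* attach to bladder epithelium with type 1 pili:
thousands of FimA subunits form the rod, capped by the FimF–FimG–FimH tip
fibrillum. Neighbouring subunits are connected by donated β-strands
(β-strand complementation), the only irreversible interaction in the pilus:
if one such connection ruptures, the pilus is lost. AFM experiments on
polyprotein constructs — each Fim domain self-complemented with its cognate
donor strand and flanked by titin I91 fingerprint handles,
(I91)₂-FimX-(I91)₂ — measured the unfolding force and released length of
every connection, the mechanical role of the conserved disulfide bonds, and
the chaperone roles of FimC and the oxidoreductase DsbA during refolding.

The raw traces behind those numbers are not publicly deposited. This package
therefore treats the published quantities as the ground truth of a generative
model: it simulates realistic noisy traces in all three AFM modes and
provides the analysis pipeline that, given only (time, extension, force),
must recover the published numbers.

## Models

* **Polymer elasticity** — Marko–Siggia worm-like chain,
  `F(x) = (kBT/p)[¼(1−x/Lc)⁻² − ¼ + x/Lc]`, persistence length
  `p = 0.4 nm`, `kBT = 4.114 pN·nm`. Unfolding releases a contour-length
  increment ΔLc obtained from consecutive WLC fits.
* **Unfolding kinetics** — Bell two-state law `k(F) = k₀·exp(FΔx/kBT)`.
  (k₀, Δx) are never printed in the published record; they are calibrated by
  root-finding so that simulated campaigns reproduce the printed mean rupture
  forces (force-extension at 400 nm/s, force-ramp at 10 pN/s) and the
  printed 300 pN rates of FimG (0.94 s⁻¹ oxidized, ~29.9 s⁻¹ reduced).
* **Refolding** — plateaued exponential `P(Δt) = P∞(1 − exp(−k_fold·Δt))`
  during 0 pN quenches; chaperone conditions (±FimC, ±DsbA) change the
  plateau and the redox chemistry (DsbA reduces unfolded domains at ~100 pN
  and reoxidizes them on folding).
* **Experiment modes** — force-extension sawtooths (cantilever spring in
  series with the WLC), force-ramp staircases (closed-form Bell-ramp rupture
  distribution), and multi-pulse force clamp with quenches.

The analysis side implements rupture-peak detection with WLC contour fits,
change-point step detection (penalised binary segmentation, L2 cost),
joint (step size, force) classification against the domain registry,
summed-trace exponential kinetics, and binomial refolding statistics.

## Worked example

Simulate twenty force-extension pulls of the FimG construct, analyse them
blind, and tabulate the classified peaks:

```sh
pilusmech simulate --construct I91x2-FimG-I91x2 --mode fx \
    --velocity 400 -n 20 --seed 42 --out demo/traces
pilusmech analyze --in demo/traces --out demo/analysis
```

which prints `{"n_traces": 20, "n_peaks": 120, "n_steps": 0}` — six peaks
per sawtooth (four I91, one FimG, one detachment). Grouping the fitted peaks
(`demo/analysis/peaks.tsv`) by domain:

```
       peak_force       delta_lc
             mean count     mean count
domain
FimG        445.0    20     40.0    20
I91         196.0    80     28.0    80
```

The I91 fingerprint shows its textbook ~200 pN / 28 nm signature and the
FimG β-strand connection its 40 nm contour increment at a force in the
400–500 pN range. `pilusmech report --in demo/analysis --out demo/figs`
renders the ΔLc-vs-force scatter and step-size histograms, and
`pilusmech recover --suite paper` runs the full closed loop against every
registry target.

## Layout

| module | contents |
| --- | --- |
| `pilusmech.wlc` | worm-like chain force/extension, theoretical ΔLc |
| `pilusmech.kinetics` | Bell rates, waiting-time sampling, calibration, refolding law |
| `pilusmech.registry` | per-domain parameter registry, constructs, conditions |
| `pilusmech.simulate` | force-extension / force-ramp / force-clamp trace generator |
| `pilusmech.analysis` | blind peak/step detection, WLC fits, classification, kinetics |
| `pilusmech.io` | TSV + JSON-sidecar trace format, HDF5 container, campaign configs |
| `pilusmech.recover` | closed-loop recovery campaigns |
| `pilusmech.cli` | `pilusmech simulate / analyze / recover / report` |

See `docs/methods.md` for the modelling assumptions, parameter provenance,
and known limitations.
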