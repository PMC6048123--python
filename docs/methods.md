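# Methods

This note records the models behind `pilusmech`, where every shipped number
comes from, the choices made where the design was genuinely open, and what
the closed-loop validation does and does not demonstrate.

## Polymer elasticity

Unfolded polypeptide is modelled with the Marko–Siggia interpolation of the
worm-like chain. Two parameters are fixed package-wide and overridable:

* persistence length `p = 0.4 nm` — the conventional value for unfolded
  polypeptide; the published WLC fits do not print `p`. With `p = 0.4 nm` a
  28 nm contour increment observed at 160 pN spans ~25 nm, matching the
  observed I91 clamp step.
* thermal energy `kBT = 4.114 pN·nm` (298 K).

`wlc_extension` inverts the force law by bracketed bisection on
`[0, (1−10⁻⁹)·Lc]` (relative tolerance 10⁻⁹; the force-side round trip is
well below 10⁻⁶ pN). The theoretical contour increment of a domain of `N`
residues is `0.4·N − 5 nm` (0.4 nm per residue minus a 5 nm folded domain).

## Unfolding kinetics and calibration

Unfolding is a two-state Bell process, `k(F) = k₀ exp(FΔx/kBT)`. The
published record prints mean rupture forces and two constant-force rates but
never (k₀, Δx), so these are **calibrated**, per domain and redox state
(`scripts/calibrate_registry.py`, results frozen in `data/registry.toml`):

* I91: k₀ from the ~200 pN force-extension mean with Δx fixed at the
  conventional 0.25 nm. FimA: k₀ from its 527 pN mean, Δx = 0.15 nm.
* FimF, FimH_P, FimH_L: (k₀, Δx) solved jointly from the force-ramp mean
  (closed-form Bell-ramp distribution at 10 pN/s, censored at 400 pN) and
  the force-extension mean (Monte-Carlo with common random numbers inside a
  1-D root-find on Δx).
* Oxidized FimG: (k₀, Δx) jointly from the 261 pN ramp mean and
  k(300 pN) = 0.94 s⁻¹. The implied force-extension mean then comes out at
  ~425 pN against a measured 431 ± 4 pN — the two-state model very nearly
  reconciles all three observables. Reduced FimG: k(300 pN) = 29.9 s⁻¹ with
  Δx = 0.20 nm.
* Reduced FimA/FimF/FimH_P (no printed reduced kinetics): 30× the oxidized
  rate at 300 pN — the measured FimG redox ratio — with unchanged Δx.

Calibrated intrinsic rates land in 10⁻⁷–10⁻² s⁻¹ with Δx 0.15–0.37 nm,
physically plausible for mechanically stable β-sandwich folds. The
calibration is self-checking: the published multi-pulse protocols (e.g.
FimH_L unfolding within 5 s at 60 pN, FimH_P within 7 s at 250 pN) come out
nearly quantitative without being fitted.

Waiting times under arbitrary force schedules are sampled by inverting the
cumulative hazard at an Exp(1) variate: closed forms for constant force and
linear ramps, trapezoid integration for tabulated schedules (the
force-extension engine integrates the hazard along the force-vs-time curve
of the cantilever–WLC series system on a 2048-point force grid).

## Refolding and redox chemistry

Refolding during a 0 pN quench follows `P(Δt) = P∞(1 − e^(−k_fold Δt))`.
A pure `1 − e^(−kt)` cannot represent the observation that FimC raises the
refolding probability at an unchanged rate; the plateau `P∞` carries the
chaperone effect. Rates are the published ones (0.021 s⁻¹ oxidized ±FimC;
0.04 / 0.027 s⁻¹ reduced −/+FimC). The plateaus are **figure-estimated** —
the published bars are not printed as numbers; the shipped values (0.55
oxidized alone, 0.85 with FimC, 0.24/0.28 reduced, 0.84 with DsbA) are
consistent with the printed prose ("around 20%" reduced alone vs "around
70%" with DsbA at 45 s). `oxidation_prob = 0.7` and `reduction_prob = 0.5`
are placeholders for the per-quench DsbA reoxidation and per-100 pN-pulse
reduction probabilities, which are plotted but not printed; they are flagged
uncalibrated in the registry.

I91 handles refold deterministically in quenches of ≥ 10 s (their fast,
well-characterised kinetics are not under study; the published probe pulses
always recover four I91 steps).

## Simulator

* Force-extension: base retracts at constant velocity; the observable force
  follows the quasi-static equilibrium of a 15 pN/nm Hookean cantilever in
  series with the WLC of the currently released contour. Detachment is a
  final event at a configurable high force (1200 ± 100 pN) so that all
  domain ruptures are observable. The recorded extension channel is the
  tip–sample separation (deflection-corrected), so F-vs-x of each state is
  exactly WLC.
* Force-ramp: force is controlled, so rupture forces of the folded units are
  independent draws from the closed-form Bell-ramp distribution, censored at
  the 400 pN end of the ramp. Observed step sizes are drawn around the
  published per-domain ramp steps (SD 1 nm). Quaternary steps: with
  probability 0.5 per trace, 1–2 steps of 6 ± 1 nm at 82 ± 20 pN.
* Force-clamp: per pulse, folded domains unfold with constant-force Bell
  kinetics producing their observed clamp steps (25 nm I91 at 160 pN, 33 nm
  oxidized / 45 nm reduced FimG at 300 pN); DsbA reduction adds a 12 nm step
  during ~100 pN pulses; quenches apply the refolding law. Within every
  force pulse the noise-free extension change equals the summed event sizes
  exactly (a tested invariant). Feedback is treated as ideal.
* Noise: Gaussian, 10 pN on the force channel (extension/ramp modes),
  0.5 nm on the extension channel (clamp/ramp), 1 kHz sampling — invented
  values (the record does not characterise noise), always recorded in trace
  metadata. Every simulation records its seed; identical configs and seeds
  reproduce trace files byte-for-byte.
* The FimH_L unfolding intermediate (6 nm at ~98 pN, then 36 nm at ~107 pN,
  occurrence 0.3) is a branch pathway in force-extension mode only.

What the generator does **not** emulate: drift, cantilever ringing,
hydrodynamic drag, surface-adhesion peaks, multiple tethers, non-ideal
clamp feedback, or continued creep of already-released contour during a
ramp. Passing closed-loop tests therefore demonstrates the correctness and
calibration of the pipeline under idealised noise, not robustness to every
instrument artefact of real data.

## Analysis pipeline

All analysis consumes only (time, extension, force).

* Peak detection: ruptures are ≥ 40 pN drops within 6 samples of the
  smoothed force from ≥ 80 pN; the rupture force is a linear extrapolation
  of the pre-drop rise to the rupture instant (unbiased under additive
  noise; empirically −0.4 ± 4 pN per event against ground truth). The last
  peak, after which force stays low, is the detachment and is excluded from
  force statistics — but its rising flank is still WLC-fitted because it
  carries the final contour.
* WLC fits: contour free, persistence fixed (shared); increments are
  differences of consecutive fitted contours. Points below 20 pN (or 8% of
  the peak force) are excluded so the fit weights the asymptote.
* Step detection: penalised binary segmentation of the extension channel
  with an L2 cost, minimum segment length 20 samples, noise-adaptive
  penalty `σ̂²·6·log n` (σ̂ from the MAD of first differences); steps are
  boundaries with level differences ≥ 3 nm. Long traces are block-averaged
  to ≤ 20 000 samples; clamp traces are segmented per constant-force pulse.
  Ramp analyses drop steps below 30 pN, where the stretching of the folded
  backbone produces spurious low-force boundaries.
* Classification: hard force regimes (< 100 pN: FimH_L and quaternary;
  100–200 pN: I91 and quaternary, size-resolved; > 200 pN: FimF/FimG/FimH_P)
  with nearest-class assignment in scaled (size/1.5 nm, force/25 pN)
  coordinates and an "unassigned" cutoff at 3.5. Campaign-level analyses use
  the joint per-trace variant (Hungarian assignment under the construct's
  multiplicities), which removes duplicate assignments and most of the
  boundary-selection bias between the overlapping FimG/FimH_P classes.
* Summed-trace kinetics: each constant-force pulse showing a step is
  normalised to [0, 1] by its two occupancy levels (histogram split —
  unbiased however early the step occurs); pulses without a step carry no
  dwell-time information and are dropped; the averaged curve is fitted to
  `1 − e^(−t/τ)` with bootstrap-over-traces errors. The fit grid keeps the
  early rise at full resolution. Over replicate campaigns of 200 traces the
  estimator is unbiased with a relative SD of ~6–8%.
* Refolding: probabilities with binomial SDs; rate from weighted least
  squares of the plateaued exponential (weights `n/(p(1−p)+0.01)`). With
  only four quench times at n ≈ 11–22 and a plateau far from saturation,
  the free-plateau rate is weakly identified — its campaign-to-campaign
  spread is comparable to the published ±0.008 band itself. Both free
  (default) and plateau-fixed fits are available.
* Alignment of summed traces uses the pulse start; first-step alignment is
  available behind `align="first_step"`.

## Closed-loop validation

Because no raw data are deposited, acceptance is closed-loop: simulate the
published campaigns at the published sample sizes (2000 force-extension
pulls for the FimA force; 100 pulls for the contour increments; 200 clamp
traces per redox state for the 300 pN rates; 200 ramp pulls for the tip
fibrillum; the 22/18/15/11-trace quench campaign), analyse blind, and
compare with the published values at the stated tolerances. The problem
sizes match the published campaigns; the whole suite runs in a few minutes
on one CPU.

## Known limitations

* Quantities marked `supplementary_estimate` (reduced-state ΔLc and forces
  of FimA/FimF/FimH_P) are plausible estimates, not published numbers.
* The FimG/FimH_P ramp classes overlap heavily (33 ± 1 vs 32 ± 1 nm at
  261 vs 238 pN); even the joint classifier retains a few-pN selection bias
  in their class means.
* Bell kinetics exclude catch-bond behaviour, multi-barrier landscapes and
  temperature dependence; FimA rod uncoiling and FimH–mannose adhesion are
  out of scope.
* The refolding-rate recovery is intrinsically noisy at the published
  sample sizes (see above); its acceptance check can fail for individual
  campaigns without indicating an implementation defect.
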