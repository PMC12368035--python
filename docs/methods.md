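# Methods

## Scope and model structure

`caclear` models cytosolic free Ca²⁺ in a spherical cell exchanging
Ca²⁺ across its membrane through three fluxes — a Hill-type pump efflux,
a constant leak, and a pulsed channel influx — optionally buffered by
EGTA, and converts the resulting concentration fields into BK-channel
open-probability traces and activation curves, the observables of the
corresponding patch-clamp experiments.  The package's purpose is the
inverse question: which per-pump cycle rate φ makes the simulated
observables match measured ones.

Units are fixed package-wide: µm, ms (solver interfaces; rate constants
are quoted in s⁻¹), µM, mV, and ion counts; membrane flux densities are
ions·µm⁻²·s⁻¹.  One constant (602.214 ions·µm⁻³·µM⁻¹) performs every
count↔concentration conversion.

## Geometry and fluxes

The cell is a sphere of surface area A (default 300 µm², radius 4.886
µm).  A fraction θ (default 0.3) of the volume is diffusion-accessible;
concentrations are defined per accessible volume and membrane fluxes are
divided by θ when converted to concentration rates, with diffusivities
understood as effective values.  No explicit obstacles are modelled.

* Pump efflux: j_PMCA = φ·ρ·f(c), f(c) = c²/(c² + 0.43²) (c in µM).
  c₁/₂ = 0.43 µM, Hill n = 2 and ρ = 50 µm⁻² are the published values; one
  Ca²⁺ ion per cycle, so a single pump at 10 kHz extrudes 10 ions/ms.
* Leak: j_leak = j_PMCA(c₀) with c₀ = 0.1 µM, making rest an exact
  steady state.  The leak is active in both boundary problems.
* Pulsed influx: 1.2×10⁶ ions uniformly over the membrane during each
  0.8 ms pulse (5×10⁶ ions·µm⁻²·s⁻¹ at default geometry); trains use a
  2.8 ms period (0.8 ms pulse + 2 ms gap).  The protocol's stated pulse
  frequency (500 Hz) and its stated 2 ms non-influx gap are mutually
  inconsistent by 0.8 ms; the gap reading is the default and the period
  is configurable.
* EGTA: second-order binding with k₊ = 2.7 µM⁻¹s⁻¹, k₋ = 0.4 s⁻¹
  (K_d ≈ 148 nM), D_b = 110 µm²/s.  These and D_c = 220 µm²/s are
  literature-typical substitutes, not study-calibrated constants; all are
  config-exposed.  The buffered conditions modelled are b_tot = 0 and
  10 mM: the experimental 0.1 mM EGTA background is treated as
  buffer-free in the pump experiments (its capacity and speed are
  negligible on the relevant time scale compared with the pumps, and a
  persistent control response requires it), while the end-of-pulse
  concentration check uses 0.1 mM literally.

## Dynamic solver

The spherically symmetric reaction–diffusion system for (c, b) is
discretized by finite volumes on a radial mesh of 48 shells graded
geometrically to ~8 nm at the membrane — the influx/efflux boundary
layer (depth √(D_c/k₊b_tot) ≈ 0.09 µm at 10 mM EGTA, and √(D_c·t) ≈
0.4 µm over a pulse) must be resolved because the channels read the
membrane-adjacent concentration.  Mass is conserved exactly by
construction (closed-system drift < 10⁻⁶ over a run, limited only by
integrator tolerance).  Time integration uses BDF (scipy `solve_ivp`)
with an analytic Jacobian sparsity pattern, segmented at pulse edges so
the discontinuous influx is exact; output is sampled at 5 µs inside and
just after pulses and 50 µs elsewhere.  A two-variable well-mixed ODE
(`wellmixed_reference`) serves as an independent oracle: with
diffusivities ×100 the PDE volume average matches it to <10⁻⁵ relative.

Halving the mesh spacing moves pulse-end concentrations and
clearance-time summaries by <0.1 %.

## Stationary solver

Under pipette infusion the problem is axisymmetric: Laplace's equation
with a Dirichlet cap (area equal to the disc of the 1 µm pipette-contact
radius — a stand-in; the contact geometry is not published) and the
nonlinear pump/leak flux balance elsewhere.  Pumps occupy only the
non-pipette surface here.  A conservative finite-volume scheme on
(r, x = cosθ) (default 80×192 cells plus a refined cap) handles the
mixed boundary condition; because the solution gradient is singular at
the cap edge, both meshes are graded toward it (geometric ratios 8
radially, 20 angularly) — without grading the membrane average converges
at only ~5 % per refinement level, with grading <1 % on halving.  The
nonlinear boundary term is solved by Newton iteration with a
backtracking line search (residual tolerance 10⁻⁸ relative,
initialization at c = c_pip); plain fixed-point iteration diverges
because the flux-to-concentration loop gain exceeds unity at kHz rates.

## BK gating model

Ten states (C₀–C₄, O₀–O₄; subscript = occupied Ca²⁺ sites of four).
Equilibrium: P_open = (1 + B(c)·L(0)·e^(−QFV/RT))⁻¹ with B(c) the
ratio of the quartic closed/open binding polynomials in c with
dissociation constants K_C1..4 and K_O1..4.  Kinetics: per-tier
opening/closing rates with a charge split x on the barrier
(α_i = a_i·e^(xQFV/RT), β_i = b_i·e^(−(1−x)QFV/RT), b_i/a_i fixed by
the tier equilibrium constant) and a single per-site Ca²⁺ on-rate with
statistical factors (on: (4−i)·k_on·c; off: (4−i)·k_on·K).  Building
unbinding rates from the equilibrium constants makes every four-state
loop satisfy detailed balance identically, and the generator's
stationary distribution reproduces the closed-form P_open to machine
precision — the steady and kinetic models are one model.

Propagation of the master equation uses per-interval matrix
exponentials at midpoint (V, c) (probability-conserving by
construction; cached for repeated inputs), with a BDF fallback; for
constant-input segments an eigen-decomposition evaluates P_open(t) in
closed form, which makes the kinetic calibration's inner loop cheap.

## Truth parameters (synthetic data)

The gating constants behind the published calibration are not publicly
printed, so the generator ships a documented behavioural stand-in,
constructed once to satisfy the published summary behaviour and then
frozen:

* L(0) = 1.16×10⁴, Q = 1.4 e — zero-Ca half-activation ≈ +170 mV,
  Boltzmann slope ≈ 18 mV;
* K_C = (10, 8, 5, 3) µM, K_O = K_C/10 — ten-fold open-state affinity
  gain per step, placing V_h at ≈161/123/12/4 mV for 0.1/1/10/50 µM
  Ca²⁺ (monotone, µM-range sensing);
* closing rates at 0 mV (700, 1500, 2800, 4500, 6500) s⁻¹, x = 0.5,
  k_on = 650 µM⁻¹s⁻¹ — chosen so the relaxation at the +70 mV test
  potential with resting Ca²⁺ is essentially mono-exponential with
  τ ≈ 8.4 ms (slowest open-weighted generator mode 8.7 ms), the
  deactivation-limited decay the 10 mM EGTA experiments show.

Synthetic datasets add seeded Gaussian noise (default σ = 0.02 on
normalized conductance, clipped to [0, 1.05]); switch responses cover
seven concentration jumps at two holding potentials (70 and 120 mV) —
single-voltage data leave the charge split degenerate with the rate
scale.  Immunogold tables are Poisson counts at a set density.  What
the generator does not emulate: capacitive/series-resistance artifacts,
1/f noise, leak subtraction residues, channel-count fluctuations, or
nanodomain Ca²⁺ heterogeneity from channel clustering — so passing
recovery tests demonstrates pipeline self-consistency under idealized
noise, not robustness to every feature of real recordings.

## Calibration

Both fits are bounded nonlinear least squares (scipy `least_squares`)
with seeded Latin-hypercube multi-starts (default 32 steady / 8
kinetic), parameters log-scaled where positive.  Four activation curves
cannot pin ten equilibrium parameters uniquely; individual K values are
reported as possibly degenerate and fit quality is judged on predicted
curves and V_h(c).  The kinetic fit pins the equilibria to the steady
result and estimates only rate scales; datasets without concentration
jumps flag the Ca²⁺ on-rate as unidentifiable.

## Experiments and trace analysis

* Steady experiment: solve the stationary field at c_pip (default
  10 µM), area-average the equilibrium P_open over the non-pipette
  membrane per test voltage (−80…+200 mV in 10 mV steps, the recording
  protocol), normalize to the maximum (tail-current convention) and fit
  the Boltzmann form (the formula as conventionally printed sometimes carries a
  typographic extra g_max; the normalized form is used).
* Pulse experiment: run the dynamic solver, feed the membrane-adjacent
  c(t) (the channels are membrane proteins; the volume average is a
  config alternative) and the command voltage (+70 mV test potential,
  −60 mV during influx) into the kinetic model, find the trace maximum
  after the last pulse and fit a·e^(−t/τ)+b from there to the end of the
  100 ms record.  Traces that have not decayed to half their peak by the
  record end are reported as persistent instead of receiving a
  meaningless τ.  The deactivation anchor is quoted at the +70 mV test
  potential; reported deactivation is alternately quoted at 50 mV, and both are reachable
  through the protocol config.
* Rate scans report V_h(φ) against the resting-calibration V_h with a
  10 mV overlay tolerance (the published criterion is visual), or
  τ_decay(φ) against a target band.  The overlay-threshold rate depends
  strongly on the pipette-contact stand-in: with the 1 µm patch the
  threshold falls at ~500 cycles/s rather than the published ~5000/s,
  while the orderings (V_h monotone in φ, no visible shift at 50/s) are
  geometry-independent.

## Known limitations

* With our stand-in gating constants and diffusivities the pump-driven
  pulse decay at 20,000 cycles/s fits τ ≈ 9.2 ms (membrane readout;
  12.4 ms with the volume readout), below the published 13.2 ± 1.2 ms —
  the simulated clearance at 20 kHz is fast enough to be
  deactivation-limited.  The published value is matched at ≈8–12×10³
  cycles/s, so the kHz-range inference itself is insensitive to the
  stand-ins, but absolute rate estimates from this package inherit
  their uncertainty.
* No Cav channel clustering or single-channel stochasticity (the influx
  is surface-averaged), no endogenous mobile buffers beyond EGTA, no
  indicator-dye kinetics, no auxiliary BK subunits, no pipette exchange
  during pulse experiments, and no membrane-potential dynamics beyond
  the commanded protocol.
* Problem sizes used throughout (and by `scripts/acceptance.py`):
  48 radial shells, 80×192 stationary cells, 100 ms records — chosen as
  the coarsest meshes whose refinement changes the reported quantities
  by less than the tolerances above.
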