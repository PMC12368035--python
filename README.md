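# caclear

Modelling how fast plasma-membrane Ca²⁺ pumps clear cytosolic calcium,
using Ca²⁺- and voltage-activated K⁺ (BK) channels as the readout.

Plasma-membrane Ca²⁺-ATPases (PMCA pumps, in complex with their
obligatory neuroplastin subunit) terminate intracellular Ca²⁺ signals.
Their per-pump transport rate under cellular conditions can be inferred
by combining three measurable ingredients: the time course of BK-type
K⁺ currents (a fast, non-buffering [Ca²⁺]ᵢ sensor at the membrane), the
surface density of pumps counted by freeze-fracture immunogold EM, and a
reaction–diffusion model of the cell that turns an assumed per-pump
cycle rate into a predicted BK response.  `caclear` implements that
forward model and the analysis around it for electrophysiologists and
modellers who want to run the inference on their own numbers.

## The model

A spherical cell (surface A = 300 µm², 30 % of the volume accessible to
diffusion) carries pumps at density ρ (default 50 µm⁻²) whose efflux
density is a Hill function of the local free Ca²⁺,

    j_PMCA(c) = φ · ρ · cⁿ/(cⁿ + c₁/₂ⁿ),    c₁/₂ = 0.43 µM, n = 2,

with φ the per-pump cycle rate (1 Ca²⁺/cycle).  A constant leak influx
j_leak = j_PMCA(c₀) pins the rest state at c₀ = 0.1 µM.  Two boundary
problems are solved:

* **stationary** — ∇²c = 0 with a Dirichlet patch (pipette infusion at
  c_pip) and the nonlinear pump/leak flux balance on the rest of the
  membrane (axisymmetric finite volumes, Newton iteration);
* **dynamic** — coupled reaction–diffusion for Ca²⁺ and EGTA
  (∂c/∂t = D_c∇²c − k₊cb + k₋(b_tot − b), likewise for b) with a pulsed
  Cav-channel influx boundary term delivering 1.2×10⁶ ions per 0.8 ms
  pulse over the surface (radial finite volumes, BDF integration).

The membrane-adjacent Ca²⁺ drives a 10-state BK gating model (five
closed/five open states, four Ca²⁺ sites).  At equilibrium

    P_open = 1 / (1 + B(c) · L(0) · e^(−QFV/RT)),

with B(c) the ratio of closed/open binding polynomials; the kinetic
extension propagates the 10-state master equation under time-varying
(V, c) with detailed balance enforced by construction.  Simulated
activation curves are fitted with a Boltzmann function
g = 1/(1+exp((V_h−V)/k)) and simulated current decays with
a·exp(−t/τ)+b, exactly as the corresponding recordings are analysed.

Both calibrations are exposed statsmodels-style: build
`BKSteadyCalibration(curves)` or `BKKineticCalibration(traces, steady)`
from data and call `.fit()` for a results object with estimates,
diagnostics and `summary()`.  A seeded synthetic-data module generates
every input (activation curves, Ca²⁺-switch responses, immunogold count
tables) from a documented stand-in truth set, so the whole pipeline is
testable without any recordings.

## Worked example

Simulate the pulsed-influx experiment with pumps at 20,000 cycles/s
(low-buffer condition) and with 10 mM EGTA instead of pumps:

```sh
$ cat pmca.json
{ "pump": {"cycle_rate": 20000.0}, "buffer": {"b_total": 0.0} }
$ caclear pulse --config pmca.json --out runs/pmca
tau_decay = 9.17 ms
$ cat egta.json
{ "pump": {"cycle_rate": 0.0}, "buffer": {"b_total": 10000.0} }
$ caclear pulse --config egta.json --out runs/egta
tau_decay = 8.41 ms
```

The 10 mM EGTA run decays with τ ≈ 8.4 ms — the buffer absorbs the
pulse in under a millisecond, so the K⁺ current decays exactly at the
channel deactivation rate.  Pumps at 20 kHz reproduce that
buffer-grade clearance (τ ≈ 9 ms); at 500 cycles/s or below the
response is persistent and no mono-exponential fits.  The stationary
counterpart:

```sh
$ caclear steady --out runs/steady
V_h = 160.26 mV, k = 15.38 mV
```

i.e. pumps at the default 5,000 cycles/s pull the membrane Ca²⁺ from
the 10 µM delivered by the pipette down to near-resting levels, shifting
BK activation (V_h ≈ 160 mV) onto the 0.1 µM calibration curve
(V_h ≈ 161 mV) — the signature from which kHz-range cycling is
inferred.  Each run writes its traces as TSV plus a `summary.json`
echoing every parameter.  See also `caclear scan`, `caclear calibrate`
and `caclear synth --out data/`.

In Python the same experiment is:

```python
import caclear as cc
truth = cc.default_truth()
res = cc.run_pulse_experiment(
    cc.CellGeometry(), cc.PumpParams(cycle_rate=20000.0),
    cc.BufferParams(b_total=0.0), cc.InfluxProtocol(), truth.bk_kinetic)
print(res.trace.tau_decay)  # 9.17 (ms)
```

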