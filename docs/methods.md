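# Methods

## The model

`neocolumn` simulates the primary current dipole — the quantity estimated by
MEG/EEG source localization, in ampere-meters — produced by a canonical
neocortical column.  The column contains multicompartment pyramidal neurons
(PNs) in layers 2/3 and 5 whose apical dendrites are aligned along the
cortical depth (Z) axis, plus single-compartment fast-spiking basket
interneurons, in a 3:1 PN:interneuron ratio per layer.  PNs of both layers
sit on the same regular XY grid (10×10 by default, 200 PNs total).

### Cells

Each pyramidal class is a reduced morphology: 8 compartments for L2/3
(soma, apical trunk, one apical section, tuft, one horizontal oblique, and
a three-section basal tree) and 9 for L5 (a second apical section; much
longer apical path).  Compartment dimensions are fixed model constants; the
basal tree points downward, Bdend2/3 at 45° (vertical factor −√2/2), the
oblique is horizontal (vertical factor 0).  Passive membrane: Rm =
23,474 Ω·cm² for both PN classes, Cm = 0.85 (L5) / 0.6195 (L2/3) µF/cm²,
Ra = 200 Ω·cm.  The resulting somatic input resistances are ≈49 MΩ (L5)
and ≈135 MΩ (L2/3): the L5 value sits near the 45 MΩ physiological target
this geometry was built around, while the L2/3 model is stiffer than its
110 MΩ experimental reference — the isopotential bound Rm/A alone is
126 MΩ for this surface area, so no positive axial resistivity can bring
the printed geometry down to 110 MΩ.  We report the model's true value
rather than retuning Rm, because Rm is shared with L5 where it is correct.

Active membrane uses standard Hodgkin–Huxley-style kinetics, uniform
density over soma and dendrites per cell: fast Na⁺/K⁺ (Traub–Miles rates,
threshold shift −55 mV) in all cells; a slow muscarinic K⁺ current
(Pospischil M-current, τ_max = 1 s) in both PN classes; and, in L5 only,
high-(L) and low-(T) threshold Ca²⁺ currents, a Ca²⁺-dependent K⁺ current
with quadratic Ca activation, an HCN current (reversal −35 mV), and a
first-order Ca²⁺ pump (baseline 0.1 µM, τ = 20 ms, shell depth 0.1 µm).
Maximal conductances (see `cells.py`) were tuned to the qualitative firing
phenotypes, which are the contract: 1 nA somatic injection for 100 ms
produces an onset burst then slowing in L5 (intrinsically bursting),
monotonically growing inter-spike intervals in L2/3 (regular spiking,
adapting), and fast regular spiking in baskets.  Conductance values are
not asserted against any reference.

Each cell class's resting potential is computed at build time as the root
of the uniform zero-current condition (gates at steady state, Ca at
baseline) and the state is initialized exactly there.  This makes the
resting column exactly silent — the dipole baseline is flat from t = 0 —
and means no settling transient is needed for evoked simulations; the
rhythm scenarios still discard a 50 ms settling window before spectral
analysis, mainly to skip drive-onset edges (the window is configurable).

### Network

Connectivity is all-to-all between coupled populations.  Weights fall off
with XY distance as exp(−d²/λ²) and delays grow as the inverse profile,
with the pathway-specific space constants λ (3 for PN-origin pathways; 20
for basket→basket; 50/70 for L2/3-/L5-basket inhibition onto PNs).
Inhibitory synapses onto PNs target the soma (GABA_A, GABA_B); excitatory
synapses onto PNs target the basal + oblique dendrites (AMPA, NMDA); all
synapses onto baskets target the soma.  Cross-layer connections: L2/3 PN →
L5 PN, L2/3 PN → L5 basket, L2/3 basket → L5 PN.  Synaptic conductances
are bi-exponential, normalized so a unit-weight event peaks at 1 µS; rise/
decay (ms) and reversals (mV): AMPA 0.5/1, 0; NMDA 1/20, 0 (no Mg²⁺ block
by default; a Jahr–Stevens block is available behind a flag); GABA_A
0.5/5, −80; GABA_B 1/20, −80.  Base (d = 0) weights are package defaults
tuned to the scenario behaviors below; per-pathway E/I gain factors
multiply them (used, e.g., to model inhibition changes under stimulation).

The 3:1 interneuron rule places round(n²/3) baskets per layer on every
third lattice node; the rounding convention is ours (the ratio, not the
rounding, is the constraint) and is configurable through the grid size.

### Drives

The column is silent without input.  Proximal drive (lemniscal-thalamic
style) excites PN basal+oblique dendrites and basket somata in both
layers and pushes current up the apical dendrites (positive dipole);
distal drive (cortico-cortical / non-lemniscal) excites PN apical tufts in
both layers and L2/3 basket somata only, pushing current down (negative
dipole).  Four drive types generate event trains: evoked (Gaussian-timed
volleys; optional synchronous delivery and per-trial start increments),
rhythmic (bursts at a set frequency with Gaussian jitter; n_bursts repeats
of the full sequence accumulate; jitter shared across cells by default,
per-cell behind a flag), Poisson (independent homogeneous trains to
somata; stop = −1 means "runs to the end"), and tonic (somatic current
clamps).  Every (drive, trial) pair owns an RNG substream keyed by the
master seed, a CRC of the drive's name, and the trial index, so adding or
removing one drive never perturbs another's realizations.

### Numerics

The integrator is the standard staggered scheme for compartmental models:
gating variables advance by exponential Euler at the current voltage
(unconditionally stable; gates stay in [0, 1]), then the voltage equation
— linear once conductances are frozen — advances by backward Euler.  Each
cell's small dense system (≤ 9×9) is solved for all cells of a class in
one batched `numpy.linalg.solve` call.  Gate steady states and decay
factors are tabulated on a 0.01 mV voltage grid per (class, dt) and looked
up by index.  Synapses are event-driven: two decaying states per receptor
per compartment, incremented per delivered spike, so cost is independent
of history.  Spikes are upward threshold crossings (default 0 mV) at the
soma with a 1 ms refractory coalescing window; delayed deliveries are
binned to integration steps.  Default dt = 0.025 ms.

Convergence: halving dt changes the aggregate evoked dipole by ~9 %
relative RMS at the default dt (dominated by O(dt) shifts of population
spike times through sharp transients) and by ~2 % at dt = 0.0125 ms; the
error ratio between successive halvings is ≈ 4, i.e. the scheme converges
superlinearly on this problem.  Subthreshold (non-spiking) simulations
agree to < 1 % under dt halving.  A target of < 2 % at the default step
for the spiking evoked scenario is not attainable with a first-order-in-
spike-time method and is left as a documented failure rather than loosened.

### Dipole

For every adjacent compartment pair the axial current (v_i − v_j)/r_axial
(r_axial from the standard half-cylinder series formula) is multiplied by
the pair's signed vertical separation and summed over all pairs of all
PNs; basket cells contribute exactly zero.  Units: mV/MΩ × µm = fAm;
traces are reported in nAm.  Only Δz enters, so absolute layer depths are
irrelevant.  The sign convention follows current flow: up the dendrites
positive, down negative.  A user-chosen scaling factor matches model
output to recorded data; scaling × (number of modeled PNs) estimates the
number of neurons contributing to the recorded signal.

### Analysis

RMSE between traces is computed after linear interpolation onto a common
grid.  PSDs use Welch's method (Hann window, 1 s or full-trace segments,
mean removed).  Spectrograms use a 7-cycle complex Morlet wavelet; edge
samples within half a wavelet of either end are flagged.  Per-trial
spectrograms/PSDs are non-negative, so averaging across trials accumulates
non-time-locked bursts instead of cancelling them.

### Evoked-response optimization

Evoked inputs are Gaussian-timed, so input k's cumulative influence is its
start-time Normal CDF.  The stepwise fitter optimizes one input at a time
in order of mean start time, minimizing a weighted RMSE whose weights are
the Extended Contribution Index ECI_k(t) = max(0, CDF_k(t) −
Σ_{i>k} CDF_i(t)·A^{−(µ_i−µ_k)/T}) with A = 1.6 and T the simulation
length; the window where ECI_k > 0.01 bounds the objective (for the first
input that window typically closes early).  The plain Unique Contribution
Index (A → ∞ limit without attenuation) is also provided.  A final step
polishes all free parameters under plain RMSE; budgets are counted in
simulations per step and a zero budget skips a step.  Each step uses
COBYLA under box constraints in bound-normalized coordinates; every
candidate is clipped to its box, so no evaluation leaves the bounds.
Single-parameter steps first spend part of their budget on a coarse
bracket scan, because wRMSE over a spiking network is rugged and a purely
local method can walk into a neighboring basin.  Bounds follow the
stdev-multiplier rule for start times and a ±percentage rule for weights
(zero-valued weights get a user-set maximum).  Re-running the fit from a
previous result is supported.  The attenuation-exponent reading of the
ECI (a multiplicative factor per subtracted CDF) is the one that produces
the documented "delayed return to zero" behavior and ECI ≥ UCI; the lower
clamp at 0 is applied to both indices.

## Packaged scenarios

* **erp** — proximal volley at 25 ms (σ 2.5), distal at 60 ms (σ 3.5),
  proximal at 125 ms (σ 7), suprathreshold; triphasic +/−/+ waveform;
  dipole scaling 3000 (→ 600,000 implied neurons at full scale).
* **alpha** — 10 Hz subthreshold proximal and distal burst trains, distal
  delayed 50 ms (anti-phase); continuous ~10 Hz dipole rhythm; scaling
  300,000 (→ 60,000,000 implied neurons).
* **beta** — the same trains in phase (0 ms delay) with the distal weight
  doubled; coincident distal bursts break the upward flow and create brief
  beta events, giving both alpha- and beta-band PSD peaks.
* **gamma_ping** — local network reduced to within-layer PN→basket (AMPA)
  and basket→PN (GABA_A, 5 ms decay) plus basket→basket; 140 Hz Poisson
  AMPA drive to PN somata; pyramidal-interneuron gamma at ~50 Hz, paced by
  the inhibitory decay time.
* **gamma_bursty** — the PING network with Poisson rates cut to 4 Hz
  (L2/3) / 5 Hz (L5) plus a small NMDA component; transient gamma bursts;
  scaling 5 (→ ~1000 implied neurons).

## Synthetic fixtures

`generate_fixture` runs a scenario at reduced scale — 5×5 PN grid
(50 PNs), 3 trials by default — and writes the parameter file (the exact
generating parameters, i.e. ground truth) plus the dipole trace in the
same text format used for recorded data.  The 5×5 grid is the smallest
that preserves each scenario's qualitative behavior; problem sizes in the
tests (3×3–10×10 grids, 1–3 trials, 150–710 ms) are chosen to exercise
the full machinery at desk scale.  What the fixtures do *not* emulate:
measurement noise, source-localization error, inter-subject variability,
and non-stationary drive statistics of real recordings — so passing
recovery tests shows the estimator works on data generated by its own
forward model, not that it is robust to model mismatch.

Parameter recovery on the synthetic evoked response (start times perturbed
by ±10 ms, timing-only fit, ~70 simulations) returns each input's start
time to within 2 ms and halves the RMSE for the packaged perturbation
pattern; with the opposite perturbation signs the distal input lands
~2.3 ms off, which is the method's realistic resolution at this budget.

## Known limitations

* Channel kinetics are standard published forms, not a reproduction of any
  specific reference implementation; only passive targets and firing
  phenotypes are asserted.
* The L2/3 passive input resistance exceeds its experimental target (see
  above); all downstream behaviors are tuned with the model as it is.
* First-order spike timing limits waveform-level reproducibility across
  integration steps to a few percent (see Numerics).
* No axons, synaptic plasticity, gap junctions, structured topology, or
  forward head modeling; the dipole is the source-space signal only.
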