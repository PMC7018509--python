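# neocolumn

A biophysical model of a canonical neocortical column that simulates the
**primary current dipole** underlying MEG/EEG signals, with layer-specific
exogenous drives for studying sensory evoked responses and alpha/beta/gamma
rhythms, and a stepwise optimizer that fits evoked-drive parameters to
recorded dipole waveforms.

It is written for MEG/EEG researchers who work with source-localized data:
the model's output has the same units (ampere-meters) as a source estimate,
so simulated and recorded waveforms can be compared one-to-one, and circuit-
level hypotheses (which layer received input, when, and how strongly) can be
tested directly against data.

## The model in brief

The column contains multicompartment layer 2/3 and layer 5 pyramidal neurons
(PNs, 8 and 9 compartments) with aligned apical dendrites, and single-
compartment fast-spiking basket interneurons, in a 3:1 PN:interneuron ratio
per layer on a 10×10 grid (200 PNs).  Membrane dynamics follow standard
Hodgkin–Huxley-style kinetics tuned to canonical phenotypes: L5 PNs burst,
L2/3 PNs adapt, baskets spike fast and regularly.  Synapses (AMPA, NMDA,
GABA_A, GABA_B) are bi-exponential, with distance-dependent weights
`w(d) = w₀·e^(−d²/λ²)` and delays `δ(d) = δ₀·e^(+d²/λ²)`.

The dipole of one PN is the sum over adjacent compartment pairs of the
axial current times the pair's vertical separation,

    Q = Σ_pairs (v_i − v_j)/r_axial · Δz,

summed over all PNs and attributed per layer.  Horizontal (oblique)
dendrites and the radially symmetric basket cells contribute nothing.
Proximal drive (basal/oblique dendrites + basket somata; lemniscal-thalamic
style) pushes current up the dendrites → positive deflection; distal drive
(apical tufts + L2/3 basket somata; cortico-cortical style) pushes current
down → negative deflection.  A scaling factor matches model output to data
magnitude; scaling × 200 PNs estimates the number of contributing neurons.

The evoked-response optimizer exploits input timing: each Gaussian-timed
input k is fitted in turn under a weighted RMSE whose weight is the
Extended Contribution Index
`ECI_k(t) = max(0, CDF_k(t) − Σ_{i>k} CDF_i(t)·A^{−(µ_i−µ_k)/T})`
(A = 1.6), restricted to the window where ECI_k > 0.01, followed by a final
all-parameter polish under plain RMSE (COBYLA, box constraints).

## Worked example

```python
from neocolumn import ColumnModel

model = ColumnModel.from_scenario("erp", n_pyr=5, seed=3)
res = model.simulate()
print(res.summary())
```

prints

```
Neocortical column simulation
==============================================
grid                 5 x 5 (50 pyramidal neurons)
trials               1
duration             170 ms (dt = 0.025 ms, settle 0 ms)
drives               evprox_1, evdist_1, evprox_2
dipole scaling       3000 (implies 150,000 neurons)
dipole peak-to-peak  92.82 nAm (max 48.18, min -44.65)
spikes/trial         L2_basket: 18, L2_pyramidal: 49, L5_basket: 5, L5_pyramidal: 2
```

The trace (`res.dipole` over `res.times`, in nAm) is the classic triphasic
evoked response: a positive peak near 30 ms as the first proximal volley
drives current up the dendrites, a negative trough near 70 ms as the distal
input pushes current down, and a late positive peak after the second
proximal volley at 125 ms.  The scaling factor 3000 says that matching a
recorded evoked field of this size would imply roughly 150,000 contributing
pyramidal neurons for this reduced 50-PN column (600,000 at the full 200-PN
scale).

Fitting drive parameters to a waveform:

```python
from neocolumn import ERPModel

erp = ERPModel("recorded_dipole.txt", model)   # time_ms, dipole_nAm columns
fit = erp.fit(sims_per_step=30, final_step_sims=30)
print(fit.summary())       # initial/final RMSE, per-step windows, parameters
fit.fitted_model.to_param_file("optimized.param")
```

The same functionality is available from the shell:

```bash
neocolumn simulate --param erp.param --out dipole.txt
neocolumn analyze psd --in dipole.txt --band 30 80
neocolumn optimize --param start.param --data recorded.txt --out fitted.param
neocolumn fixture gamma_ping --seed 1 --out-dir fixtures/
```

Packaged scenarios: `erp`, `alpha` (anti-phase 10 Hz bursts → continuous
alpha), `beta` (in-phase bursts, stronger distal → alpha + beta events),
`gamma_ping` (140 Hz Poisson drive, E–I loop → ~50 Hz gamma),
`gamma_bursty` (weak Poisson drive → transient gamma bursts).  See
`docs/methods.md` for model details, parameter meanings and limitations.

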