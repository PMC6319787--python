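# rotoranchor

Rotor dynamics around fibrotic scars in 2D human ventricular tissue.

Reentrant arrhythmias such as ventricular tachycardia are often driven by
*rotors* — spiral waves of excitation turning around a functional core — and
clinically these rotors are found anchored to fibrotic scar tissue
remarkably often.  `rotoranchor` is a research package for studying one
candidate explanation in silico, *dynamical anchoring*: a fibrotic scar is
not just a passive anchor but actively restructures the activation pattern,
breaking the waves of a distant rotor into secondary sources that propagate
back, annihilate the original rotor, and leave a rotor pinned on the scar —
visible on the (pseudo-)ECG as a transition from polymorphic to monomorphic
tachycardia.  It is intended for computational electrophysiologists who want
a compact, testable 2D platform for scar–rotor interaction studies.

## What is inside

* **Ionic model** — ten Tusscher–Panfilov 2006 (TP06) human ventricular
  myocyte, with the fibrosis-dependent ionic remodeling
  G_Na = (1 − 1.55 f/100) G_Na0, G_Kr = (1 − 1.75 f/100) G_Kr0,
  G_Ks = (1 − 2 f/100) G_Ks0 for a local fibrosis percentage f.
* **Tissue** — discrete monodomain sheet (250 µm nodes),
  C_m dV_i/dt = Σ_j η_ij g_gap (V_j − V_i) − I_ion, forward Euler at
  dt = 0.02 ms with Rush–Larsen gate updates, g_gap = 103.6 nS calibrated to
  a planar conduction velocity of 72 cm/s at 1 Hz.  JIT-compiled kernel,
  ~40 ns per node-step on one core.
* **Fibrosis / scar synthesis** — fibrosis-percentage fields (radial
  gradient scars, uniform disks, necrotic/no-scar controls) and seeded
  Bernoulli obstacle textures; above ~41 % fibrosis the tissue stops
  conducting (site percolation) and behaves as solid scar.
* **Protocols** — planar-wave CV measurement, conduction-block sweeps,
  automatic cross-field S1S2 rotor initiation.
* **Rotor analysis** — phase-singularity detection (winding number of a
  time-delay phase), period measurement, and the outcome classifier
  (terminated / anchored single or multi-armed, with chirality /
  not anchored; anchoring threshold: period > 280 ms over a 320 ms window).
* **Pseudo-ECG** — far-field dipole electrogram and beat-morphology
  features (cycle lengths, amplitude variability).
* **Experiment drivers** — outcome-vs-distance sweeps, anchoring-time
  regressions, the (scar size × fibrosis level) attraction phase diagram,
  and control runs, at configurable scale.

See `docs/methods.md` for the model, calibration and numerical choices.

## A worked example

```sh
python examples/01_single_cell_action_potential.py
```

prints

```
healthy epicardial cell: V_rest = -86.1 mV, peak = 41.8 mV, APD90 = 302 ms
remodeling at f = 40 %: scale factors s_Na = 0.38, s_Kr = 0.30, s_Ks = 0.20
remodeled cell:          V_rest = -86.1 mV, peak = 30.5 mV, APD90 = 487 ms (+185 ms vs healthy)
```

i.e. a normal human epicardial action potential, and the 62 %/70 %/80 %
conductance reductions that a 40 % fibrotic environment imposes — the
remodeled cell repolarizes far later, the heterogeneity that seeds wave
breaks at the scar border.  The other examples walk through conduction
velocity in fibrotic tissue (`02`), scar synthesis (`03`), conduction block
at the percolation threshold (`04`), phase-singularity detection (`05`),
the pseudo-ECG (`06`) and the anchoring experiment drivers (`07`).

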