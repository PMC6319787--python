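# Methods

This package simulates rotor (spiral-wave) dynamics around fibrotic scars in
a two-dimensional sheet of human ventricular tissue and provides the
protocols and analyses needed to study *dynamical anchoring*: the process by
which a fibrotic scar destabilizes a distant rotor through secondary wave
breaks and ultimately replaces it with a rotor anchored on the scar.

## Tissue model

The tissue is a rectangular grid of nodes with 250 µm spacing, each node a
ten Tusscher–Panfilov 2006 (TP06) human ventricular myocyte or an
electrically uncoupled, unexcitable obstacle.  The membrane equation is the
discrete monodomain form

    C_m dV_i/dt = Σ_j η_ij · g_gap · (V_j − V_i) − I_ion,i ,

where η_ij ∈ {0, 1} couples myocyte i to its four von Neumann neighbors,
g_gap = 103.6 nS is the gap-junction conductance (identical everywhere,
including fibrotic areas), and I_ion is the full TP06 current sum in pA/pF.
Obstacle and out-of-domain edges carry no current, so domain boundaries are
no-flux by construction.

Stencil: the coupling sum runs over the four edge-sharing neighbors.  A
diagonal (vertex-sharing) reading of the neighbor sum is dimensionally
possible but decouples the lattice into two non-interacting sublattices;
the edge-sharing stencil is the standard discretization and is validated by
the conduction-velocity calibration below.

### Numerics

* Forward Euler for the voltage and ion concentrations at dt = 0.02 ms.
* Rush–Larsen exponential updates for the 12 Hodgkin–Huxley gates.  This is
  not optional: the TP06 m-gate time constant (τ_m = α_m·β_m) is ≈ 1 µs at
  the resting potential, three orders of magnitude below dt, so explicit
  Euler on the gates diverges within a few steps.  The exponential update is
  exact for the frozen-voltage gate equation and is what the published TP06
  integrators use.
* Calcium buffering (cytosol, subspace, SR) uses TP06's instantaneous
  algebraic buffering projection.
* All voltage-dependent right-hand-side factors are pre-tabulated on a
  0.05 mV grid and linearly interpolated inside a compiled kernel; the
  interpolation error is below the cross-implementation tolerance of the
  test suite (a 20-node cable agrees with a table-free dense reference
  integrator to < 0.1 mV away from the upstroke).
* Reversal potentials are refreshed every 0.5 ms (intracellular
  concentrations drift on the scale of seconds).
* Double precision by default; a single-precision mode exists for storage
  parity with GPU-style implementations.
* Determinism: the integrator draws no random numbers; a run is a pure
  function of (grid, config, stimuli, initial state).

### Units contract and the coupling constant

TP06 currents are per-capacitance (pA/pF); the coupling term g_gap·ΔV is a
current (pA).  The conversion is the node capacitance C_m, fixed **once** by
requiring that a plane wave paced at cycle length 1000 ms travel at
72 cm/s: C_m = 40.36 pF, i.e. g_gap/C_m = 2.567 ms⁻¹ and an effective
diffusion coefficient D = g_gap·dx²/C_m ≈ 1.6·10⁻³ cm²/ms.  This single
constant closes the unit system; it is not retuned per experiment.

### Calibrated parameter set

`CellParams.epicardial()` is the published TP06 epicardial set and is what
the single-cell tests validate against an independent reference integrator.
Tissue-level experiments use `CellParams.calibrated()`: the epicardial set
with the delayed-rectifier conductances G_Kr and G_Ks scaled by 1.12.  The
calibration surface is (i) planar CV = 72 cm/s at 1 Hz and (ii) a free-rotor
period of ≈ 222 ms.  With the published set the free rotor turns at ≈ 237 ms
and drifts; the mild delayed-rectifier increase shortens the high-rate APD
enough to bring the period to ≈ 222 ms (221.9 ms over the final 640 ms of a
settled rotor in the 8 × 11.2 cm sheet; 223.7 ms in a 9.6 × 12.8 cm one)
while leaving planar CV at 71.9 cm/s (I_Na-driven) and the conduction-block
threshold (structural) untouched.  Both scale factors are module constants, applied nowhere else.

## Fibrosis model

Diffuse fibrosis is modeled as randomly uncoupled unexcitable nodes: the
local fibrosis percentage f(x) ∈ [0, 100] is the probability for the node
at x to be an obstacle.  Textures are drawn by comparing one shared
per-node uniform field (seeded `numpy` generator) against f/100, so a seed
fully reproduces a texture and raising f pointwise can only add obstacles.

Ionic remodeling in fibrotic border zones (optional, per run):

    G_Na = (1 − 1.55 f/100) G_Na0
    G_Kr = (1 − 1.75 f/100) G_Kr0
    G_Ks = (1 − 2.00 f/100) G_Ks0

clamped at zero where the linear form would go negative (f > 64.5 % for
I_Na, f > 50 % for I_Ks; such nodes are almost always obstacles anyway).
At f = 40 % these give the canonical reductions of 62 %, 70 % and 80 %.
Remodeling prolongs the APD inside the scar, which is why the first wave
breaks appear earlier when it is enabled.

Scar geometries produced by the generator:

* **gradient scar** — a disk (default diameter 6.4 cm) whose fibrosis falls
  linearly from 50 % at the center to 0 % at the rim.  Its f > 41 % core
  conducts nothing (below), so it emulates an imaging-derived scar: necrotic
  core plus partially fibrotic border zone.  The synthetic normalized
  signal-intensity field is f/100 by construction.
* **uniform disks** for the (diameter × fibrosis level) phase diagram;
* **controls** — no scar at all, and "necrotic-only": the same disk as a
  solid obstacle with no fibrotic border and no remodeling.

What the generator does *not* emulate: anisotropy, patchy/interstitial
fibrosis textures, the irregular geometry of real infarcts, and
image-resolution effects.  Conclusions from passing tests therefore concern
the isotropic random-obstacle idealization, not patient anatomy.

## Protocols

* **CV measurement** — thin strip, plane waves paced from one edge at a
  given cycle length, tissue pre-set to the single-cell paced steady state;
  velocity from the activation-time difference (first upward crossing of
  −20 mV, median over rows) between two probe columns ≥ 2 cm apart, after
  two conditioning beats.  Textured (fibrotic) strips report a mean ± sd
  over seeds; a wave that never reaches the distal probes is an explicit
  "blocked" outcome.  At 30 % fibrosis the measured CV is ≈ 46–48 cm/s.
* **Conduction block** — single plane waves aimed at a band of uniform
  fibrosis on a small patch; the block threshold is the lowest level (1 %
  steps) at which no texture seed conducts.  This sits at ≈ 41 %,
  i.e. where the myocyte fraction (1 − f) crosses the 2D site-percolation
  threshold (≈ 0.593) and the conducting cluster stops spanning.
* **S1S2 rotor initiation** — S1 plane wave from the left edge; S2 over a
  quadrant, triggered automatically when the S1 wave-back (−60 mV downward
  crossing) clears a monitor point.  The S2 break settles a reproducible
  displacement down-left of the trigger (the functional refractory boundary
  trails the −60 mV line), so the monitor is offset so that the rotor lands
  on the requested position; mirroring the quadrant flips chirality.  The
  protocol verifies that exactly one *persistent* phase singularity remains
  (median count over the last five stored frames — rotor cores shed
  short-lived singularity pairs) and raises a diagnostic failure otherwise.
  Free rotors need room for their first rotation (the 1-Hz wavelength,
  ≈ 20 cm of path): sheets of ≈ 9.6 × 12.8 cm or larger sustain them;
  smaller sheets are used only for deliberately-failing protocol tests.

## Rotor analysis

* **Phase singularities** — time-delay phase θ = atan2(V(t) − V*,
  V(t−τ) − V*) with τ = 20 ms, V* = −40 mV; singularities are grid
  plaquettes with winding number ±2π; charge +1 is counter-clockwise in
  grid coordinates (rows increasing downward).  Plaquettes touching
  obstacles are skipped (phase undefined there); the fast vectorized
  detector is tested against a brute-force per-plaquette oracle.
* **Period** — activation times are −20 mV upward crossings of the probe
  traces; the period over a measuring window (320 ms for classification) is
  the median of all inter-activation intervals pooled across probes, and is
  right-censored at the window length when no probe activates twice.
  Pooling across probes (rather than censoring each probe separately)
  matters: a 222 ms rotor gives two crossings per 320 ms window in only
  ~45 % of probes, and a per-probe median would censor the majority.
* **Classification** (applied at a configured late time): *terminated* if
  every myocyte is below −20 mV; else *anchored* if the period exceeds
  280 ms over the 320 ms window (an anchored scar rotor is anatomical
  reentry around ≥ 2.6 cm of obstacle and turns at ≥ ~300 ms; a free rotor
  turns at ≈ 222 ms); else *not anchored*.  Arms and chirality of anchored
  rotors come from same-sign singularities within 1 cm of the scar rim.
  Probes for classification sit on a 16-point ring 1 cm outside the scar
  rim plus four far-field points, so both anchored and free rotors are
  observable.
* **Time to anchoring** — earliest time from which the sliding-window
  period stays above threshold until the end of the run (transient
  excursions are ignored); for terminated runs, the last suprathreshold
  frame.

## Pseudo-ECG

Far-field dipole-source electrogram assuming an infinite volume conductor:
ECG(t) = Σ nodes (r · D∇V)/|r|³ dx², with ∇V by central differences
(one-sided at obstacles and boundaries), D = g_gap·dx²/C_m, and the
electrode 10 cm above the sheet center.  Units are relative; only
morphology and timing are interpreted.  Beat features (cycle lengths from
prominence-detected peaks; amplitude coefficient of variation over sliding
5-beat windows) quantify the polymorphic-to-monomorphic transition that
accompanies anchoring.

## Experiment drivers and scale

The full study design (25.6 × 12.8 cm sheet, 40 s per run, 60–300 textures
per sweep point) is cluster work.  The drivers in
`rotoranchor.experiments` default to a desk scale — 12.8 × 6.4 cm domain,
20 s runs, classification at the end of the run, 10 textures per point —
and accept a `paper_scale` flag restoring the full setup.  Every output row
carries its seed, configuration hash and scale so any single run can be
reproduced bit-for-bit.  Failures (e.g. a rotor that does not survive
initiation) are recorded as rows, never dropped.

The test suite and the acceptance script use further-reduced problem sizes
chosen so the whole suite runs on one CPU core in well under half an hour:
CV strips of 12 × 400 and 12 × 280 nodes, block-threshold patches of
32 × 120 nodes with a 1.4 cm fibrotic band, free-rotor sheets of
8 × 11.2 cm, and a 7.5 cm sheet for the anchored (pinned) rotor.  The
methodological content — dt, dx, conductances, thresholds, protocols — is
identical at every scale; only domain extent, run duration and replicate
counts shrink.

## Known limitations

* Isotropic 2D monodomain only: no fiber anisotropy, no transmural
  heterogeneity, no 3D geometry.
* The free rotor of the calibrated set meanders within ~1 cm of its mean
  position (and occasionally sheds short-lived singularity pairs); "the
  rotor stays at its initiation site" is therefore asserted against the
  time-averaged core position.
* The conduction-block threshold is a percolation quantity; on small
  patches its finite-size uncertainty is about ±1–2 %.
* Pseudo-ECG amplitudes are uncalibrated by design (relative units).
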