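# Methods

## System and model

The package models the electrochemistry of an ionizable, amphoteric drug
(danofloxacin: carboxylic acid pKa1 = 6.07, piperazinium pKa2 = 8.50,
charge +1 below pH ~6) at two transducers:

1. an **electrified liquid–liquid interface** (water | 1,2-dichloroethane),
   where the current reports the transfer of the protonated cation across
   the interface rather than a redox reaction, and
2. a **glassy carbon electrode** (3 mm disc, 0.071 cm²), where the drug is
   oxidized and quantified by square-wave voltammetry.

### Reversible transfer simulation

`synth.simulate_cv_reversible` treats ion transfer as a reversible
(Nernstian) process limited by semi-infinite planar diffusion on both
sides of the interface:

* one species with bulk concentration C in the donor phase (diffusion
  coefficient D₁) and zero in the acceptor phase (D₂);
* interfacial equilibrium c₂(0)/c₁(0) = √(D₁/D₂)·exp(zF(E − E½)/RT), so
  the configured `half_wave_potential` is the actual half-wave potential
  regardless of the D₁/D₂ ratio;
* flux continuity across the interface; current I = zFA·J.

Numerics: explicit FTCS on uniform per-phase grids spanning six diffusion
lengths (dxᵢ = 6√(Dᵢ·t_total)/n_space), with the interface condition and
the current evaluated from second-order one-sided three-point gradients.
Because each phase's grid scales with its own diffusion length, the
stability number λ = D·dt/dx² = n_space²/(36·n_time) is phase-independent;
λ > 0.5 raises a configuration error naming the offending grid. A uniform
grid with second-order interface gradients was chosen over an expanding
grid: at the default grid (n_space = 240, n_time = 6000) the forward peak
current already matches the Randles–Ševčík closed form to 0.12 % and
halving the time step moves it by < 0.02 %, so a graded mesh would add
complexity without accuracy.

Known model limits, deliberate:

* no uncompensated resistance, double layer, capacitive current or
  adsorption — so the simulated peak separation is the ideal reversible
  ~58 mV/z, below the ~75 mV observed experimentally at resistive
  liquid-liquid cells (the observed value ships as a documentation
  benchmark in `voltities.benchmarks`, never as a computed result);
* the midpoint half-wave estimator carries a small (~0.4 mV at a ±0.25 V
  window) bias from the finite switching potential; it is physical, not
  numerical (it persists under grid refinement), and shrinks with a wider
  window.

### Partition diagram and constants

The half-wave potential of the cation obeys

Δφ½(pH) = Δφ⁰ + (RT/zF)·ln((10^−pH + Ka·K_D + Ka)/10^−pH),  Ka = 10^−pKa2.

Only the piperazinium equilibrium enters this expression; the carboxylate
equilibrium matters for speciation but not for the transfer diagram. K_D
is used in the **organic-favouring orientation** [drug]_org/[drug]_aq —
the orientation under which a larger K_D produces the larger high-pH
shift and K_D ≈ 600 means the neutral form overwhelmingly partitions into
the organic phase. Conventions differ between sources, so
`fit_partition_model(..., invert=True)` reports the reciprocal,
water-favouring value instead.

Fitting is one-dimensional: for fixed K_D the optimal Δφ⁰ is the mean
residual, so the search runs over log₁₀K_D on a coarse grid (−2 … 6, step
0.02) followed by bounded scalar refinement. Both a floating-Δφ⁰ mode and
a fixed-Δφ⁰ mode (anchoring at the low-pH plateau) are provided, since
either is defensible; flat data with a floating Δφ⁰ is reported as
unidentifiable rather than silently fitted. With the study's grid (pH
2–12, step 0.5) and 2 mV potential noise the median K_D error over 50
seeds is below 10 %, and the error tends to zero with the noise.

logP′ = −Δφ⁰′zF/(2.303RT) and ΔG′ = zFΔφ⁰′ are algebraically the same
quantity on different scales; `PhysChemConstants` enforces the identity on
construction. Constants use R = 8.314 J mol⁻¹ K⁻¹, F = 96 485 C mol⁻¹,
T = 298 K unless stated, and the TPrA⁺ reference transfer potential
−0.091 V anchors the Galvani potential axis.

### Peak analysis

* Peaks are raw extrema per segment (forward → maximum, backward →
  minimum, ties to the first occurrence along the scan), optionally after
  subtracting a straight line through the window edges. No baseline
  treatment was prescribed by the source data, so the linear chord is the
  deliberately simple default.
* The backward peak of a cyclic voltammogram rides on the forward sweep's
  decaying tail; its zero-line magnitude underestimates the true peak
  current by ~25 %. `reversibility_ratio` therefore applies Nicholson's
  empirical correction |ip_b/ip_f| = |ip_b0/ip_f| + 0.485·|i_sp/ip_f| +
  0.086, which returns 1.00–1.02 on simulated reversible traces.
* `randles_sevcik_D` fits |Ip| vs √v with a free intercept (matching how
  linear relationships are fitted throughout) and inverts the 298-K
  coefficient 2.69×10⁵; other temperatures are rejected rather than
  mis-scaled.
* The log Ip–log v regime bands are [0.45, 0.55] → diffusion and
  [0.90, 1.10] → adsorption, centred on the theoretical 0.5 and 1.0;
  anything else (e.g. the 0.40 observed at the glassy carbon electrode)
  is "mixed". The bands are disjoint by construction.

### Calibration statistics

LOD = 3·SE_b/a and LOQ = 10·SE_b/a, with SE_b the **regression standard
error of the intercept** (µA) and a the slope (A M⁻¹ ≡ µA/µM), giving
limits directly in µM; this is the definition that reproduces the
reference validation table (e.g. 3·0.0725/0.1022 = 2.13 µM) even though
such tables sometimes describe SE_b loosely as a blank SD. LOQ/LOD = 10/3
exactly, and both are invariant under rescaling all currents. The linear
dynamic range is recorded as the fitted concentration span — no
breakpoint detection is attempted. Calibrations on negative (backward)
currents use the slope magnitude for detection limits while preserving
sign in reports.

Standard addition regresses signal on added concentration and extrapolates
to zero signal; a multiplicative matrix effect scales slope and intercept
alike and cancels exactly, which the tests assert for suppression factors
0.3–1.0. Selectivity follows the ±10 % signal-change rule.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`; no global RNG state.

* **CV/ITV**: physically simulated (above). Default conditions mirror the
  study: 0.33 mM analyte, D_aq = 1.13×10⁻⁶ and D_org = 0.14×10⁻⁶ cm² s⁻¹,
  z = +1, 20 mV s⁻¹, half-wave 0.123 V. The interfacial area is a required
  argument — it is an experimental fact, and the 1.331 cm² used in tests
  is the value consistent with the validation table's slope
  normalization, not a hidden default.
* **SWV**: a sech² bell (half-width at half-maximum as the width
  parameter) on a polynomial baseline, with the optimized waveform preset
  (f = 60 Hz, amplitude 90 mV, step 12 mV) stored as metadata. Square-wave
  peaks are used only for calibration, so linearity of height in
  concentration is the property that matters; no pulse-level mechanism is
  simulated.
* **Noise**: additive homoscedastic Gaussian on current (defaults
  0.05–0.1 µA, a plausible instrument scale) or on potential (2 mV for
  partition data); heteroscedasticity, drift correlation and real matrix
  chemistry are not modelled. The milk surrogate is sensitivity
  suppression (0.7 by default) plus a linear blank drift — enough to
  exercise blank subtraction and standard addition, not a model of milk.

Consequently, passing tests demonstrate correctness of the computational
pipeline under idealized noise, not robustness to every instrumental
artefact (electrode fouling, non-Gaussian spikes, capacitive backgrounds).

## Problem sizes

Defaults were chosen so the whole suite exercises realistic grids while
remaining quick: CV grids of 240 × 6000 (default) and 340 × 12000 (fine),
50-seed Monte Carlo for K_D recovery, 100 seeds for standard addition,
200 seeds for calibration-slope bias, speciation grids at 0.005 pH
resolution. The acceptance script re-runs all of these from scratch in a
few seconds.

## Degenerate inputs and tie-breaks

Empty traces, mismatched array lengths, non-positive scan rates, unknown
segment labels, non-overlapping blank ranges, monotone currents (no
interior extremum), zero concentration variance, non-positive slopes,
K_D ≤ 0, pKa1 ≥ pKa2, zero charge and T ≠ 298 K in Randles–Ševčík all
raise typed errors; peak ties resolve to the first point along the scan
direction; double axis calibration is a state error.
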