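# voltities

Voltammetric analysis for drug electroanalysis at **electrified
liquid–liquid interfaces (ITIES)** and **solid electrodes**, built around
the comparative study of the fluoroquinolone antibiotic danofloxacin.

It is aimed at electroanalytical chemists who record ion-transfer or
square-wave voltammograms and want a tested, scriptable route from raw
potential/current traces to physicochemical constants and validated
analytical figures of merit — without spreadsheet archaeology.

## What it computes

**Ion transfer at the ITIES.** A cationic drug transfers from water into
1,2-dichloroethane once the Galvani potential difference Δφ exceeds its
formal transfer potential Δφ⁰′. The pH dependence of the half-wave
potential follows the ionic partition diagram

```
Δφ½(pH) = Δφ⁰ + (RT/zF) · ln( (10^-pH + Ka·K_D + Ka) / 10^-pH )
```

with Ka = 10^−pKa and K_D the distribution constant of the neutral form.
`fit_partition_model` estimates K_D (and optionally Δφ⁰) from
(pH, Δφ½) data; the formal potential then yields the lipophilicity
constants

```
logP′ = −Δφ⁰′·z·F / (2.303·R·T)        ΔG′(aq→org) = z·F·Δφ⁰′
```

**Voltammetry.** `simulate_cv_reversible` solves reversible Nernstian
transfer between two semi-infinite diffusion fields by explicit finite
differences, reproducing the Randles–Ševčík peak current
Ip = 2.69×10⁵ z³ᐟ² A C √(D v) to better than 2 %. Peak tools extract peak
potentials/currents, peak-to-peak separation (~59 mV/z when reversible),
the Nicholson-corrected forward/backward current ratio, diffusion
coefficients from Ip vs √v, and the log Ip–log v slope that separates
diffusion (≈0.5) from adsorption (≈1.0) control.

**Validation statistics.** `linear_calibration` gives OLS slope/intercept
with standard errors, R², LOD = 3·SE_b/a, LOQ = 10·SE_b/a and
area-normalized sensitivity; `standard_addition` quantifies an analyte in
a complex matrix (e.g. milk) where multiplicative matrix effects cancel;
`interference_effect` applies the ±10 % selectivity rule.

**Synthetic data.** Every input class (CV/ITV traces, SWV peaks on
drifting baselines, calibration series, partition data, milk-matrix
standard additions, interference series) can be generated with known
ground truth from a seed, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from voltities import (SimulationConfig, simulate_cv_reversible, find_peak,
                       fit_partition_model, logp_from_phi, gibbs_from_phi)
from voltities.synth import generate_partition_data

# 1. a reversible ion-transfer CV at a 1.331 cm^2 interface, 20 mV/s
vg = simulate_cv_reversible(SimulationConfig(area=1.331))
fwd, bwd = find_peak(vg, "forward"), find_peak(vg, "backward")
print(f"Ip = {fwd.peak_current:.2f} uA, dEp = "
      f"{1000*abs(fwd.peak_potential - bwd.peak_potential):.1f} mV")

# 2. fit an ionic partition diagram (2 mV noise) and derive constants
data, _ = generate_partition_data(0.123, 8.50, 600.0,
                                  np.arange(2, 12.01, 0.5),
                                  noise_sd=0.002, seed=1)
model, diag = fit_partition_model(data, pKa=8.50)
print(f"K_D = {model.K_D:.0f}, phi0 = {model.phi0*1000:.1f} mV")
print(f"logP = {logp_from_phi(model.phi0):.2f}, "
      f"dG = {gibbs_from_phi(model.phi0):.2f} kJ/mol")
```

prints

```
Ip = 17.74 uA, dEp = 58.2 mV
K_D = 585, phi0 = 123.5 mV
logP = -2.09, dG = 11.91 kJ/mol
```

i.e. the simulated transfer behaves reversibly (peak separation near the
59 mV/z ideal), the partition fit recovers the generating distribution
constant of 600 within a few percent despite the 2 mV noise (K_D ≈ 600:
the neutral drug strongly favours the organic phase), and the ~+0.123 V
formal potential translates into logP′ ≈ −2.08 — a hydrophilic cation
that needs ~12 kJ/mol to cross into 1,2-dichloroethane.

A command-line interface drives the same machinery from YAML configs:

```sh
voltities synth --config config.yaml          # synthetic study bundle
voltities ities --config config.yaml          # partition fit + calibration
voltities gce   --config config.yaml          # SWV calibration + regime
voltities milk  --config config.yaml          # blank subtraction + std. addition
voltities report out/report.json --out table/ # comparison table
```

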