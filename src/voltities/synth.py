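"""Seeded synthetic-data generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and seed: identical
calls are bit-identical, and the ground truth used to produce a dataset is
returned alongside it so recovery tests can close the loop.

The centrepiece is an explicit finite-difference simulation of reversible
(Nernstian) ion transfer across an interface separating two semi-infinite
diffusion fields — the model behind cyclic voltammetry at an electrified
liquid-liquid interface, and formally identical to a reversible redox
couple at a solid electrode.  The remaining generators are phenomenological:
square-wave peaks are bell-shaped curves on a polynomial baseline,
calibration and standard-addition series are straight lines with additive
Gaussian current noise, and the milk-matrix surrogate combines sensitivity
suppression with baseline drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import F, R, T_DEFAULT, GridError, Voltammogram
from .physchem import PartitionModel, partition_halfwave

__all__ = [
    "SimulationConfig",
    "simulate_cv_reversible",
    "generate_swv_trace",
    "generate_calibration_series",
    "generate_partition_data",
    "generate_matrix_series",
    "generate_interference_series",
    "MatrixSeries",
    "write_xy_csv",
    "write_truth",
    "ITIES_CALIBRATION_LEVELS_UM",
    "GCE_CALIBRATION_LEVELS_UM",
    "MILK_ITIES_ADDITIONS_UM",
    "MILK_GCE_ADDITIONS_UM",
    "INTERFERENT_LEVELS_UM",
    "GCE_INTERFERENT_LEVELS_UM",
    "ITIES_SCAN_RATES_VS",
    "DEFAULT_SWV_WAVEFORM",
]

# ---------------------------------------------------------------------------
# Study presets: the concentration levels, additions and waveform settings
# used throughout the danofloxacin study these tools were designed around.
# ---------------------------------------------------------------------------

#: ITIES calibration levels, uM
ITIES_CALIBRATION_LEVELS_UM = (7.13, 14.24, 35.46, 104.9, 138.9, 205.5, 270.3, 333.3)
#: GCE (square-wave) calibration levels, uM
GCE_CALIBRATION_LEVELS_UM = (13.71, 43.37, 101.6, 158.6, 214.2, 268.5, 321.6, 373.6)
#: standard additions used for milk analysis at the ITIES, uM
MILK_ITIES_ADDITIONS_UM = (14.24, 21.34, 28.41, 42.49, 56.50, 70.42, 104.9)
#: standard additions used for milk analysis at the GCE, uM
MILK_GCE_ADDITIONS_UM = (19.92, 24.88, 29.82, 34.76, 39.68, 44.60, 49.50)
#: interferent concentration levels for the ITIES selectivity screen, uM
INTERFERENT_LEVELS_UM = (14.3, 140.6, 277.4, 1248.0)
#: interferent concentration levels for the GCE selectivity screen, uM
GCE_INTERFERENT_LEVELS_UM = (6.09, 56.20, 572.4)
#: scan rates of the ITIES scan-rate study, V/s
ITIES_SCAN_RATES_VS = (0.005, 0.010, 0.015, 0.020, 0.025, 0.030, 0.035)
#: optimized square-wave waveform: frequency, amplitude, step potential
DEFAULT_SWV_WAVEFORM = {"frequency_Hz": 60.0, "amplitude_V": 0.090, "step_V": 0.012}


# ---------------------------------------------------------------------------
# Reversible CV / ITV finite-difference simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for a reversible-transfer cyclic voltammetry simulation.

    ``area`` has no default: the interfacial area is an experimental fact
    the user must supply, never an assumption of the simulator.

    Phase 1 is the donor phase (aqueous for a cation transferring
    aq -> org on the forward sweep); phase 2 is the acceptor (organic).
    ``half_wave_potential`` is the half-wave potential the trace is
    centred on; with equal diffusion coefficients it coincides with the
    formal transfer potential.

    Defaults mirror the danofloxacin ITIES study: 0.33 mM analyte,
    D_aq = 1.13e-6 cm2/s, D_org = 0.14e-6 cm2/s, z = +1, 20 mV/s, 298 K,
    and a +-0.25 V window around the 0.123 V half-wave potential.
    """

    area: float  # cm^2
    half_wave_potential: float = 0.123  # V
    D_phase1: float = 1.13e-6  # cm^2 s^-1 (donor / aqueous)
    D_phase2: float = 0.14e-6  # cm^2 s^-1 (acceptor / organic)
    bulk_concentration: float = 3.3e-7  # mol cm^-3 (= 0.33 mM)
    charge: int = 1
    scan_rate: float = 0.020  # V s^-1
    window: tuple[float, float] = (-0.127, 0.373)  # (start, vertex), V
    T: float = T_DEFAULT
    n_space: int = 240
    n_time: int = 6000
    noise_sd: float = 0.0  # uA
    seed: int = 0
    technique: str = "ITV"

    def __post_init__(self) -> None:
        for name in ("area", "D_phase1", "D_phase2", "scan_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.bulk_concentration < 0:
            raise ValueError("bulk_concentration must be >= 0")
        if self.window[1] == self.window[0]:
            raise ValueError("vertex potential must differ from start potential")
        if self.charge == 0:
            raise ValueError("charge must be nonzero")
        if self.n_space < 10 or self.n_time < 10:
            raise ValueError("grid too coarse: need n_space, n_time >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.T <= 0:
            raise ValueError("temperature must be positive")


def _sweep_potentials(start: float, vertex: float, v: float, n_time: int):
    """Triangular potential program sampled at n_time+1 instants."""
    span = abs(vertex - start)
    t_total = 2.0 * span / v
    dt = t_total / n_time
    n_half = n_time // 2
    t = np.arange(n_time + 1) * dt
    sgn = 1.0 if vertex > start else -1.0
    E = np.empty(n_time + 1)
    E[: n_half + 1] = start + sgn * v * t[: n_half + 1]
    E[n_half + 1 :] = vertex - sgn * v * (t[n_half + 1 :] - t[n_half])
    return E, dt, n_half


def simulate_cv_reversible(cfg: SimulationConfig) -> Voltammogram:
    """Simulate a reversible-transfer cyclic voltammogram.

    Model: one ionic species diffusing in two semi-infinite phases coupled
    at a planar interface by the Nernst condition

        c2(0) / c1(0) = sqrt(D1/D2) * exp( zF (E - E_1/2) / RT ),

    solved with an explicit (FTCS) finite-difference scheme on uniform
    per-phase grids spanning six diffusion lengths.  Surface concentrations
    and the current use second-order one-sided gradients.  With zero noise
    the forward peak current reproduces the Randles-Sevcik closed form
    (coefficient 2.69e5 at 298 K) using the donor-phase D, and the
    forward/backward peak separation is the reversible ~57-59 mV for z=1.

    Raises
    ------
    GridError
        If the diffusion number D*dt/dx^2 exceeds the 0.5 stability limit
        of the explicit scheme.
    """
    start, vertex = cfg.window
    E, dt, n_half = _sweep_potentials(start, vertex, cfg.scan_rate, cfg.n_time)
    n_pts = E.size
    t_total = cfg.n_time * dt

    D1, D2 = cfg.D_phase1, cfg.D_phase2
    dx1 = 6.0 * np.sqrt(D1 * t_total) / cfg.n_space
    dx2 = 6.0 * np.sqrt(D2 * t_total) / cfg.n_space
    lam1 = D1 * dt / dx1**2
    lam2 = D2 * dt / dx2**2
    for lam, phase in ((lam1, "phase1"), (lam2, "phase2")):
        if lam > 0.5:
            raise GridError(
                f"explicit scheme unstable for {phase}: diffusion number "
                f"{lam:.3f} > 0.5 at n_space={cfg.n_space}, "
                f"n_time={cfg.n_time}; increase n_time or decrease n_space"
            )

    current = np.zeros(n_pts)
    C = cfg.bulk_concentration
    if C > 0:
        z, T = cfg.charge, cfg.T
        ratio0 = np.sqrt(D1 / D2)
        theta_all = ratio0 * np.exp(z * F / (R * T) * (E - cfg.half_wave_potential))
        a = np.full(cfg.n_space + 1, C)  # donor phase, index 0 = interface
        b = np.zeros(cfg.n_space + 1)  # acceptor phase
        c1 = D1 / (2.0 * dx1)
        c2 = D2 / (2.0 * dx2)
        # k = 0 is the initial rest state: equilibrate the surface only.
        for k in range(n_pts):
            if k > 0:
                a[1:-1] += lam1 * (a[2:] - 2.0 * a[1:-1] + a[:-2])
                b[1:-1] += lam2 * (b[2:] - 2.0 * b[1:-1] + b[:-2])
                a[-1] = C
                b[-1] = 0.0
            theta = theta_all[k]
            # Nernst + flux continuity with 3-point one-sided gradients:
            #   D1 (-3a0+4a1-a2)/(2dx1) = D2 (3b0-4b1+b2)/(2dx2),  b0 = theta*a0
            a0 = (c1 * (4.0 * a[1] - a[2]) + c2 * (4.0 * b[1] - b[2])) / (
                3.0 * c1 + 3.0 * theta * c2
            )
            a[0] = a0
            b[0] = theta * a0
            flux = c1 * (-3.0 * a[0] + 4.0 * a[1] - a[2])  # mol cm^-2 s^-1
            current[k] = z * F * cfg.area * flux * 1e6  # uA

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        current = current + rng.normal(0.0, cfg.noise_sd, size=n_pts)

    segments = np.where(np.arange(n_pts) <= n_half, "forward", "backward")
    metadata = {
        "analyte": "synthetic",
        "half_wave_V": cfg.half_wave_potential,
        "D_phase1_cm2_s": D1,
        "D_phase2_cm2_s": D2,
        "bulk_concentration_mol_cm3": C,
        "area_cm2": cfg.area,
        "charge": cfg.charge,
        "T_K": cfg.T,
        "noise_sd_uA": cfg.noise_sd,
        "seed": cfg.seed,
    }
    return Voltammogram(
        potential=E,
        current=current,
        scan_rate=cfg.scan_rate,
        technique=cfg.technique,
        segments=segments,
        axis="galvani",
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Square-wave voltammetry surrogate
# ---------------------------------------------------------------------------


def generate_swv_trace(
    peak_potential: float,
    peak_height: float,
    half_width: float,
    baseline=(),
    frequency: float = DEFAULT_SWV_WAVEFORM["frequency_Hz"],
    amplitude: float = DEFAULT_SWV_WAVEFORM["amplitude_V"],
    step: float = DEFAULT_SWV_WAVEFORM["step_V"],
    noise_sd: float = 0.0,
    seed: int = 0,
    window: tuple[float, float] | None = None,
) -> Voltammogram:
    """Synthetic net-current square-wave voltammogram.

    The peak is a sech^2 bell of height ``peak_height`` and half-width at
    half-maximum ``half_width`` sitting on a polynomial baseline
    (``baseline`` holds coefficients, highest power first, evaluated in
    volts -> uA).  The potential grid is anchored so that
    ``peak_potential`` falls exactly on a grid point sampled every ``step``
    volts; the default window spans +-6 half-widths.  A window narrower
    than 4 half-widths sets ``metadata['window_warning']``.

    The waveform settings (default: f = 60 Hz, amplitude 90 mV, step
    12 mV — the optimized preset of the study) are stored as metadata; the
    trace's scan_rate is the effective staircase rate step*frequency.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    if window is None:
        window = (peak_potential - 6.0 * half_width, peak_potential + 6.0 * half_width)
    lo, hi = window
    if hi <= lo:
        raise ValueError("window upper bound must exceed lower bound")
    k_lo = int(np.ceil((lo - peak_potential) / step - 1e-12))
    k_hi = int(np.floor((hi - peak_potential) / step + 1e-12))
    if k_hi - k_lo + 1 < 2:
        raise ValueError("window too narrow for the requested step")
    E = peak_potential + step * np.arange(k_lo, k_hi + 1)

    k_half = np.arccosh(np.sqrt(2.0))  # sech^2(k_half) = 1/2
    current = peak_height / np.cosh(k_half * (E - peak_potential) / half_width) ** 2
    if len(tuple(np.atleast_1d(baseline))):
        current = current + np.polyval(np.atleast_1d(baseline), E)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=E.size)

    metadata = {
        "analyte": "synthetic",
        "frequency_Hz": frequency,
        "amplitude_V": amplitude,
        "step_V": step,
        "true_peak_potential_V": peak_potential,
        "true_peak_height_uA": peak_height,
        "noise_sd_uA": noise_sd,
        "seed": seed,
    }
    if hi - lo < 4.0 * half_width:
        metadata["window_warning"] = True
    return Voltammogram(
        potential=E,
        current=current,
        scan_rate=step * frequency,
        technique="SWV",
        segments=np.full(E.size, "forward"),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Calibration, partition, matrix and interference series
# ---------------------------------------------------------------------------


def generate_calibration_series(
    concentrations,
    sensitivity: float,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], dict]:
    """Linear calibration series: I = sensitivity*C + intercept + noise.

    ``sensitivity`` is in A M^-1, numerically identical to uA/uM, so with
    concentrations in uM the currents come out in uA.  Returns the
    ``(concentration, peak_current)`` pairs and the ground-truth dict.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size < 2:
        raise ValueError("need at least 2 concentration levels")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else 0.0
    currents = sensitivity * conc + intercept + noise
    truth = {
        "sensitivity_A_per_M": sensitivity,
        "intercept_uA": intercept,
        "noise_sd_uA": noise_sd,
        "seed": seed,
    }
    return list(zip(conc.tolist(), np.asarray(currents, dtype=float).tolist())), truth


def generate_partition_data(
    phi0: float,
    pKa: float,
    K_D: float,
    pH_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], dict]:
    """Half-wave potentials on a pH grid from the partition-diagram model,
    plus mV-scale Gaussian noise.  Returns data and ground truth."""
    pH = np.asarray(list(pH_grid), dtype=float)
    if np.any(pH < 0) or np.any(pH > 14):
        raise ValueError("pH grid must lie within [0, 14]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    model = PartitionModel(phi0=phi0, pKa=pKa, K_D=K_D)  # validates K_D > 0
    phi = partition_halfwave(pH, model)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, noise_sd, size=pH.size)
    truth = {
        "phi0_V": phi0,
        "pKa": pKa,
        "K_D": K_D,
        "noise_sd_V": noise_sd,
        "seed": seed,
    }
    return list(zip(pH.tolist(), np.asarray(phi, dtype=float).tolist())), truth


@dataclass
class MatrixSeries:
    """A standard-addition dataset in a complex (milk-like) matrix."""

    additions: np.ndarray  # uM
    signals: np.ndarray  # uA
    blank: Voltammogram
    truth: dict = field(default_factory=dict)


def generate_matrix_series(
    true_concentration: float,
    additions,
    sensitivity: float,
    suppression_factor: float = 1.0,
    baseline_drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MatrixSeries:
    """Standard-addition series in a matrix surrogate.

    The matrix suppresses the sensitivity by ``suppression_factor`` (in
    (0, 1]) and contributes a linearly drifting blank baseline
    (``baseline_drift`` in uA per volt).  Signals follow

        I_k = suppression * sensitivity * (C_true + addition_k) + noise.

    Because the matrix scales signal and additions alike, standard-addition
    extrapolation recovers ``true_concentration`` regardless of the
    suppression.
    """
    add = np.asarray(list(additions), dtype=float)
    if np.any(add < 0):
        raise ValueError("additions must be non-negative")
    if np.any(np.diff(add) <= 0):
        raise ValueError("additions must be strictly increasing")
    if not (0.0 < suppression_factor <= 1.0):
        raise ValueError(
            f"suppression_factor must lie in (0, 1], got {suppression_factor}"
        )
    if true_concentration < 0:
        raise ValueError("true_concentration must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=add.size) if noise_sd > 0 else 0.0
    signals = suppression_factor * sensitivity * (true_concentration + add) + noise

    E = np.linspace(-0.2, 0.6, 201)
    blank_current = baseline_drift * (E - E[0])
    blank = Voltammogram(
        potential=E,
        current=blank_current,
        scan_rate=DEFAULT_SWV_WAVEFORM["step_V"] * DEFAULT_SWV_WAVEFORM["frequency_Hz"],
        technique="SWV",
        segments=np.full(E.size, "forward"),
        metadata={"analyte": "blank", "baseline_drift_uA_per_V": baseline_drift},
    )
    truth = {
        "true_concentration_uM": true_concentration,
        "sensitivity_A_per_M": sensitivity,
        "suppression_factor": suppression_factor,
        "baseline_drift_uA_per_V": baseline_drift,
        "noise_sd_uA": noise_sd,
        "seed": seed,
    }
    return MatrixSeries(
        additions=add, signals=np.asarray(signals, dtype=float), blank=blank,
        truth=truth,
    )


def generate_interference_series(
    reference_signal: float,
    effect_fractions,
    concentrations=INTERFERENT_LEVELS_UM,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Signals in the presence of an interfering agent at graded levels.

    ``signal_k = reference * (1 + effect_fraction_k)``; the labels follow
    the four-level concentration scheme of the selectivity screen.  The
    generator is deterministic; ``seed`` is accepted for API uniformity.
    """
    if reference_signal <= 0:
        raise ValueError("reference_signal must be > 0")
    eff = np.asarray(list(effect_fractions), dtype=float)
    labels = np.asarray(list(concentrations), dtype=float)
    if eff.size != labels.size:
        raise ValueError(
            f"{eff.size} effect fractions vs {labels.size} concentration levels"
        )
    signals = reference_signal * (1.0 + eff)
    return list(zip(labels.tolist(), signals.tolist()))


# ---------------------------------------------------------------------------
# Tidy-CSV + truth sidecar helpers
# ---------------------------------------------------------------------------


def write_xy_csv(rows, path: str | Path, columns: tuple[str, str]) -> Path:
    """Write (x, y) pairs as a two-column tidy CSV."""
    path = Path(path)
    lines = [",".join(columns)]
    for x, y in rows:
        lines.append(f"{x:.17g},{y:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_truth(truth: dict, path: str | Path) -> Path:
    """Write a ground-truth sidecar JSON next to a generated dataset."""
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", "utf-8")
    return path
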