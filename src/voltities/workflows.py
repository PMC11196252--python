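"""Pipeline orchestration: configuration, logging and the four workflows.

Workflows
---------
``synth``
    Generate a complete synthetic study bundle (partition data,
    calibration series, a simulated cyclic voltammogram, a milk-surrogate
    standard-addition set) with ground truth sidecars.
``ities``
    Ion-transfer analysis: fit the ionic partition diagram (K_D, phi0),
    derive logP and the Gibbs energy of transfer, and validate the
    forward/backward calibrations.
``gce``
    Solid-electrode analysis: square-wave calibration statistics plus the
    scan-rate regime diagnostic.
``milk``
    Real-sample quantification: optional blank subtraction on a trace
    pair, then standard-addition extrapolation.

Every run writes ``report.json`` (deterministic, byte-identical for a
fixed config and seed), display CSVs, and a timestamped ``run.log``
recording the package version, seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import linear_calibration, standard_addition
from .core import PHI_REF_TPRA, T_DEFAULT, VoltammetryError, read_voltammogram, write_voltammogram
from .peaks import ScanRateStudy, find_peak, scan_rate_diagnostic, subtract_blank
from .physchem import (
    PKA1_DANO,
    PKA2_DANO,
    PhysChemConstants,
    fit_partition_model,
    speciation_fractions,
)
from .report import make_report
from .synth import (
    ITIES_CALIBRATION_LEVELS_UM,
    GCE_CALIBRATION_LEVELS_UM,
    MILK_ITIES_ADDITIONS_UM,
    SimulationConfig,
    generate_calibration_series,
    generate_matrix_series,
    generate_partition_data,
    simulate_cv_reversible,
    write_truth,
    write_xy_csv,
)

__all__ = ["PipelineConfig", "PipelineConfigError", "run_workflow"]

WORKFLOWS = ("synth", "ities", "gce", "milk")

logger = logging.getLogger("voltities")


class PipelineConfigError(VoltammetryError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``inputs`` maps role names (``partition``, ``calibration_forward``,
    ``calibration_backward``, ``scan_rate_study``, ``standard_additions``,
    ``sample_trace``, ``blank_trace``) to file paths; paths in a YAML
    config are resolved relative to the config file.
    """

    workflow: str
    outdir: Path
    inputs: dict = field(default_factory=dict)
    electrode_area: float | None = None  # cm^2
    pKa1: float = PKA1_DANO
    pKa2: float = PKA2_DANO
    temperature: float = T_DEFAULT
    reference_potential: float = PHI_REF_TPRA  # TPrA+ axis anchor, V
    seed: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise PipelineConfigError(
                f"workflow must be one of {WORKFLOWS}, got {self.workflow!r}"
            )
        self.outdir = Path(self.outdir)
        self.inputs = {k: Path(v) for k, v in self.inputs.items()}
        if self.electrode_area is not None and self.electrode_area <= 0:
            raise PipelineConfigError("electrode_area must be > 0 cm^2")
        if self.pKa1 >= self.pKa2:
            raise PipelineConfigError("pKa1 must be < pKa2")
        if self.temperature <= 0:
            raise PipelineConfigError("temperature must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise PipelineConfigError(f"{path}: invalid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise PipelineConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        base = path.parent
        inputs = {k: base / v for k, v in (raw.get("inputs") or {}).items()}
        raw = {**raw, "inputs": inputs}
        if "outdir" in raw:
            raw["outdir"] = base / raw["outdir"]
        else:
            raise PipelineConfigError(f"{path}: 'outdir' is required")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is
        excluded: it cannot affect results)."""
        payload = dataclasses.asdict(self)
        del payload["outdir"]
        payload["inputs"] = {k: str(v) for k, v in payload["inputs"].items()}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require_inputs(config: PipelineConfig, *roles: str) -> dict[str, Path]:
    found = {}
    for role in roles:
        path = config.inputs.get(role)
        if path is None:
            raise PipelineConfigError(
                f"workflow {config.workflow!r} requires input {role!r}"
            )
        if not path.exists():
            raise FileNotFoundError(f"input {role!r} not found: {path}")
        found[role] = path
    return found


def _read_xy(path: Path, xcol: str, ycol: str) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path, comment="#")
    for col in (xcol, ycol):
        if col not in frame.columns:
            raise VoltammetryError(f"{path}: missing column {col!r}")
    return frame[xcol].to_numpy(float), frame[ycol].to_numpy(float)


# ---------------------------------------------------------------------------
# Workflow bodies
# ---------------------------------------------------------------------------


def _run_synth(config: PipelineConfig, outdir: Path) -> dict:
    opts = config.options
    seed = config.seed
    truth_all: dict = {}

    partition, truth = generate_partition_data(
        phi0=opts.get("phi0", 0.123),
        pKa=config.pKa2,
        K_D=opts.get("K_D", 600.0),
        pH_grid=np.arange(2.0, 12.0 + 1e-9, 0.5),
        noise_sd=opts.get("partition_noise_sd_V", 0.002),
        seed=seed,
    )
    write_xy_csv(partition, outdir / "partition.csv", ("pH", "half_wave_V"))
    truth_all["partition"] = truth

    for label, sens, noise, sub in (
        ("calibration_forward", 0.1022, 0.07, 1),
        ("calibration_backward", -0.1168, 0.08, 2),
        ("calibration_gce", 0.0300, 0.10, 3),
    ):
        levels = (
            GCE_CALIBRATION_LEVELS_UM if label.endswith("gce")
            else ITIES_CALIBRATION_LEVELS_UM
        )
        series, truth = generate_calibration_series(
            levels, sensitivity=sens, noise_sd=noise, seed=seed * 10 + sub
        )
        write_xy_csv(series, outdir / f"{label}.csv", ("concentration_uM", "current_uA"))
        truth_all[label] = truth

    cv = simulate_cv_reversible(
        SimulationConfig(area=opts.get("area", 1.331), seed=seed)
    )
    write_voltammogram(cv, outdir / "cv_trace.csv")
    truth_all["cv_trace"] = {
        k: cv.metadata[k]
        for k in ("half_wave_V", "D_phase1_cm2_s", "bulk_concentration_mol_cm3")
    }

    matrix = generate_matrix_series(
        true_concentration=opts.get("milk_true_uM", 30.0),
        additions=MILK_ITIES_ADDITIONS_UM,
        sensitivity=0.1022,
        suppression_factor=opts.get("suppression", 0.7),
        baseline_drift=opts.get("baseline_drift", 2.0),
        noise_sd=opts.get("milk_noise_sd_uA", 0.05),
        seed=seed * 10 + 4,
    )
    write_xy_csv(
        zip(matrix.additions, matrix.signals),
        outdir / "standard_additions.csv",
        ("addition_uM", "current_uA"),
    )
    write_voltammogram(matrix.blank, outdir / "blank_trace.csv")
    truth_all["standard_additions"] = matrix.truth

    write_truth(truth_all, outdir / "truth.json")
    files = sorted(p.name for p in outdir.iterdir() if p.suffix == ".csv")
    return {"generated_files": files, "truth": truth_all}


def _run_ities(config: PipelineConfig, outdir: Path) -> dict:
    paths = _require_inputs(config, "partition", "calibration_forward")
    logger.info("fitting ionic partition diagram from %s", paths["partition"])
    pH, phi = _read_xy(paths["partition"], "pH", "half_wave_V")
    model, diag = fit_partition_model(
        zip(pH, phi), pKa=config.pKa2, fit_phi0=True, T=config.temperature
    )
    constants = PhysChemConstants.from_phi(
        model.phi0, z=model.z, T=config.temperature, K_D=model.K_D
    )

    calibrations = {}
    for role in ("calibration_forward", "calibration_backward"):
        path = config.inputs.get(role)
        if path is None:
            continue
        conc, cur = _read_xy(path, "concentration_uM", "current_uA")
        calibrations[role.removeprefix("calibration_")] = linear_calibration(
            conc, cur, area=config.electrode_area
        )
        logger.info("calibrated %s: %d levels", role, conc.size)

    spec = speciation_fractions(
        np.arange(0.0, 14.0 + 1e-9, 0.05), config.pKa1, config.pKa2
    )
    extra = {
        "partition_fit": diag,
        "phi0_V": model.phi0,
        "speciation": {
            "pKa1": config.pKa1,
            "pKa2": config.pKa2,
            "neutral_fraction_argmax_pH": float(spec.pH[np.argmax(spec.f_neutral)]),
        },
    }
    make_report(
        {"calibrations": calibrations, "constants": constants, "extra": extra},
        outdir,
    )
    return {
        **extra,
        "K_D": model.K_D,
        "constants": constants.as_dict(),
        "calibrations": {k: v.as_dict() for k, v in calibrations.items()},
    }


def _run_gce(config: PipelineConfig, outdir: Path) -> dict:
    paths = _require_inputs(config, "calibration")
    conc, cur = _read_xy(paths["calibration"], "concentration_uM", "current_uA")
    cal = linear_calibration(conc, cur, area=config.electrode_area)
    result: dict = {"calibrations": {"gce": cal.as_dict()}}

    srs_path = config.inputs.get("scan_rate_study")
    if srs_path is not None:
        v, ip = _read_xy(srs_path, "scan_rate_Vs", "Ip_uA")
        study = ScanRateStudy(scan_rates=v, peak_currents=ip)
        slope, regime = scan_rate_diagnostic(study)
        result["scan_rate_diagnostic"] = {"loglog_slope": slope, "regime": regime}
        logger.info("scan-rate diagnostic: slope %.3f -> %s", slope, regime)

    make_report(
        {"calibrations": {"gce": cal}, "extra": {k: v for k, v in result.items()
                                                 if k != "calibrations"}},
        outdir,
    )
    return result


def _run_milk(config: PipelineConfig, outdir: Path) -> dict:
    paths = _require_inputs(config, "standard_additions")
    result: dict = {}

    sample_path = config.inputs.get("sample_trace")
    blank_path = config.inputs.get("blank_trace")
    if sample_path is not None and blank_path is not None:
        sample = read_voltammogram(sample_path)
        blank = read_voltammogram(blank_path)
        corrected = subtract_blank(sample, blank)
        write_voltammogram(corrected, outdir / "blank_subtracted_trace.csv")
        peak = find_peak(corrected, segment="forward", baseline="linear")
        result["blank_subtracted_peak"] = {
            "peak_potential_V": peak.peak_potential,
            "peak_current_uA": peak.peak_current,
        }
        logger.info("blank-subtracted peak: %.3f V, %.3f uA",
                    peak.peak_potential, peak.peak_current)

    add, sig = _read_xy(paths["standard_additions"], "addition_uM", "current_uA")
    sa = standard_addition(sig, add)
    result["standard_addition"] = {
        "concentration_uM": sa.concentration,
        "se_uM": sa.se,
        "slope_A_per_M": sa.slope,
        "r2": sa.r2,
    }
    make_report({"extra": result}, outdir)
    return result


_BODIES = {"synth": _run_synth, "ities": _run_ities, "gce": _run_gce, "milk": _run_milk}


def run_workflow(config: PipelineConfig) -> dict:
    """Execute a workflow end to end and write its report bundle.

    Stages run in the fixed order read -> (axis-calibrate) ->
    blank-subtract -> peak/fit analysis -> report.  Any stage failure is
    re-raised annotated with the workflow and stage.  The report JSON is a
    pure function of (config, seed): re-running the same configuration
    reproduces it byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.perf_counter()
    try:
        logger.info(
            "voltities %s | workflow=%s seed=%d config_hash=%s",
            __version__, config.workflow, config.seed, config.config_hash(),
        )
        try:
            body = _BODIES[config.workflow]
            result = body(config, outdir)
        except (PipelineConfigError, FileNotFoundError):
            raise
        except Exception as exc:
            raise VoltammetryError(
                f"workflow {config.workflow!r} failed: {exc}"
            ) from exc
        report = {
            "workflow": config.workflow,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
            "results": result,
        }
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8",
        )
        logger.info("workflow finished in %.2f s", time.perf_counter() - t0)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
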