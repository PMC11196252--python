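"""Core domain types, physical constants, voltammogram I/O and potential-axis calibration.

Unit conventions (package-wide)
-------------------------------
* potentials in volts (V)
* currents in microamperes (uA)
* concentrations in micromolar (uM) at the user-facing surface; mol cm^-3
  internally for the Randles-Sevcik analysis
* electrode / interface areas in cm^2
* temperatures in kelvin

Sign convention: positive current corresponds to cation transfer from the
aqueous to the organic phase (at an electrified liquid-liquid interface) or
to oxidation (at a solid electrode); the return/backward process gives
negative current.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "R",
    "F",
    "T_DEFAULT",
    "PHI_REF_TPRA",
    "RANDLES_SEVCIK_COEFF",
    "GCE_AREA_CM2",
    "TECHNIQUES",
    "SEGMENT_LABELS",
    "VoltammetryError",
    "FormatError",
    "TraceParseError",
    "AxisStateError",
    "NoPeakError",
    "GridError",
    "Voltammogram",
    "read_voltammogram",
    "write_voltammogram",
    "calibrate_potential_axis",
    "nernst_slope",
]

# ---------------------------------------------------------------------------
# Physical constants (read-only module attributes)
# ---------------------------------------------------------------------------

#: molar gas constant, J mol^-1 K^-1
R: float = 8.314
#: Faraday constant, C mol^-1
F: float = 96485.0
#: default temperature, K
T_DEFAULT: float = 298.0
#: standard Galvani transfer potential of the tetrapropylammonium cation
#: (TPrA+), used as the internal reference for ITIES potential-axis
#: calibration, V
PHI_REF_TPRA: float = -0.091
#: Randles-Sevcik coefficient at 298 K in the
#: A mol^-1 cm^3 (V/s)^-1/2 cm^-2 convention:
#: Ip = 2.69e5 * z^(3/2) * A * C * sqrt(D * v)
RANDLES_SEVCIK_COEFF: float = 2.69e5
#: geometric area of a 3 mm diameter glassy carbon disc electrode, cm^2
GCE_AREA_CM2: float = 0.071

TECHNIQUES = ("CV", "SWV", "ITV")
SEGMENT_LABELS = ("forward", "backward")


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------


class VoltammetryError(Exception):
    """Base class for errors raised by this package."""


class FormatError(VoltammetryError):
    """A file does not conform to the voltammogram CSV contract."""


class TraceParseError(FormatError):
    """A row of a voltammogram CSV could not be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class AxisStateError(VoltammetryError):
    """Operation incompatible with the trace's potential-axis state."""


class NoPeakError(VoltammetryError):
    """No interior extremum exists in the requested region."""


class GridError(VoltammetryError):
    """Finite-difference grid violates the explicit-scheme stability bound."""


# ---------------------------------------------------------------------------
# Voltammogram container
# ---------------------------------------------------------------------------


@dataclass
class Voltammogram:
    """A single voltammetric trace.

    Parameters
    ----------
    potential
        Applied potential in volts, ordered as scanned.
    current
        Measured current in microamperes, one value per potential.
    scan_rate
        Potential sweep rate in V s^-1 (for SWV: step potential times
        frequency, the effective staircase rate).
    technique
        One of ``"CV"``, ``"SWV"``, ``"ITV"``.  ITV (ion-transfer
        voltammetry) is cyclic voltammetry recorded at an electrified
        liquid-liquid interface.
    segments
        Per-point label, ``"forward"`` or ``"backward"``.  A CV/ITV trace
        consists of exactly one forward block followed by one backward
        block; an SWV trace is forward-only.
    axis
        ``"raw"`` for an instrument potential axis, ``"galvani"`` once the
        axis has been calibrated to the Galvani potential-difference scale
        (see :func:`calibrate_potential_axis`).
    metadata
        Free key-value annotations (analyte, pH, concentration_uM, ...).
    """

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    technique: str
    segments: np.ndarray
    axis: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.segments = np.asarray(self.segments, dtype="U8")
        if self.potential.ndim != 1 or self.current.ndim != 1:
            raise ValueError("potential and current must be 1-D arrays")
        n = self.potential.size
        if n < 2:
            raise ValueError("a voltammogram needs at least 2 points")
        if self.current.size != n or self.segments.size != n:
            raise ValueError(
                f"length mismatch: potential has {n} points, current "
                f"{self.current.size}, segments {self.segments.size}"
            )
        if not np.isfinite(self.scan_rate) or self.scan_rate <= 0:
            raise ValueError(f"scan_rate must be > 0, got {self.scan_rate}")
        if self.technique not in TECHNIQUES:
            raise ValueError(
                f"technique must be one of {TECHNIQUES}, got {self.technique!r}"
            )
        if self.axis not in ("raw", "galvani"):
            raise ValueError(f"axis must be 'raw' or 'galvani', got {self.axis!r}")
        bad = set(np.unique(self.segments)) - set(SEGMENT_LABELS)
        if bad:
            raise ValueError(f"unknown segment labels: {sorted(bad)}")
        transitions = int(np.count_nonzero(self.segments[1:] != self.segments[:-1]))
        if self.technique in ("CV", "ITV"):
            if (
                transitions != 1
                or self.segments[0] != "forward"
                or self.segments[-1] != "backward"
            ):
                raise ValueError(
                    "a CV/ITV trace must contain exactly one forward segment "
                    "followed by one backward segment"
                )
        else:  # SWV
            if transitions != 0 or self.segments[0] != "forward":
                raise ValueError("an SWV trace must be forward-only")

    def __len__(self) -> int:
        return int(self.potential.size)

    def has_segment(self, name: str) -> bool:
        return bool(np.any(self.segments == name))

    def segment(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(potential, current)`` of one segment, in scan order."""
        if name not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment {name!r}")
        mask = self.segments == name
        if not np.any(mask):
            raise ValueError(f"trace has no {name!r} segment")
        return self.potential[mask], self.current[mask]

    def replace(self, **changes) -> "Voltammogram":
        """Return a copy with the given fields replaced (validates again)."""
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: comma-separated, '.' decimal, one trace per file.  A commented
# metadata block ('# key: value' lines) precedes the header row
# 'potential_V,current_uA,segment'.  The keys technique, scan_rate_Vs and
# axis are reserved; every other key lands in Voltammogram.metadata.
# ---------------------------------------------------------------------------

_RESERVED_KEYS = ("technique", "scan_rate_Vs", "axis")
_REQUIRED_COLUMNS = ("potential_V", "current_uA", "segment")


def _coerce_value(text: str):
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def read_voltammogram(path: str | Path) -> Voltammogram:
    """Read a voltammogram from its CSV representation.

    Raises
    ------
    FormatError
        If the header or required columns are missing or malformed.
    TraceParseError
        If a data row is non-numeric; the error carries the line number.
    """
    path = Path(path)
    meta: dict = {}
    n_comment = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line.lstrip("#").strip()
            if not body:
                continue
            if ":" not in body:
                raise FormatError(
                    f"{path}: malformed metadata line {n_comment}: {body!r}"
                )
            key, _, value = body.partition(":")
            meta[key.strip()] = _coerce_value(value.strip())

    try:
        frame = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas-level failure
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc

    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    numeric = {}
    for col in ("potential_V", "current_uA"):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # file line = metadata block + header row + data rows before it
            raise TraceParseError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} in "
                f"column {col}",
                line_number=n_comment + 1 + row + 1,
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise TraceParseError(
                f"{path}: empty value in column {col}",
                line_number=n_comment + 1 + row + 1,
            )
        numeric[col] = converted.to_numpy(dtype=float)

    technique = str(meta.pop("technique", "CV"))
    scan_rate = meta.pop("scan_rate_Vs", None)
    if scan_rate is None:
        raise FormatError(f"{path}: metadata key 'scan_rate_Vs' is required")
    axis = str(meta.pop("axis", "raw"))

    try:
        return Voltammogram(
            potential=numeric["potential_V"],
            current=numeric["current_uA"],
            scan_rate=float(scan_rate),
            technique=technique,
            segments=frame["segment"].str.strip().to_numpy(),
            axis=axis,
            metadata=meta,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_voltammogram(vg: Voltammogram, path: str | Path) -> Path:
    """Write a voltammogram as CSV readable by :func:`read_voltammogram`.

    Numeric fields survive a write/read round trip to better than 1e-9
    relative (floats are serialized with 17 significant digits).
    """
    path = Path(path)
    lines = [
        f"# technique: {vg.technique}",
        f"# scan_rate_Vs: {vg.scan_rate!r}",
        f"# axis: {vg.axis}",
    ]
    for key, value in vg.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append("potential_V,current_uA,segment")
    for e, i, s in zip(vg.potential, vg.current, vg.segments):
        lines.append(f"{e:.17g},{i:.17g},{s}")
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write voltammogram to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Potential-axis calibration and the Nernstian slope
# ---------------------------------------------------------------------------


def calibrate_potential_axis(
    vg: Voltammogram,
    measured_ref_halfwave: float,
    reference_value: float = PHI_REF_TPRA,
) -> Voltammogram:
    """Shift a raw potential axis onto the Galvani potential-difference scale.

    The half-wave potential of an internal reference ion (by default TPrA+,
    whose standard transfer potential is -0.091 V) measured on the raw axis
    anchors the shift: every potential moves by
    ``reference_value - measured_ref_halfwave``.  Currents are untouched, so
    peak separations and peak heights are exactly invariant.

    Raises
    ------
    AxisStateError
        If the trace is already on the Galvani axis.
    """
    if vg.axis == "galvani":
        raise AxisStateError("trace is already on the galvani axis")
    shift = reference_value - measured_ref_halfwave
    meta = dict(vg.metadata)
    meta["axis_shift_V"] = shift
    return vg.replace(potential=vg.potential + shift, axis="galvani", metadata=meta)


def nernst_slope(T: float = T_DEFAULT, z: int = 1) -> float:
    """Nernstian slope 2.303*R*T/(|z|*F) in volts (59 mV per unit charge
    at 298 K)."""
    if T <= 0:
        raise ValueError(f"temperature must be > 0 K, got {T}")
    if z == 0:
        raise ValueError("charge z must be nonzero")
    return np.log(10.0) * R * T / (abs(z) * F)
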