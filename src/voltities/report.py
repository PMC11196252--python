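"""Report generation: comparison tables for calibrations, physicochemical
constants and interference screens.

The calibration comparison mirrors the layout of a standard
electroanalytical validation table (linear range, slope, normalized slope,
standard errors, R^2, LOD, LOQ, one column per electrode configuration);
constants and selectivity sheets mirror the usual supplementary-table
shapes.  Stored JSON keeps full precision; rounding happens only in the
display CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .calibration import CalibrationResult, InterferenceRecord
from .physchem import PhysChemConstants

__all__ = ["make_report"]

_CAL_ROWS = [
    ("Linear concentration range [uM]", lambda c: f"{c.ldr[0]:g}-{c.ldr[1]:g}"),
    ("Slope (a) (A/M)", lambda c: round(c.slope, 4)),
    ("Normalized slope (A/M/cm2)", lambda c: None
     if c.normalized_slope is None else round(c.normalized_slope, 4)),
    ("Standard error of slope (SE_a) (A/M)", lambda c: round(c.se_slope, 4)),
    ("Intercept (b) (uA)", lambda c: round(c.intercept, 4)),
    ("Standard error of intercept (SE_b) (uA)", lambda c: round(c.se_intercept, 4)),
    ("Coefficient of determination (R2)", lambda c: round(c.r2, 4)),
    ("LOD (uM)", lambda c: round(c.lod, 2)),
    ("LOQ (uM)", lambda c: round(c.loq, 2)),
    ("Number of points", lambda c: c.n_points),
]


def make_report(results: dict, outdir: str | Path) -> dict[str, Path]:
    """Emit CSV + JSON reports for a collection of results.

    Parameters
    ----------
    results
        Mapping with any of the keys:

        * ``"calibrations"``: dict of label -> :class:`CalibrationResult`
        * ``"constants"``: :class:`PhysChemConstants`
        * ``"interference"``: list of :class:`InterferenceRecord`
        * ``"extra"``: free-form JSON-serializable dict merged into the
          stored report

    Returns a dict of the files written.  An empty collection is an error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calibrations = results.get("calibrations") or {}
    constants = results.get("constants")
    interference = results.get("interference") or []
    extra = results.get("extra") or {}
    if not calibrations and constants is None and not interference and not extra:
        raise ValueError("nothing to report: results collection is empty")

    written: dict[str, Path] = {}
    stored: dict = dict(extra)

    if calibrations:
        table = pd.DataFrame(
            {
                label: [fn(cal) for _, fn in _CAL_ROWS]
                for label, cal in calibrations.items()
            },
            index=[name for name, _ in _CAL_ROWS],
        )
        table.index.name = "Parameter"
        path = outdir / "calibration_table.csv"
        table.to_csv(path)
        written["calibration_table"] = path
        stored["calibrations"] = {
            label: cal.as_dict() for label, cal in calibrations.items()
        }

    if constants is not None:
        frame = pd.Series(constants.as_dict(), name="value").rename_axis("constant")
        path = outdir / "physchem_constants.csv"
        frame.to_csv(path)
        written["physchem_constants"] = path
        stored["constants"] = constants.as_dict()

    if interference:
        frame = pd.DataFrame(
            [
                {
                    "interferent": r.interferent,
                    "concentration_uM": r.concentration,
                    "signal_change_pct": round(r.signal_change, 2),
                    "selective": r.selective,
                }
                for r in interference
            ]
        )
        matrix = frame.pivot_table(
            index="interferent",
            columns="concentration_uM",
            values="signal_change_pct",
            aggfunc="first",
        )
        path = outdir / "selectivity_table.csv"
        matrix.to_csv(path)
        written["selectivity_table"] = path
        stored["interference"] = frame.to_dict(orient="records")

    json_path = outdir / "report.json"
    json_path.write_text(
        json.dumps(stored, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    written["report_json"] = json_path
    return written
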