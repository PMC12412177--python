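"""Reading and writing ATD workbooks, calibrant lists, curves and results.

Two trace layouts are supported:

* **canonical** XLSX: one sheet per (analyte, separation time) named
  ``<analyte>__ts<t_s>`` with two header columns ``drift_time_ms`` and
  ``intensity``; an optional ``_meta`` sheet (columns ``analyte``, ``mz``,
  ``charge``) attaches ion identities.
* **long** CSV: columns ``analyte, separation_time_ms, drift_time_ms,
  intensity`` plus optional ``mz`` and ``charge``.

Calibration curves persist as a versioned JSON document; results are
written as CSV or XLSX with deterministic (input-order) rows.
"""

from __future__ import annotations

import datetime
import json
import math
import re
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import openpyxl
from openpyxl.utils import get_column_letter

from .calibration import CalibrationCurve
from .core import ATDTrace, CalibrantSpec, ResultRecord
from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "read_atd_workbook",
    "write_atd_workbook",
    "read_calibrant_list",
    "persist_curve",
    "load_curve",
    "write_results",
]

_SHEET_RE = re.compile(r"^(?P<analyte>.+)__ts(?P<ts>[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)$")
_META_SHEET = "_meta"
_CURVE_FORMAT = "cimscal.calibration-curve"
_CURVE_VERSION = 1

# Fixed document timestamp so identical inputs give byte-identical files.
_EPOCH = datetime.datetime(2000, 1, 1)


class _DeterministicZipFile(zipfile.ZipFile):
    """ZipFile that pins every entry's timestamp to the fixed epoch."""

    def writestr(self, zinfo_or_arcname, data, *args, **kwargs):
        if isinstance(zinfo_or_arcname, str):
            zinfo = zipfile.ZipInfo(
                zinfo_or_arcname, date_time=(2000, 1, 1, 0, 0, 0)
            )
            zinfo.compress_type = self.compression
            zinfo.external_attr = 0o600 << 16
        else:
            zinfo = zinfo_or_arcname
            zinfo.date_time = (2000, 1, 1, 0, 0, 0)
        super().writestr(zinfo, data, *args, **kwargs)

    def write(self, filename, arcname=None, *args, **kwargs):
        # route file-backed parts (worksheet temp files) through writestr
        # so they get the pinned timestamp instead of the file mtime
        with open(filename, "rb") as fh:
            self.writestr(arcname or str(filename), fh.read())


def _sheet_name(trace: ATDTrace) -> str:
    # repr() gives the shortest decimal string that round-trips the float
    name = f"{trace.analyte_id}__ts{trace.separation_time!r}"
    if len(name) > 31:
        raise ValidationError(
            f"sheet name '{name}' exceeds the 31-character XLSX limit; "
            "shorten the analyte id"
        )
    return name


def write_atd_workbook(traces: list[ATDTrace], path: str | Path) -> None:
    """Write traces in the canonical layout (or long CSV if path ends .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_long_csv(traces, path)
        return
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    meta_rows = {}
    for trace in traces:
        ws = wb.create_sheet(_sheet_name(trace))
        ws.append(["drift_time_ms", "intensity"])
        for t, y in zip(trace.times, trace.intensities):
            ws.append([float(t), float(y)])
        if trace.mz is not None:
            meta_rows[trace.analyte_id] = (trace.mz, trace.charge)
    if meta_rows:
        ws = wb.create_sheet(_META_SHEET)
        ws.append(["analyte", "mz", "charge"])
        for analyte, (mz, charge) in meta_rows.items():
            ws.append([analyte, float(mz), int(charge)])
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    # openpyxl's Workbook.save() stamps wall-clock times into the document
    # properties and zip entries, breaking byte-for-byte reproducibility;
    # drive the writer directly through a timestamp-pinning archive.
    from openpyxl.writer.excel import ExcelWriter

    with _DeterministicZipFile(
        path, "w", zipfile.ZIP_DEFLATED, allowZip64=True
    ) as archive:
        ExcelWriter(wb, archive).save()


def _write_long_csv(traces: list[ATDTrace], path: Path) -> None:
    frames = []
    for trace in traces:
        frames.append(
            pd.DataFrame(
                {
                    "analyte": trace.analyte_id,
                    "separation_time_ms": trace.separation_time,
                    "drift_time_ms": trace.times,
                    "intensity": trace.intensities,
                    "mz": np.nan if trace.mz is None else trace.mz,
                    "charge": trace.charge,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_atd_workbook(
    path: str | Path, dialect: str | None = None
) -> list[ATDTrace]:
    """Read traces from a canonical XLSX workbook or a long-format CSV.

    ``dialect`` may be "canonical", "long" or None (inferred from the file
    suffix).  Non-numeric cells raise :class:`ParseError` naming the cell;
    malformed sheets or headers raise :class:`FormatError` naming the sheet.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if dialect is None:
        dialect = "long" if path.suffix.lower() == ".csv" else "canonical"
    if dialect == "long":
        return _read_long_csv(path)
    if dialect == "canonical":
        return _read_canonical_xlsx(path)
    raise FormatError(f"unknown workbook dialect '{dialect}'")


def _read_canonical_xlsx(path: Path) -> list[ATDTrace]:
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    meta: dict[str, tuple[float, int]] = {}
    if _META_SHEET in wb.sheetnames:
        ws = wb[_META_SHEET]
        rows = ws.iter_rows(values_only=True)
        header = next(rows, None)
        if header is None or list(header[:3]) != ["analyte", "mz", "charge"]:
            raise FormatError(
                f"sheet '{_META_SHEET}': expected header analyte, mz, charge"
            )
        for row in rows:
            if row[0] is None:
                continue
            meta[str(row[0])] = (float(row[1]), int(row[2]))
    traces = []
    for name in wb.sheetnames:
        if name == _META_SHEET:
            continue
        m = _SHEET_RE.match(name)
        if m is None:
            raise FormatError(
                f"sheet '{name}' does not match the '<analyte>__ts<t_s>' layout"
            )
        analyte = m.group("analyte")
        ts = float(m.group("ts"))
        ws = wb[name]
        rows = ws.iter_rows(values_only=True)
        header = next(rows, None)
        if header is None or list(header[:2]) != ["drift_time_ms", "intensity"]:
            raise FormatError(
                f"sheet '{name}': expected header columns "
                "'drift_time_ms', 'intensity'"
            )
        times, intens = [], []
        for i, row in enumerate(rows, start=2):
            if row is None or (row[0] is None and (len(row) < 2 or row[1] is None)):
                continue
            for j, label in ((0, "drift_time_ms"), (1, "intensity")):
                value = row[j] if len(row) > j else None
                cell = f"{name}!{get_column_letter(j + 1)}{i}"
                if value is None:
                    raise ParseError(f"empty {label} cell at {cell}")
                if not isinstance(value, (int, float)):
                    raise ParseError(
                        f"non-numeric {label} value {value!r} at {cell}"
                    )
            times.append(float(row[0]))
            intens.append(float(row[1]))
        mz, charge = meta.get(analyte, (None, 1))
        traces.append(
            ATDTrace(
                analyte_id=analyte,
                separation_time=ts,
                times=np.array(times),
                intensities=np.array(intens),
                mz=mz,
                charge=charge,
            )
        )
    wb.close()
    return traces


def _read_long_csv(path: Path) -> list[ATDTrace]:
    df = pd.read_csv(path)
    required = {"analyte", "separation_time_ms", "drift_time_ms", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s) {', '.join(sorted(missing))}"
        )
    for col in ("separation_time_ms", "drift_time_ms", "intensity"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(
                f"{path.name}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column '{col}', row {row}"
            )
    traces = []
    for (analyte, ts), grp in df.groupby(
        ["analyte", "separation_time_ms"], sort=False
    ):
        grp = grp.sort_values("drift_time_ms")
        mz = None
        charge = 1
        if "mz" in grp.columns and not math.isnan(float(grp["mz"].iloc[0])):
            mz = float(grp["mz"].iloc[0])
        if "charge" in grp.columns:
            charge = int(grp["charge"].iloc[0])
        traces.append(
            ATDTrace(
                analyte_id=str(analyte),
                separation_time=float(ts),
                times=grp["drift_time_ms"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
                mz=mz,
                charge=charge,
            )
        )
    return traces


def read_calibrant_list(path: str | Path) -> list[CalibrantSpec]:
    """Read a comma-separated calibrant list (name, mz, charge, ccs[, adduct]).

    Rows are returned in file order; non-positive CCS values and duplicate
    names are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "ccs" not in df.columns and "ccs_ref" in df.columns:
        df = df.rename(columns={"ccs_ref": "ccs"})
    missing = {"name", "mz", "charge", "ccs"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(sorted(missing))}"
        )
    dupes = df["name"][df["name"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(
            f"{path.name}: duplicate calibrant name(s): {', '.join(map(str, dupes))}"
        )
    specs = []
    for _, row in df.iterrows():
        adduct = row.get("adduct")
        specs.append(
            CalibrantSpec(
                name=str(row["name"]),
                mz=float(row["mz"]),
                charge=int(row["charge"]),
                ccs_ref=float(row["ccs"]),
                adduct=None if adduct is None or pd.isna(adduct) else str(adduct),
            )
        )
    return specs


def persist_curve(curve: CalibrationCurve, path: str | Path) -> None:
    """Save a calibration curve as a versioned JSON document."""
    doc = {
        "format": _CURVE_FORMAT,
        "version": _CURVE_VERSION,
        "A": curve.A,
        "B": curve.B,
        "mode": curve.mode,
        "gas_mass": curve.gas_mass,
        "fit_r_squared": curve.fit_r_squared,
        "calibrant_table": list(curve.calibrant_table),
        "created_with": curve.created_with,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_curve(path: str | Path) -> CalibrationCurve:
    """Load a curve saved by :func:`persist_curve`.

    Raises :class:`FormatError` on truncated files or on a format/version
    tag this package does not understand.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: not a valid curve file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != _CURVE_FORMAT:
        raise FormatError(f"{path.name}: not a cimscal calibration-curve document")
    if doc.get("version") != _CURVE_VERSION:
        raise FormatError(
            f"{path.name}: unsupported curve version {doc.get('version')!r} "
            f"(this build reads version {_CURVE_VERSION})"
        )
    try:
        return CalibrationCurve(
            A=float(doc["A"]),
            B=float(doc["B"]),
            mode=str(doc["mode"]),
            gas_mass=float(doc["gas_mass"]),
            fit_r_squared=float(doc["fit_r_squared"]),
            calibrant_table=tuple(doc["calibrant_table"]),
            created_with=dict(doc.get("created_with", {})),
        )
    except KeyError as exc:
        raise FormatError(f"{path.name}: curve file missing field {exc}") from exc


def write_results(records: list[ResultRecord], path: str | Path) -> None:
    """Write result rows (input order preserved) as CSV or XLSX."""
    rows = []
    for r in records:
        row = {
            "analyte": r.analyte_id,
            "mode": r.mode,
            "ccs_measured": r.ccs_measured,
            "ccs_reference": r.ccs_reference,
            "percent_difference": r.percent_difference,
        }
        for key, value in r.diagnostics.items():
            row[key] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    if all(r.ccs_reference is None for r in records):
        df = df.drop(columns=["ccs_reference", "percent_difference"])
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
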