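"""Reader/writer for the ``generic_qhts`` tabular dialect (.csv / .xlsx).

Layout contract (two stacked header rows above the data):

    row 1:  Format, <tag>, ..., Log_Conc_M, conc_0, ..., conc_N
    row 2:  Fit_Output, Comp_ID, Readout, <annotations...>,
            Log_AC50_M, S_0, S_Inf, Hill_Slope, Data0, ..., DataN
    row 3+: one record per row

The ``Log_Conc_M`` tag in row 1 sits in the column immediately before
the response block; each response column carries its log10-molar
concentration in row 1 and a ``Data<k>`` header (consecutively numbered
from 0) in row 2.  Extra columns are carried through verbatim as
annotations.  The NCATS-internal ``ncats_qhts`` dialect is recognized
and rejected with a pointer to this generic format.

Header matching is case-insensitive and whitespace-trimmed; canonical
names are written back on output.  Empty cells, "NA" and "NaN" all read
as a missing response; only the empty cell is ever written.
"""

from __future__ import annotations

import csv
import math
import re
from pathlib import Path
from typing import Any, Optional

from .model import (
    CurveFitParams,
    DataValidationError,
    FormatError,
    Issue,
    QHTSDataset,
    ResponseRecord,
    UnsupportedDialectError,
    ValidationReport,
)

GENERIC_TAG = "generic_qhts"
NCATS_TAG = "ncats_qhts"

# canonical row-2 header names, in written order
_FIXED_HEAD = ["Fit_Output", "Comp_ID", "Readout"]
_PARAM_HEAD = ["Log_AC50_M", "S_0", "S_Inf", "Hill_Slope"]
_DATA_RE = re.compile(r"^data(\d+)$")
_MISSING_TOKENS = {"", "na", "nan"}


def _norm(cell: Any) -> str:
    return "" if cell is None else str(cell).strip()


def _key(cell: Any) -> str:
    return _norm(cell).lower()


def _load_rows(path: str | Path) -> list[list[Any]]:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        with open(path, newline="", encoding="utf-8-sig") as fh:
            return [list(row) for row in csv.reader(fh)]
    if suffix == ".xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        try:
            ws = wb.worksheets[0]
            return [list(row) for row in ws.iter_rows(values_only=True)]
        finally:
            wb.close()
    raise FormatError(f"unsupported file extension {suffix!r}; expected .csv or .xlsx")


def _parse_number(cell: Any, locator: str) -> Optional[float]:
    """Parse one numeric cell; None for a missing token.

    Scientific notation is accepted; thousands separators are rejected
    (a comma never parses as part of a number).
    """
    if isinstance(cell, (int, float)):
        return float(cell)
    text = _norm(cell)
    if text.lower() in _MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise DataValidationError(f"{locator}: cannot parse number from {text!r}")


def detect_format(path: str | Path) -> str:
    """Return the file's format token (lower-cased, trimmed).

    The first cell of the first row must hold the ``Format`` keyword;
    the adjacent cell's content is the token.
    """
    rows = _load_rows(path)
    if not rows or _key(rows[0][0] if rows[0] else None) != "format":
        raise FormatError(
            f"{path}: no Format tag -- the first cell of row 1 must be 'Format'"
        )
    if len(rows[0]) < 2:
        raise FormatError(f"{path}: Format keyword present but the tag value cell is missing")
    return _key(rows[0][1])


def _locate_data_block(row1: list[Any], row2: list[Any], path) -> tuple[int, list[float]]:
    """Find the Log_Conc_M tag and parse the concentration block."""
    tag_col = None
    for j, cell in enumerate(row1):
        if _key(cell) == "log_conc_m":
            tag_col = j
            break
    if tag_col is None:
        raise FormatError(f"{path}: row 1 has no Log_Conc_M tag before the data block")

    # every Data<k> header anywhere in row 2 must live in the contiguous
    # block starting right after the tag column, numbered from 0
    data_cols = [j for j, c in enumerate(row2) if _DATA_RE.match(_key(c))]
    if not data_cols:
        raise FormatError(f"{path}: row 2 contains no Data0..DataN headers")
    start = tag_col + 1
    if data_cols[0] != start:
        raise FormatError(
            f"{path}: first data column is {_norm(row2[data_cols[0]])!r} at column "
            f"{data_cols[0] + 1}, expected it immediately after the Log_Conc_M tag"
        )
    for rank, j in enumerate(data_cols):
        if j != start + rank:
            raise FormatError(
                f"{path}: data block is not contiguous at column {j + 1} "
                f"(header {_norm(row2[j])!r})"
            )
        idx = int(_DATA_RE.match(_key(row2[j])).group(1))
        if idx != rank:
            raise FormatError(
                f"{path}: data headers must be consecutively numbered from Data0; "
                f"found {_norm(row2[j])!r} where Data{rank} was expected"
            )

    concs: list[float] = []
    for rank, j in enumerate(data_cols):
        cell = row1[j] if j < len(row1) else None
        v = _parse_number(cell, f"row 1, column {j + 1}")
        if v is None or not math.isfinite(v):
            raise FormatError(
                f"{path}: no parseable concentration above data header Data{rank} "
                f"(row 1, column {j + 1})"
            )
        concs.append(v)
    return start, concs


def read_generic_qhts(path: str | Path) -> QHTSDataset:
    """Read a generic_qhts file into a :class:`QHTSDataset`.

    Records keep the file's row order; extra columns are preserved as
    annotations in original order; blank response cells become missing
    values.  Raises :class:`UnsupportedDialectError` for ``ncats_qhts``
    files and :class:`FormatError` / :class:`DataValidationError` for
    layout or content defects, naming the offending row or column.
    """
    path = Path(path)
    tag = detect_format(path)
    if tag == NCATS_TAG:
        raise UnsupportedDialectError(
            f"{path}: the NCATS-internal 'ncats_qhts' dialect is not supported; "
            f"export your data in the '{GENERIC_TAG}' layout instead"
        )
    if tag != GENERIC_TAG:
        raise FormatError(f"{path}: unknown format tag {tag!r}; expected {GENERIC_TAG!r}")

    rows = _load_rows(path)
    if len(rows) < 2:
        raise FormatError(f"{path}: missing the column-header row (row 2)")
    row1, row2 = rows[0], rows[1]
    data_start, concs = _locate_data_block(row1, row2, path)
    n_data = len(concs)

    head_by_key = {}
    for j, cell in enumerate(row2):
        k = _key(cell)
        if k and not _DATA_RE.match(k):
            head_by_key.setdefault(k, j)
    fixed_cols: dict[str, int] = {}
    for name in _FIXED_HEAD + _PARAM_HEAD:
        j = head_by_key.get(name.lower())
        if j is None:
            raise FormatError(f"{path}: required column {name!r} not found in row 2")
        fixed_cols[name] = j

    fixed_set = set(fixed_cols.values())
    annotation_cols = [
        (j, _norm(row2[j]))
        for j in range(len(row2))
        if j not in fixed_set
        and not (data_start <= j < data_start + n_data)
        and _norm(row2[j])
    ]

    records: list[ResponseRecord] = []
    for r, row in enumerate(rows[2:], start=3):
        if all(_norm(c) == "" for c in row):
            continue  # trailing blank lines are common in hand-edited files

        def cell(j: int) -> Any:
            return row[j] if j < len(row) else None

        loc = f"row {r}"
        fo_raw = _norm(cell(fixed_cols["Fit_Output"]))
        if fo_raw not in {"0", "1"}:
            # xlsx numeric cells arrive as 0.0/1.0
            v = _parse_number(cell(fixed_cols["Fit_Output"]), loc)
            if v not in (0.0, 1.0):
                raise DataValidationError(f"{loc}: Fit_Output must be 0 or 1, got {fo_raw!r}")
            fit_output = int(v)
        else:
            fit_output = int(fo_raw)

        comp_id = _norm(cell(fixed_cols["Comp_ID"]))
        readout = _norm(cell(fixed_cols["Readout"]))
        if not readout:
            raise DataValidationError(f"{loc}: Readout is empty")

        pvals = [
            _parse_number(cell(fixed_cols[name]), f"{loc}, column {name}")
            for name in _PARAM_HEAD
        ]
        if all(v is not None for v in pvals):
            params = CurveFitParams(*pvals)
        else:
            if fit_output == 1:
                missing = [n for n, v in zip(_PARAM_HEAD, pvals) if v is None]
                raise DataValidationError(
                    f"{loc}: Fit_Output=1 but curve parameter(s) missing: "
                    + ", ".join(missing)
                )
            params = None

        responses = [
            _parse_number(cell(data_start + k), f"{loc}, column Data{k}")
            for k in range(n_data)
        ]
        annotations = {name: _norm(cell(j)) for j, name in annotation_cols}
        records.append(
            ResponseRecord(
                fit_output=fit_output,
                comp_id=comp_id,
                readout=readout,
                responses=responses,
                params=params,
                annotations=annotations,
            )
        )

    return QHTSDataset(
        format_tag=GENERIC_TAG, log_conc_m=concs, records=records, source=str(path)
    )


def validate_dataset(ds: QHTSDataset) -> ValidationReport:
    """Schema validation; errors make the report not-ok, warnings do not.

    Errors: grid/record length mismatch, non-finite concentrations, a
    fitted record with incomplete parameters or a zero Hill slope.
    Warnings: non-monotonic concentration grid, duplicate
    (comp_id, readout) pairs, responses outside +/-200 % (suspicious
    scale for normalized data).
    """
    report = ValidationReport()
    n = ds.n_concs
    for i, c in enumerate(ds.log_conc_m):
        if c is None or not math.isfinite(c):
            report.add("error", f"grid point {i}", f"non-finite concentration {c!r}")

    diffs = [b - a for a, b in zip(ds.log_conc_m, ds.log_conc_m[1:])]
    if diffs and not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
        report.add("warning", "concentration grid", "grid is not strictly monotonic")

    seen: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(ds.records):
        loc = f"record {i} ({rec.comp_id!r}/{rec.readout!r})"
        if len(rec.responses) != n:
            report.add("error", loc, f"{len(rec.responses)} responses vs {n} grid points")
        if rec.fit_output == 1:
            if not rec.has_complete_params():
                report.add("error", loc, "Fit_Output=1 but curve parameters incomplete")
            elif rec.params.hill_slope == 0:
                report.add("error", loc, "fitted record has Hill_Slope = 0")
        key = (rec.comp_id, rec.readout)
        if key in seen:
            report.add(
                "warning", loc, f"duplicate (Comp_ID, Readout) pair, first at record {seen[key]}"
            )
        else:
            seen[key] = i
        for k, v in enumerate(rec.responses):
            if v is not None and not (-200.0 <= v <= 200.0):
                report.add("warning", f"{loc}, Data{k}", f"response {v:g}% outside [-200, 200]")
                break  # one scale warning per record is enough
    return report


def _fmt_number(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(float(v))


def write_generic_qhts(ds: QHTSDataset, path: str | Path) -> None:
    """Write a dataset in the generic_qhts layout (.csv or .xlsx by extension).

    Refuses to write a dataset whose validation report carries errors.
    Floats are written at full precision so a read-back round-trips.
    """
    report = validate_dataset(ds)
    if not report.ok:
        raise DataValidationError(
            "refusing to write an invalid dataset:\n" + report.summary()
        )
    path = Path(path)

    ann_keys: list[str] = []
    for rec in ds.records:
        for k in rec.annotations:
            if k not in ann_keys:
                ann_keys.append(k)

    head2 = _FIXED_HEAD + ann_keys + _PARAM_HEAD
    tag_col = len(head2) - 1  # Hill_Slope column, immediately before Data0
    row1: list[Any] = ["Format", GENERIC_TAG] + [""] * (tag_col - 1)
    row1[tag_col] = "Log_Conc_M"
    row2: list[Any] = head2 + [f"Data{k}" for k in range(ds.n_concs)]

    body: list[list[Any]] = []
    for rec in ds.records:
        p = rec.params
        pvals = (
            [p.log_ac50_m, p.s0, p.s_inf, p.hill_slope] if p is not None else [None] * 4
        )
        body.append(
            [rec.fit_output, rec.comp_id, rec.readout]
            + [rec.annotations.get(k, "") for k in ann_keys]
            + pvals
            + list(rec.responses)
        )

    suffix = path.suffix.lower()
    if suffix == ".csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow([_norm(c) for c in row1] + [_fmt_number(c) for c in ds.log_conc_m])
            w.writerow(row2)
            for rec_row in body:
                out = rec_row[:3 + len(ann_keys)] + [
                    _fmt_number(v) for v in rec_row[3 + len(ann_keys):]
                ]
                w.writerow(out)
    elif suffix == ".xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.append(row1 + [float(c) for c in ds.log_conc_m])
        ws.append(row2)
        for rec_row in body:
            ws.append([("" if v is None else v) for v in rec_row])
        wb.save(path)
    else:
        raise FormatError(f"unsupported output extension {suffix!r}; use .csv or .xlsx")
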