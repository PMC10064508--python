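"""generic_qhts dialect: detection, parsing, round-trips, validation."""

import csv

import pytest

from qhtsplot import (
    GeneratorSpec,
    QHTSDataset,
    ResponseRecord,
    detect_format,
    generate_dataset,
    read_generic_qhts,
    validate_dataset,
    write_generic_qhts,
)
from qhtsplot.model import (
    CurveFitParams,
    DataValidationError,
    FormatError,
    UnsupportedDialectError,
)

MINIMAL = [
    ["Format", "generic_qhts", "", "", "", "", "", "", "Log_Conc_M", "-9", "-8", "-7", "-6", "-5"],
    ["Fit_Output", "Comp_ID", "Readout", "SMILES", "Log_AC50_M", "S_0", "S_Inf",
     "Hill_Slope", "", "Data0", "Data1", "Data2", "Data3", "Data4"],
    ["1", "C1", "FLuc", "CCO", "-7", "0", "100", "1.2", "", "1.0", "5", "50", "95", "99"],
    ["0", "C2", "FLuc", "c1ccccc1", "", "", "", "", "", "0.5", "", "-1", "2", "0"],
]


def _write_csv(path, rows):
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)
    return path


@pytest.fixture
def minimal_csv(tmp_path):
    return _write_csv(tmp_path / "min.csv", MINIMAL)


def test_detect_format_tokens(tmp_path, minimal_csv):
    assert detect_format(minimal_csv) == "generic_qhts"
    ncats = _write_csv(tmp_path / "n.csv", [["Format", "ncats_qhts"]])
    assert detect_format(ncats) == "ncats_qhts"
    # case/whitespace tolerant
    spaced = _write_csv(tmp_path / "s.csv", [[" format ", "  Generic_QHTS "]] + MINIMAL[1:])
    assert detect_format(spaced) == "generic_qhts"


def test_detect_format_requires_tag(tmp_path):
    bad = _write_csv(tmp_path / "b.csv", MINIMAL[1:])
    with pytest.raises(FormatError, match="Format"):
        detect_format(bad)


def test_ncats_dialect_rejected_with_pointer(tmp_path):
    rows = [["Format", "ncats_qhts"]] + MINIMAL[1:]
    path = _write_csv(tmp_path / "n.csv", rows)
    with pytest.raises(UnsupportedDialectError, match="generic_qhts"):
        read_generic_qhts(path)


def test_read_minimal_file(minimal_csv):
    ds = read_generic_qhts(minimal_csv)
    assert ds.format_tag == "generic_qhts"
    assert ds.log_conc_m == [-9.0, -8.0, -7.0, -6.0, -5.0]
    assert [r.comp_id for r in ds.records] == ["C1", "C2"]
    fitted = ds.records[0]
    assert fitted.fit_output == 1
    assert fitted.params == CurveFitParams(-7.0, 0.0, 100.0, 1.2)
    assert fitted.annotations == {"SMILES": "CCO"}
    pts = ds.records[1]
    assert pts.fit_output == 0 and pts.params is None
    assert pts.responses == [0.5, None, -1.0, 2.0, 0.0]  # blank cell -> missing


def test_eleven_point_titration_has_eleven_grid_points(tmp_path):
    ds, _ = generate_dataset(GeneratorSpec(n_compounds=5, seed=1))
    path = tmp_path / "t.csv"
    write_generic_qhts(ds, path)
    back = read_generic_qhts(path)
    assert back.n_concs == 11
    header = path.read_text().splitlines()[1]
    assert header.split(",")[-1] == "Data10" and "Data0" in header


def test_missing_token_spellings(tmp_path):
    rows = [r[:] for r in MINIMAL]
    rows[3] = ["0", "C2", "FLuc", "x", "", "", "", "", "", "NA", "nan", "NaN", "", "3"]
    ds = read_generic_qhts(_write_csv(tmp_path / "m.csv", rows))
    assert ds.records[1].responses == [None, None, None, None, 3.0]


def test_fitted_row_missing_parameter_is_located(tmp_path):
    rows = [r[:] for r in MINIMAL]
    rows[2][7] = ""  # drop Hill_Slope of the Fit_Output=1 row
    path = _write_csv(tmp_path / "bad.csv", rows)
    with pytest.raises(DataValidationError, match=r"row 3.*Hill_Slope"):
        read_generic_qhts(path)


def test_noncontiguous_data_block_rejected(tmp_path):
    rows = [r[:] for r in MINIMAL]
    rows[1][11] = "Notes"  # breaks the Data0..Data4 block
    with pytest.raises(FormatError, match="Data"):
        read_generic_qhts(_write_csv(tmp_path / "nc.csv", rows))


def test_data_headers_must_start_at_zero_without_gaps(tmp_path):
    rows = [r[:] for r in MINIMAL]
    rows[1][9] = "Data1"  # first header not Data0
    with pytest.raises(FormatError, match="Data0"):
        read_generic_qhts(_write_csv(tmp_path / "g.csv", rows))
    rows = [r[:] for r in MINIMAL]
    rows[1][11] = "Data5"  # skipped index
    with pytest.raises(FormatError, match="Data2"):
        read_generic_qhts(_write_csv(tmp_path / "g2.csv", rows))


@pytest.mark.parametrize("ext", ["csv", "xlsx"])
def test_roundtrip_preserves_everything(tmp_path, small_dataset, ext):
    ds, _ = small_dataset
    path = tmp_path / f"rt.{ext}"
    write_generic_qhts(ds, path)
    back = read_generic_qhts(path)
    assert back.log_conc_m == pytest.approx(ds.log_conc_m)
    assert len(back.records) == len(ds.records)
    for a, b in zip(ds.records, back.records):
        assert (a.fit_output, a.comp_id, a.readout) == (b.fit_output, b.comp_id, b.readout)
        assert a.annotations == b.annotations
        if a.params is None:
            assert b.params is None
        else:
            for f in ("log_ac50_m", "s0", "s_inf", "hill_slope"):
                assert getattr(b.params, f) == pytest.approx(getattr(a.params, f), rel=1e-12)
        assert b.responses == pytest.approx(a.responses, rel=1e-12)


@pytest.mark.parametrize("ext", ["csv", "xlsx"])
def test_double_roundtrip_is_exact_identity(tmp_path, small_dataset, ext):
    """After one write/read cycle the dataset is a fixed point of the codec."""
    ds, _ = small_dataset
    p1, p2 = tmp_path / f"a.{ext}", tmp_path / f"b.{ext}"
    write_generic_qhts(ds, p1)
    once = read_generic_qhts(p1)
    write_generic_qhts(once, p2)
    twice = read_generic_qhts(p2)
    assert twice.log_conc_m == once.log_conc_m
    assert twice.records == once.records


def test_csv_and_xlsx_encodings_parse_equal(tmp_path, small_dataset):
    ds, _ = small_dataset
    write_generic_qhts(ds, tmp_path / "x.csv")
    write_generic_qhts(ds, tmp_path / "x.xlsx")
    a = read_generic_qhts(tmp_path / "x.csv")
    b = read_generic_qhts(tmp_path / "x.xlsx")
    assert len(a.records) == len(b.records)
    for ra, rb in zip(a.records, b.records):
        assert (ra.fit_output, ra.comp_id, ra.readout, ra.annotations) == (
            rb.fit_output, rb.comp_id, rb.readout, rb.annotations)
        assert rb.responses == pytest.approx(ra.responses, rel=1e-12)


def test_validate_generator_output_is_clean(small_dataset):
    ds, _ = small_dataset
    report = validate_dataset(ds)
    assert report.ok and not report.errors


def test_validate_flags_fitted_record_defects():
    rec = ResponseRecord(
        fit_output=1, comp_id="C1", readout="FLuc", responses=[0.0, 1.0],
        params=CurveFitParams(-6.0, 0.0, 100.0, 0.0),
    )
    ds = QHTSDataset("generic_qhts", [-9.0, -4.0], [rec])
    report = validate_dataset(ds)
    assert not report.ok
    assert any("Hill_Slope = 0" in i.message for i in report.errors)

    rec2 = ResponseRecord(
        fit_output=1, comp_id="C2", readout="FLuc", responses=[0.0, 1.0],
        params=CurveFitParams(-6.0, 0.0, float("nan"), 1.0),
    )
    ds2 = QHTSDataset("generic_qhts", [-9.0, -4.0], [rec2])
    rep2 = validate_dataset(ds2)
    assert not rep2.ok and any("incomplete" in i.message for i in rep2.errors)


def test_validate_warns_without_failing():
    recs = [
        ResponseRecord(fit_output=0, comp_id="C1", readout="FLuc", responses=[0.0, 350.0, 1.0]),
        ResponseRecord(fit_output=0, comp_id="C1", readout="FLuc", responses=[0.0, 1.0, 2.0]),
    ]
    ds = QHTSDataset("generic_qhts", [-9.0, -5.0, -7.0], recs)  # shuffled grid
    report = validate_dataset(ds)
    assert report.ok
    messages = " | ".join(i.message for i in report.warnings)
    assert "monotonic" in messages
    assert "duplicate" in messages
    assert "outside" in messages


def test_writer_refuses_invalid_dataset(tmp_path):
    rec = ResponseRecord(
        fit_output=1, comp_id="C1", readout="FLuc", responses=[0.0, 1.0],
        params=CurveFitParams(-6.0, 0.0, 100.0, 0.0),
    )
    ds = QHTSDataset("generic_qhts", [-9.0, -4.0], [rec])
    with pytest.raises(DataValidationError, match="refusing"):
        write_generic_qhts(ds, tmp_path / "no.csv")
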