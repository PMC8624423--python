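"""Peak-table data model, CSV round-trips and retention-index calibration."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srdkit import (
    AlkaneLadder,
    PeakRecord,
    PeakTable,
    ProcedureLabel,
    compute_retention_index,
    delta_ri_percent,
    read_peak_table,
    write_peak_table,
)
from srdkit.peak_table import FormatError, PeakTableError

from conftest import build_table


# ---------------------------------------------------------------------------
# procedure labels and records
# ---------------------------------------------------------------------------

def test_procedure_label_grammar():
    lab = ProcedureLabel.make("PorapakQ", 6)
    assert lab.label == "P6h" and lab.sampling_time == 6.0
    parsed = ProcedureLabel.parse("H4h")
    assert parsed.sampling_time == 4.0 and parsed.adsorbent == "H"
    with pytest.raises(FormatError):
        ProcedureLabel.parse("not-a-code")
    with pytest.raises(PeakTableError):
        ProcedureLabel(adsorbent="P", sampling_time=0.0, label="P0h")


def test_record_validation():
    with pytest.raises(PeakTableError):
        PeakRecord(retention_time=-1.0)
    with pytest.raises(PeakTableError):
        PeakRecord(retention_time=1.0, match_factor=150.0)


def test_table_shape_and_sign_validation():
    procs = [ProcedureLabel.parse("P1h")]
    recs = [PeakRecord(retention_time=1.0), PeakRecord(retention_time=2.0)]
    with pytest.raises(PeakTableError):
        PeakTable(records=recs, procedures=procs, intensities=np.ones((3, 1)))
    with pytest.raises(PeakTableError):
        PeakTable(records=recs, procedures=procs, intensities=-np.ones((2, 1)))
    with pytest.raises(PeakTableError):
        PeakTable(
            records=recs,
            procedures=[ProcedureLabel.parse("P1h"), ProcedureLabel.parse("P1h")],
            intensities=np.ones((2, 2)),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_roundtrip_small_table():
    table = build_table(
        [[1.5, 2.0], [0.0, 3.25], [7.0, 0.5]],
        labels=["P1h", "H2h"],
        records=[
            PeakRecord(retention_time=1.1, name="a", match_factor=91.5,
                       ri_calculated=850.0, ri_literature=845.0),
            PeakRecord(retention_time=2.2, name="b", area_percent=0.5),
            PeakRecord(retention_time=3.3, name="c", formula="C6H12O", cas="1-2-3"),
        ],
    )
    buf = io.StringIO()
    write_peak_table(table, buf)
    assert read_peak_table(io.StringIO(buf.getvalue())) == table


def test_empty_intensity_cell_becomes_zero():
    csv = "rt_min,compound,P1h,P2h\n1.0,x,,5\n2.0,y,3,4\n"
    table = read_peak_table(io.StringIO(csv))
    assert table.intensities[0, 0] == 0.0
    assert table.intensities[0, 1] == 5.0


def test_rows_resorted_by_retention_time():
    csv = "rt_min,compound,P1h\n5.0,late,1\n1.0,early,2\n3.0,mid,3\n"
    table = read_peak_table(io.StringIO(csv))
    assert [r.name for r in table.records] == ["early", "mid", "late"]
    assert list(table.intensities[:, 0]) == [2.0, 3.0, 1.0]


def test_header_only_roundtrip():
    table = build_table(np.empty((0, 2)), labels=["P1h", "P2h"], records=[])
    buf = io.StringIO()
    write_peak_table(table, buf)
    back = read_peak_table(io.StringIO(buf.getvalue()))
    assert back.n_compounds == 0 and back.procedure_labels == ["P1h", "P2h"]


@pytest.mark.parametrize(
    "csv,err",
    [
        ("", FormatError),
        ("compound,P1h\nx,1\n", FormatError),  # no rt_min column
        ("rt_min,P1h\n1.0,-3\n", PeakTableError),  # negative intensity
        ("rt_min,P1h,P1h\n1.0,1,2\n", PeakTableError),  # duplicate label
    ],
)
def test_read_errors(csv, err):
    with pytest.raises(err):
        read_peak_table(io.StringIO(csv))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.data())
def test_roundtrip_identity_property(data):
    n = data.draw(st.integers(1, 8), label="n")
    m = data.draw(st.integers(1, 4), label="m")
    rts = sorted(
        data.draw(
            st.lists(
                st.floats(0.1, 50.0, allow_nan=False),
                min_size=n, max_size=n, unique=True,
            ),
            label="rts",
        )
    )
    mat = np.array(
        data.draw(
            st.lists(
                st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=m, max_size=m),
                min_size=n, max_size=n,
            ),
            label="mat",
        )
    )
    mf = data.draw(
        st.lists(st.one_of(st.none(), st.floats(0, 100)), min_size=n, max_size=n),
        label="mf",
    )
    records = [
        PeakRecord(retention_time=rts[i], name=f"c{i}", match_factor=mf[i])
        for i in range(n)
    ]
    table = build_table(mat, labels=[f"P{j + 1}h" for j in range(m)], records=records)
    buf = io.StringIO()
    write_peak_table(table, buf)
    assert read_peak_table(io.StringIO(buf.getvalue())) == table


# ---------------------------------------------------------------------------
# retention indices
# ---------------------------------------------------------------------------

@pytest.fixture
def ladder() -> AlkaneLadder:
    return AlkaneLadder(carbon_numbers=(8, 9, 10), retention_times=(10.0, 12.0, 15.0))


@pytest.mark.parametrize(
    "rt,expected",
    [(11.0, 850.0), (10.0, 800.0), (11.5, 875.0), (12.0, 900.0), (15.0, 1000.0)],
)
def test_retention_index_linear_interpolation(ladder, rt, expected):
    assert compute_retention_index(rt, ladder) == pytest.approx(expected)


def test_retention_index_refuses_extrapolation(ladder):
    for rt in (9.99, 15.01):
        with pytest.raises(PeakTableError):
            compute_retention_index(rt, ladder)


def test_retention_index_monotone(ladder):
    rts = np.linspace(10.0, 15.0, 101)
    ri = compute_retention_index(rts, ladder)
    assert np.all(np.diff(ri) >= 0)


def test_ladder_validation():
    with pytest.raises(PeakTableError):
        AlkaneLadder(carbon_numbers=(8,), retention_times=(10.0,))
    with pytest.raises(PeakTableError):
        AlkaneLadder(carbon_numbers=(8, 9), retention_times=(12.0, 10.0))
    with pytest.raises(PeakTableError):
        AlkaneLadder(carbon_numbers=(9, 8), retention_times=(10.0, 12.0))


def test_ladder_csv_roundtrip(tmp_path):
    ladder = AlkaneLadder(carbon_numbers=tuple(range(8, 21)),
                          retention_times=tuple(np.linspace(4.0, 26.0, 13)))
    path = tmp_path / "ladder.csv"
    ladder.to_csv(path)
    assert AlkaneLadder.from_csv(path) == ladder


# ---------------------------------------------------------------------------
# delta RI
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "calc,lit,expected",
    [
        (1000.0, 1000.0, 0.0),
        (1025.0, 1051.0, 100.0 * 26.0 / 1051.0),  # ~2.47%
        (1100.0, 1000.0, 10.0),  # exactly at the elimination boundary
    ],
)
def test_delta_ri_percent(calc, lit, expected):
    assert delta_ri_percent(calc, lit) == pytest.approx(expected)


def test_delta_ri_rejects_nonpositive():
    with pytest.raises(PeakTableError):
        delta_ri_percent(1000.0, 0.0)
    with pytest.raises(PeakTableError):
        delta_ri_percent(-5.0, 1000.0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    calc=st.floats(1.0, 3000.0, allow_nan=False),
    lit=st.floats(1.0, 3000.0, allow_nan=False),
)
def test_delta_ri_nonnegative_zero_iff_equal(calc, lit):
    d = delta_ri_percent(calc, lit)
    assert d >= 0
    assert (d == 0) == (calc == lit)
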