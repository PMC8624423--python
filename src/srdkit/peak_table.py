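"""GC-MS compound peak tables: data model, CSV I/O and retention-index calibration.

The central exchange object is :class:`PeakTable`: per-compound metadata
(retention time, identification, retention indices) plus a dense non-negative
intensity matrix with one column per sampling procedure. Missing peaks
(compound not detected under a procedure) are stored as 0, which keeps every
column rankable.

Retention indices for temperature-programmed runs use the linear
(van den Dool-Kratz) interpolation against an n-alkane ladder: the index is
100 times the carbon number at each alkane and piecewise-linear in retention
time between consecutive alkanes.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTableError",
    "FormatError",
    "ProcedureLabel",
    "PeakRecord",
    "PeakTable",
    "AlkaneLadder",
    "read_peak_table",
    "write_peak_table",
    "compute_retention_index",
    "delta_ri_percent",
    "METADATA_COLUMNS",
]


class PeakTableError(ValueError):
    """Invalid peak-table content (shape, sign, duplicate labels ...)."""


class FormatError(PeakTableError):
    """Malformed input file (missing header, unknown layout)."""


#: Reserved CSV column names holding compound metadata; every other column in a
#: peak-table file is interpreted as one sampling procedure's intensities.
METADATA_COLUMNS = (
    "rt_min",
    "compound",
    "formula",
    "cas",
    "area_percent",
    "match_factor",
    "ri_calculated",
    "ri_literature",
)

_LABEL_RE = re.compile(r"^([A-Za-z][A-Za-z_-]*?)(\d+(?:\.\d+)?)h$")


def _fmt_hours(hours: float) -> str:
    return str(int(hours)) if float(hours).is_integer() else str(hours)


@dataclass(frozen=True)
class ProcedureLabel:
    """One sampling procedure: an adsorbent sampled for a fixed duration.

    The short label follows the first-letter-plus-hours grammar used for
    dynamic-headspace procedure codes, e.g. ``P6h`` for Porapak Q / 6 h,
    ``C2h`` for Carbotrap / 2 h.
    """

    adsorbent: str
    sampling_time: float  # hours
    label: str

    def __post_init__(self) -> None:
        if not self.adsorbent:
            raise PeakTableError("adsorbent name must be non-empty")
        if not (self.sampling_time > 0):
            raise PeakTableError(
                f"sampling_time must be > 0, got {self.sampling_time!r}"
            )
        if not self.label:
            raise PeakTableError("procedure label must be non-empty")

    @classmethod
    def make(cls, adsorbent: str, sampling_time: float) -> "ProcedureLabel":
        """Build a label from the adsorbent's initial and the time in hours."""
        return cls(
            adsorbent=adsorbent,
            sampling_time=float(sampling_time),
            label=f"{adsorbent[0].upper()}{_fmt_hours(sampling_time)}h",
        )

    @classmethod
    def parse(cls, label: str) -> "ProcedureLabel":
        """Parse a short code like ``P6h``; the prefix is kept as adsorbent."""
        m = _LABEL_RE.match(label)
        if m is None:
            raise FormatError(
                f"procedure column {label!r} does not match the "
                "<adsorbent><hours>h label grammar (e.g. 'P6h')"
            )
        return cls(adsorbent=m.group(1), sampling_time=float(m.group(2)), label=label)


@dataclass(frozen=True)
class PeakRecord:
    """Metadata of one detected compound (one chromatogram peak)."""

    retention_time: float  # minutes
    name: str = ""
    formula: str | None = None
    cas: str | None = None
    area_percent: float | None = None
    match_factor: float | None = None  # library match, percent
    ri_calculated: float | None = None
    ri_literature: float | None = None

    def __post_init__(self) -> None:
        if not (self.retention_time >= 0):
            raise PeakTableError(
                f"retention_time must be >= 0, got {self.retention_time!r}"
            )
        if self.area_percent is not None and self.area_percent < 0:
            raise PeakTableError("area_percent must be >= 0")
        if self.match_factor is not None and not (0 <= self.match_factor <= 100):
            raise PeakTableError("match_factor must lie in [0, 100]")


@dataclass
class PeakTable:
    """Compound records plus a compounds x procedures intensity matrix.

    Records are kept sorted by retention time (elution order); the intensity
    rows are permuted together with the records at construction. Intensities
    are non-negative; a 0 means "not detected".
    """

    records: list[PeakRecord]
    procedures: list[ProcedureLabel]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.records = list(self.records)
        self.procedures = list(self.procedures)
        mat = np.asarray(self.intensities, dtype=float)
        if mat.ndim != 2:
            raise PeakTableError("intensities must be a 2-D matrix")
        if mat.shape != (len(self.records), len(self.procedures)):
            raise PeakTableError(
                f"intensity matrix shape {mat.shape} does not match "
                f"{len(self.records)} records x {len(self.procedures)} procedures"
            )
        if np.isnan(mat).any():
            mat = np.nan_to_num(mat, nan=0.0)
        if (mat < 0).any():
            raise PeakTableError("intensities must be non-negative")
        labels = [p.label for p in self.procedures]
        if len(set(labels)) != len(labels):
            raise PeakTableError("duplicate procedure labels")
        order = np.argsort([r.retention_time for r in self.records], kind="stable")
        self.records = [self.records[i] for i in order]
        self.intensities = np.ascontiguousarray(mat[order])

    # -- basic geometry -------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return len(self.records)

    @property
    def n_procedures(self) -> int:
        return len(self.procedures)

    @property
    def procedure_labels(self) -> list[str]:
        return [p.label for p in self.procedures]

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([r.retention_time for r in self.records])

    def subset(self, indices: Sequence[int]) -> "PeakTable":
        """New table restricted to the given record rows (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return PeakTable(
            records=[self.records[i] for i in idx],
            procedures=list(self.procedures),
            intensities=self.intensities[idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return (
            self.records == other.records
            and self.procedures == other.procedures
            and np.array_equal(self.intensities, other.intensities)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: metadata columns followed by intensity columns."""
        data: dict[str, object] = {
            "rt_min": [r.retention_time for r in self.records],
            "compound": [r.name for r in self.records],
            "formula": [r.formula for r in self.records],
            "cas": [r.cas for r in self.records],
            "area_percent": [r.area_percent for r in self.records],
            "match_factor": [r.match_factor for r in self.records],
            "ri_calculated": [r.ri_calculated for r in self.records],
            "ri_literature": [r.ri_literature for r in self.records],
        }
        for j, proc in enumerate(self.procedures):
            data[proc.label] = self.intensities[:, j]
        return pd.DataFrame(data)


def _opt_float(value: object) -> float | None:
    if value is None:
        return None
    try:
        f = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def _opt_str(value: object) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value)
    return s if s else None


def _read_text(source) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text(encoding="utf-8")
    data = source.read()
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    return data


def read_peak_table(source, sep: str = ",") -> PeakTable:
    """Read a delimited peak table (header row required).

    Columns named in :data:`METADATA_COLUMNS` carry compound metadata
    (``rt_min`` is mandatory); every remaining column is one procedure's
    intensities, its header a ``P6h``-style procedure code. Empty intensity
    cells become 0; rows are re-sorted into elution order.
    """
    text = _read_text(source)
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise FormatError("peak table has no header row")
    header = next(iter(pd.read_csv(io.StringIO(lines[0]), sep=sep, header=None).values)).tolist()
    header = [str(h) for h in header]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise PeakTableError(f"duplicate column labels: {dupes}")
    if "rt_min" not in header:
        raise FormatError(
            "missing required 'rt_min' column — is this a peak-table CSV?"
        )
    df = pd.read_csv(io.StringIO(text), sep=sep, float_precision="round_trip")
    proc_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    procedures = [ProcedureLabel.parse(c) for c in proc_cols]
    intens = df[proc_cols].to_numpy(dtype=float) if proc_cols else np.empty((len(df), 0))
    if np.nan_to_num(intens, nan=0.0).min(initial=0.0) < 0:
        raise PeakTableError("negative intensity value in input")
    records = []
    for _, row in df.iterrows():
        records.append(
            PeakRecord(
                retention_time=float(row["rt_min"]),
                name=_opt_str(row.get("compound")) or "",
                formula=_opt_str(row.get("formula")),
                cas=_opt_str(row.get("cas")),
                area_percent=_opt_float(row.get("area_percent")),
                match_factor=_opt_float(row.get("match_factor")),
                ri_calculated=_opt_float(row.get("ri_calculated")),
                ri_literature=_opt_float(row.get("ri_literature")),
            )
        )
    return PeakTable(records=records, procedures=procedures, intensities=np.nan_to_num(intens, nan=0.0))


def write_peak_table(table: PeakTable, sink, sep: str = ",") -> None:
    """Write a table as CSV readable by :func:`read_peak_table` (round-trip identity)."""
    frame = table.to_frame()
    if isinstance(sink, (str, Path)):
        frame.to_csv(sink, sep=sep, index=False)
    else:
        frame.to_csv(sink, sep=sep, index=False)


@dataclass(frozen=True)
class AlkaneLadder:
    """n-Alkane calibration ladder: carbon numbers and their retention times."""

    carbon_numbers: tuple[int, ...]
    retention_times: tuple[float, ...]  # minutes

    def __post_init__(self) -> None:
        cn = tuple(int(c) for c in self.carbon_numbers)
        rt = tuple(float(t) for t in self.retention_times)
        object.__setattr__(self, "carbon_numbers", cn)
        object.__setattr__(self, "retention_times", rt)
        if len(cn) != len(rt):
            raise PeakTableError("carbon_numbers and retention_times differ in length")
        if len(cn) < 2:
            raise PeakTableError("alkane ladder needs at least two rungs")
        if any(b <= a for a, b in zip(cn, cn[1:])):
            raise PeakTableError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rt, rt[1:])):
            raise PeakTableError("ladder retention times must be strictly increasing")

    @classmethod
    def from_csv(cls, source, sep: str = ",") -> "AlkaneLadder":
        """Two-column CSV ``carbon_number,rt_min`` with header."""
        df = pd.read_csv(
            io.StringIO(_read_text(source)), sep=sep, float_precision="round_trip"
        )
        if not {"carbon_number", "rt_min"} <= set(df.columns):
            raise FormatError("ladder file needs 'carbon_number' and 'rt_min' columns")
        return cls(
            carbon_numbers=tuple(df["carbon_number"].astype(int)),
            retention_times=tuple(df["rt_min"].astype(float)),
        )

    def to_csv(self, sink, sep: str = ",") -> None:
        pd.DataFrame(
            {"carbon_number": self.carbon_numbers, "rt_min": self.retention_times}
        ).to_csv(sink, sep=sep, index=False)


def compute_retention_index(rt, ladder: AlkaneLadder):
    """Linear (programmed-temperature) retention index of ``rt`` minutes.

    Piecewise-linear interpolation of 100 x carbon number against the ladder's
    retention times; exactly 100 x c at each alkane. No extrapolation: ``rt``
    outside the ladder span raises.

    Accepts a scalar or an array; returns the same shape.
    """
    rt_arr = np.asarray(rt, dtype=float)
    lo, hi = ladder.retention_times[0], ladder.retention_times[-1]
    if np.any(rt_arr < lo) or np.any(rt_arr > hi):
        raise PeakTableError(
            f"retention time outside ladder span [{lo}, {hi}] min; "
            "extend the alkane ladder instead of extrapolating"
        )
    ri = np.interp(rt_arr, ladder.retention_times, 100.0 * np.asarray(ladder.carbon_numbers))
    return float(ri) if np.isscalar(rt) or rt_arr.ndim == 0 else ri


def delta_ri_percent(ri_calculated: float, ri_literature: float) -> float:
    """Percent discrepancy of a calculated vs literature retention index.

    ``100 * |RI_calc - RI_lit| / RI_lit`` — the identification-plausibility
    statistic thresholded by the delta-RI filter.
    """
    if not (ri_literature > 0):
        raise PeakTableError("literature retention index must be > 0")
    if not (ri_calculated > 0):
        raise PeakTableError("calculated retention index must be > 0")
    return 100.0 * abs(ri_calculated - ri_literature) / ri_literature
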