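"""Reading, writing and annotating capillary-electrophoresis peak tables.

Fragment-analysis software (GeneMapper and kin) exports one row per called
peak with the fragment size in bp and the signal height in relative
fluorescence units (RFU).  This module parses those exports into per-sample
traces, joins them with an experiment sample sheet (run, clone, treatment,
timepoint, baseline status, known repeat length for calibration standards),
and writes them back out losslessly.

Export headers vary between software versions, so column names are supplied
through a :class:`Dialect` mapping; the default matches a GeneMapper 5
tab-delimited export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    DuplicateKeyError,
    EmptyInputError,
    FormatError,
    ValidationError,
)

__all__ = [
    "Dialect",
    "FragmentPeak",
    "SampleTrace",
    "PeakTable",
    "read_peak_table",
    "write_peak_table",
    "read_sample_sheet",
    "join_sample_sheet",
]

SHEET_COLUMNS = (
    "sample_id",
    "run_id",
    "clone_id",
    "treatment",
    "timepoint_days",
    "is_baseline",
    "known_repeat",
)


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a peak-table export.

    ``ladder_dyes`` names channels carrying the internal size standard
    (e.g. the LIZ ladder); rows on those dyes are instrument plumbing,
    already consumed for sizing, and are dropped at parse time.
    ``size_range`` rows outside the plausible sizing regime are flagged in
    the parse report but kept.
    """

    sample: str = "Sample File"
    size: str = "Size"
    height: str = "Height"
    area: str | None = "Area"
    dye: str | None = "Dye"
    ladder_dyes: tuple[str, ...] = ("LIZ", "O")
    size_range: tuple[float, float] = (50.0, 1200.0)


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class FragmentPeak:
    """One called peak: fragment size in bp and signal height in RFU."""

    size_bp: float
    height: float
    area: float | None = None
    dye: str | None = None

    def __post_init__(self) -> None:
        if not self.size_bp > 0:
            raise ValidationError(f"size_bp must be positive, got {self.size_bp}")
        if self.height < 0:
            raise ValidationError(f"height must be non-negative, got {self.height}")


@dataclass
class SampleTrace:
    """All peaks for one sample plus its experiment metadata."""

    sample_id: str
    peaks: list[FragmentPeak] = field(default_factory=list)
    run_id: str | None = None
    clone_id: str | None = None
    treatment: str | None = None
    replicate: str | None = None
    timepoint_days: float | None = None
    is_baseline: bool = False
    known_repeat: float | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)
        if self.is_baseline and self.timepoint_days not in (None, 0, 0.0):
            raise ValidationError(
                f"sample {self.sample_id!r}: is_baseline requires "
                f"timepoint_days 0, got {self.timepoint_days}"
            )
        if self.known_repeat is not None and not self.known_repeat > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: known_repeat must be positive"
            )

    @property
    def is_standard(self) -> bool:
        return self.known_repeat is not None


@dataclass
class PeakTable:
    """A collection of sample traces plus the parse/join bookkeeping.

    ``report`` records per-row rejections (non-numeric size/height),
    out-of-range size flags and, after a sample-sheet join, orphan samples
    present in the peaks but missing from the sheet.
    """

    traces: list[SampleTrace] = field(default_factory=list)
    dialect: Dialect = DEFAULT_DIALECT
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.sample_id for t in self.traces]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise DuplicateKeyError(f"duplicate sample_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def get(self, sample_id: str) -> SampleTrace:
        for t in self.traces:
            if t.sample_id == sample_id:
                return t
        raise KeyError(sample_id)

    def run_ids(self) -> list[str]:
        return sorted({t.run_id for t in self.traces if t.run_id is not None})


def read_peak_table(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> PeakTable:
    """Parse a tab-delimited peak export into a :class:`PeakTable`.

    Rows whose size or height do not parse as numbers are rejected and
    listed (with reasons) in ``table.report["rejected_rows"]``.  Rows with
    sizes outside ``dialect.size_range`` are kept but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty peak table: {path}") from None
    if df.empty:
        raise EmptyInputError(f"peak table has no rows: {path}")
    for col in (dialect.sample, dialect.size, dialect.height):
        if col not in df.columns:
            raise FormatError(f"peak table missing mandatory column {col!r}")

    rejected: list[dict] = []
    flagged: list[dict] = []
    by_sample: dict[str, list[FragmentPeak]] = {}
    lo, hi = dialect.size_range
    has_area = dialect.area is not None and dialect.area in df.columns
    has_dye = dialect.dye is not None and dialect.dye in df.columns

    for idx, row in df.iterrows():
        dye = str(row[dialect.dye]) if has_dye and pd.notna(row[dialect.dye]) else None
        if dye is not None and dye in dialect.ladder_dyes:
            continue
        size = pd.to_numeric(row[dialect.size], errors="coerce")
        height = pd.to_numeric(row[dialect.height], errors="coerce")
        if pd.isna(size) or pd.isna(height) or size <= 0 or height < 0:
            rejected.append(
                {"row": int(idx), "size": row[dialect.size], "height": row[dialect.height]}
            )
            continue
        area = None
        if has_area:
            a = pd.to_numeric(row[dialect.area], errors="coerce")
            area = None if pd.isna(a) else float(a)
        if not lo <= size <= hi:
            flagged.append({"row": int(idx), "size": float(size)})
        by_sample.setdefault(str(row[dialect.sample]), []).append(
            FragmentPeak(size_bp=float(size), height=float(height), area=area, dye=dye)
        )

    traces = [SampleTrace(sample_id=s, peaks=pk) for s, pk in by_sample.items()]
    if not traces:
        raise EmptyInputError(f"no parsable peak rows in {path}")
    return PeakTable(
        traces=traces,
        dialect=dialect,
        report={"rejected_rows": rejected, "out_of_range": flagged},
    )


def write_peak_table(
    table: PeakTable, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> Path:
    """Write a tab-delimited peak table readable by :func:`read_peak_table`.

    Missing areas are emitted as empty fields and re-read as absent.
    """
    if not table.traces:
        raise EmptyInputError("refusing to write an empty peak table")
    path = Path(path)
    rows = []
    for trace in table.traces:
        for p in trace.peaks:
            rows.append(
                {
                    dialect.sample: trace.sample_id,
                    dialect.dye or "Dye": p.dye if p.dye is not None else "B",
                    dialect.size: repr(p.size_bp),
                    dialect.height: repr(p.height),
                    dialect.area or "Area": "" if p.area is None else repr(p.area),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the CSV sample sheet and normalize its dtypes."""
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing column(s): {missing}")
    return sheet


def join_sample_sheet(
    table: PeakTable, sheet: pd.DataFrame | str | Path
) -> PeakTable:
    """Attach sample-sheet metadata to each trace.

    Samples present in the peak table but absent from the sheet are left
    unannotated and listed in ``report["orphans"]``; the join itself
    succeeds.  A duplicated sample_id in the sheet is an error.
    """
    if not isinstance(sheet, pd.DataFrame):
        sheet = read_sample_sheet(sheet)
    if sheet["sample_id"].duplicated().any():
        dupes = sorted(sheet.loc[sheet["sample_id"].duplicated(), "sample_id"])
        raise DuplicateKeyError(f"duplicate sample_id(s) in sheet: {dupes}")

    meta = sheet.set_index("sample_id")
    has_replicate = "replicate" in sheet.columns
    orphans: list[str] = []
    joined: list[SampleTrace] = []
    for trace in table.traces:
        if trace.sample_id not in meta.index:
            orphans.append(trace.sample_id)
            joined.append(trace)
            continue
        row = meta.loc[trace.sample_id]
        known = row["known_repeat"]
        days = row["timepoint_days"]
        joined.append(
            replace(
                trace,
                run_id=_opt_str(row["run_id"]),
                clone_id=_opt_str(row["clone_id"]),
                treatment=_opt_str(row["treatment"]),
                replicate=_opt_str(row["replicate"]) if has_replicate else None,
                timepoint_days=None if pd.isna(days) else float(days),
                is_baseline=bool(row["is_baseline"]),
                known_repeat=None if pd.isna(known) else float(known),
            )
        )
    report = dict(table.report)
    report["orphans"] = orphans
    return PeakTable(traces=joined, dialect=table.dialect, report=report)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return str(value)


def sample_sheet_frame(traces: Iterable[SampleTrace]) -> pd.DataFrame:
    """Render traces' metadata back into a sample-sheet DataFrame."""
    rows = []
    for t in traces:
        rows.append(
            {
                "sample_id": t.sample_id,
                "run_id": t.run_id,
                "clone_id": t.clone_id,
                "treatment": t.treatment,
                "replicate": t.replicate,
                "timepoint_days": t.timepoint_days,
                "is_baseline": t.is_baseline,
                "known_repeat": t.known_repeat,
            }
        )
    return pd.DataFrame(rows, columns=list(SHEET_COLUMNS) + ["replicate"])
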