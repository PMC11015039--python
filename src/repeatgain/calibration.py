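"""Per-run conversion of fragment sizes (bp) to repeat units.

Capillary sizing drifts between runs, so each run carries its own affine
map from bp to repeat number, fit by ordinary least squares on standards of
known repeat length (each standard anchored at its modal peak).  For a pure
CAG tract the true slope is 1/3 repeat per bp; fits far from that are
suspicious and trigger a warning.

Regression direction is ``repeat ~ bp`` so that application is a single
affine evaluation per peak.  Fractional repeat lengths are retained
throughout: the downstream weighted mean is a continuous statistic and
rounding would only discard information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, EmptyTraceError, RunMismatchError
from .peak_io import SampleTrace

__all__ = [
    "CalibrationModel",
    "RepeatTrace",
    "fit_calibration",
    "fit_all_runs",
    "apply_calibration",
    "invert_calibration",
    "calibration_report",
]

PLAUSIBLE_SLOPE = (0.25, 0.45)


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map repeat = intercept + slope * size_bp for one run."""

    run_id: str
    slope: float
    intercept: float
    n_standards: int
    residuals: tuple[float, ...]
    bp_span: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(
                f"run {self.run_id!r}: non-positive calibration slope {self.slope}"
            )

    def bp_to_repeat(self, size_bp):
        return self.intercept + self.slope * np.asarray(size_bp, dtype=float)

    def repeat_to_bp(self, repeat):
        return (np.asarray(repeat, dtype=float) - self.intercept) / self.slope


@dataclass
class RepeatTrace:
    """A sample trace on the repeat scale: (repeat_length, height) pairs.

    ``extrapolated`` marks traces with peaks converted outside the bp span
    of the run's calibration standards.
    """

    sample_id: str
    repeats: np.ndarray
    heights: np.ndarray
    run_id: str | None = None
    clone_id: str | None = None
    treatment: str | None = None
    replicate: str | None = None
    timepoint_days: float | None = None
    is_baseline: bool = False
    known_repeat: float | None = None
    extrapolated: bool = False
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.repeats = np.asarray(self.repeats, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        order = np.argsort(self.repeats, kind="stable")
        self.repeats = self.repeats[order]
        self.heights = self.heights[order]

    def __len__(self) -> int:
        return len(self.repeats)


def modal_peak_bp(trace: SampleTrace) -> tuple[float, float]:
    """Return (size_bp, height) of the trace's highest peak.

    Ties are broken toward the smaller fragment size.
    """
    if not trace.peaks or all(p.height <= 0 for p in trace.peaks):
        raise EmptyTraceError(f"sample {trace.sample_id!r}: no peak with height > 0")
    best = trace.peaks[0]
    for p in trace.peaks:  # peaks sorted ascending by size, first max wins
        if p.height > best.height:
            best = p
    return best.size_bp, best.height


def fit_calibration(standards: Sequence[SampleTrace], run_id: str) -> CalibrationModel:
    """OLS fit of known repeat length on the standards' modal-peak bp size.

    Requires at least two standards with distinct known repeats and
    distinct modal sizes.  Noiseless affine standards are recovered
    exactly (up to floating point).
    """
    standards = [t for t in standards if t.known_repeat is not None]
    if len(standards) < 2:
        raise CalibrationError(
            f"run {run_id!r}: need >=2 standards with known_repeat, "
            f"got {len(standards)}"
        )
    bp = np.array([modal_peak_bp(t)[0] for t in standards], dtype=float)
    rep = np.array([t.known_repeat for t in standards], dtype=float)
    if len(set(rep)) < 2 or np.ptp(bp) == 0:
        raise CalibrationError(
            f"run {run_id!r}: standards are collinear/degenerate "
            f"(repeats {sorted(set(rep))}, bp spread {np.ptp(bp)})"
        )
    # OLS of repeat on bp via the normal equations on centered data:
    # exact for 2 points and numerically stable for small designs.
    bpc = bp - bp.mean()
    slope = float(bpc @ (rep - rep.mean()) / (bpc @ bpc))
    intercept = float(rep.mean() - slope * bp.mean())
    residuals = tuple(float(r) for r in rep - (intercept + slope * bp))
    if not PLAUSIBLE_SLOPE[0] - 1e-9 <= slope <= PLAUSIBLE_SLOPE[1] + 1e-9:
        warnings.warn(
            f"run {run_id!r}: calibration slope {slope:.4f} outside the "
            f"plausible CAG range {PLAUSIBLE_SLOPE} (expect ~1/3 repeat/bp)",
            stacklevel=2,
        )
    return CalibrationModel(
        run_id=run_id,
        slope=slope,
        intercept=intercept,
        n_standards=len(standards),
        residuals=residuals,
        bp_span=(float(bp.min()), float(bp.max())),
    )


def fit_all_runs(traces: Iterable[SampleTrace]) -> dict[str, CalibrationModel]:
    """Fit one calibration per run from the standards in a trace collection."""
    by_run: dict[str, list[SampleTrace]] = {}
    for t in traces:
        if t.known_repeat is not None and t.run_id is not None:
            by_run.setdefault(t.run_id, []).append(t)
    return {run: fit_calibration(stds, run) for run, stds in sorted(by_run.items())}


def apply_calibration(
    model: CalibrationModel, trace: SampleTrace, force: bool = False
) -> RepeatTrace:
    """Convert a trace's peak sizes to repeat units.

    Refuses cross-run application unless ``force`` is set (borrowing a
    pooled model for a run without standards is an explicit act, not a
    silent default).  Heights are unchanged; extrapolation beyond the
    standards' bp span is flagged on the result.
    """
    if trace.run_id is not None and trace.run_id != model.run_id and not force:
        raise RunMismatchError(
            f"model for run {model.run_id!r} applied to trace "
            f"{trace.sample_id!r} from run {trace.run_id!r} (use force=True)"
        )
    bp = np.array([p.size_bp for p in trace.peaks], dtype=float)
    heights = np.array([p.height for p in trace.peaks], dtype=float)
    lo, hi = model.bp_span
    return RepeatTrace(
        sample_id=trace.sample_id,
        repeats=model.bp_to_repeat(bp),
        heights=heights,
        run_id=trace.run_id,
        clone_id=trace.clone_id,
        treatment=trace.treatment,
        replicate=trace.replicate,
        timepoint_days=trace.timepoint_days,
        is_baseline=trace.is_baseline,
        known_repeat=trace.known_repeat,
        extrapolated=bool(bp.size and ((bp < lo).any() or (bp > hi).any())),
    )


def invert_calibration(model: CalibrationModel, repeat_trace: RepeatTrace) -> np.ndarray:
    """Map a repeat trace's positions back to bp (affine inverse)."""
    return model.repeat_to_bp(repeat_trace.repeats)


def calibration_report(
    models: dict[str, CalibrationModel], path: str | Path | None = None
) -> pd.DataFrame:
    """Tabulate per-run fits; optionally write the table as CSV."""
    df = pd.DataFrame(
        [
            {
                "run_id": m.run_id,
                "slope": m.slope,
                "intercept": m.intercept,
                "n_standards": m.n_standards,
                "max_abs_residual": max((abs(r) for r in m.residuals), default=0.0),
            }
            for m in models.values()
        ]
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
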