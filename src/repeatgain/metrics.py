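"""Height-weighted somatic-instability metrics for repeat traces.

The metric chain per sample: identify the modal peak (highest signal),
restrict to a window of +/-40 repeat units around it with a height floor of
5% of the modal height, then take the peak-height-weighted arithmetic mean
of the repeat lengths.  Per lineage (clone x treatment x replicate), the
average repeat gain of each timepoint is its weighted mean minus the
lineage's day-0 weighted mean, and the repeat gain per week is the slope of
a through-origin regression of gain on elapsed weeks,
``slope = sum(t*g) / sum(t^2)`` — which for a single timepoint reduces to
gain divided by weeks.

All arithmetic stays on the continuous repeat scale; peaks are never binned
to integer repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import RepeatTrace
from .errors import (
    DegenerateDesignError,
    DegenerateWeightError,
    EmptyTraceError,
    PairingError,
)

__all__ = [
    "MetricsConfig",
    "InstabilityResult",
    "call_modal_peak",
    "filter_window_threshold",
    "weighted_mean_repeat",
    "average_repeat_gain",
    "gain_per_week",
    "analyze_timecourse",
    "detrend_signal_bias",
]

DEFAULT_LINEAGE_KEY = ("clone_id", "treatment", "replicate")


@dataclass(frozen=True)
class MetricsConfig:
    """Window/threshold constants of the instability metric.

    window_repeats: half-width of the analysis window in repeat units.
    height_threshold_frac: height floor as a fraction of the modal height
        (inclusive comparison).
    week_days: days per week used to convert timepoints.
    """

    window_repeats: float = 40.0
    height_threshold_frac: float = 0.05
    week_days: float = 7.0

    def __post_init__(self) -> None:
        if not self.window_repeats > 0:
            raise ValueError("window_repeats must be positive")
        if not 0 <= self.height_threshold_frac < 1:
            raise ValueError("height_threshold_frac must be in [0, 1)")


@dataclass
class InstabilityResult:
    """Per-sample instability metrics (gain_per_week is lineage-level)."""

    sample_id: str
    modal_repeat: float
    modal_height: float
    weighted_mean_repeat: float
    n_peaks_used: int
    average_repeat_gain: float | None = None
    weeks: float | None = None
    gain_per_week: float | None = None


def call_modal_peak(trace: RepeatTrace) -> tuple[float, float]:
    """Return (modal_repeat, modal_height): the peak of maximum height.

    Ties break toward the smaller repeat length.
    """
    if len(trace) == 0 or not (trace.heights > 0).any():
        raise EmptyTraceError(
            f"sample {trace.sample_id!r}: no peak with positive height"
        )
    # repeats are sorted ascending, argmax returns the first maximum
    i = int(np.argmax(trace.heights))
    return float(trace.repeats[i]), float(trace.heights[i])


def filter_window_threshold(
    trace: RepeatTrace,
    modal: tuple[float, float],
    cfg: MetricsConfig = MetricsConfig(),
) -> RepeatTrace:
    """Restrict a trace to the modal-anchored window and height floor.

    Keeps peaks with |repeat - modal_repeat| <= window AND
    height >= height_threshold_frac * modal_height (both inclusive).  The
    modal peak itself always survives, so the result is never empty.
    """
    modal_repeat, modal_height = modal
    keep = (np.abs(trace.repeats - modal_repeat) <= cfg.window_repeats) & (
        trace.heights >= cfg.height_threshold_frac * modal_height
    )
    keep |= (trace.repeats == modal_repeat) & (trace.heights == modal_height)
    return replace(trace, repeats=trace.repeats[keep], heights=trace.heights[keep])


def weighted_mean_repeat(trace: RepeatTrace) -> float:
    """Peak-height-weighted arithmetic mean of repeat length."""
    total = trace.heights.sum()
    if not total > 0:
        raise DegenerateWeightError(
            f"sample {trace.sample_id!r}: total peak height is zero"
        )
    return float((trace.repeats * trace.heights).sum() / total)


def average_repeat_gain(sample_mean: float, baseline_mean: float) -> float:
    """Weighted mean repeat minus the lineage's day-0 weighted mean."""
    return sample_mean - baseline_mean


def gain_per_week(points: Sequence[tuple[float, float]]) -> float:
    """Through-origin slope of average repeat gain on elapsed weeks.

    ``slope = sum(t*g) / sum(t^2)`` over all points; week-0 points
    contribute nothing and a single positive-week point gives g/t.
    """
    t = np.array([p[0] for p in points], dtype=float)
    g = np.array([p[1] for p in points], dtype=float)
    denom = (t * t).sum()
    if not denom > 0:
        raise DegenerateDesignError("all points at week 0: slope undefined")
    return float((t * g).sum() / denom)


def sample_metrics(trace: RepeatTrace, cfg: MetricsConfig = MetricsConfig()) -> InstabilityResult:
    """Modal call, window/threshold filter and weighted mean for one sample."""
    modal = call_modal_peak(trace)
    filtered = filter_window_threshold(trace, modal, cfg)
    return InstabilityResult(
        sample_id=trace.sample_id,
        modal_repeat=modal[0],
        modal_height=modal[1],
        weighted_mean_repeat=weighted_mean_repeat(filtered),
        n_peaks_used=len(filtered),
    )


def analyze_timecourse(
    traces: Iterable[RepeatTrace],
    cfg: MetricsConfig = MetricsConfig(),
    lineage_key: Sequence[str] = DEFAULT_LINEAGE_KEY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full metric chain over a timecourse of calibrated traces.

    Returns ``(samples, lineages)``: a tidy per-sample table (modal repeat,
    weighted mean, average repeat gain, weeks) and a per-lineage table with
    the through-origin gain per week.  Calibration standards (traces with
    ``known_repeat`` set) are excluded from lineage analysis.  Multiple
    day-0 replicates within a lineage are averaged into one baseline mean.
    A lineage without any baseline sample is a pairing error; a lineage
    with only baselines gets a warning and no slope.
    """
    traces = [t for t in traces if t.known_repeat is None]
    rows = []
    for t in traces:
        res = sample_metrics(t, cfg)
        key = tuple(getattr(t, k) for k in lineage_key)
        rows.append(
            {
                "sample_id": t.sample_id,
                **dict(zip(lineage_key, key)),
                "timepoint_days": t.timepoint_days,
                "is_baseline": t.is_baseline,
                "modal_repeat": res.modal_repeat,
                "modal_height": res.modal_height,
                "weighted_mean_repeat": res.weighted_mean_repeat,
                "n_peaks_used": res.n_peaks_used,
            }
        )
    samples = pd.DataFrame(rows).sort_values("sample_id", kind="stable").reset_index(drop=True)
    if samples.empty:
        raise EmptyTraceError("no analyzable (non-standard) traces")

    samples["weeks"] = samples["timepoint_days"] / cfg.week_days
    gains = []
    lineage_rows = []
    for key, grp in samples.groupby(list(lineage_key), dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        base = grp[grp["is_baseline"]]
        if base.empty:
            raise PairingError(f"lineage {dict(zip(lineage_key, key))}: no baseline sample")
        baseline_mean = float(base["weighted_mean_repeat"].mean())
        gain = grp["weighted_mean_repeat"] - baseline_mean
        gains.append(pd.Series(gain, index=grp.index))
        later = grp[~grp["is_baseline"]]
        lineage = dict(zip(lineage_key, key))
        lineage["baseline_mean_repeat"] = baseline_mean
        lineage["n_timepoints"] = int(later["timepoint_days"].nunique())
        if later.empty or not (later["weeks"] > 0).any():
            warnings.warn(
                f"lineage {dict(zip(lineage_key, key))}: only day-0 samples, "
                "gain_per_week not estimable",
                stacklevel=2,
            )
            lineage["gain_per_week"] = np.nan
        else:
            pts = list(zip(grp["weeks"], gain))
            lineage["gain_per_week"] = gain_per_week(pts)
        lineage_rows.append(lineage)

    samples["average_repeat_gain"] = pd.concat(gains).sort_index()
    lineages = pd.DataFrame(lineage_rows)
    return samples, lineages


def detrend_signal_bias(trace: RepeatTrace, slope_per_bp: float, bp_per_repeat: float = 3.0,
                        offset_bp: float = 0.0) -> RepeatTrace:
    """Undo a linear size-dependent signal loss (optional plumbing, off by
    default in the pipeline).

    Raw capillary traces lose signal with increasing fragment size; the
    instrument software normally corrects this before export.  When heights
    were exported uncorrected, dividing by ``1 - slope_per_bp * size_bp``
    restores a flat response.  ``size_bp`` is reconstructed from the repeat
    scale as ``offset_bp + bp_per_repeat * repeat``.
    """
    size_bp = offset_bp + bp_per_repeat * trace.repeats
    factor = 1.0 - slope_per_bp * size_bp
    if (factor <= 0).any():
        raise ValueError("bias slope implies non-positive response in range")
    return replace(trace, repeats=trace.repeats, heights=trace.heights / factor)
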