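"""End-to-end glue: peak table -> calibration -> instability metrics.

One call takes an annotated peak table (e.g. straight from
:func:`repeatgain.simulate.simulate_timecourse` or from
``read_peak_table`` + ``join_sample_sheet``), fits one calibration per run
from the standards it contains, converts every non-standard trace to the
repeat scale, and runs the windowed weighted-mean / repeat-gain analysis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, apply_calibration, fit_all_runs
from .errors import CalibrationError
from .metrics import DEFAULT_LINEAGE_KEY, MetricsConfig, analyze_timecourse
from .peak_io import PeakTable

__all__ = ["run_instability_pipeline", "has_two_modes"]


def run_instability_pipeline(
    table: PeakTable,
    cfg: MetricsConfig = MetricsConfig(),
    lineage_key: Sequence[str] = DEFAULT_LINEAGE_KEY,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, CalibrationModel]]:
    """Calibrate per run and compute instability metrics per sample/lineage.

    Returns (samples, lineages, calibration models).  Every run referenced
    by a non-standard trace must contribute standards.
    """
    models = fit_all_runs(table)
    repeat_traces = []
    for trace in table:
        if trace.known_repeat is not None:
            continue
        if trace.run_id not in models:
            raise CalibrationError(
                f"run {trace.run_id!r} (sample {trace.sample_id!r}) has no "
                "calibration standards"
            )
        repeat_traces.append(apply_calibration(models[trace.run_id], trace))
    samples, lineages = analyze_timecourse(repeat_traces, cfg, lineage_key)
    return samples, lineages, models


def has_two_modes(
    positions: np.ndarray,
    heights: np.ndarray,
    min_separation: float = 4.0,
    smooth: int = 3,
    min_mode_frac: float = 0.05,
) -> bool:
    """Detect a bimodal peak profile with a strict interior dip.

    After a light moving-average smoothing, the two tallest local maxima at
    least ``min_separation`` apart (both at least ``min_mode_frac`` of the
    global maximum) must bracket a strictly lower interior local minimum.
    Used to flag mixture phenotypes (e.g. heterogeneously edited pools)
    in rendered traces.
    """
    order = np.argsort(positions)
    x = np.asarray(positions, dtype=float)[order]
    h = np.asarray(heights, dtype=float)[order]
    if len(h) < 3:
        return False
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        h = np.convolve(h, kernel, mode="same")
    is_max = np.r_[False, (h[1:-1] >= h[:-2]) & (h[1:-1] > h[2:]), False]
    peaks = np.flatnonzero(is_max)
    peaks = peaks[h[peaks] >= min_mode_frac * h.max()]
    if len(peaks) < 2:
        return False
    # two tallest admissible modes, separated enough
    peaks = peaks[np.argsort(h[peaks])][::-1]
    first = peaks[0]
    for second in peaks[1:]:
        if abs(x[second] - x[first]) >= min_separation:
            lo, hi = sorted((first, second))
            dip = h[lo + 1 : hi].min() if hi > lo + 1 else np.inf
            return bool(dip < h[lo] and dip < h[hi])
    return False
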