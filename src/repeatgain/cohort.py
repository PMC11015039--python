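"""Clone-wise vehicle normalization and treatment contrasts.

Expansion rates differ systematically between clones, so treated lineages
are expressed relative to the mean vehicle (DMSO) rate of their own clone
before any cross-clone comparison.  Group contrasts are plain two-sample
Welch t-tests with t-based 95% intervals, on the difference scale or (via a
log transform of positive values) the fold-change scale.  This is a
deliberately simple summary: no mixed-effects or marginal-effects
machinery, and no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationError, SampleSizeError, ScaleError

__all__ = [
    "ContrastResult",
    "normalize_to_vehicle",
    "compare_groups",
    "summarize_group",
]


@dataclass(frozen=True)
class ContrastResult:
    """A two-group contrast: estimate with 95% CI and Welch p-value."""

    group_a: str
    group_b: str
    scale: str  # "difference" | "ratio"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int


def normalize_to_vehicle(
    lineages: pd.DataFrame,
    vehicle_label: str = "DMSO",
    clone_col: str = "clone_id",
    treatment_col: str = "treatment",
    value_col: str = "gain_per_week",
    out_col: str = "relative_gain_per_week",
) -> pd.DataFrame:
    """Divide each lineage's rate by its clone's mean vehicle rate.

    Vehicle rows average to 1 within each clone by construction.  A clone
    without vehicle replicates, or with a zero vehicle mean, cannot be
    normalized and raises naming the clone.
    """
    out = lineages.copy()
    out[out_col] = np.nan
    for clone, grp in out.groupby(clone_col, dropna=False):
        vehicle = grp.loc[grp[treatment_col] == vehicle_label, value_col]
        if vehicle.empty:
            raise NormalizationError(
                f"clone {clone!r} has no {vehicle_label!r} replicate to normalize against"
            )
        vmean = float(vehicle.mean())
        if vmean == 0 or np.isnan(vmean):
            raise NormalizationError(
                f"clone {clone!r}: vehicle mean rate is {vmean}, normalization degenerate"
            )
        out.loc[grp.index, out_col] = grp[value_col] / vmean
    return out


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    """Welch statistic pieces: (mean diff, se, satterthwaite df, p)."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = np.sqrt(va / na + vb / nb)
    diff = a.mean() - b.mean()
    if se == 0:
        # identical constant groups: no evidence of difference
        return float(diff), 0.0, float(na + nb - 2), 1.0 if diff == 0 else 0.0
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2 * stats.t.sf(abs(diff / se), df)
    return float(diff), float(se), float(df), float(p)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    scale: str = "difference",
    label_a: str = "a",
    label_b: str = "b",
    conf: float = 0.95,
) -> ContrastResult:
    """Two-tailed Welch t-test contrast of two groups of rates.

    On the ``ratio`` scale the test and CI are computed on log-transformed
    values (positive values required) and back-transformed, so the estimate
    is the geometric-mean fold change and ratio(a, b) == 1 / ratio(b, a)
    with an identical p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError(f"need n >= 2 per group, got {len(a)} and {len(b)}")
    if scale == "ratio":
        if (a <= 0).any() or (b <= 0).any():
            raise ScaleError("ratio scale requires strictly positive values")
        diff, se, df, p = _welch(np.log(a), np.log(b))
        tcrit = stats.t.ppf(0.5 + conf / 2, df) if se > 0 else 0.0
        est, lo, hi = np.exp(diff), np.exp(diff - tcrit * se), np.exp(diff + tcrit * se)
    elif scale == "difference":
        diff, se, df, p = _welch(a, b)
        tcrit = stats.t.ppf(0.5 + conf / 2, df) if se > 0 else 0.0
        est, lo, hi = diff, diff - tcrit * se, diff + tcrit * se
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return ContrastResult(
        group_a=label_a,
        group_b=label_b,
        scale=scale,
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        n_a=len(a),
        n_b=len(b),
    )


def summarize_group(values: Sequence[float], conf: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mean and t-based confidence interval of one group."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise SampleSizeError(f"need n >= 2, got {len(x)}")
    mean = float(x.mean())
    sem = x.std(ddof=1) / np.sqrt(len(x))
    if sem == 0:
        return mean, (mean, mean)
    half = stats.t.ppf(0.5 + conf / 2, len(x) - 1) * sem
    return mean, (mean - float(half), mean + float(half))


def contrast_table(contrasts: Sequence[ContrastResult]) -> pd.DataFrame:
    """Render contrast results as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame([c.__dict__ for c in contrasts])
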