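"""Instability metrics: modal call, filter, weighted mean, gain, slope."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repeatgain.calibration import RepeatTrace
from repeatgain.errors import (
    DegenerateDesignError,
    EmptyTraceError,
    PairingError,
)
from repeatgain.metrics import (
    MetricsConfig,
    analyze_timecourse,
    average_repeat_gain,
    call_modal_peak,
    detrend_signal_bias,
    filter_window_threshold,
    gain_per_week,
    weighted_mean_repeat,
)


def trace(pairs, sample_id="t", **meta):
    reps, hts = zip(*pairs)
    return RepeatTrace(sample_id=sample_id, repeats=reps, heights=hts, **meta)


class TestModalPeak:
    def test_returns_highest_peak(self):
        assert call_modal_peak(trace([(113, 100), (115, 900), (117, 300)])) == (115, 900)

    def test_tie_breaks_toward_smaller_repeat(self):
        assert call_modal_peak(trace([(110, 500), (118, 500)])) == (110, 500)

    def test_all_zero_heights_is_empty_trace(self):
        with pytest.raises(EmptyTraceError):
            call_modal_peak(trace([(110, 0.0), (115, 0.0)]))


class TestWindowThreshold:
    def test_worked_example(self):
        t = trace([(74, 600), (90, 49), (90.5, 50), (115, 1000), (155, 60)])
        out = filter_window_threshold(t, (115, 1000), MetricsConfig())
        kept = set(zip(out.repeats, out.heights))
        # outside [75, 155] dropped; below 50 RFU dropped; boundaries kept
        assert kept == {(90.5, 50.0), (115.0, 1000.0), (155.0, 60.0)}

    def test_threshold_zero_and_huge_window_is_identity(self):
        t = trace([(10, 1), (115, 1000), (900, 2)])
        cfg = MetricsConfig(window_repeats=1e9, height_threshold_frac=0.0)
        out = filter_window_threshold(t, (115, 1000), cfg)
        assert len(out) == len(t)

    def test_modal_peak_always_retained(self):
        t = trace([(115, 5.0)])
        out = filter_window_threshold(t, (115, 5.0), MetricsConfig())
        assert len(out) == 1

    @given(
        st.lists(
            st.tuples(st.floats(50, 200), st.floats(0.1, 1000)),
            min_size=1,
            max_size=20,
        ),
        st.floats(0, 0.5),
        st.floats(0, 0.49),
    )
    def test_raising_threshold_never_keeps_more(self, pairs, frac_lo, frac_extra):
        t = trace(pairs)
        modal = call_modal_peak(t)
        lo = filter_window_threshold(t, modal, MetricsConfig(height_threshold_frac=frac_lo))
        hi = filter_window_threshold(
            t, modal, MetricsConfig(height_threshold_frac=min(frac_lo + frac_extra, 0.99))
        )
        assert len(hi) <= len(lo)


class TestWeightedMean:
    def test_hand_summed_example(self, tiny_trace):
        # sum(r*h) = 230300, sum(h) = 2000
        assert weighted_mean_repeat(tiny_trace) == pytest.approx(115.15, abs=1e-12)

    def test_symmetric_heights_give_center(self):
        assert weighted_mean_repeat(trace([(100, 1), (101, 2), (102, 1)])) == 101.0

    def test_single_peak_identity(self):
        assert weighted_mean_repeat(trace([(115, 7.0)])) == 115.0

    def test_scale_invariance(self, tiny_trace):
        scaled = RepeatTrace("s", tiny_trace.repeats, tiny_trace.heights * 37.5)
        assert weighted_mean_repeat(scaled) == pytest.approx(
            weighted_mean_repeat(tiny_trace), abs=1e-12
        )

    def test_mean_stays_inside_window(self, rng):
        cfg = MetricsConfig()
        for _ in range(200):
            n = rng.integers(1, 15)
            t = trace(
                list(zip(rng.uniform(60, 180, n), rng.uniform(0.1, 1000, n))),
            )
            modal = call_modal_peak(t)
            f = filter_window_threshold(t, modal, cfg)
            wm = weighted_mean_repeat(f)
            assert modal[0] - cfg.window_repeats <= wm <= modal[0] + cfg.window_repeats


class TestGain:
    def test_difference(self):
        assert average_repeat_gain(117.4, 115.15) == pytest.approx(2.25)

    def test_through_origin_slope_closed_form(self):
        assert gain_per_week([(0, 0), (2, 1.8), (4, 4.2)]) == pytest.approx(1.02)

    def test_single_timepoint_divides_gain_by_weeks(self):
        assert gain_per_week([(2.0, 3.0)]) == pytest.approx(1.5)

    def test_exactly_linear_data_recovered(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert gain_per_week(list(zip(t, 1.34 * t))) == pytest.approx(1.34, abs=1e-12)

    def test_all_week_zero_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            gain_per_week([(0.0, 0.0), (0.0, 0.1)])


def lineage_traces(drift, days=(0, 7, 14, 21, 28), **meta):
    """Noiseless single-allele lineage expanding by `drift` repeats/week."""
    out = []
    for d in days:
        r = 115 + drift * d / 7
        out.append(
            trace(
                [(r - 1, 100), (r, 1000), (r + 1, 100)],
                sample_id=f"s.d{d}",
                clone_id="c1",
                treatment="DMSO",
                replicate="r1",
                timepoint_days=float(d),
                is_baseline=(d == 0),
                **meta,
            )
        )
    return out


class TestTimecourse:
    def test_noiseless_drift_recovered_exactly(self):
        samples, lineages = analyze_timecourse(lineage_traces(1.0))
        assert lineages.loc[0, "gain_per_week"] == pytest.approx(1.0, abs=1e-9)
        base = samples[samples["is_baseline"]]
        assert (base["average_repeat_gain"] == 0).all()

    def test_input_order_does_not_matter(self):
        traces = lineage_traces(0.7)
        a = analyze_timecourse(traces)[1]
        b = analyze_timecourse(traces[::-1])[1]
        pd.testing.assert_frame_equal(a, b)

    def test_missing_baseline_is_pairing_error(self):
        traces = [t for t in lineage_traces(1.0) if not t.is_baseline]
        with pytest.raises(PairingError, match="c1"):
            analyze_timecourse(traces)

    def test_multiple_baselines_averaged(self):
        traces = lineage_traces(1.0)
        extra = trace(
            [(115.2, 1000)],
            sample_id="s.d0b",
            clone_id="c1",
            treatment="DMSO",
            replicate="r1",
            timepoint_days=0.0,
            is_baseline=True,
        )
        samples, _ = analyze_timecourse(traces + [extra])
        base_mean = samples[samples["is_baseline"]]["weighted_mean_repeat"].mean()
        wk1 = samples[samples["timepoint_days"] == 7.0]
        assert wk1["average_repeat_gain"].iloc[0] == pytest.approx(
            wk1["weighted_mean_repeat"].iloc[0] - base_mean
        )

    def test_baseline_only_lineage_warns_and_has_no_slope(self):
        traces = [t for t in lineage_traces(1.0) if t.is_baseline]
        with pytest.warns(UserWarning, match="day-0"):
            _, lineages = analyze_timecourse(traces)
        assert np.isnan(lineages.loc[0, "gain_per_week"])

    def test_standards_excluded_from_lineage_analysis(self):
        traces = lineage_traces(1.0)
        std = trace([(100, 1000)], sample_id="std1", known_repeat=100.0)
        samples, _ = analyze_timecourse(traces + [std])
        assert "std1" not in set(samples["sample_id"])


def test_detrend_undoes_linear_signal_loss():
    r = np.array([100.0, 120.0, 140.0])
    flat = trace(list(zip(r, [500.0, 500.0, 500.0])))
    size_bp = 79 + 3 * r
    biased = RepeatTrace("b", r, flat.heights * (1 - 0.0008 * size_bp))
    fixed = detrend_signal_bias(biased, 0.0008, bp_per_repeat=3.0, offset_bp=79.0)
    assert np.allclose(fixed.heights, 500.0)
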