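"""Synthetic repeat-instability data generator.

Emulates the raw material of a fragment-analysis instability experiment:
a population of repeat-containing molecules per culture well drifts over
weeks (each molecule taking integer expansion/contraction steps), and each
timepoint is rendered as a capillary-electrophoresis peak table with PCR
stutter, an optional size-dependent signal loss, multiplicative height
noise, sizing jitter, and noiseless known-repeat standards for per-run
calibration.

The generative model is a per-molecule Poisson-difference (Skellam) step:
over ``dt`` weeks a molecule gains ``Poisson(mu_gain * dt) -
Poisson(mu_loss * dt)`` repeats with ``mu_gain - mu_loss`` equal to the
component drift and ``mu_gain + mu_loss`` the per-week variance, so drift
and dispersion are controlled independently.  Trajectories are Markov in
weeks and fully deterministic given the seed.  A mixture of drift
components reproduces the bimodal length distributions seen in
heterogeneously edited pools.

Defaults mirror the engineered cell model the generator stands in for:
~115 starting repeats, drift near 1.3 repeats/week, a pure-CAG sizing of
3 bp/repeat, and minus-direction stutter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, RenderError
from .peak_io import FragmentPeak, PeakTable, SampleTrace, sample_sheet_frame

__all__ = [
    "SimulationConfig",
    "RepeatPopulation",
    "TimecourseDesign",
    "EditingTruth",
    "simulate_repeat_population",
    "render_peak_table",
    "simulate_timecourse",
    "simulate_editing_outcomes",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    drift_per_week is the expected repeat gain per molecule per week (may
    be negative); dispersion is the per-week variance of the molecular
    step (floored at |drift| so the Poisson-difference construction is
    well defined; 0 means a deterministic shift).  mixture, when set,
    is a list of (weight, drift) components replacing the single drift.
    stutter_ratio is the geometric per-step fraction for minus-direction
    PCR stutter peaks.  height_bias_slope is the fractional signal loss
    per bp of fragment size (0 emulates software-corrected exports).
    """

    n_molecules: int = 10_000
    initial_repeat: float = 115.0
    initial_sd: float = 1.0
    drift_per_week: float = 1.34
    dispersion: float = 3.0
    mixture: tuple[tuple[float, float], ...] | None = None
    stutter_ratio: float = 0.15
    plus_stutter_ratio: float = 0.0
    amplicon_offset_bp: float = 79.0
    bp_per_repeat: float = 3.0
    height_bias_slope: float = 0.0
    noise_sd: float = 0.1
    sizing_noise_sd_bp: float = 0.15
    height_scale: float = 10.0
    stutter_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ConfigError(f"n_molecules must be positive, got {self.n_molecules}")
        if not self.bp_per_repeat > 0:
            raise ConfigError("bp_per_repeat must be positive")
        if not 0 <= self.stutter_ratio < 1 or not 0 <= self.plus_stutter_ratio < 1:
            raise ConfigError("stutter ratios must be in [0, 1)")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.mixture is not None:
            w = sum(weight for weight, _ in self.mixture)
            if abs(w - 1.0) > 1e-9:
                raise ConfigError(f"mixture weights must sum to 1, got {w}")

    def components(self) -> tuple[tuple[float, float], ...]:
        if self.mixture is None:
            return ((1.0, self.drift_per_week),)
        return self.mixture


@dataclass
class RepeatPopulation:
    """Molecule counts by repeat length at one timepoint."""

    timepoint_days: float
    counts: dict[float, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def mean_repeat(self) -> float:
        return sum(r * c for r, c in self.counts.items()) / self.total


def _component_sizes(cfg: SimulationConfig) -> list[int]:
    """Deterministic molecule allocation across mixture components."""
    comps = cfg.components()
    sizes = [int(round(w * cfg.n_molecules)) for w, _ in comps]
    sizes[-1] += cfg.n_molecules - sum(sizes)
    return sizes


def _simulate(cfg: SimulationConfig, timepoints_days: Sequence[float],
              rng: np.random.Generator) -> list[RepeatPopulation]:
    days = sorted(float(d) for d in timepoints_days)
    if not days or days[0] != 0.0:
        raise ConfigError("timepoints must include day 0")
    comps = cfg.components()
    arrays = []
    for size in _component_sizes(cfg):
        if cfg.initial_sd > 0:
            init = cfg.initial_repeat + np.round(rng.normal(0.0, cfg.initial_sd, size))
        else:
            init = np.full(size, cfg.initial_repeat, dtype=float)
        arrays.append(init)
    pops = []
    prev_day = 0.0
    for day in days:
        dt = (day - prev_day) / 7.0
        if dt > 0:
            for arr, (_, drift) in zip(arrays, comps):
                if cfg.dispersion == 0:
                    arr += drift * dt
                else:
                    v = max(cfg.dispersion, abs(drift))
                    mu_gain = 0.5 * (v + drift) * dt
                    mu_loss = 0.5 * (v - drift) * dt
                    arr += rng.poisson(mu_gain, arr.size) - rng.poisson(mu_loss, arr.size)
        prev_day = day
        pooled = np.round(np.concatenate(arrays), 6)
        values, counts = np.unique(pooled, return_counts=True)
        pops.append(
            RepeatPopulation(
                timepoint_days=day,
                counts={float(v): int(c) for v, c in zip(values, counts)},
            )
        )
    return pops


def simulate_repeat_population(
    cfg: SimulationConfig, timepoints_days: Sequence[float]
) -> list[RepeatPopulation]:
    """Simulate the repeat-length distribution at each timepoint."""
    rng = np.random.default_rng(cfg.seed)
    return _simulate(cfg, timepoints_days, rng)


def _render_trace(
    pop: RepeatPopulation,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    **meta,
) -> SampleTrace:
    """Render one population as a stuttered, noisy peak trace."""
    heights: dict[float, float] = {}
    for r, c in sorted(pop.counts.items()):
        parent = c * cfg.height_scale
        heights[r] = heights.get(r, 0.0) + parent
        for ratio, sign in ((cfg.stutter_ratio, -1), (cfg.plus_stutter_ratio, +1)):
            if ratio <= 0:
                continue
            k, h = 1, parent * ratio
            while h >= cfg.stutter_floor:
                pos = r + sign * k
                heights[pos] = heights.get(pos, 0.0) + h
                k += 1
                h *= ratio
    peaks = []
    for r in sorted(heights):
        bp = cfg.amplicon_offset_bp + cfg.bp_per_repeat * r
        if cfg.sizing_noise_sd_bp > 0:
            bp += rng.normal(0.0, cfg.sizing_noise_sd_bp)
        h = heights[r] * max(0.0, 1.0 - cfg.height_bias_slope * bp)
        if cfg.noise_sd > 0:
            h *= np.exp(rng.normal(0.0, cfg.noise_sd))
        if h > 0 and bp > 0:
            peaks.append(FragmentPeak(size_bp=float(bp), height=float(h)))
    if not peaks:
        raise RenderError(
            f"sample {sample_id!r}: no positive-height peak rendered "
            "(height_bias_slope too steep?)"
        )
    return SampleTrace(sample_id=sample_id, peaks=peaks, **meta)


def _standard_traces(
    cfg: SimulationConfig, standards: Sequence[float], run_id: str | None
) -> list[SampleTrace]:
    out = []
    for kr in standards:
        out.append(
            SampleTrace(
                sample_id=f"STD.{run_id}.{kr:g}",
                peaks=[
                    FragmentPeak(
                        size_bp=cfg.amplicon_offset_bp + cfg.bp_per_repeat * kr,
                        height=1000.0,
                    )
                ],
                run_id=run_id,
                known_repeat=float(kr),
                timepoint_days=0.0,
            )
        )
    return out


def render_peak_table(
    populations: Sequence[RepeatPopulation],
    cfg: SimulationConfig,
    standards: Sequence[float] = (),
    rng: np.random.Generator | None = None,
    prefix: str = "S",
    run_id: str = "run1",
    **meta,
) -> PeakTable:
    """Render a population timecourse plus noiseless calibration standards.

    Each timepoint becomes one trace named ``{prefix}.d{day}``; standards
    become extra traces with ``known_repeat`` set.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    traces = []
    for pop in populations:
        traces.append(
            _render_trace(
                pop,
                cfg,
                rng,
                sample_id=f"{prefix}.d{pop.timepoint_days:g}",
                run_id=run_id,
                timepoint_days=pop.timepoint_days,
                is_baseline=pop.timepoint_days == 0,
                **meta,
            )
        )
    traces.extend(_standard_traces(cfg, standards, run_id))
    return PeakTable(traces=traces)


@dataclass(frozen=True)
class TimecourseDesign:
    """Plate layout: clones x treatments x replicates x timepoints.

    ``treatments`` maps a condition label to a multiplier applied to the
    configured drift (1.0 = vehicle).  All lineages share one capillary
    run with the listed calibration standards.
    """

    clones: tuple[str, ...] = ("clone1",)
    treatments: Mapping[str, float] = field(default_factory=lambda: {"DMSO": 1.0})
    n_replicates: int = 5
    timepoints_days: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0)
    standards: tuple[float, ...] = (100.0, 115.0)
    run_id: str = "run1"

    def __post_init__(self) -> None:
        if not self.clones or not self.treatments or self.n_replicates < 1:
            raise ConfigError("design must have >=1 clone, treatment and replicate")
        if 0.0 not in tuple(float(t) for t in self.timepoints_days):
            raise ConfigError("design timepoints must include day 0")


def simulate_timecourse(
    cfg: SimulationConfig, design: TimecourseDesign
) -> tuple[PeakTable, pd.DataFrame]:
    """Simulate and render a full experiment; returns analysis-ready inputs.

    One lineage per clone x treatment x replicate, each with its own
    reproducible random stream spawned from ``cfg.seed``.  Treatment
    multipliers scale the drift (every mixture component when a mixture is
    configured).  Returns the peak table (traces already annotated, plus
    per-run standards) and the matching sample sheet.
    """
    ss = np.random.SeedSequence(cfg.seed)
    lineages = [
        (clone, treatment, mult, rep)
        for clone in design.clones
        for treatment, mult in design.treatments.items()
        for rep in range(1, design.n_replicates + 1)
    ]
    children = ss.spawn(len(lineages))
    traces: list[SampleTrace] = []
    for (clone, treatment, mult, rep), child in zip(lineages, children):
        rng = np.random.default_rng(child)
        if cfg.mixture is not None:
            lineage_cfg = replace(
                cfg, mixture=tuple((w, d * mult) for w, d in cfg.mixture)
            )
        else:
            lineage_cfg = replace(cfg, drift_per_week=cfg.drift_per_week * mult)
        pops = _simulate(lineage_cfg, design.timepoints_days, rng)
        for pop in pops:
            traces.append(
                _render_trace(
                    pop,
                    lineage_cfg,
                    rng,
                    sample_id=f"{clone}.{treatment}.r{rep}.d{pop.timepoint_days:g}",
                    run_id=design.run_id,
                    clone_id=clone,
                    treatment=treatment,
                    replicate=f"r{rep}",
                    timepoint_days=pop.timepoint_days,
                    is_baseline=pop.timepoint_days == 0,
                )
            )
    traces.extend(_standard_traces(cfg, design.standards, design.run_id))
    table = PeakTable(traces=traces)
    sheet = sample_sheet_frame(traces)
    return table, sheet


@dataclass(frozen=True)
class EditingTruth:
    """Ground truth for one simulated CRISPR clone."""

    clone_id: str
    zygosity: str  # "homozygous" | "heterozygous"
    signatures: tuple[str, ...]

    def __post_init__(self) -> None:
        need = 1 if self.zygosity == "homozygous" else 2
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ConfigError(f"unknown zygosity {self.zygosity!r}")
        if len(self.signatures) < need:
            raise ConfigError(
                f"{self.zygosity} truth needs >= {need} signature(s)"
            )


def simulate_editing_outcomes(
    truths: Sequence[EditingTruth],
    error_rate: float = 0.02,
    n_reads: int = 10_000,
    seed: int | np.random.Generator = 0,
    n_noise_signatures: int = 3,
) -> pd.DataFrame:
    """Simulate amplicon-sequencing outcome tables for edited clones.

    A homozygous clone yields one dominant signature at fraction
    ``1 - error_rate``; a heterozygous clone two signatures near
    ``(1 - error_rate) / 2`` each.  The error mass is spread over spurious
    signatures and read counts are multinomial.
    """
    if not 0 <= error_rate <= 0.2:
        raise ConfigError("error_rate must be in [0, 0.2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for truth in truths:
        if truth.zygosity == "homozygous":
            real = [(truth.signatures[0], 1.0 - error_rate)]
        else:
            real = [
                (truth.signatures[0], (1.0 - error_rate) / 2),
                (truth.signatures[1], (1.0 - error_rate) / 2),
            ]
        noise = [
            (f"noise.{truth.clone_id}.{i}", error_rate / n_noise_signatures)
            for i in range(n_noise_signatures)
        ]
        sigs, probs = zip(*(real + noise))
        counts = (
            rng.multinomial(n_reads, probs)
            if error_rate > 0
            else np.array([int(round(p * n_reads)) for p in probs])
        )
        for sig, n in zip(sigs, counts):
            if n > 0:
                rows.append({"clone_id": truth.clone_id, "signature": sig, "reads": int(n)})
    return pd.DataFrame(rows)
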