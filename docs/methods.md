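# Methods

## The instability metric

The quantity of interest is the rate at which a population of repeat
tracts lengthens over time in culture. Each sample's fragment-analysis
trace is reduced to a single continuous statistic, the peak-height-
weighted mean repeat length, computed over a restricted peak set: peaks
within ±`window_repeats` (default 40) repeat units of the modal (highest)
peak that reach at least `height_threshold_frac` (default 0.05) of the
modal height. The window bounds and the height floor are both inclusive;
the modal peak always survives the filter, so the filtered trace is never
empty and the weighted mean is always defined. Modal ties break toward
the smaller repeat length, making the statistic deterministic under peak
reordering. The window is applied before the threshold; for this
modal-anchored rule the two commute in the retained set, the order only
affects intermediate bookkeeping.

Average repeat gain is the weighted mean minus the lineage's day-0
weighted mean; when a lineage has several day-0 replicates their
arithmetic mean is the baseline. Gain per week is the slope of a
regression through the origin of gain on elapsed weeks
(`weeks = timepoint_days / 7` exactly):

    slope = Σ tᵢ gᵢ / Σ tᵢ²

over all of the lineage's points. Week-0 points contribute zero to both
sums, so including them is harmless and done for explicitness; a single
positive-week point reduces the formula to g/t. The intercept is pinned
at zero because gain is zero at day 0 by construction.

Peaks are never rounded to integer repeats anywhere in the chain: the
calibration is affine and the weighted mean is a continuous statistic, so
rounding would only discard information.

## Calibration

Each capillary run carries its own affine map from fragment size (bp) to
repeat units, fit by OLS of known repeat length on the modal-peak size of
that run's standards (the modal peak is taken as the standard's nominal
allele). The regression direction is repeat ~ bp so that application is a
single affine evaluation per peak. At least two standards with distinct
repeats and distinct modal sizes are required; noiseless affine standards
are recovered to floating-point accuracy (the fit uses centered normal
equations, exact for two points). Slopes outside [0.25, 0.45] repeat/bp
trigger a warning since a pure CAG tract sizes at ~1/3 repeat/bp.
Conversion outside the standards' bp span is allowed but flagged as
extrapolation on the resulting trace. Cross-run application requires an
explicit `force`; runs without standards are refused rather than silently
borrowing a pooled model.

Raw (uncorrected) capillary exports lose signal with fragment size; the
pipeline assumes heights were bias-corrected by the instrument software.
An optional linear detrending operation (`detrend_signal_bias`) is
provided for uncorrected exports and is off by default.

## Treatment contrasts

Expansion rates differ systematically between clones, so each lineage's
gain per week is divided by the mean vehicle (DMSO) rate of its own clone
before cross-arm comparison; vehicle rows then average to 1 per clone.
Contrasts are two-sample Welch t-tests with t-based 95% intervals; on the
fold-change scale the test and interval are computed on logs and
back-transformed, which makes the contrast exactly symmetric under group
swap. This is a deliberate simplification relative to model-based
marginal-effect intervals: the point estimates agree, interval widths may
differ slightly, and no multiplicity correction is applied. The suite
verifies the contrast machinery by simulation: type-I error 0.05 ± 0.02
and CI coverage 95% ± 2% over 2000 draws.

## Zygosity rule

Amplicon outcomes are aggregated by indel signature (not full read
sequence), ranked by read fraction with lexicographic tie-breaks, and a
clone is called homozygous when top/(top + second) > 0.85 strictly.
Reference alleles are eligible for either top-two slot, so unedited and
monoallelically edited clones fall out of the same rule. A clone with a
single aggregated outcome is called homozygous (ratio 1.0) with a
low-complexity warning. The call is invariant to read-depth scaling.

## Splice screen

A junction's `position` is the 1-based coordinate of the intron-side base
adjacent to the exon–intron boundary; the mutagenesis window is the
`flank` (default 50) nt immediately on each side of the boundary, giving
2·flank covered positions and 3 SNVs per position, deduplicated across
overlapping windows and truncated at sequence ends. Minus-strand
junctions are handled by reverse-complementing the window, and the screen
is verified against brute-force position enumeration.

The shipped scorer is a position-weight-matrix model over consensus base
frequencies (9-mer donor: exonic −3..−1 + intronic +1..+6; 15-mer
acceptor: polypyrimidine tract, AG, first exonic base), with near-
invariant positions carrying pseudocounts. A site's summed log2-odds
against a uniform background is min–max normalized to [0, 1], so the
variant delta lies in [−1, 1] and the reverse mutation's delta is the
exact negation of the forward one. Variants with delta ≥ +0.1 are
classified sensitizing (predicted to enhance pseudoexon inclusion),
≤ −0.1 interfering; the 0.1 default is a package choice, exposed as a
parameter. The PWM scorer is a deliberately simple, fully transparent
model: it captures the canonical-site strength that dominates near-
junction variants but none of the longer-range context a trained splice
model sees, so its deltas rank variants rather than predict inclusion
probabilities. Common vs. rare variants split at MAF 1%. Exon novelty is
decided against GFF3 exon records with a coordinate tolerance (default
1 bp) on both boundaries. Event lists carrying a per-event type column
have intron-retention rows excluded before overlap analysis. Gene-set
overlap is row-normalized (|row ∩ col| / |row|), hence asymmetric with a
unit diagonal.

## Synthetic generator

The generator emulates a plate-based instability experiment on an
engineered line carrying ~115 CAG repeats. Each culture is a population
of `n_molecules` (default 10 000) repeat tracts; over `dt` weeks each
molecule steps by `Poisson(μ_gain·dt) − Poisson(μ_loss·dt)` with
`μ_gain − μ_loss` the drift (default 1.34 repeats/week, a realistic
unperturbed-culture rate) and `μ_gain + μ_loss` the per-week variance
(`dispersion`, default 3.0, floored at |drift| so the construction is
well defined; 0 gives a deterministic shift). Trajectories are Markov in
weeks and deterministic given the seed (lineages draw from independent
spawned streams). A mixture of (weight, drift) components models
heterogeneously edited pools; a 50/50 mix of non-expanding and
2-repeats/week components produces the characteristic bimodal length
distribution by week 6.

Rendering maps repeat r to `amplicon_offset_bp + bp_per_repeat·r`
(defaults 79 + 3r bp), adds a minus-direction geometric stutter ladder
(`stutter_ratio` default 0.15 — a placeholder magnitude, exposed in
config, since true stutter for 100+ CAG amplicons is not well
characterized), multiplies heights by an optional linear size bias
(default 0: corrected exports), applies lognormal height noise
(`noise_sd` 0.1) and Gaussian sizing jitter (0.15 bp), and emits
noiseless known-repeat standards (100 and 115 by default) per run.

What the generator does not emulate: mechanistic DNA-repair biochemistry,
transcription-coupled covariates, instrument saturation or pull-up
artifacts, inter-run sizing drift beyond the affine model, and real
stutter shape. Pipeline tests on this generator therefore demonstrate
correctness of the metric chain under the stated generative model — drift
recovery to ±0.15 repeats/week at study scale (10 000 molecules, 8
replicates, 4 weekly timepoints), stutter invariance of the estimated
rate to ±0.05, exact recovery in the noiseless limit — not robustness to
every artifact of real electropherograms.

## Numerical and design choices

- Modal calling happens on the calibrated repeat scale; since calibration
  is strictly increasing and affine, this choice only fixes units.
- Height threshold comparison is inclusive (≥), as is the window bound.
- Parsing rejects non-numeric peak rows with a per-row report rather than
  failing the file; sizes outside 50–1200 bp are flagged, not dropped;
  ladder-dye rows are removed.
- The analysis lineage key defaults to clone × treatment × replicate; the
  sample sheet may carry an optional `replicate` column.
- Welch p-values for identical constant groups are reported as 1.0 (no
  evidence of difference) rather than NaN.
- Problem sizes in the test suite and acceptance script (1000-set
  oracles, 2000-draw calibration simulations, 8-replicate study designs)
  were chosen to give comfortable statistical margins while keeping a
  full run in seconds.

## Known limitations

- The PWM splice scorer is a ranking tool, not a splicing predictor;
  swap in a stronger backend via the `score(sequence, junction)` contract
  for real predictions.
- Contrast intervals are plain t-based summaries, not model-based
  marginal effects.
- The expansion-index family of alternative instability metrics is out of
  scope; only the weighted-mean/gain chain is implemented.
- Raw `.fsa` parsing and ladder-based sizing are not implemented; the
  pipeline starts from sized peak exports.
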