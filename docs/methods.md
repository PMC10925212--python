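# Methods

This note documents the models and procedures implemented in
`oscipipe`, the defaults and why they were chosen, the numerical
decisions, and what the synthetic benchmarks do and do not demonstrate.

## Preprocessing and artifact rejection

The standard filter chain (`pipeline.preprocess_raw`) mean-centers the
recording, applies a zero-phase FIR low-pass at 40 Hz (10 Hz
transition), notch filters at the mains frequency and its harmonics,
resamples to 250 Hz, and high-passes at 0.5 Hz with a Kaiser-window FIR
(stop-band edge 0.25 Hz, 60 dB attenuation, 0.05 pass-band ripple).
These values are configuration, not derived quantities; all filtering is
forward-backward, so attenuations are effectively doubled and phase is
zero.

Gross artifacts are detected on a separate 1–40 Hz filtered copy in a
grid of channels × 3-s segments.  A cell is *major* above 500 µV
absolute ("exceeds X µV" is read as absolute value, not peak-to-peak),
*flat* at zero variance, and *minor* when its best absolute Pearson
correlation with the topological neighbors in the same segment is below
.3.  The maximum (not mean) over neighbors is used: one well-correlated
neighbor is enough to certify that a channel carries signal.

Resolution removes majors first — each by deleting the whole channel or
the whole segment, whichever destroys fewer clean cells, with ties going
to the segment because channels carry spatial information downstream.
Minors (including flats, where correlation is undefined) are then
removed greedily: at each step the candidate channel and candidate
segment with the most minor cells are compared by minors cleared per
clean cell destroyed, until every remaining channel and segment holds at
most 30% minor cells.  Each iteration removes at least one channel or
segment, so termination is guaranteed; on small grids the greedy
clean-data loss is compared against exhaustive search in the tests and
stays near the optimum (the greedy objective itself is a design choice —
the ordering is not uniquely determined by the constraint).

The component screen consumes externally computed decomposition
component spectra (the decomposition itself is out of scope), fits the
aperiodic model over 8–30 Hz, and rejects components with exponent
strictly below 0.5 — near-flat or upward-tilted spectra characteristic
of muscle and other non-physiological sources.  The comparison is
strict, so an exactly-0.5 exponent is kept, and the screen is monotone
in the exponent.

The final gate removes remaining cells still exceeding 140 µV and fails
the recording when more than 25 channels were removed or fewer than 60 s
of segments survive.

## Cycle-by-cycle burst detection

Narrowband decomposition uses zero-phase FIR band-passes in six
overlapping bands, 4 Hz wide and stepped by 2 Hz (2–6 … 12–16 Hz), with
a 1 Hz transition width.  Zero-crossings of the narrowband trace define
windows in which troughs and positive peaks are located in the broadband
trace; extremum times are refined by parabolic interpolation of the
three samples around the peak, giving sub-sample cycle periods.  A cycle
runs from positive peak to positive peak through the trough between
them; the number of cycles extracted from a clean tone equals its number
of positive peaks minus one (pseudo-crossings at the signal boundaries
make the first and last extremum usable).

The criteria the original method names are implemented with the
following formulas (the names are established; the formulas are this
package's decisions):

* `period_consistency_i` — min over existing neighbors *j* of
  `min(p_i, p_j) / max(p_i, p_j)`;
* `amplitude_consistency_i` — the same ratio on the mean of decay and
  rise amplitude;
* `flank_consistency_i` — `min(decay, rise) / max(decay, rise)`;
* `shape_consistency_i` — each cycle's broadband waveform resampled to
  100 points and z-scored; mean over neighbors of the positive part of
  the Pearson correlation;
* `monotonicity_time_i` — fraction of sample-to-sample steps moving in
  the flank's direction (zero steps count as consistent);
* `monotonicity_amplitude_i` — net directed change divided by total
  absolute change, averaged over the two flanks, floored at 0;
* `reversal_ratio_i` — one minus the largest counter-direction excursion
  relative to the flank amplitude, worst flank, floored at 0.

Edge cycles use their single existing neighbor; a lone cycle scores 0 on
the neighbor-based criteria (no consistency evidence); zero-amplitude
cycles score 0 on ratio-based criteria.  Every criterion is a ratio, so
the detected burst set is invariant under rescaling of the signal —
amplitude is never thresholded, by design, to avoid coupling amplitude
and density.

Three criteria sets are applied independently (thresholds pass at
equality): a many-criterion low-threshold set with minimum 4 cycles, a
fewer-criterion set with minimum 5, and a strict-monotonicity set with
minimum 3.  Runs are maximal sequences of consecutive passing cycles.
Bursts found by different sets or bands in one channel are merged when
they overlap in time within 1 Hz of frequency (union interval, united
cycles); union-then-merge maximizes sensitivity without double-counting
density.  Burst frequency is the inverse of the mean distance between
successive troughs.

The per-cycle frequency gate (`frequency_ok`) is strict: the sub-sample
period must lie inside the band.  Consequently a detected burst in the
12–16 Hz band can never be shorter than `min_cycles / 16` s — 187.5 ms
for the 3-cycle set — as a structural guarantee.  Cycles at the very
edge of a truncated burst are measured slightly fast (their outer peak
is biased inward by up to ~1 sample), so bursts injected at exactly
16 Hz sit astride the gate; the observed minimum over a frequency sweep
is ~192 ms, the bound plus this measurement excess.

## Oscillation measures

Measure bands are theta 4–7, alpha 8–11 and low beta 12–16 Hz with
inclusive edges and 1-Hz gaps between bands (frequencies in 7–8 and
11–12 Hz contribute to no band), plus the pooled 4–16 Hz range.
Amplitude is the mean trough-to-positive-peak voltage over every cycle
of every in-band burst and is NaN (not zero) when no burst exists.
Density is the summed burst duration as a percentage of the recording;
pooling sums durations across bands, so pooled density can exceed 100%
when bursts of different frequencies co-occur.

Clusters connect bursts whose overlap covers at least 50% of the shorter
one (inclusive) within 1 Hz; the relation is closed transitively via
connected components, cluster frequency is the duration-weighted mean of
member frequencies, and cluster density uses the union interval.
Per-channel measures use channel bursts (topographies); global measures
use clusters, so a burst visible on ten channels counts once.

## Spectral decomposition

Welch spectra use 4-s Hann windows with 50% overlap (0.25 Hz
resolution, minimum 8 s of data).  Smoothing is a centered moving
average of log10 power with 2 Hz support, shrinking symmetrically at the
endpoints (the kernel is a decision; log-power averaging keeps the
smoother linear in the quantity being fitted).

The aperiodic + peaks fit alternates, twice: fit a line to log-power
vs log-frequency, flatten, extract Gaussians iteratively (largest
residual first, fitted with bounded least squares, sigma within half of
the 0.5–12 Hz width limits) while the peak exceeds 2 standard deviations
of the flattened spectrum, jointly refit all Gaussians, subtract, and
robust-refit the line on the lowest-50%-residual points.  The second
pass removes the upward bias the peaks impose on the first line.  The
peak-threshold stop rule carries a 1e-9 log-power numerical floor so a
noiseless power law yields exactly zero peaks.  On noiseless analytic
spectra over exponent {0.5…2.5} × offset {−1, 0, 1}, recovery is exact
to ≈1e-15, and within 0.04 with an injected alpha peak.  `r_squared` and
`mae` score the full model on log power in the 2–35 Hz fit range.

Band log-power is the mean log10 power over 4–16 Hz; periodic power is
the same mean after subtracting the aperiodic line, hence invariant to a
constant log-power shift.

## Sleep slow waves

Sleep EEG is average-referenced and band-pass filtered 0.5–4 Hz with a
zero-phase Chebyshev type II design (stop-band edges 0.1 and 10 Hz,
40 dB stop-band attenuation).  The pass-band deviation is held to
0.2 dB: Chebyshev II keeps its ripple in the stop band, and the flat
pass band preserves in-band wave amplitudes to within ~1% — the
ripple/attenuation values are design choices, only the corner
frequencies being fixed requirements.

Slow waves are negative half-waves between a downward and the next
upward zero-crossing separated by 0.25–1 s, detected inside externally
supplied NREM intervals (sleep staging is out of scope).  Amplitude is
the depth of the most negative sample; the descending slope is
amplitude divided by the time from the downward zero-crossing to the
trough.

Amplitude matching pairs each first-hour wave with the unused last-hour
wave of closest amplitude (both lists sorted; greedy, without
replacement) when the relative difference is within tolerance.  The
default tolerance is 10%, chosen so overlapping realistic amplitude
distributions match roughly 60% of waves; the exact matching algorithm
is a design decision.  Matched amplitude distributions agree within
tolerance by construction, which is the mechanism that makes overnight
slope comparisons amplitude-independent; slope summaries are computed
over matched waves only and flagged undefined when no pairs exist.

## Statistics

The main model is
`measure ~ task + time*age + group + sex + (1|participant) +
(1|participant:session)`, with random intercepts for participant and
session nested in participant, fitted by REML through a standard
linear-mixed-model routine (a variance component implements the nested
intercept).  Reference levels are task = oddball, time = evening,
group = control, sex = female, so every categorical beta is a departure
from those baselines.  Reported statistics are Wald t = beta/SE with
residual degrees of freedom `n − rank(X)` and two-sided p-values; the
estimation method (REML vs ML) is a switch.  Rows with a missing
response are dropped per response.

Channel-wise models (`measure ~ time + task` plus the random
intercepts) are corrected across channels with Benjamini–Hochberg FDR
at q = .05; failed channel fits are flagged missing and excluded from
the correction count.  Age correlations restrict to one task, average a
participant's sessions within each time of day, and report r for
evening, morning, and the morning-minus-evening change (averaging within
time before differencing is a decision; the alternative ordering is
ambiguous).  Cross-measure models follow the same conventions with a
second measure as predictor, optionally without the session intercept
for one-session-per-participant designs.

## Synthetic data: what it emulates, and what it does not

The background generator shapes a random-phase spectrum to the target
one-sided PSD `10^offset / f^exponent` and inverse-transforms, per
channel, mixing in a common component so the expected pairwise channel
correlation is `channel_correlation` (default 0.6) — volume conduction
makes real neighboring channels strongly correlated, and fully
independent channels would look like bad electrodes to the artifact
heuristics.  The mixing leaves each channel's PSD on target; the Welch
spectrum of generated background matches the analytic target within a
0.1 median absolute log10-power error over 2–35 Hz.

Bursts are superposed (not spliced) onto the background, preserving the
aperiodic statistics underneath — the additive periodic + aperiodic
model.  Burst waveforms run from positive peak to positive peak
inclusive, with an optional rise-time asymmetry and an optional
single-cycle linear taper (off by default, since tapering degrades
amplitude consistency at the edges in ways the detection criteria do not
model).  Truth tables record one row per (burst, channel); overlapping
same-channel bursts within 1 Hz are merged with a warning.

Slow waves are two half-sine segments joined at the trough, so
amplitude and descending slope are analytic
(`slope = amplitude / falling_time`).  Hann-shaped positive up-state
lobes of half the wave duration flank the deflection, with amplitudes
solved so the waveform has zero area and zero first time-moment; its
spectrum then vanishes quadratically at DC and the detector's band-pass
preserves the trough.  Waves are placed with a zero-sum spatial pattern
(+1 on the target channel, −1/(C−1) elsewhere), emulating the zero-mean
topography of a referenced source, so average re-referencing leaves the
target waveform intact; the mirrored deflection on other channels is a
known artifact of this pattern and is small for ≥8 channels.  The
canonical wave population has half-wave durations of 0.44–0.50 s (a ~1 Hz
slow oscillation); outside that range an isolated half-wave's spectrum
spills past the 0.5–4 Hz passband and the detected amplitude drops — by
~2% at 0.42 s or 0.52 s and ~5% at 0.40 s or 0.56 s.  This is a property
of any band-pass-based detector, and it means amplitude round-trip
guarantees hold for the canonical population, not arbitrary shapes.

Cohort tables place one recording per (task, time) pair in each session,
with the response equal to the linear predictor plus Gaussian
participant, session and residual effects.  Defaults mirror a
developmental wake-EEG cohort: 100 participants aged 3.5–24.7 years, two
sessions, evening and morning recordings, 36% patients, 38% female, and
fixed effects of roughly the magnitude seen for oscillation amplitudes
(age −0.8 µV/year, overnight −4 µV, interaction +0.14, male −1.5,
patient −0.6).

All generators are pure functions of their spec including the seed.

Passing the synthetic benchmarks shows the pipeline recovers known
ground truth under the stated signal-to-noise and shape assumptions.  It
does not establish performance on real EEG, where oscillations are
non-sinusoidal and non-stationary, artifacts are structured rather than
white, channel correlation is distance-dependent, and slow-wave shapes
vary beyond two half-sines.

## Benchmark problem sizes

The acceptance benchmarks use 60-s recordings at 250 Hz: a five-point
low-beta frequency sweep of 3-cycle bursts for the minimum-duration
bound; twenty 8-channel recordings of 10-cycle bursts at 4× background
RMS (plus five burst-free recordings) for recovery and false-positive
rates; a 15-point noiseless grid for aperiodic recovery; one canonical
and ~25 population slow waves for the sleep round trip; 200 cohort
replicates for mixed-model CI coverage (the coverage criterion is a
proportion; more replicates reduce its Monte-Carlo error) and 12
replicates × 8 channels for the null FDR map.  The full script runs in
a few minutes on one core.

## Known limitations

* Decomposition (ICA) and component classification are not implemented;
  the screen consumes externally computed component spectra.
* Sleep staging is not implemented; NREM intervals are inputs.
* EDF files are read (via `mne`) but not written; the native recording
  format is a float32 array with a JSON sidecar.
* The aperiodic model is fixed-mode (no knee); spectra with a bend
  inside 2–35 Hz will bias the exponent.
* Slow-wave amplitude fidelity degrades for half-waves much longer or
  shorter than the canonical ~0.5 s, as described above.
* Burst detection at the exact 16 Hz band edge is conservative: edge
  cycles of short bursts measure slightly fast and fail the strict
  frequency gate, which is the price of the hard minimum-duration
  guarantee.
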