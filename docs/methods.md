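# Methods

## The experimental design being emulated

A neuron in primary visual cortex is driven through its classical receptive
field (CRF) by a continuously drifting grating whose contrast is set to evoke
roughly half the maximal response (here: a constant 60 spikes/s drive), so
that both increases and decreases of firing are visible. The extra-classical
surround (eCRF) is probed with a rapid dynamic sequence: every 20 ms an
annular high-contrast grating changes to a new orientation drawn uniformly at
random from 18 drift directions (20° apart) crossed with two spatial phases,
occasionally replaced by a mean-grey blank. Trials are 10 s long; a standard
experiment is 40 trials. Reverse correlation of spikes against this sequence
separates surround mechanisms by their temporal signature.

The blank probability is not pinned down by the protocol description beyond
"occasional"; the default here is `p_blank = 1/19`, which makes the blank a
balanced 19th stimulus class: each orientation (marginal over phase) and the
blank all have prior probability 1/19, so the log-odds statistic below is
exactly zero under the null. It is configurable.

## Generative model

Each surround mechanism is a multiplicative gain kernel acting on the
Poisson CRF drive:

* temporal profile: Gaussian, `K(t) = A · exp(−(t−μ)² / 2σ²)` — peak gain
  contribution `A` (dimensionless), latency `μ` (ms), width `σ` (ms);
* orientation profile: either uniform (untuned) or an axial Von Mises
  `α(θ) = exp(κ(cos 2θ − 1))` with `κ = ln 2 / (1 − cos 2·HWHH)`, so
  `α` is exactly 1 at the peak, 0.5 at the half-width-at-half-height, and
  has period 180° (both drift directions of a grating are equivalent).

Canonical parameters: facilitation A=1.2, μ=50, σ=5; strong suppression
A=1.7, μ=80, σ=10; untuned suppression A=1.1, μ=60, σ=7; tuned suppression
A=1.1, μ=80, σ=10 with Von Mises peak 0°, HWHH 30°.

Per-kernel drives sum linearly over frames, and the total gain is

    G(t) = Π_facilitative (1 + D_k(t)) / Π_suppressive (1 + D_k(t)),

which is strictly positive. The "+1" means unity gain in the absence of
surround input. Both suppressive kernels of the two-suppression duration
model are divisive; writing the tuned term in the numerator would make a
"suppressive mechanism" facilitative and the suppression index negative,
so the divisive form is used for both.

**Discretised convolution convention.** Each 20-ms frame contributes one
kernel evaluation referenced to the frame's temporal *center*
(onset + duration/2). This is the symmetric discretisation of convolving the
kernel with the frame train. It has two properties worth caring about:
printed amplitudes remain exact single-frame peak gains, and the
occupancy-based reverse correlation below recovers the kernel latency μ
without bias. (Referencing kernels to frame *onsets* instead shifts the
spike-triggered occupancy window to be centered at μ − frame/2, so recovered
peak lags would read 10 ms early — a half-frame discretisation artifact, not
physiology.)

Spiking is an inhomogeneous Poisson process with rate `r(t) = baseline·G(t)`,
simulated by per-bin Poisson counts on a 1-ms grid (exact for the
piecewise-constant rate) with spike times uniform within bins. The simulator
refuses bins whose expected count reaches 1 and instructs a smaller `dt`.

## Reverse correlation

For each spike at time `t` and each lag `τ` on a 5-ms grid spanning
0–200 ms, the stimulus class occupying `t − τ` (half-open frame intervals;
spikes with `t − τ` before trial start are dropped at that lag only) is
tallied. The modulation statistic is the log-odds ratio

    R_θ(τ) = ln[ (c_θ(τ) + p) / (c_blank(τ) + p) ],

with Laplace pseudo-count `p = 1` (negligible at realistic counts of
hundreds per class and lag; recorded in the map's metadata). Positive values
mean the orientation preceded spikes more often than a blank (facilitation),
negative mean suppression. By default the two spatial phases are pooled; a
phase-conditioned mode produces one map per phase.

The lag resolution (5 ms) and smoothing are free parameters of the analysis;
5 ms resolves sub-frame timing while keeping per-bin counts large.

**z-scoring.** Cortical latencies exceed ~30 ms, so map entries at lags
0–20 ms are noise. The baseline SD is the sample SD of all map entries in
that window and `z = R/SD`; |z| > 2 is the significance criterion.

A calibration fact that matters when interpreting significance counts: the
0–20 ms window holds only 5 lag columns × 18 rows, and those samples are
strongly correlated (adjacent 5-ms columns share 75% of their 20-ms frames;
all rows at a lag share the blank denominator). The SD estimate therefore
carries substantial error, making z effectively t-distributed with small
degrees of freedom: under the null the per-map fraction of |z| > 2 bins runs
at ~9–11% rather than the normal 4.6%. With a precisely estimated SD (pooled
over 20 independent null maps) the measured rate is 5.2%, i.e. the LOR/z
pipeline itself is calibrated and the inflation is purely estimator noise.
Consequently single-readout detections at z barely above 2 should be treated
as provisional; driven components in these simulations sit at |z| ≈ 10–18.

**Bootstrap.** Trial-resampling (with replacement) percentile intervals per
bin, computed from per-trial count tables so resamples are cheap; seeded and
reproducible.

## Component extraction

Band averages over map rows: collinear = orientations within 20° of 0° and
180° (rows {340, 0, 20, 160, 180, 200} on the default grid); orthogonal =
within 20° of 90° and 270° (rows {80, 100, 260, 280} — the centers fall
between grid orientations). The three readouts are:

* **tuned facilitation** — positive extremum of the collinear band;
* **untuned suppression** — negative extremum of the orthogonal band;
* **tuned suppression** — negative extremum of the collinear − orthogonal
  *difference*, which cancels the orientation-unselective part so a purely
  untuned mechanism does not register as tuned. The difference is left in
  map-z units; its noise is slightly larger than a single band's, so the
  shared |z| > 2 threshold is conservative for this readout.

Peak = extremum of the requested sign (ties break to the earliest lag);
onset/offset = the threshold crossings bracketing the peak, linearly
interpolated between lag samples and clamped to the grid edge if the curve
never drops below threshold inside it; duration = offset − onset. Components
whose peak does not exceed the threshold report NaN timing.

Because the readout takes the band extremum over all 41 lags, pathway-free
readouts cross |z| = 2 in a nontrivial fraction of runs (~25–35% for the
positive readout on suppression-only neurons under the noisy per-map SD) —
marginal peaks at random lags, always dominated by the driven component.
The recovery tests assert dominance and weakness of such readouts rather
than their absence.

**Tuning curves.** Mean z per orientation over a per-neuron window
(component peak ± half its duration, mirroring per-neuron window adjustment;
fixed windows can be passed instead). Peak orientation is the extremum of
largest magnitude; bandwidth is the full width at half height of the
sign-rectified curve about that extremum, linearly interpolated with
circular wrap, reported missing (NaN) when a flank never falls to half
height, and flagged `at_resolution` when at or below the 20° grid step.
Circular variance uses doubled (axial) angles,
`CV = 1 − |Σ r·e^{2iθ}| / Σ r`; responses are offset by the curve minimum
only when it is negative, so non-negative curves (e.g. a flat one, CV = 1)
are untouched. An all-zero curve is undefined and raises.

## Group-template cross-correlation

Group templates are elementwise means of member z-maps, optionally after
scaling each member to unit peak |z| so every neuron weighs equally. The
cross-correlation r(L) between a map and a template is the Pearson
correlation of the map with the template shifted by L ∈ [−100, +100] ms
(map lag step), over the overlapping columns only — no zero padding, which
would bias r toward zero asymmetrically. Sign convention: L is the shift
applied to the template, so a neuron whose dynamics *lead* the template
peaks at negative L. The zero-lag correlation difference between two group
templates classifies members; with the two synthetic groups (early
untuned+tuned vs late tuned-only suppression) leave-one-out assignment is
~100% correct and early members peak at ≈ −30 ms against the late template.

## Duration experiments

A surround stimulus of fixed orientation is held for d ∈ [10, 1920] ms as a
train of 20-ms frame events (a final partial frame contributes pro rata)
over constant CRF drive. Spiking is averaged over exactly the presentation
window [0, d) and compared with a matched no-surround control:
modulation index = (R_with − R_ctrl)/R_ctrl, suppression index =
1 − R_with/R_ctrl. Since the spike count of an inhomogeneous Poisson
presentation is Poisson with mean equal to the integrated rate, each
repetition draws the paired (with, control) counts from those exact
distributions; the control rate is the mean over control repetitions, and
per-repetition paired differences normalised by it give the Monte-Carlo
mean and sem. The default duration grid
{10, 20, 40, 60, 80, 120, 200, 480, 960, 1920} ms straddles the three
regimes (no modulation, net facilitation, net suppression); default 500
repetitions per duration give sem ≈ 0.004–0.06 depending on window length.

Whether kernels re-trigger during sustained stimulation is not constrained
by the protocol description; treating sustained stimuli as a frame-event
train (they do re-trigger, every 20 ms) is consistent with the dynamic
protocol and gives a well-defined analytic steady state: the mean of G over
one frame period under an infinite periodic event train
(`steady_state_mean_gain`), which the 1920-ms index approaches up to the
~100-ms onset transient (measured gap ≈ 0.03 for the
facilitation+suppression model).

## Problem sizes used by the test suite and acceptance script

Full-protocol recordings (40 trials × 10 s, 60 Hz) simulate in under a
second, so the recovery properties run 20 seeds × 4 single-kernel neurons at
full scale. Null-calibration checks use 20 seeds of 10-trial recordings;
group classification uses 6 + 6 members at 20 trials; duration experiments
use 200–1000 repetitions per duration. The whole suite runs in well under a
minute on one CPU.

## What the synthetic data do and do not show

The generator reproduces the protocol's statistics (frame timing, class
priors, trial structure) and the gain-kernel response model exactly, so
passing tests demonstrate that the estimators recover the model's own
parameters and obey their analytic properties. Real recordings differ in
ways the generator does not emulate: firing-rate nonstationarity and
adaptation across trials, non-Poisson spiking (refractoriness, bursting),
mixtures of mechanisms with heterogeneous spatial footprints, eye-movement
jitter, and layer-dependent CRF properties. Population-level figures from
recorded neurons (prevalences, average peak times and durations) depend on
those factors and on sample composition, and are not reproduced here; the
synthetic mimics are built to reproduce qualitative orderings only (e.g.
facilitation briefer than untuned suppression briefer than tuned
suppression).

## Known limitations

* The spatial geometry of the surround (annulus radii, border placement) is
  carried only as named presets that rescale kernel amplitudes; no spatial
  receptive-field model is fit.
* The z-map noise model ignores the weak negative correlation between class
  counts at a lag induced by the shared spike total.
* Bootstrap bounds are computed on phase-marginal maps only.
* `stimulus_at` assumes the uniform frame tiling the generator produces
  (constant frame duration); arbitrary tilings would need the slower
  search-based lookup.
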