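# Methods

This note documents the models, conventions and design choices behind
`neurorhythm`, in the order the data flow through the pipeline.

## Activity scoring of calcium traces

A recording is one neuron's raw fluorescence sampled for 45 s (default
10 Hz) at one clock time point; sessions recur every 4 h. Scoring proceeds:

1. **Baseline** F₀ = 10th percentile of the raw trace (numpy's
   linear-interpolation percentile). A low percentile is robust to sparse
   transients; the exact choice matters little for sparse activity because
   the score is gain-invariant by construction (ΔF/F₀ is unchanged when the
   raw trace is multiplied by any positive gain, F₀ being estimated from the
   same trace). The percentile must lie in (0, 50].
2. **ΔF/F₀** = (F − F₀)/F₀, elementwise.
3. **Peaks** are maximal runs of at least `min_frames = 3` consecutive
   frames with ΔF/F₀ above `noise_k = 3` robust noise SDs, the robust SD
   being 1.4826 × MAD of the whole ΔF/F₀ trace. On a silent trace the MAD
   measures pure noise, so the expected false-positive segment rate is far
   below 0.5 per 45 s trace (verified by simulation). On an active trace the
   MAD is partially signal-contaminated, which makes the threshold — and
   hence the score — mildly activity-dependent; the synthetic defaults keep
   firing sparse enough that this stays a second-order effect (below).
4. **Score** = Σ over peak segments of the trapezoidal integral of
   ΔF/F₀ clipped below at 0, with dt = 1/sampling rate; units ΔF/F₀·s.
   The area is measured above zero, not above the threshold, because the
   quantity of interest is the whole calcium transient, the threshold only
   defining where a transient is. Segment endpoints are inclusive, frame
   indices 0-based. A degenerate segment with zero integral does not count
   as a peak, preserving "score = 0 ⇔ no peaks".

Scores pivot into a complete neurons × sessions matrix. Median
normalization (each row divided by its median) is available for display and
comparison across neurons; rows with median 0 are left unscaled and flagged
rather than dropped, because all-zero rows still carry rank information in
the Friedman test. Missing or duplicated (neuron, session) cells are
errors — the repeated-measures statistics require a complete design.

## Rhythm statistics

**Friedman test.** Within-subject mid-ranks with the tie correction
C = 1 − Σ(t³−t)/(nk(k²−1)); statistic
χ²_F = [12/(nk(k+1)) Σ_j R_j² − 3n(k+1)] / C. Fully tied data (C ≤ 0)
returns statistic 0, p = 1. The p value is exact — full enumeration of the
(k!)ⁿ within-row rank permutations, computed by dynamic programming over
column-sum states — whenever (k!)ⁿ ≤ 10⁶, and the χ² approximation on
k − 1 df otherwise. The implementation is cross-checked in the tests
against `scipy.stats.friedmanchisquare` (statistic) and a brute-force
enumeration oracle (exact p).

**Dunn's post hoc (repeated measures).** Mean-rank differences of each
condition against the reference, standardized by
SE = √(k(k+1)/(6n) · C), two-sided normal p values, Bonferroni-adjusted
over the (k−1)-comparison many-to-one family. Bonferroni is the
conventional family correction for this design; with two conditions the
family is a single comparison and adjusted = raw.

**Randomization control.** Each of the `n_reps = 1000` repetitions permutes
every neuron's scores across sessions independently — preserving each
neuron's score multiset and the repeated-measures structure while
destroying any shared temporal pattern — then recomputes the Friedman test.
Because a within-row permutation of scores permutes the within-row ranks
identically, the ranks and tie term are computed once and only shuffled,
which makes the 1000 repetitions a vectorized array operation. All
repetitions use the χ² p value (the designs of interest are far beyond
enumeration), and the observed p value is computed the same way so the
comparison "observed below all permuted" is internally consistent. The
1000 p values are adjusted with Bonferroni by default (Benjamini-Hochberg
by configuration); the result reports the fractions of raw and adjusted
p values below α. Under exchangeable null data the raw fraction is
calibrated (~5%); note that across very many null repetitions occasional
raw p values below α/n_reps are *expected* — a correctly calibrated null
produces them at rate α/n_reps — so "no adjusted repetition significant"
is a per-experiment statement that holds with probability ≈ 1 − α, not a
law.

**Correlations.** Pearson r with the two-sided t-based p value on n − 2 df
(`scipy.stats.pearsonr`); zero-variance input is an error, not r = 0. The
split-half utility averages scores over neurons per session and correlates
the first half-window against the second, matched by offset; it requires an
even session cadence and a span of at least two windows.

**Between-group tests** follow the standard assignments for these assay
designs: Mann-Whitney for two independent groups (exact enumeration when
both n ≤ 8 and the pooled sample is tie-free, tie-corrected normal
approximation otherwise); Kruskal-Wallis with tie correction plus Dunn's
z comparisons against a reference group (exact permutation p by
enumeration when the number of distinct group assignments is ≤ 10⁶);
one-way ANOVA with Dunnett's many-to-one comparisons (adjusted p from the
multivariate-t reference distribution via `scipy.stats.dunnett`, seeded,
reproducible; with two groups this reduces to the two-sample t test within
Monte-Carlo tolerance ±0.002); and two-way ANOVA with interaction using
Type II sums of squares (statsmodels OLS; Type II because the image
designs can be unbalanced) followed by Tukey HSD over the cell means
(`scipy.stats.tukey_hsd`). Degenerate inputs are handled explicitly:
zero pooled variance with unequal means gives p = 0 without division
errors, empty factor cells are reported by name, and a single replicate
per cell is rejected when the interaction is requested.

## Reporter model

The destabilized GFP obeys dG/dt = P(t) − kG with k = ln 2 / t₁/₂ and
t₁/₂ = 2 h. For a sinusoidal promoter drive
P(t) = m + a·cos(ω(t − φ)), ω = 2π/24 h⁻¹, the periodic solution is

G(t) = m/k + a/√(k² + ω²) · cos(ω(t − φ) − ψ),  ψ = atan(ω/k),

i.e. the oscillation is attenuated by 1/√(k² + ω²) and lags the promoter
by ψ/ω ≈ 2.47 h at these constants. With an initial condition the
transient (G₀ − G_p(0))e^(−kt) is added; promoter-off decay therefore
halves the level every 2 h exactly. The closed form is the implementation;
a fine-step Euler integrator exists only as a test oracle. Because of the
lag, "reporter anti-phase to activity" is a statement about the *observed*
reporter curve: the default promoter phase is back-shifted by ψ/ω so the
reporter peak (not the promoter peak) sits 12 h from the activity peak,
matching the biological observation being emulated — the measured clock-
reporter signal peaks at night while activity peaks in the afternoon.

## Puncta detection and ROI quantification

Detection runs on the marker channel: difference-of-Gaussians band-pass
(σ = 100 nm and 400 nm, converted to pixels via the image's pixel size),
threshold at the DoG median + `threshold_k` × 1.4826 × MAD of the DoG
image, 8-connected components, area gate 4-10⁴ px. The background
dominates the DoG histogram because puncta are sparse, so median/MAD is a
background estimate. `threshold_k` defaults to 4: the band-passed noise
field is spatially correlated, and at 3 robust SDs the suprathreshold
noise pixels of an empty Poisson-noise background cluster past the 4-px
area gate (~4 false objects per 256² image), while at 4 SDs empty
backgrounds yield zero false objects and diffraction-limited puncta at
SNR ≥ 5 remain far above threshold. Detection is deterministic.

ROI broadening dilates the union mask with a Euclidean disc of radius
round(broaden_nm / pixel_size_nm) px — "in each direction" is isotropic —
so 200 nm at 100 nm/px is the exact 13-pixel discrete disc of radius 2.
Overlapping broadened ROIs merge into their union and every pixel is
counted once. Quantification reports, per signal channel, the mean
intensity over the mask, with the off-mask median as the background
estimate, subtracted (floored at 0) when background correction is on. An
empty mask yields NaN intensities flagged undefined, never a silent 0.
The per-image mean is the downstream unit of analysis, matching the
convention of pooling images per condition; no hierarchical modeling of
experiment nesting is attempted. The same quantify path serves every
staining read-out (antibody/nanobody uptake, RBM3, puromycin, FISH), with
the marker channel configurable.

## Synthetic data: what it emulates, and what it does not

**Culture simulator.** Neuron i draws a phase φᵢ ~ N(phase_mean, jitter²)
— partial desynchronization of the culture — and fires as a Poisson
process with rate r(t) = r₀(1 + A·cos(2π(t − φᵢ)/24)), clipped at 0,
scaled by ε_TTX under TTX. Events become ΔF/F₀ through a causal
exponential kernel (amplitude 1 ΔF/F₀, τ = 1 s, implemented as a one-pole
IIR filter), and raw fluorescence is F₀(1 + ΔF/F₀) plus Gaussian noise
(SD 0.05 F₀). Defaults: 156 neurons (the reference cohort size), sessions
every 4 h over 64 h, 45 s at 10 Hz, A = 0.6, phase mean 14 h, jitter
SD 1 h. The baseline rate is 0.1 Hz (≈4.5 transients per recording):
sparse network-burst-like firing for which transients rarely overlap the
indicator decay, keeping the trace-MAD threshold noise-dominated and the
score response near-linear in rate — at substantially higher rates the
threshold becomes signal-contaminated and the score saturates, which
distorts pattern correlations. Events are Poisson without bursting; real
cultures burst, adding overdispersion the simulator does not model.

**Reporter simulator** samples the closed form above at the configured
times (default 0-24 h every 4 h) plus Gaussian noise (SD 0.05, ≈1.7% of
the steady-state mean).

**Image simulator** places spot centers uniformly at random with a minimum
separation (6 px, so ground-truth matching is unambiguous; an error is
raised after bounded rejection-sampling retries if the density is
infeasible), renders isotropic Gaussian spots (σ 150 nm) for marker and
signal channels at shared centers, scales the signal amplitudes by the
condition factor (active 1×, TTX 0.3×, knockdown 1.5× — the directions of
the silencing and knockdown effects being emulated), and applies Poisson
shot noise plus Gaussian read noise (SD 3) over a background of 100.

All simulators draw from a single seeded generator per run, with
deterministic per-neuron/per-image substreams (`numpy` SeedSequence
spawning), so identical seeds give bitwise-identical outputs.

Passing tests on these synthetics demonstrate the *analysis chain* —
scoring, rank statistics, permutation machinery, detection geometry — under
known ground truth. They do not certify performance on real recordings,
which add bursting, photobleaching, movement, uneven illumination,
ragged cell morphology and inter-culture variability that the generators
deliberately omit.

## Problem sizes and numerical conventions

* Exact-vs-asymptotic switchovers: Friedman and Kruskal-Wallis enumerate
  when the relabeling count is ≤ 10⁶; rank tests use exact enumeration at
  n ≤ 8 per group without ties.
* The acceptance script runs 20-25 replicates per stochastic quantity
  (e.g. 20 null cultures of 156 neurons × 9 sessions × 1000 permutations);
  the test suite uses up to 100 replicates for the calibration and power
  checks. These sizes give binomial standard errors of a few percent on
  the reported rates.
* All p values lie in [0, 1]; adjusted p ≥ raw p always; ties broken by
  mid-ranks throughout; comparisons are two-sided unless stated.
* Times are real-valued hours; `clock_time_h` is a label (no time-zone
  logic). Pixel coordinates are 0-based row-major; intensities stay in
  native arbitrary units (no flat-field correction).

## Known limitations

* The activity score depends mildly on overall activity through the
  trace-MAD threshold; comparisons across very different activity regimes
  should keep this in mind.
* The randomization control's permuted p values use the χ² approximation;
  for tiny designs (where the exact Friedman p would differ) the null
  fractions inherit the approximation.
* Dunn and Dunnett comparisons are many-to-one only; all-pairs families
  are out of scope, as are circular statistics, period estimation
  (MetaCycle-style), mixed-effects models and 3-D image stacks.
* The two-way ANOVA assumes homoscedastic normal residuals; the image
  simulators satisfy this approximately but real intensity data may not.
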