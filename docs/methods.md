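# Methods

## Measurement model

A recorded cell is a matrix of stimulus-aligned trials of membrane
potential (mV) at a common sampling rate (default 20 kHz), with the 1 ms
optogenetic stimulus at a known onset time. All features are computed on
the trial-averaged trace, not per trial: averaging ~20 trials suppresses
membrane noise by ~√20 and matches how such recordings are analyzed in
practice; per-trial rise-slope fits on noisy traces are unstable.

* **Baseline**: mean of the averaged trace over the 100 ms before stimulus
  onset (`baseline_window_ms`, default 100).
* **Peak amplitude**: maximum of the averaged trace in the half-open window
  (0, 100] ms after onset, minus baseline; ties broken by the earliest
  sample. The 100 ms default covers the evoked peak for all kinetics used
  here (slowest preset peaks at ~6.3 ms) with wide margin; it is
  configurable (`peak_window_ms`).
* **Rise crossings**: the 20% and 50% levels above baseline are located by
  walking backward from the peak through the contiguous run of samples
  above each threshold and linearly interpolating the upward crossing at
  its start. Backward-contiguous search makes the crossing robust to
  pre-stimulus noise wandering above threshold. If the trace is already
  above threshold at the first post-stimulus sample (a sub-sample rise) or
  the peak amplitude is non-positive, the crossings — and hence the slope —
  are reported missing rather than zero; the amplitude is still reported.
  This missing-slope rule is one plausible reason published slope sample
  sizes are occasionally one or two below the amplitude sample sizes; it is
  a reasoned convention, not a claim about any particular study's rule.
* **Slope**: ordinary least squares of V̄(t) against t over [t₂₀, t₅₀].
  The interval is resampled to 201 uniform points by linear interpolation
  before the fit. Rationale: for fast kinetics (PV preset, rise window
  ~0.2 ms) the 20 kHz grid puts only ~4 samples inside the interval, and a
  raw-sample fit neither spans the full interval nor weights it evenly,
  deviating by up to ~5% from a dense-grid fit on the underlying waveform;
  the resampled fit agrees to <0.1% across all presets and amplitudes,
  and degenerates to the secant through the interpolated endpoints when no
  interior samples exist.

Feature extraction is invariant to adding a constant to all samples and
equivariant under amplitude scaling; both properties are tested.

## Layer assignment and normalization

Layers are assigned from subpial depth by contiguous half-open bands
[lo, hi) with depth 0 at the pia; an explicit layer label in the metadata
takes precedence. The shipped default bands are transcribed from the
Lefort et al. (2009) average mouse C2 barrel-column geometry: L1 0–128,
L2 128–269, L3 269–418, L4 418–588, L5A 588–708, L5B 708–890,
L6 890–1154 µm. L1 is assignable but flagged as not analyzed (no L1
recordings in the emulated experiments). Half-open intervals avoid double
assignment at boundaries.

Absolute EPSP amplitudes confound synaptic strength with the slice's opsin
expression level. Within each slice, every cell's amplitude (slope) is
therefore divided by the mean amplitude (slope over slope-defined cells)
of the control-condition excitatory cells in the pathway's reference layer
(L4 for VPM, L5A for POm). Reference cells are included in their own
denominator — forced by the fact that the reference cell of a published
normalized summary matrix reads mean = median = 1.00 — and only
control-condition cells enter the denominator (a receptor-blocked
reference cell would zero it). Slices without a reference cell are
excluded with a logged warning naming the slice.

Two exact identities follow and are exploited by the tests: the pooled
reference-group normalized mean is exactly 1 regardless of slice sizes,
and when no slice holds more than two reference cells, the reference
values form mirror pairs (1−d, 1+d) plus exact 1's, so the pooled
reference *median* is also exactly 1 — the published "1.00" medians are
structural, not rounding.

## Rank statistics

Two-tailed Wilcoxon rank-sum and signed-rank tests are provided in two
modes. The exact mode enumerates the full permutation null — all
C(n₁+n₂, n₁) rank assignments, or all 2ⁿ sign patterns — by dynamic
programming over doubled mid-ranks (ties produce half-integer mid-ranks;
doubling makes the statistic integral), and reports twice the smaller tail
probability, capped at 1. The normal-approximation mode delegates to the
tie-corrected asymptotic tests with continuity correction. The automatic
mode switches at combined n = 20, below which enumeration is cheap and
above which the approximation error is negligible (|Δp| < 0.01 at n = 15,
tested). Zero paired differences are dropped (Wilcoxon convention); an
all-zero difference vector returns p = 1 with a warning. No
multiple-comparison adjustment is applied by default, mirroring common
reporting practice for these designs; Bonferroni and Holm adjustments are
available as options.

Note that an exact two-tailed signed-rank test with n = 8 informative
pairs cannot produce p below 2/256 ≈ 0.0078; published values below that
for such designs imply a normal approximation or different convention.
Both modes are provided; neither is asserted as "the" published
computation.

Group summaries use the n−1 SD (blank for n = 1), SEM = SD/√n, type-7
(linear-interpolation) quantiles — the most common default; configurable
behavior was not needed — and box-plot whiskers at the extreme data points
within 1.5×IQR of the first/third quartile.

## Generative model

The simulator generates complete cohorts with the statistical structure
the analysis assumes, one pathway per cohort:

* **Slices**: `n_slices` slices (default 33 VPM / 43 POm); each slice s
  draws an absolute reference scale R_s, log-normal with median 14.5 mV
  (VPM) or 11.7 mV (POm) — the published reference-layer group means — and
  log-SD 0.4, emulating slice-to-slice opsin expression variability of
  roughly ±50%.
* **Cells**: each (cell type, layer) group contributes its published
  sample size, dealt deterministically across slices; reference-layer
  excitatory cells are spread first so every slice holds at least one
  (two while supply lasts — the published counts, e.g. 65 reference cells
  over 33 slices, do not allow two everywhere). A cell's normalized
  amplitude g is drawn from a log-normal moment-matched to the group's
  published mean and SD (σ² = ln(1+(SD/mean)²), μ = ln mean − σ²/2);
  its absolute amplitude is R_s · g. The log-normal, rather than a
  zero-truncated normal, is used because the published group medians lie
  far below the group means (e.g. 0.077 vs 0.39): a truncated normal
  matched to the same moments puts its median 5–25× too high and cannot
  reproduce the strong reference-layer dominance (rank-sum p < 10⁻⁷)
  reported at these sample sizes, whereas the moment-matched log-normal
  lands within ~2× of every published median. Depth is drawn uniformly
  within the cell's layer band.
* **Trials**: each trial is v_rest (−70 mV) + stationary
  Ornstein–Uhlenbeck noise (σ = 0.3 mV, τ = 10 ms; exact discretization
  x_{k+1} = a x_k + σ√(1−a²) ε with a = e^(−Δt/τ)) + a dual-exponential
  EPSP w(t) = A(e^(−t/τ_d) − e^(−t/τ_r))/N, peak-normalized so
  max w = A. Kinetics per cell type: EXC 2/40 ms, PV 0.5/15 ms,
  SST 2/40 ms, VIP 1/25 ms — chosen so that equal-amplitude inputs give
  PV cells ~2–3× larger rise slopes than excitatory cells, the
  qualitative signature of fast-spiking interneurons. Per-trial amplitude
  is max(0, Normal(A, cv·A)) with cv = 0.1 (trial-to-trial jitter affects
  variances, not means). Traces default to 0.3 s at 20 kHz with the
  stimulus at 0.12 s; the test suite and acceptance script use 0.24 s
  with the stimulus at 0.11 s (full 100 ms baseline plus 130 ms
  post-stimulus — ample for all kinetics) to keep published-scale
  cohorts fast.
* **Conditions**: `CNQX_APV` forces the evoked amplitude to zero
  (receptor blockade); `late_timepoint` multiplies the cell's mean
  amplitude by (1 + drift_per_hour), with zero drift by default
  (emulating stable optogenetic stimulation over ~1 h).

The same configuration and seed always yield a bit-identical dataset.

### What the simulator does and does not emulate

It reproduces the group-level mean/SD structure, skewness consistent with
the published medians, slice-level expression scaling, trial noise, and
cell-type kinetics. It does not model conductance-based biophysics,
dendritic filtering, light-power spatial profiles, per-trial latency
jitter, or correlations between amplitude and kinetics within a group;
all cell types share each slice in a single cohort, whereas the real
interneuron datasets came from separate animals (irrelevant to the pooled
statistics, which never compare across slices without normalization).
Passing tests therefore demonstrate that the *analysis* recovers the
assumed statistical structure — they do not validate the biophysics of
real recordings.

### Known measurement limits (deliberate, tested)

Peak extraction is a maximum over a noisy window, so cells with zero or
near-zero true input report a small positive amplitude — the noise floor,
~E[max of the trial-averaged OU process] ≈ 0.1–0.15 mV at the default
noise, i.e. ~0.01 normalized units for POm-scale reference amplitudes.
Group means of the weakest groups (published means ~0.01) are therefore
biased upward by roughly their own magnitude. This mirrors the real
method's behavior; it is why blocked-condition amplitudes are compared
against a pure-noise reference distribution rather than against zero.

Group-mean recovery at published scale is assessed two ways: against the
cohort's realized generative means (what the pipeline can actually be
held to, given one finite cohort) with a noise-floor allowance, and
against the population generative means, where ~38 simultaneous two-SE
checks on heavy-tailed small-n groups fail for a large fraction of seeds
by elementary sampling statistics; the acceptance suite reports the
latter comparison's z-statistics rather than pretending a single cohort
can pin population means.

## Numerical choices

* Times are stored in seconds on disk (SI), reported in ms; potentials in
  mV, uncorrected for liquid junction potential.
* Peak ties: earliest sample. Crossing interpolation: linear between the
  bracketing samples.
* Exact-test p-values use doubled mid-ranks (integer DP) — no floating
  point in the null distribution counts.
* Datasets are written sorted by cell id; pipeline artifacts are
  byte-reproducible under a fixed seed (manifest records input hashes,
  parameters, exclusions and package version).
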