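# Methods

This note documents the models, estimators, and design choices behind
`eegcpm`: what each stage computes, which knobs matter, what the synthetic
cohorts do and do not emulate, and where the genuinely open choices were
made.

## Preprocessing

Average re-referencing subtracts the across-channel mean at every sample;
it is linear and idempotent, and afterwards the channel mean is exactly
zero. Filtering applies a second-order IIR notch (50 Hz, quality factor
30) followed by a Butterworth band-pass (0.1–30 Hz, order 4), both run
forward–backward (`filtfilt`) so the pipeline is zero-phase — phase
distortion would corrupt the downstream phase-synchronization estimates.
Orders and the notch Q are conventional EEG choices and are exposed as
parameters.

Amplitude screening computes, per channel, the fraction of samples whose
absolute value exceeds 100 µV; a channel is flagged when that fraction
*strictly* exceeds 0.5 ("more than half"), so a fraction of exactly one
half is retained. The subject-level rule applies the same criterion to the
across-channel maximum-amplitude trace. The two rules are reported
separately (per-channel flags and a subject decision) because artifact
screening in practice conflates them; both are pure functions of
|amplitude| and therefore invariant to sign flips. Visual bad-channel
interpolation and ICA artifact removal are manual/toolbox procedures and
are deliberately out of scope.

## Spectral arousal index

Power spectra use Welch's method with Hann-tapered, **non-overlapping**
2-s windows: a 2-s window fixes the 0.5 Hz grid, and non-overlap makes a
200-s recording exactly 100 windows. Density scaling preserves Parseval
(the PSD integral equals the windowed signal variance), which the tests
check against a pure tone to within 2%. The grid is restricted to
1–30 Hz (59 bins).

The arousal index is the mean PSD over the 8–13 Hz bins, then over all
channels — both averages in linear power, before the log — expressed as
`10·log10(power)` with absolute power (µV²/Hz) as the dB reference. Any
fixed reference shifts all subjects equally and leaves the median split
unchanged, so the reference convention is immaterial to the grouping.
Consequences worth knowing: the index is invariant under channel
permutation, a silent channel strictly lowers it, and scaling all samples
by c shifts it by 20·log10(c).

The median split assigns values strictly below the sample median to the
**high**-arousal group (low alpha = high arousal) and values at or above
the median to the **low**-arousal group. This tie/median policy is
deterministic, yields an equal split for even n with distinct values, and
places the median element of an odd-n sample in the low-arousal group. A
sample with all values identical has no defined split and is an error.

## WPLI connectomes

For each band (delta 1–4, theta 4–7, alpha 8–13, beta 13–30 Hz) the trace
is Butterworth band-passed (order 4, zero-phase), the analytic signal is
taken by Hilbert transform of the **full** filtered trace (avoiding
per-epoch transform edge effects), and the signal is cut into consecutive
non-overlapping 2-s epochs, the same length as the spectral windows. For
a channel pair (i, j) with instantaneous cross-spectrum
X(t) = z_i(t)·conj(z_j(t)):

    WPLI = |Σ Im X| / Σ |Im X|

with the sums running over all time points of all epochs (the "pooled"
estimator, default). The expectation-across-epochs structure follows the
original definition of the estimator and the standard toolbox
implementations; its null value converges to zero as epochs accumulate
(measured ≈0.04 at 100 epochs). The alternative reading — a WPLI ratio
within each 2-s epoch, then an unweighted mean across epochs — is provided
as `estimator="epoch-mean"`, but it is not the default for a measured
reason: a 2-s epoch of a 5-Hz-wide band contains only a handful of
independent phase samples, giving that variant an irreducible positive
null bias of ≈0.34 that averaging over epochs cannot remove.

Degenerate pairs (identical signals, exactly zero-lag coupling) have an
identically zero imaginary cross-spectrum; the 0/0 case is defined as 0 —
conservative, no spurious coupling. The matrix is symmetric with a zero
diagonal, entries in [0, 1]; the estimator ignores per-channel amplitude
scaling and the sign of the phase lag. Edge vectors use the strict upper
triangle in row-major order throughout, including on-disk formats.

## Group statistics

The one-way ANOVA is computed from sufficient statistics — SSB =
Σ nᵢ(mᵢ − m̄)² with the n-weighted grand mean, SSW = Σ (nᵢ−1)·sdᵢ², F =
(SSB/df₁)/(SSW/df₂), partial η² = SSB/(SSB+SSW) — so the raw-data mode and
the summary-statistics mode are algebraically identical (tested to 1e-10),
and published F statistics can be reproduced from printed group summaries
alone. The t test is the pooled-variance (Student) form with
df = n₁+n₂−2 and Cohen's d = Δm / pooled SD; the pooled form is what
published t values computed from group summaries correspond to. Bonferroni
post hocs multiply each pairwise p by the number of pairs, capped at 1.

A practical caution encoded in the API docs: published tables sometimes
label standard deviations as "SE". The summary-mode functions take their
inputs at face value as SDs; the caller decides how to read a printed
table. (Reading the behavioral dispersions of the emulated study as SDs is
what reproduces its printed F.)

## CPM

The protocol is strictly fold-contained: for each left-out subject, every
edge is correlated with behavior **on the training set only**; edges with
p < threshold are split by sign into positive and negative networks; each
training subject's selected edges are summed into network strengths
(combined = positive sum − negative sum); a one-predictor least-squares
line predicts the held-out subject from their strength under the training
masks. After all folds, Pearson's r between predicted and observed scores
(with its parametric two-sided p) scores each network. An explicit test
perturbs the held-out subject's score and verifies the fold's masks never
change.

Choices where the protocol is genuinely underdetermined:

* **Combined network** = positive − negative strength as a single
  predictor. Under this sign convention anticorrelated edges add signal
  rather than cancel, so the combined network can outperform either
  single-sign network.
* **Empty-mask folds** predict the training mean; a network with no
  selected edge in *any* fold carries no prediction and reports NaN
  (the dash of published CPM tables). A negative r is reported as-is and
  read as failure to predict.
* **Permutation test**: behavior is shuffled across subjects and the whole
  LOOCV re-run; `p_perm = #{r_perm > r_obs}/n_perm` with strict inequality
  and no +1 correction, so 0 is attainable. The (b+1)/(m+1) estimator is
  available via `plus_one=True`. Permutations whose network yields no
  prediction count as not exceeding. The internal LOOCV uses a
  sufficient-statistic downdate (remove one subject from the per-edge
  correlation sums) plus an equivalent critical-|r| selection cut, making
  each permutation O(n·edges); tests verify fold-by-fold equality with the
  naive recomputation.
* **Age control** applies two levers at once when a covariate is given:
  partial correlation (covariate residualized out of edges and behavior)
  at the selection step, and the covariate regressed out of the training
  scores before the strength model is fit, with the covariate component
  added back to the held-out prediction so raw scores remain the target.

## Synthetic cohorts

Each channel is pink (1/f, exponent 1) background noise plus one
narrow-band oscillation per configured band, synthesized as
band-pass-filtered white noise — filtered noise has non-degenerate phase
within epochs, where a pure sinusoid would zero the WPLI denominator. The
oscillation is scaled to the background's in-band RMS (1:1 in-band SNR by
default). Per-subject alpha amplitude is drawn once per subject with a
configurable between-subject spread (default 3 dB, of the order of the
group SDs printed in resting-state alpha tables).

Coupling on an edge (i, j, band, lag, κ) replaces channel j's band
component with κ·shift(x_i, lag) + (1−κ)·own, rescaled to the original
RMS, where `shift` rotates the analytic signal by a constant phase. The
default lag is π/2, which maximizes the imaginary cross-spectrum WPLI is
built on; lags of 0 or π make the imaginary cross-spectrum vanish and
trigger a warning. Per-subject realized strengths are κ jittered by a
uniform half-width (`coupling_spread`, default 0) and clipped to [0, 1].
The random stream layout is independent of parameter values, so sweeping κ
at a fixed seed yields common-random-number-coupled simulations — the
basis of the monotonicity checks, which find the measured WPLI
nondecreasing in κ seed by seed.

Behavior for subject s is `4 + β·(S_s − E[S]) + ε`, clipped to the 1–7
rating scale, where S_s is the subject's summed realized edge strength and
ε ~ N(0, σ) with σ = 0.8 rating units (of the order of printed behavioral
dispersions). Centering on the scale midpoint keeps clipping rare at
realistic noise levels. β = 0 with designated edges gives a true-null
cohort; β ≠ 0 without edges is an error (the effect has no carrier).

What the generator does **not** emulate: scalp topography and volume
conduction, non-stationarity, eye/muscle/cardiac artifacts, realistic
cross-frequency structure, or task-evoked activity. Passing tests
therefore demonstrate the correctness and calibration of the estimators
and the prediction protocol under the assumed generative structure — not
robustness to the full messiness of real recordings.

## Validation study conditions

Scaled-down cohort sizes, chosen once in `eegcpm.scenarios`, keep
whole-cohort simulations tractable on one CPU while preserving the 2-s
epoch grid and band structure:

* **Recovery**: 75 subjects, 16 channels, 250 Hz, 60 s (30 epochs), five
  coupled alpha edges with per-subject strengths U(0.1, 0.9), β sized so
  the population R² between strength sum and behavior is 0.5; alpha-power
  heterogeneity disabled so the cohort varies only in the parameter under
  recovery (between-subject amplitude jitter changes in-band SNR, a
  separate mechanism exercised by the arousal checks). The combined
  network's LOOCV r exceeds 0.4 with permutation p ≤ .05 in the large
  majority of seeds; per-seed success probability is roughly 0.8–0.9, so
  individual 20-seed families occasionally dip below that range.
* **Null calibration**: 30 subjects, 8 channels, 20-s recordings, β = 0;
  across 100 cohorts the combined-network permutation p is
  indistinguishable from uniform (KS) and the empirical type-I rate at
  .05 sits inside the exact binomial interval. Occasional cohorts select
  no edge in any fold and legitimately return no prediction; they are
  excluded from the rate's denominator.
* **WPLI sweeps**: two channels, one alpha edge, 100 s (50 epochs),
  κ ∈ {0, .25, .5, .75, 1}.

## Numerical notes and limitations

* Percentile-band stimulus selection uses numpy's linear-interpolation
  percentile convention with inclusive bounds; with all ratings identical
  every item matches every percentile.
* Correlation p values use the exact t transform; constant edges are
  defined to have r = 0, p = 1 and can never be selected.
* The zero-phase band-pass has long transients near the 0.1 Hz edge;
  amplitude-preservation checks measure the central portion of long
  signals.
* LOOCV folds are enumerated in subject order; all stochastic stages take
  explicit seeds or Generators, and identical (config, seed) reruns are
  bit-identical.
* Only LOOCV is implemented (no k-fold), one band per model, no
  external-cohort generalization step, no graph-theoretic summaries, and
  no source reconstruction.
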