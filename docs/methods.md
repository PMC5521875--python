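# Methods

This note documents the models, estimators and statistical procedures the
package implements, the choices made where the design was genuinely open,
and what the synthetic-data generator does and does not emulate.

## The model

Each output (CA1) unit's binary spike train, binned at 4 ms, is described by
a multi-input linear autoregressive model with a continuous drive

    y(t) = c + Σ_{n=1..N} Σ_{τ=0..M} k_n(τ) x_n(t−τ)
             + Σ_{τ=1..M+1} k_AR(τ) y(t−τ)

where `x_n` are the input (CA3) spike trains, `k_n` the feedforward filters
(the circuit-level analogue of an EPSP waveform, which may carry inhibitory
components from feedforward interneurons), and `k_AR` the feedback
(autoregressive) filter (the analogue of the afterhyperpolarization,
including refractoriness and resonance).  An intercept `c` is included even
though the canonical form of the model equation has none: without it any
nonzero baseline rate would bias every filter.  It is recorded in model
metadata as an addition.

Filters are expanded over `L` discrete orthonormal Laguerre functions with
decay `alpha` and memory `M` bins, reducing each filter to `L` coefficients.
Two constructions of the basis exist in the package: the stable two-term
recursion (production path) and the closed-form binomial sum (test oracle);
they agree to 1e−9 over the tested range.  Coefficient projection onto the
basis uses an exact least-squares solve rather than `Bᵀv`, so the tiny
non-orthonormality left by truncating the basis at lag M never leaks into
round-trip identities.

**Defaults: `alpha = 0.7`, `L = 5`, `M = 120` (480 ms).**  These were chosen,
not copied: 480 ms covers the ~40 ms refractory trough and the period of a
low-theta (3.5 Hz) resonance with margin, and at `alpha = 0.7` the truncated
basis is orthonormal to ~2e−9 and decayed below 1e−3 at lag M.  Larger decay
values (0.8–0.9) lose orthonormality badly at M = 120 and would need
M ≥ 400.  All three are config keys (`laguerre.alpha/L/M`).

## Estimation

Ordinary least squares of the binary output on the Laguerre regressors — a
linear-probability reading of the model, chosen because the model is linear
with no link function; there is no point-process (GLM) likelihood here by
design.  The feedback regressor shifts the observed output one bin into the
past before basis convolution, implementing lags 1..M+1 exactly.
Concatenated trial segments are zero-padded at each seam and the first M+1
bins of every segment are masked out of fitting and correlation.  Optional
ridge (`fit.ridge_lambda`) handles collinear candidate inputs; otherwise a
rank-deficient design raises an error naming the inputs.

Out-of-sample evaluation uses a contiguous 80/20 split (`fit.test_fraction`):
the model is fit on the first 80% of bins and the Pearson correlation ρ
between the continuous one-step-ahead drive and the binary output is
computed on the last 20%.  ρ is computed on unsmoothed series by default;
`fit.smooth_sigma` optionally Gaussian-smooths both series first, for
users who prefer correlating rate envelopes rather than raw bins.

## Connectivity

Forward stepwise selection starts from the feedback-only model and adds, in
each round, the candidate input that most improves out-of-sample ρ, provided
the improvement exceeds `select.epsilon` (default 0.01 in ρ units — at the
default 600 s session length this keeps the null false-inclusion rate below
5%).  Ties break lexicographically on unit id, so the procedure is
deterministic given the data.

Model significance is Monte-Carlo: each of `surrogate.n = 40` surrogates
circularly shifts every input train by an independent random offset of at
least 1 s, refits the feedforward coefficients *with the feedback
coefficients retained* (so the null isolates feedforward predictive
content), and records its out-of-sample ρ.  Circular shifting is used
rather than full permutation because it preserves each train's
autocorrelation (rate, theta rhythm), making the null stricter and better
calibrated; `surrogate.mode = "permute"` preserves the literal
shuffled-input reading.  The p-value is parametric: the upper-tail normal
probability of the true Fisher z under a normal fit to the 40 surrogate
z-scores — an empirical p with 40 surrogates could never reach the 1e−4
significance threshold.  Edges and filters are harvested from significant
models only.

Predictive power is summarised by the ROC/AUC of the continuous drive
against the binary output over valid test bins (curve via scikit-learn with
no intermediate-point dropping; AUC by the trapezoid rule, identical to the
Mann–Whitney statistic).

## Filter metrics and modes

Filter spectra are plain magnitude-squared FFTs of the zero-padded filter
(resolution ≤ 0.25 Hz); filters are short deterministic sequences, so no
tapering is appropriate.  Band power is the fraction of unit-total power in
a half-open band; the filter-domain theta band defaults to [4, 9) Hz
(feedforward resonances sit at 8–9 Hz) while the signal-domain band stays
[4, 7] Hz; both are config keys.  The excitatory index is
EI = Σ max(k, 0) / Σ |k|, reading "total filter area" as the absolute sum so
EI is always in [0, 1]; the signed-sum alternative can leave the interval
and was rejected.  An all-zero filter has undefined EI and spectrum (error,
not 0).

Global principal dynamic modes are the leading right singular vectors of the
row-stacked filter matrix of one family, pooled over *all* sessions and
conditions (one mode set, never per condition).  Rows are not mean-centred —
this is an SVD of the filters, not PCA (`gpdm.center` enables the variant).
Each mode is sign-flipped so its largest-magnitude element is positive,
since SVD sign is arbitrary.  Mode strength in a filter is the plain inner
product; session strength is the mean over the session's filters.
`gpdm.n_modes` defaults to 3.

## Signal metrics

Spike-train spectra use Welch's method (4 s Hann windows, 50% overlap) on
the mean-subtracted binary series, normalized per cell to unit total power
over 1–50 Hz before any cross-cell averaging or differencing — condition
contrasts therefore compare spectral shape, not rate.  Group spectral
differences are within-unit (paired) differences averaged across units with
pointwise percentile bootstrap bounds (resampling units, 2000 draws, 99%
coverage by default).  Units recorded in several sessions of one condition
are averaged before pairing.

The sample-presentation classifier is this package's own definition (no
standard one exists): the rate in a 1.5 s post-event window is compared
with the 99th percentile of a null built from 1000 circular shifts of the
event times; cells with fewer than 20 events are undetermined and counted
separately.

## Population statistics

Sessions are independent points.  Drug-session reductions are taken relative
to the same animal's control-session mean (per-animal baselines; the pooled
alternative is a flag) and behavioral deficit regressions pool sessions
across animals, each drug session contributing one point.  Group contrasts
report the permutation p (10k label permutations by default; sign-flips in
paired mode) with a parametric t-test alongside, and percentile-bootstrap
CIs.  No multiple-comparison correction is applied across the contrast
family; the number of tests is reported.  The contrast family has 12
metrics: CA1 mean rate, signal theta, filter theta and EI per family, model
/ significant-model / edge counts, mean AUC, and the two behavior-relevant
mode strengths (second feedforward, third feedback).  Behavior correlations
cover both EIs and all six mode strengths.

A convenience converts a performance drop into percent of the range above
chance: a 12.2-point drop from a 74.4% control mean is 24.4% of the 50-point
range above the 50% chance level.

## The synthetic-data generator

The generator emulates what the analysis assumes and nothing more:

* **Inputs** are independent Bernoulli trains with per-bin probability
  `rate·Δ·(1 + depth·cos(2πft))` (defaults 8 Hz, theta 6 Hz, depth 0.6) —
  theta-modulated but otherwise memoryless; real inter-spike statistics
  (bursting, refractoriness of CA3 cells themselves) are not matched.
* **Feedforward filters** are a Gaussian excitatory bump (peak ~12 ms) with
  a delayed inhibitory lobe whose latency is tuned so the filter spectrum
  peaks at a requested frequency (default 8.5 Hz, high theta); EI ≈ 0.67.
* **Feedback filters** are an exponential-plus-Gaussian refractory trough
  (negative through ~40 ms) plus a rebound bump tuned to a 3.5 Hz low-theta
  resonance, and a slow positive component used only by the drug scenario's
  EI shift.
* All ground-truth filters are built inside the Laguerre span of the
  fitting basis (their coefficients are stored), so noise-free recovery is
  exact by construction; `off_basis_component` injects orthogonal energy for
  robustness checks.
* **Output spikes** are Bernoulli with probability clip(drive, 0, 1).  The
  clipped-linear law (not a sigmoid) matches the linear model being fit, so
  recovery is unbiased where the clip is inactive.  The clip *is* active
  during refractory troughs (the drive goes below zero after a spike), which
  is logged; it introduces a mild mismatch between the generative and
  fitted model that the recovery tests absorb (shape correlations ≈ 0.99
  rather than 1).
* **Studies**: each animal has one circuit (default 4 CA3 × 6 CA1, ~half
  the pairs connected) shared by its sessions.  Each drug session draws a
  single latent effect magnitude g ~ U[0.3, 1] that scales all programmed
  channels — feedforward amplitude ×(1−0.4g), oscillatory feedback component
  ×(1−0.75g), additive feedback excitation 0.9g, connection drop 0.25g —
  and behavior = animal baseline − 18.8·g + N(0, 2²).  With 12 drug
  sessions these defaults give a mean drop near 12 points and a latent
  behavior R² near 0.8.  Because one latent magnitude drives every channel,
  each recovered metric's reduction should correlate with behavioral
  deficit; the strongest recoverable coupling sits in the mode-strength
  metrics, whose per-session estimates are the least noisy.

What passing tests show — and do not show.  Recovery results demonstrate
internal consistency: the pipeline finds structure of exactly the kind the
generator programs (linear filters in the fitting span, stationary rates,
independent inputs).  They do not show that real recordings satisfy those
assumptions; in particular the generator has no common input from outside
the observed set, no nonstationarity across a session, and no spike-sorting
noise, all of which can bias effective-connectivity estimates on real data.

## Problem sizes and determinism

Default study analyses use 600 s sessions; calibration suites use 120–300 s
sessions and 20–200 replicates, sizes at which every stated recovery and
calibration property is comfortably resolved.  Every stochastic routine
takes a seed and study generation is a pure function of its seed; all
resample counts are reported alongside their results.
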