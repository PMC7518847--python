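# Methods

## Forward model

The spike-to-fluorescence transform is phenomenological: a
double-exponential calcium kernel followed by a static readout
nonlinearity.  The kernel is used exactly as written (unnormalized
amplitude); the fitted readout scale (F_m, or F_max) absorbs any kernel
normalization, so normalizing the kernel peak would only reparametrize
the model.  The latent c(t) is computed in continuous time — evaluated
exactly at requested time points from the spike list, with a default
1 ms simulation grid when a full trace is materialized — and the readout
is evaluated at imaging-frame centers (67 ms default, one frame).  Frame
sampling is treated as an observation step, not part of the dynamics.

Noise enters in two places.  Internal noise σ_i is white on the
simulation grid and added to c(t) before the zero-truncation (the
truncation order matters: noise can drive the latent negative, the
physical variable cannot be).  Whether internal noise should be white on
the simulation grid or on the frame grid is a genuine modelling choice;
we chose the simulation grid because σ_i stands for fluctuations of the
latent calcium process itself, and flagged the alternative for
sensitivity testing (at 67 ms frames the practical difference is a
rescaling of σ_i).  External noise σ_e is white per output frame,
modelling shot/readout noise of the sampled measurement.

Synthetic ΔF/F is reported raw, including the non-zero sigmoid output at
c = 0.  Baseline handling is analytically consequential (see the
slow-baseline simulation below), so it is kept explicit: an optional
`subtract_baseline` utility exists in the single-neuron module and
nothing subtracts silently.

### Parameters

| parameter | meaning | units | typical (slow / fast indicator) |
|---|---|---|---|
| τ_r | kernel rise time | s | 0.07 / 0.025 |
| τ_d | kernel decay time | s | 1.3 / 0.35 |
| σ_i | internal noise SD | latent units | 0.05 |
| F_m | max fluorescence change (sigmoid) | ΔF/F | 3 / 1.5 |
| k | nonlinearity sharpness | 1/latent | ~1 |
| c_1/2 | half-activation | latent units | 1.5 / 2 |
| σ_e | external noise SD | ΔF/F | 0.02·F_m / 0.05·F_m |
| F_max, F_0 | linear scale / baseline | ΔF/F | — |
| n, K_d | Hill exponent / half-activation | — / latentⁿ | — |

The invariant τ_d > τ_r is enforced structurally (the optimizer works
in log τ_r and log(τ_d − τ_r)).

The shipped per-neuron parameter distributions ("6s-like", "6f-like")
are synthetic and illustrative: lognormal spreads around the medians
above, with the inverse c_1/2–k association imposed through a shared
lognormal factor.  They reflect the qualitative kinetics of slow vs fast
indicators (second-scale vs several-fold faster decay, larger vs smaller
transients) but are not fitted values from any recording; analyses meant
to describe a specific indicator batch should fit their own distribution
from paired data and load it via `ParamDistribution.from_csv`.

## Fitting

Loss and optimizer are not dictated by the model, so we chose mean
squared error between the noise-free model output at the measured frame
times and the measured ΔF/F, minimized by multi-start (default 20)
bounded trust-region least squares.  Multi-start matters because the
sigmoid has a c_1/2–k trade-off ridge; the first start is a data-driven
heuristic (latent scale estimated as mean rate × 1 s) and the rest are
drawn log-uniformly over plausible kinetic ranges.  Fit quality is the
explained variance EV = 1 − SS_res/SS_tot on a held-out validation split
(default 70/30 by trials, mirroring the decoding protocol).  σ_e is
estimated as the training residual standard deviation; σ_i is not
separately identified by the MSE loss and is left at zero by the fitter.

Parameter sensitivity uses a symmetric ±10% relative perturbation around
the optimum, averaged: g = (ΔEV/EV)/(ΔP/P).  The relative formulation
makes g unit-free.  g is undefined (error) when the optimum EV ≤ 0.

Nonlinearity re-matching handles regimes where the recorded dynamic
range under-constrains (k, c_1/2): given a neuron's mean latent and a
library of candidate mean ΔF/F traces, each candidate is fitted with its
own (F_m, k, c_1/2); the best candidate by normalized squared mismatch
is accepted if its Spearman correlation with the matched synthetic trace
exceeds 0.7.  Selection is by fit loss rather than by the correlation
itself because any monotone readout of the same latent has rank
correlation ≈ 1; the correlation is the acceptance gate, not the
ranking.  On failure the function returns `None` and the caller decides
the fallback (our metric-distribution pipeline then draws (k, c_1/2)
jointly from the parameter distribution, preserving their empirical
correlation).

Metric distributions (the distribution of a population measure ψ induced
by parameter and noise variability) are computed by direct Monte Carlo:
per draw, per-neuron parameters are resampled from the empirical
distribution, the whole population is re-simulated, ψ is evaluated, and
the per-draw seed is recorded so any sample can be regenerated.

## Synthetic data

The generator emulates a two-alternative delayed-response task.  Epoch
defaults: 1.0 s presample, 1.3 s sample, 1.3 s delay, 1.5 s response
(sample + delay = 2.6 s is the task constant; the other durations are
conventions — the metrics only consume boundaries, so the schedule is
fully configurable).  Spiking is inhomogeneous Poisson (thinning),
baseline rates 1–10 Hz log-uniform, selectivity injected as stated rate
differences between trial types; sessions require ≥ 20 trials per type.
Ramp-down cells default to a higher baseline (≈12 Hz) because ramping
down needs headroom, matching the empirical association of ramp
direction with baseline rate.  What the generator does **not** emulate:
non-Poisson spiking statistics (bursting, refractoriness), correlated
trial-to-trial variability across neurons, behavioral covariates, and
slow non-stationarities — so passing tests demonstrate correctness of
the transform and metrics under the stated statistical model, not
robustness to every feature of real recordings.

Merge artifacts pair trials by (trial type, index after within-type
shuffling); real sorting merges conflate concurrent activity, but trial
pairing across separately generated neurons is not otherwise defined, so
a random within-type pairing is the neutral choice.  Rate subsampling is
i.i.d. Bernoulli thinning (not time-rescaling): it preserves the
temporal profile shape in expectation, isolating pure rate effects.

### Slow-baseline simulation and the peak-over-ramp ratio

The scenario: tonic baseline (1 s), linear ramp +2 Hz over 4 s, phasic
burst (70 ms at 15 or 30 Hz), reset.  Detectability of the phasic burst
against the ramp is quantified by a peak-over-ramp ratio with two modes.
The plain mode divides the maximum after phasic onset by the maximum
before it (≈ 30/5 = 6 in the spike domain at defaults).  The default
mode measures amplitudes above the running level — phasic amplitude =
(max after onset − pre-onset level), ramp amplitude = (pre-onset level −
tonic baseline mean) — because the plain ratio is bounded below by ~1
for any monotone readout of a growing latent and therefore cannot
express the regime where the fluorescence change comes almost entirely
from the slow ramp and almost not at all from the burst.  The
amplitude-based ratio is the one reported by `slow_baseline_ratios` and
the acceptance script; with slow-indicator parameters the fold reduction
from spikes to fluorescence exceeds an order of magnitude and grows with
the baseline rate.  When binning spikes at the frame interval, the bin
straddling the phasic onset is assigned to the "after" segment so burst
spikes cannot leak into the ramp estimate.

## Single-neuron metrics

The per-bin test is Student's two-sample t-test with pooled variance
(Welch available via `equal_var=False`); no multiple-comparison
correction is applied — the ≥ 5-consecutive-bin same-sign run
requirement is the false-positive control, and under the null it drives
the family-wise rate to ≈ 0 (verified against a brute-force simulation
of the run statistic).  Runs must be strictly consecutive; a single
non-significant bin breaks a run.  Preference of a multiphasic neuron is
taken from its first significant run.  Bins start at presample onset;
a partial final bin is dropped.

The outlier-trial rule (flag a trial when > 30% of its samples are > 3
SD from the median) computes median and SD per neuron across all of its
trials' time points: the rule targets baseline fluctuations across
trials, so the reference population must span trials.

AP-snippet extraction mirrors paired loose-seal/imaging analysis: 1.2 s
snippets whose spikes all fall 0.2–0.4 s from onset, grouped by spike
count; spike-free snippets define the baseline; snippets whose pre-AP
fluorescence deviates > 3 baseline SDs are discarded.  d′ compares the
1-AP peak distribution to baseline peaks; the ROC/AUC uses a threshold
sweep over peak ΔF/F (trapezoid AUC equals the pairwise-comparison
probability, ties counted half).

The PSD-based SNR (noise = amplitude equivalent of exp(mean(log PSD))
over the upper half-band) is only used to rank neurons for
threshold-sweep analyses; its absolute scale is not calibrated.

## Population metrics

PCA centers each neuron by its mean over (type, time) and applies no
variance scaling — the decomposition is of mean-removed activity, not
correlations.  With balanced 2×T scores of zero mean, EV_t + EV_s +
EV_other = 1 exactly per component (two-way ANOVA orthogonality); this
identity is tested to 1e−9 against an explicit-loop oracle.  Bootstrap
uncertainty resamples neurons with replacement (1000 draws default,
seeded).

Peakiness discretizes time in frame bins and treats P_i(t) as
probability mass per (trial type, bin), with uniform reference
P̄ = 1/(2T).  A continuous-density convention would only rescale s; the
mass convention makes s dimensionless, s(uniform) = 0 exactly and
s(point mass) = √(2T − 1), and it is applied uniformly so
cross-condition comparisons are unaffected.  Peak ties break to the
earliest bin.  Per-neuron preference for peak placement is the trial
type with the larger maximum.  Ramp-down cells are excluded from
peakiness (their "peak" is a baseline artifact); flat neurons are
excluded with a reported count.  KL(P‖uniform) is provided as an
alternative dispersion metric with optional pseudo-mass smoothing for
empty bins; s and KL are rank-concordant on uniform→point-mass families.

## Decoding

"Sparsity-regularized LDA" is implemented as diagonal-shrinkage LDA
(per-feature pooled variance shrunk toward its mean, level chosen by
3-fold cross-validation on the training trials over a fixed grid) with
soft-threshold sparsification of the discriminant weights at a quantile
(default 0.25) of their absolute values.  This is a stated stand-in that
reproduces the intent — stability when the population size approaches
the trial count — without the original regularizer.  Chance levels are
0.5 (trial type) and 0.25 (epoch); accuracy is reported per bin, never
trial-pooled.  Train/test trial sets are disjoint and stratified;
degenerate splits are resampled.  Unit subsamples are drawn without
replacement within a draw, independently across draws, all seeded.
Per-neuron affine rescaling of activity changes the CV-selected
shrinkage level in general, so decoder accuracy is only
scale-invariant up to that selection (documented limitation).

The filtered decoder applies a causal boxcar (1 s default) to per-trial
activity before the identical protocol; a window of one bin reduces to
the instantaneous decoder.  The epoch decoder trains one four-class
model on (trial, bin) samples of the training trials and reports
per-bin mean class probabilities, per-bin accuracy, and per-epoch
latency (first bin after epoch onset with accuracy ≥ 0.7, NaN if never
reached).

## Problem sizes and determinism

Default analysis sizes in the test suite and acceptance script (tens of
neurons, 25–200 trials per type, 10–20 optimizer starts, hundreds of
bootstrap draws) were chosen as the smallest sizes at which the
statistics stabilize; every stochastic step takes an integer seed or a
`numpy` Generator and is bit-reproducible given it.  File formats are
plain delimited text with a companion trial table so generated fixtures
round-trip losslessly (spike times to 1e−6 s).

## Known limitations

- The forward model is static per neuron: no adaptation of the
  spike-to-calcium coupling, no photobleaching, no motion artifacts.
- σ_i is not estimated by the MSE fitter (only σ_e, from residuals).
- The shipped parameter distributions are illustrative, not fitted.
- Spike inference (fluorescence-to-spikes) is deliberately out of scope:
  only a subprocess adapter with a documented exchange format is
  provided, and a missing tool raises — it is never silently emulated.
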