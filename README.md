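# spikefluor

Calcium imaging reports spiking only indirectly: the spike → calcium →
indicator-fluorescence chain low-pass filters, delays, saturates and
adds noise to the underlying activity. `spikefluor` implements a
phenomenological **spike-to-fluorescence (S2F) forward model** together
with the full set of single-neuron and population statistics needed to
ask, for any spike-train dataset, *"what would this analysis have looked
like if this population had been recorded with a calcium indicator?"*
It is aimed at systems neuroscientists comparing electrophysiology and
two-photon imaging of the same circuits (e.g. delayed-response-task
recordings in frontal cortex), and at anyone benchmarking
spike-inference algorithms against ground truth.

## The model

Spikes at times {t_k} are convolved with an unnormalized
double-exponential kernel into a latent calcium variable

```
c(t) = Σ_{t_k < t} exp(−(t − t_k)/τ_d) · (1 − exp(−(t − t_k)/τ_r)) + n_i(t)
```

with rise time τ_r, decay time τ_d and internal Gaussian noise
n_i ~ N(0, σ_i²) (c is truncated at zero).  The latent is then pushed
through a readout nonlinearity, sampled at imaging-frame centers
(67 ms default) with external per-frame noise n_e ~ N(0, σ_e²):

- **sigmoid** (default): ΔF/F(t) = F_m / (1 + exp[−k·(c(t) − c_1/2)]) + n_e(t)
- **linear**: F_max·c(t) + F_0 + n_e(t)
- **Hill**: F_max·c(t)ⁿ / (c(t)ⁿ + K_d) + n_e(t)

Model parameters are estimated from paired spike/ΔF/F recordings by
multi-start bounded least squares (`S2FModel(...).fit()`, statsmodels
style), scored as explained variance on held-out trials, with
per-parameter sensitivity g = (ΔEV/EV)/(ΔP/P).

Both representations are scored with identical statistics:

- **selectivity phases** — per-67 ms-bin two-sample t-tests, with a
  ≥ 5-consecutive-bin (>335 ms) same-sign run rule separating
  monophasic / multiphasic / non-selective neurons, plus left/right
  preference and ramp-up/ramp-down classes;
- **PCA variance decomposition** — per principal component, the variance
  split into temporal dynamics EV_t, trial-type EV_s and interaction;
- **peakiness** — s = (1/P̄)·√(⟨(P_i(t) − P̄)²⟩) of the population
  peak-time distribution against temporal uniformity (KL divergence as
  an alternative);
- **decoding** — per-bin shrinkage-regularized LDA of trial type on
  100-unit subsamples (70/30 trial splits), a 1-s-filtered variant, and
  a four-class behavioral-epoch decoder with latency extraction.

A synthetic-data module generates trial-structured Poisson populations
(selectivity archetypes, ramps), spike-sorting merge artifacts, rate
subsampling, the slow-baseline/phasic-burst scenario and the seven
peakiness-sensitivity configurations.

## Worked example

Fit the forward model to paired data it generated itself:

```python
import numpy as np
import spikefluor as sf

rng = np.random.default_rng(7)
true = sf.S2FParams(tau_r=0.06, tau_d=1.2, F_m=3.0, k=1.3, c_half=1.6,
                    sigma_e=0.06)
epochs = sf.EpochSchedule()
spikes, fluor = [], []
for i in range(40):
    tt = "left" if i % 2 else "right"
    st = sf.sample_poisson_train(6.0 if i % 2 else 10.0, 0.0,
                                 epochs.trial_end, rng)
    s = sf.SpikeTrain(st, tt, True, epochs)
    spikes.append(s)
    fluor.append(sf.simulate_fluorescence(s, true, rng_seed=rng))

res = sf.S2FModel(spikes, fluor).fit(n_starts=10, rng_seed=0)
res.sensitivity()
print(res.summary())
```

prints

```
                      S2F model fit
==========================================================
variant:            sigmoid
trials (train/val): 28/12
starts converged:   10
EV (train):         0.9891
EV (validation):    0.9915
MSE per frame:      0.0035633
----------------------------------------------------------
parameter         estimate     sensitivity g
tau_r             0.059484            0.0031
tau_d               1.2152            0.0256
F_m                 2.9971            1.8261
k                   1.3034            0.0157
c_half              1.6116            0.0576
sigma_e           0.059693    (residual std)
==========================================================
```

All five generating parameters come back within a few percent despite
the measurement noise (the true values were τ_r = 0.06, τ_d = 1.2,
F_m = 3.0, k = 1.3, c_1/2 = 1.6, σ_e = 0.06); 99% of the held-out
variance is explained.  The sensitivity column says the fit constrains
F_m tightly while τ_r barely matters at this frame rate — exactly the
kind of parameter heterogeneity information that makes naive inversion
of imaging data hard.

A shell session gets the same machinery via the `spikefluor` CLI
(`simulate`, `transform`, `fit`, `classify`, `pca`, `peakiness`,
`decode`, `sensitivity`, `slow-baseline`, `run`).

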