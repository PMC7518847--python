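"""Synthetic spike-train populations and artifact simulations.

Generators produce trial-structured inhomogeneous-Poisson spike trains
with the response archetypes the metrics assume (monophasic/multiphasic
selectivity, nonselective modulation, ramp-up/ramp-down dynamics), plus
the dedicated artifact scenarios: spike-sorting merges, firing-rate
subsampling, the slow-baseline/phasic-response simulation, and the seven
peakiness-sensitivity configurations.  Everything is reproducible from an
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .forward import frame_centers, simulate_fluorescence
from .params import ParamDistribution, S2FParams, default_distribution
from .trials import (
    FRAME_INTERVAL,
    TRIAL_TYPES,
    EpochSchedule,
    SpikeTrain,
    TrialEnsemble,
    bin_spike_ensemble,
)

__all__ = [
    "RateProfile",
    "ARCHETYPES",
    "make_archetype",
    "sample_poisson_train",
    "generate_population",
    "extend_pretrial",
    "merge_neurons",
    "resample_to_rate",
    "slow_baseline_scenario",
    "peak_over_ramp_ratio",
    "slow_baseline_ratios",
    "peakiness_sensitivity_set",
]

ARCHETYPES = (
    "monophasic_sel",
    "multiphasic_sel",
    "nonselective",
    "ramp_up",
    "ramp_down",
    "custom",
)


@dataclass
class RateProfile:
    """Firing-rate profile: time (s) and trial type -> rate (Hz)."""

    profile: Callable[[np.ndarray, str], np.ndarray]
    archetype: str = "custom"
    baseline_rate: float = 2.0

    def rate(self, t: np.ndarray, trial_type: str) -> np.ndarray:
        r = np.asarray(self.profile(np.asarray(t, dtype=float), trial_type), dtype=float)
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")
        return r

    def max_rate(self, t0: float, t1: float, n_grid: int = 2000) -> float:
        g = np.linspace(t0, t1, n_grid)
        return max(float(self.rate(g, tt).max()) for tt in TRIAL_TYPES)


def _window(t, a, b):
    return (t >= a) & (t < b)


def make_archetype(
    archetype: str,
    epochs: EpochSchedule | None = None,
    baseline: float = 2.0,
    delta: float = 6.0,
    preference: str = "right",
) -> RateProfile:
    """Build one of the canonical rate profiles.

    ``delta`` is the selectivity (or modulation) amplitude in Hz.
    Ramp-down cells keep the preferred type near a high baseline while the
    non-preferred type ramps down; ramp-up cells ramp the preferred type
    up from a low baseline — mirroring the association of preference with
    ramp direction seen in frontal-cortex recordings.
    """
    e = epochs or EpochSchedule()
    other = "left" if preference == "right" else "right"

    if archetype == "monophasic_sel":
        def profile(t, tt):
            r = np.full_like(t, baseline, dtype=float)
            if tt == preference:
                r = r + delta * _window(t, e.sample_start, e.response_start)
            return r
    elif archetype == "multiphasic_sel":
        def profile(t, tt):
            r = np.full_like(t, baseline, dtype=float)
            mid = 0.5 * (e.delay_start + e.response_start)
            if tt == preference:
                r = r + delta * _window(t, e.sample_start, e.delay_start)
            else:
                r = r + delta * _window(t, e.delay_start, e.trial_end)
            del mid
            return r
    elif archetype == "nonselective":
        def profile(t, tt):
            return baseline + delta * _window(t, e.sample_start, e.delay_start)
    elif archetype == "ramp_up":
        def profile(t, tt):
            frac = np.clip(
                (t - e.sample_start) / (e.response_start - e.sample_start), 0, 1
            )
            gain = delta if tt == preference else 0.25 * delta
            return baseline + gain * frac
    elif archetype == "ramp_down":
        def profile(t, tt):
            frac = np.clip(
                (t - e.sample_start) / (e.response_start - e.sample_start), 0, 1
            )
            depth = min(delta, 0.9 * baseline)
            drop = depth if tt == other else 0.15 * depth
            return baseline - drop * frac
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return RateProfile(profile, archetype, baseline)


def sample_poisson_train(
    rate: RateProfile | Callable[[np.ndarray], np.ndarray] | float,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    trial_type: str = "right",
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on [t0, t1) by thinning."""
    if isinstance(rate, RateProfile):
        rate_fn = lambda t: rate.rate(t, trial_type)
        rmax = rate.max_rate(t0, t1)
    elif callable(rate):
        rate_fn = rate
        rmax = float(np.max(rate_fn(np.linspace(t0, t1, 2000))))
    else:
        const = float(rate)
        rate_fn = lambda t: np.full_like(t, const)
        rmax = const
    if rmax <= 0:
        return np.array([])
    n = rng.poisson(rmax * (t1 - t0))
    times = np.sort(rng.uniform(t0, t1, size=n))
    keep = rng.random(n) < rate_fn(times) / rmax
    times = times[keep]
    return np.unique(times)


def generate_population(
    n_neurons: int,
    archetype_mix: dict[str, float],
    epochs: EpochSchedule | None = None,
    n_trials_per_type: int = 25,
    rng_seed: int | None = 0,
    baseline_range: tuple[float, float] = (1.0, 10.0),
    delta: float = 6.0,
    ramp_down_baseline: float = 12.0,
) -> list[TrialEnsemble]:
    """Population of trial-structured Poisson neurons.

    ``archetype_mix`` maps archetype name to fraction (must sum to 1);
    sessions require at least 20 trials per type.  Baseline rates are
    drawn log-uniformly from ``baseline_range`` except for ramp-down cells
    whose baseline centers on ``ramp_down_baseline`` (ramping down needs
    headroom).  Preference alternates across selective neurons.
    """
    if n_trials_per_type < 20:
        raise ValueError("need at least 20 trials per trial type")
    total = sum(archetype_mix.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"archetype fractions must sum to 1, got {total}")
    epochs = epochs or EpochSchedule()
    rng = np.random.default_rng(rng_seed)

    # largest-remainder allocation of neurons to archetypes
    names = sorted(archetype_mix)
    raw = np.array([archetype_mix[a] * n_neurons for a in names])
    counts = np.floor(raw).astype(int)
    rem = n_neurons - counts.sum()
    for i in np.argsort(raw - np.floor(raw))[::-1][:rem]:
        counts[i] += 1

    ensembles: list[TrialEnsemble] = []
    nid = 0
    for name, cnt in zip(names, counts):
        for j in range(cnt):
            if name == "ramp_down":
                base = ramp_down_baseline * np.exp(rng.normal(0, 0.2))
            else:
                lo, hi = baseline_range
                base = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            pref = TRIAL_TYPES[(nid + j) % 2]
            prof = make_archetype(name, epochs, baseline=base, delta=delta, preference=pref)
            trials = []
            for tt in TRIAL_TYPES:
                for _ in range(n_trials_per_type):
                    st = sample_poisson_train(prof, 0.0, epochs.trial_end, rng, tt)
                    trials.append(SpikeTrain(st, tt, True, epochs))
            ensembles.append(TrialEnsemble(trials, neuron_id=nid))
            nid += 1
    return ensembles


def extend_pretrial(
    spikes: SpikeTrain,
    extension: float,
    baseline_rate: float,
    rng_seed: int | np.random.Generator | None = None,
) -> SpikeTrain:
    """Prepend a homogeneous-Poisson baseline on [t_start - extension,
    t_start), emulating the unrecorded inter-trial interval."""
    if extension <= 0:
        raise ValueError("extension must be > 0")
    rng = np.random.default_rng(rng_seed)
    t0 = spikes.t_start - extension
    pre = sample_poisson_train(baseline_rate, t0, spikes.t_start, rng)
    times = np.concatenate([pre, spikes.spike_times])
    return SpikeTrain(times, spikes.trial_type, spikes.correct, spikes.epochs, t_start=t0)


def merge_neurons(
    ensembles: Sequence[TrialEnsemble],
    p_merge: float,
    rng_seed: int | None = 0,
) -> list[TrialEnsemble]:
    """Simulate spike-sorting merge artifacts.

    Each neuron independently, with probability ``p_merge``, is conflated
    with one other (uniformly chosen, not yet consumed) neuron: their
    per-trial spike trains are unioned, trials paired by trial type and
    index after shuffling within type.  A merged pair replaces both
    members with a single unit.
    """
    if not 0 <= p_merge <= 1:
        raise ValueError("p_merge must be in [0, 1]")
    if len(ensembles) < 2:
        raise ValueError("need at least 2 neurons")
    rng = np.random.default_rng(rng_seed)
    consumed: set[int] = set()
    out: list[TrialEnsemble] = []
    n = len(ensembles)
    for i in range(n):
        if i in consumed:
            continue
        free = [j for j in range(n) if j != i and j not in consumed]
        if free and rng.random() < p_merge:
            j = int(rng.choice(free))
            consumed.update((i, j))
            out.append(_union_ensembles(ensembles[i], ensembles[j], rng))
        else:
            consumed.add(i)
            out.append(ensembles[i])
    return out


def _union_ensembles(
    a: TrialEnsemble, b: TrialEnsemble, rng: np.random.Generator
) -> TrialEnsemble:
    trials = []
    for tt in TRIAL_TYPES:
        ta = a.by_type(tt)
        tb = b.by_type(tt)
        rng.shuffle(ta)
        rng.shuffle(tb)
        for sa, sb in zip(ta, tb):
            times = np.unique(np.concatenate([sa.spike_times, sb.spike_times]))
            trials.append(
                SpikeTrain(times, tt, sa.correct, sa.epochs,
                           t_start=min(sa.t_start, sb.t_start))
            )
    return TrialEnsemble(trials, neuron_id=f"{a.neuron_id}+{b.neuron_id}")


def resample_to_rate(
    spikes: SpikeTrain,
    target_mean_rate: float,
    rng_seed: int | np.random.Generator | None = None,
    current_rate: float | None = None,
) -> SpikeTrain:
    """Subsample a spike train to a target mean rate by i.i.d. Bernoulli
    thinning (preserves the temporal profile shape in expectation).

    ``current_rate`` may be supplied (e.g. an ensemble-level estimate) to
    thin all trials of a neuron with a common probability.
    """
    duration = spikes.t_end - spikes.t_start
    cur = current_rate if current_rate is not None else spikes.n_spikes / duration
    if target_mean_rate > cur + 1e-12:
        raise ValueError(
            f"target rate {target_mean_rate} Hz above current {cur:.3g} Hz "
            "(thinning only)"
        )
    if cur == 0 or target_mean_rate == cur:
        return spikes
    rng = np.random.default_rng(rng_seed)
    keep = rng.random(spikes.n_spikes) < target_mean_rate / cur
    return SpikeTrain(
        spikes.spike_times[keep], spikes.trial_type, spikes.correct, spikes.epochs,
        t_start=spikes.t_start,
    )


# ---------------------------------------------------------------------------
# slow-baseline simulation
# ---------------------------------------------------------------------------

def slow_baseline_scenario(
    baseline_rate: float = 3.0,
    ramp_delta: float = 2.0,
    ramp_duration: float = 4.0,
    phasic_rate: float = 30.0,
    phasic_duration: float = 0.07,
    n_trials: int = 200,
    baseline_duration: float = 1.0,
    post_duration: float = 1.0,
    rng_seed: int | None = 0,
) -> TrialEnsemble:
    """Single neuron whose rate ramps slowly from ``baseline_rate`` to
    ``baseline_rate + ramp_delta`` over ``ramp_duration``, fires a brief
    phasic burst at ``phasic_rate`` for ``phasic_duration``, then resets
    to baseline.  The epoch schedule encodes the segment boundaries
    (sample = ramp onset, delay = phasic onset, response = reset)."""
    if min(baseline_rate, ramp_duration, phasic_rate, phasic_duration) <= 0:
        raise ValueError("durations and rates must be positive")
    t_ramp = baseline_duration
    t_phasic = t_ramp + ramp_duration
    t_reset = t_phasic + phasic_duration
    t_end = t_reset + post_duration
    epochs = EpochSchedule(0.0, t_ramp, t_phasic, t_reset, t_end)

    def profile(t, tt):
        r = np.full_like(t, baseline_rate, dtype=float)
        ramp = _window(t, t_ramp, t_phasic)
        r[ramp] = baseline_rate + ramp_delta * (t[ramp] - t_ramp) / ramp_duration
        r[_window(t, t_phasic, t_reset)] = phasic_rate
        return r

    prof = RateProfile(profile, "custom", baseline_rate)
    rng = np.random.default_rng(rng_seed)
    trials = [
        SpikeTrain(sample_poisson_train(prof, 0.0, t_end, rng, "right"),
                   "right", True, epochs)
        for _ in range(n_trials)
    ]
    return TrialEnsemble(trials, neuron_id="slow_baseline")


def peak_over_ramp_ratio(
    times: np.ndarray,
    values: np.ndarray,
    phasic_onset: float,
    baseline_end: float | None = None,
) -> float:
    """Detectability of a phasic response against a slow ramp.

    With ``baseline_end`` given (the end of the tonic baseline segment),
    amplitudes are measured above the running level: the ratio is
    (max after phasic onset - pre-onset level) over (pre-onset level -
    tonic baseline mean).  Without it, the plain ratio of the maximum
    after onset to the maximum before onset is returned.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    after = values[times >= phasic_onset]
    before = values[times < phasic_onset]
    if after.size == 0 or before.size == 0:
        raise ValueError("phasic onset must split the trace")
    if baseline_end is None:
        return float(after.max() / before.max())
    base = values[times < baseline_end]
    ramp = values[(times >= baseline_end) & (times < phasic_onset)]
    if base.size == 0 or ramp.size == 0:
        raise ValueError("baseline_end must precede phasic onset")
    pre_level = ramp.max()
    ramp_amp = pre_level - base.mean()
    peak_amp = after.max() - pre_level
    if ramp_amp <= 0:
        raise ValueError("no ramp amplitude above baseline")
    return float(peak_amp / ramp_amp)


def slow_baseline_ratios(
    ensemble: TrialEnsemble,
    params: S2FParams,
    frame_interval: float = FRAME_INTERVAL,
    dt: float = 0.001,
    rng_seed: int | None = 0,
    subtract_baseline: bool = True,
) -> dict[str, float]:
    """Peak-over-ramp ratios of a slow-baseline ensemble in the spike
    domain (trial-averaged rate) and the fluorescence domain (mean
    synthetic dF/F), and the fold reduction between them."""
    epochs = ensemble.epochs
    # a bin whose window overlaps the phasic interval counts as "after":
    # split half a frame before the onset so the straddling bin cannot
    # leak phasic spikes into the ramp segment
    onset = epochs.delay_start - frame_interval / 2
    base_end = epochs.sample_start if subtract_baseline else None

    binned = bin_spike_ensemble(ensemble, bin_width=frame_interval, as_rate=True)
    psth = binned.matrix.mean(axis=0)
    spike_ratio = peak_over_ramp_ratio(binned.bin_centers, psth, onset, base_end)

    rng = np.random.default_rng(rng_seed)
    fluor = [
        simulate_fluorescence(tr, params, frame_interval=frame_interval, dt=dt,
                              rng_seed=rng)
        for tr in ensemble.trials
    ]
    mean_dff = np.mean([f.values for f in fluor], axis=0)
    fluor_ratio = peak_over_ramp_ratio(fluor[0].frame_times, mean_dff, onset, base_end)
    return {
        "spike_ratio": spike_ratio,
        "fluor_ratio": fluor_ratio,
        "reduction_factor": spike_ratio / fluor_ratio,
    }


# ---------------------------------------------------------------------------
# peakiness sensitivity configurations
# ---------------------------------------------------------------------------

def peakiness_sensitivity_set(
    variant: int,
    n_neurons: int = 50,
    rng_seed: int | None = 0,
    indicator: str = "6s",
    n_trials_per_type: int = 25,
    epochs: EpochSchedule | None = None,
    n_base_spikes: int = 3,
    rate_range: tuple[float, float] = (0.1, 5.0),
) -> tuple[list[TrialEnsemble], list[S2FParams]]:
    """The seven artificial configurations probing what disperses peak
    times: all neurons fire only within one imaging frame, and the
    variants progressively free spike jitter, firing rate, the indicator
    decay time and the nonlinearity.

    1. shared parameters, identical spike times (noise only)
    2. shared parameters, spikes jittered within the frame
    3. shared parameters, per-neuron rates spanning ``rate_range`` Hz
       (Poisson spike counts, all spikes within the frame)
    4. decay time resampled per neuron
    5. nonlinearity (k, c_half) resampled per neuron
    6. decay time and nonlinearity resampled
    7. as 6, plus variable rates as in 3
    """
    if variant not in range(1, 8):
        raise ValueError("variant must be 1..7")
    epochs = epochs or EpochSchedule()
    rng = np.random.default_rng(rng_seed)
    dist = default_distribution(indicator, n_samples=max(200, n_neurons), seed=12345)
    base = S2FParams(sigma_i=0.05, sigma_e=0.06) if indicator.startswith("6s") else \
        S2FParams(tau_r=0.025, tau_d=0.35, F_m=1.5, k=1.0, c_half=2.0,
                  sigma_i=0.05, sigma_e=0.075)

    # the single active frame: first frame of the delay epoch
    ft = frame_centers(0.0, epochs.trial_end, FRAME_INTERVAL)
    frame_idx = int(np.searchsorted(ft - FRAME_INTERVAL / 2, epochs.delay_start))
    f0 = frame_idx * FRAME_INTERVAL
    f1 = f0 + FRAME_INTERVAL
    base_times = f0 + FRAME_INTERVAL * (np.arange(n_base_spikes) + 1) / (n_base_spikes + 1)

    jitter = variant in (2,)
    var_rate = variant in (3, 7)
    var_tau = variant in (4, 6, 7)
    var_nl = variant in (5, 6, 7)

    rates = np.geomspace(rate_range[0], rate_range[1], n_neurons)
    ensembles, params_list = [], []
    for i in range(n_neurons):
        p = base
        row = dist.samples[int(rng.integers(0, len(dist)))]
        if var_tau:
            p = p.replace(tau_d=max(row.tau_d, p.tau_r * 1.5))
        if var_nl:
            p = p.replace(k=row.k, c_half=row.c_half)
        params_list.append(p)
        trials = []
        for tt in TRIAL_TYPES:
            for _ in range(n_trials_per_type):
                if var_rate:
                    count = rng.poisson(rates[i] * epochs.trial_end)
                    times = np.unique(rng.uniform(f0, f1, size=count))
                elif jitter:
                    times = np.unique(rng.uniform(f0, f1, size=n_base_spikes))
                else:
                    times = base_times.copy()
                trials.append(SpikeTrain(times, tt, True, epochs))
        ensembles.append(TrialEnsemble(trials, neuron_id=i))
    return ensembles, params_list
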