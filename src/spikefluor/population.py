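"""Population-level statistics.

PCA is performed on trial-type-averaged activity r(s,t) (neurons x 2T,
the two trial types concatenated) after subtracting each neuron's mean
over (s,t).  Per principal component, the variance is decomposed into a
temporal-dynamics fraction

    EV_t(i) = < <x_i(s,t)>_s^2 >_t / < x_i(s,t)^2 >_{t,s},

a trial-type fraction EV_s(i) (s and t roles swapped) and an interaction
remainder EV_other = 1 - EV_t - EV_s.  With balanced (2 x T) scores of
zero grand mean the three fractions are an exact ANOVA decomposition.

"Peakiness" s measures how far the distribution of per-neuron peak times
P_i(t) (mass per trial type x bin, summing to 1) deviates from temporal
uniformity Pbar = 1/(2T):

    s = (1/Pbar) * sqrt( (1/(2T)) * sum_i sum_t (P_i(t) - Pbar)^2 )

so s = 0 exactly for a uniform peak-time distribution.  The
Kullback-Leibler divergence from uniform is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trials import TRIAL_TYPES, BinnedActivity

__all__ = [
    "PopulationTensor",
    "PCADecomposition",
    "PeakinessResult",
    "build_tensor",
    "pca_decompose",
    "peak_time_distribution",
    "peakiness",
    "peakiness_kl",
    "heatmap_order",
]


@dataclass
class PopulationTensor:
    """Trial-averaged activity, neurons x trial-type x time."""

    data: np.ndarray  # (n_neurons, 2, T); axis 1 ordered as TRIAL_TYPES
    bin_centers: np.ndarray
    normalized: bool = False
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("tensor must be (n_neurons, 2, T)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("tensor has missing bins")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.data.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    @property
    def flat(self) -> np.ndarray:
        """(n_neurons, 2T) view: both trial types concatenated."""
        return self.data.reshape(self.n_neurons, -1)

    @property
    def mean_vector(self) -> np.ndarray:
        """Per-neuron mean over (s, t): the PCA centering vector."""
        return self.flat.mean(axis=1)


@dataclass
class PCADecomposition:
    components: np.ndarray  # (n_neurons, n_pcs)
    scores: np.ndarray  # (n_pcs, 2, T)
    variance_fraction: np.ndarray  # per PC
    ev_time: np.ndarray
    ev_type: np.ndarray
    ev_other: np.ndarray
    ev_time_std: np.ndarray | None = None
    ev_type_std: np.ndarray | None = None


@dataclass
class PeakinessResult:
    s: float
    distribution: np.ndarray  # (2, T) peak-time mass per trial type
    uniform_mass: float
    bootstrap_std: float | None = None
    n_excluded: int = 0


def build_tensor(
    binned_list: list[BinnedActivity], normalize: bool = False
) -> PopulationTensor:
    """Stack trial-type-averaged activity of a population.

    With ``normalize`` each neuron is scaled by its maximum across both
    trial types (the heatmap / peak-analysis convention).
    """
    if not binned_list:
        raise ValueError("empty population")
    n_bins = binned_list[0].n_bins
    centers = binned_list[0].bin_centers
    rows = []
    for b in binned_list:
        if b.n_bins != n_bins:
            raise ValueError("heterogeneous binning across neurons")
        rows.append([b.trial_mean(tt) for tt in TRIAL_TYPES])
    data = np.asarray(rows, dtype=float)
    if normalize:
        peak = np.abs(data).max(axis=(1, 2), keepdims=True)
        peak[peak == 0] = 1.0
        data = data / peak
    return PopulationTensor(data, centers, normalized=normalize)


def _ev_fractions(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EV_t, EV_s, EV_other per PC from (n_pcs, 2, T) scores."""
    total = (scores**2).mean(axis=(1, 2))
    total = np.where(total == 0, np.nan, total)
    ev_t = (scores.mean(axis=1) ** 2).mean(axis=1) / total
    ev_s = (scores.mean(axis=2) ** 2).mean(axis=1) / total
    return ev_t, ev_s, 1.0 - ev_t - ev_s


def pca_decompose(
    tensor: PopulationTensor,
    n_components: int | None = None,
    n_boot: int = 1000,
    rng_seed: int | None = 0,
) -> PCADecomposition:
    """PCA of mean-centered trial-averaged activity with per-PC variance
    decomposition into temporal, trial-type and interaction content.

    Bootstrap (resampling neurons with replacement) gives the standard
    deviation of the EV fractions; set ``n_boot=0`` to skip it.
    """
    if tensor.n_neurons < 2 or tensor.n_bins < 2:
        raise ValueError("need at least 2 neurons and 2 bins")
    R = tensor.flat - tensor.mean_vector[:, None]
    if not np.any(R):
        raise ValueError("degenerate (zero-variance) tensor")

    def decompose(Rmat):
        U, S, Vt = np.linalg.svd(Rmat, full_matrices=False)
        k = n_components or S.size
        comps = U[:, :k]
        scores = (S[:k, None] * Vt[:k]).reshape(k, 2, tensor.n_bins)
        var_frac = S[:k] ** 2 / (S**2).sum()
        return comps, scores, var_frac

    comps, scores, var_frac = decompose(R)
    ev_t, ev_s, ev_o = _ev_fractions(scores)
    ev_t_std = ev_s_std = None
    if n_boot:
        rng = np.random.default_rng(rng_seed)
        k = scores.shape[0]
        bt, bs = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, tensor.n_neurons, size=tensor.n_neurons)
            Rb = R[idx]
            if not np.any(Rb):
                continue
            _, sc, _ = decompose(Rb)
            t_, s_, _ = _ev_fractions(sc)
            bt.append(t_[:k])
            bs.append(s_[:k])
        if bt:
            ev_t_std = np.std(np.vstack(bt), axis=0)
            ev_s_std = np.std(np.vstack(bs), axis=0)
    return PCADecomposition(comps, scores, var_frac, ev_t, ev_s, ev_o, ev_t_std, ev_s_std)


def peak_time_distribution(
    tensor: PopulationTensor,
    exclude: np.ndarray | None = None,
    min_range: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-neuron peak placement and the population peak-time distribution.

    For each neuron the peak bin of trial-averaged activity in its
    preferred trial type (the type with the larger maximum) is found; ties
    go to the earliest bin.  Flat neurons (range <= ``min_range``) and
    neurons flagged in ``exclude`` (e.g. ramp-down cells) are dropped.

    Returns (peaks, P, n_excluded) where ``peaks`` is (n_kept, 2) of
    (type_index, bin) and ``P`` is the (2, T) distribution of total mass 1.
    """
    data = tensor.data
    n, _, T = data.shape
    if exclude is None:
        exclude = np.zeros(n, dtype=bool)
    peaks = []
    n_excluded = 0
    for i in range(n):
        if exclude[i]:
            n_excluded += 1
            continue
        if np.ptp(data[i]) <= min_range:
            n_excluded += 1
            continue
        pref = int(np.argmax(data[i].max(axis=1)))  # earliest/lowest index on tie
        peak_bin = int(np.argmax(data[i, pref]))
        peaks.append((pref, peak_bin))
    if not peaks:
        raise ValueError("no neurons left after exclusions")
    peaks = np.array(peaks, dtype=int)
    P = np.zeros((2, T))
    for s, b in peaks:
        P[s, b] += 1
    P /= P.sum()
    return peaks, P, n_excluded


def peakiness(
    P: np.ndarray,
    peaks: np.ndarray | None = None,
    n_boot: int = 1000,
    rng_seed: int | None = 0,
) -> PeakinessResult:
    """Peakiness s of a normalized peak-time distribution.

    When per-neuron peak assignments are supplied, a bootstrap over
    neurons yields the standard deviation of s.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError("P must be (n_trial_types, n_bins)")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError(f"P must sum to 1, got {P.sum()}")
    n_total = P.size
    pbar = 1.0 / n_total
    s = np.sqrt(np.mean((P - pbar) ** 2)) / pbar
    boot_std = None
    if peaks is not None and n_boot:
        rng = np.random.default_rng(rng_seed)
        n = peaks.shape[0]
        vals = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Pb = np.zeros_like(P)
            for s_i, b_i in peaks[idx]:
                Pb[s_i, b_i] += 1
            Pb /= n
            vals[b] = np.sqrt(np.mean((Pb - pbar) ** 2)) / pbar
        boot_std = float(vals.std())
    return PeakinessResult(float(s), P, pbar, boot_std)


def peakiness_kl(P: np.ndarray, smoothing: float = 0.0) -> float:
    """KL(P || uniform) of a normalized peak-time distribution.

    ``smoothing`` adds a pseudo-mass per bin before re-normalizing (small-
    count smoothing for empirical distributions with empty bins).
    """
    P = np.asarray(P, dtype=float)
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("P must sum to 1")
    if smoothing > 0:
        P = (P + smoothing) / (P + smoothing).sum()
    pbar = 1.0 / P.size
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / pbar)))


def heatmap_order(tensor: PopulationTensor) -> np.ndarray:
    """Neuron ordering for population heatmaps: grouped by preferred trial
    type, then sorted by latency of peak activity."""
    data = tensor.data
    pref = np.argmax(data.max(axis=2), axis=1)
    peak_bin = np.array([int(np.argmax(data[i, pref[i]])) for i in range(len(data))])
    return np.lexsort((peak_bin, pref))
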