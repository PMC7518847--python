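"""Single-neuron metrics, applied identically to spike rates and dF/F.

Trial-type selectivity is assessed per 67 ms bin with two-sample t-tests;
a neuron is selective if significance persists for at least 5 consecutive
bins (>335 ms) of consistent sign, and multiphasic if significant runs of
both signs occur.  Ramp class compares baseline- vs delay-epoch activity
with a paired t-test.  Detectability of action potentials in fluorescence
is quantified with ROC curves and d-prime over snippet peak dF/F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .trials import BinnedActivity, EpochSchedule, FluorTrace

__all__ = [
    "SelectivityLabel",
    "DPrimeResult",
    "classify_selectivity",
    "classify_ramp",
    "extract_ap_snippets",
    "detectability",
    "neuropil_correct",
    "flag_outlier_trials",
    "preprocess_fluor",
    "estimate_snr",
    "subtract_baseline",
]


@dataclass
class SelectivityLabel:
    category: str  # nonselective | monophasic | multiphasic
    preference: str  # left | right | none
    ramp: str = "unknown"  # ramp_up | ramp_down | other | unknown
    significant_runs: list[tuple[int, int, int]] = field(default_factory=list)
    # each run is (start_bin, end_bin_exclusive, sign); sign +1 = right > left


@dataclass
class DPrimeResult:
    d_prime: float
    roc_points: np.ndarray  # (n, 2) of (fpr, tpr)
    auc: float


def _significant_runs(sig: np.ndarray, sign: np.ndarray, min_run: int):
    """Maximal runs of consecutive significant bins with constant sign."""
    runs = []
    i, n = 0, sig.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < n and sig[j] and sign[j] == sign[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j, int(sign[i])))
        i = j
    return runs


def classify_selectivity(
    binned: BinnedActivity,
    alpha: float = 0.05,
    min_run_bins: int = 5,
    equal_var: bool = True,
    min_trials: int = 20,
) -> SelectivityLabel:
    """Classify trial-type selectivity as nonselective / monophasic /
    multiphasic from per-bin two-sample t-tests (left vs right trials).

    Preference is the trial type with higher activity in the first
    significant run.
    """
    left = binned.by_type("left")
    right = binned.by_type("right")
    if left.shape[0] < min_trials or right.shape[0] < min_trials:
        raise ValueError(
            f"need >= {min_trials} trials per type, got "
            f"left={left.shape[0]}, right={right.shape[0]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(right, left, axis=0, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)
    diff = right.mean(axis=0) - left.mean(axis=0)
    sig = p < alpha
    sign = np.sign(diff).astype(int)
    sign[sign == 0] = 1
    runs = _significant_runs(sig, sign, min_run_bins)
    if not runs:
        return SelectivityLabel("nonselective", "none", significant_runs=runs)
    signs = {s for _, _, s in runs}
    category = "multiphasic" if len(signs) > 1 else "monophasic"
    preference = "right" if runs[0][2] > 0 else "left"
    return SelectivityLabel(category, preference, significant_runs=runs)


def classify_ramp(
    binned: BinnedActivity,
    epochs: EpochSchedule | None = None,
    alpha: float = 0.05,
) -> str:
    """Ramp class from a paired t-test of baseline-epoch vs delay-epoch
    per-trial mean activity: greater baseline -> ramp_down, greater delay
    -> ramp_up, otherwise other."""
    epochs = epochs or binned.epochs
    t = binned.bin_centers
    b0, b1 = epochs.epoch_window("presample")
    d0, d1 = epochs.epoch_window("delay")
    base_bins = (t >= b0) & (t < b1)
    delay_bins = (t >= d0) & (t < d1)
    if not base_bins.any() or not delay_bins.any():
        raise ValueError("baseline or delay epoch contains no bins")
    base = binned.matrix[:, base_bins].mean(axis=1)
    delay = binned.matrix[:, delay_bins].mean(axis=1)
    if base.size < 2:
        raise ValueError("need at least 2 trials for the paired test")
    tstat, p = stats.ttest_rel(base, delay)
    if np.isnan(p) or p >= alpha:
        return "other"
    return "ramp_down" if tstat > 0 else "ramp_up"


def extract_ap_snippets(
    fluor_values: np.ndarray,
    frame_times: np.ndarray,
    spike_times: np.ndarray,
    snippet_len: float = 1.2,
    ap_window: tuple[float, float] = (0.2, 0.4),
    baseline_tol_sd: float = 3.0,
) -> dict[int, list[np.ndarray]]:
    """Cut snippets of a continuous paired recording around isolated APs.

    A snippet of length ``snippet_len`` qualifies if all its spikes fall in
    ``ap_window`` from snippet onset.  No-spike snippets (key 0) define the
    baseline distribution; AP snippets whose pre-AP fluorescence (before
    ``ap_window[0]``) deviates from the baseline median by more than
    ``baseline_tol_sd`` baseline SDs are excluded.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    fluor_values = np.asarray(fluor_values, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    t_end = frame_times[-1]

    def window(t0):
        m = (frame_times >= t0) & (frame_times < t0 + snippet_len)
        return fluor_values[m]

    groups: dict[int, list[np.ndarray]] = {0: []}
    # no-AP snippets: non-overlapping spike-free windows
    t0 = frame_times[0]
    while t0 + snippet_len <= t_end:
        n_in = np.count_nonzero((spike_times >= t0) & (spike_times < t0 + snippet_len))
        if n_in == 0:
            groups[0].append(window(t0))
            t0 += snippet_len
        else:
            t0 += snippet_len / 4
    if groups[0]:
        base_all = np.concatenate(groups[0])
        base_med, base_sd = np.median(base_all), np.std(base_all)
    else:
        base_med, base_sd = 0.0, np.inf

    # AP snippets anchored so the first spike sits at ap_window[0]
    i = 0
    while i < spike_times.size:
        onset = spike_times[i] - ap_window[0]
        in_snip = (spike_times >= onset) & (spike_times < onset + snippet_len)
        in_win = (spike_times >= onset + ap_window[0]) & (
            spike_times < onset + ap_window[1]
        )
        n_snip = int(np.count_nonzero(in_snip))
        n_win = int(np.count_nonzero(in_win))
        if n_snip == n_win and onset >= frame_times[0] and onset + snippet_len <= t_end:
            vals = window(onset)
            pre = vals[: max(1, int(round(ap_window[0] / snippet_len * vals.size)))]
            if np.abs(pre.mean() - base_med) <= baseline_tol_sd * base_sd:
                groups.setdefault(n_win, []).append(vals)
            i += n_snip
        else:
            i += 1
    return groups


def detectability(
    snippets: dict[int, list[np.ndarray]], n_aps: int = 1
) -> DPrimeResult:
    """ROC and d-prime for detecting ``n_aps`` action potentials against
    baseline fluorescence fluctuations, from snippet peak dF/F.

    d' = (<max dF/F>_AP - <max dF/F>_noAP) / std(max dF/F)_noAP.
    """
    if not snippets.get(0):
        raise ValueError("baseline (0-AP) snippet group is empty")
    if not snippets.get(n_aps):
        raise ValueError(f"{n_aps}-AP snippet group is empty")
    base_peaks = np.array([s.max() for s in snippets[0]])
    ap_peaks = np.array([s.max() for s in snippets[n_aps]])
    sd = base_peaks.std()
    if sd == 0:
        raise ValueError("zero baseline variance: d-prime undefined")
    d_prime = (ap_peaks.mean() - base_peaks.mean()) / sd

    thresholds = np.concatenate(
        [[np.inf], np.unique(np.concatenate([base_peaks, ap_peaks]))[::-1], [-np.inf]]
    )
    tpr = [(ap_peaks >= th).mean() for th in thresholds]
    fpr = [(base_peaks >= th).mean() for th in thresholds]
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return DPrimeResult(float(d_prime), roc, auc)


def neuropil_correct(
    f_roi: np.ndarray, f_neuropil: np.ndarray, r: float = 0.7
) -> np.ndarray:
    """F_cell(t) = F_roi(t) - r * F_neuropil(t)."""
    f_roi = np.asarray(f_roi, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_roi.shape != f_neuropil.shape:
        raise ValueError("ROI and neuropil traces must have the same shape")
    return f_roi - r * f_neuropil


def flag_outlier_trials(
    trial_matrix: np.ndarray, outlier_sd: float = 3.0, outlier_frac: float = 0.30
) -> np.ndarray:
    """Flag trials in which more than ``outlier_frac`` of time points lie
    more than ``outlier_sd`` SDs from the median.  Median and SD are taken
    per neuron across all of its trials' time points."""
    m = np.asarray(trial_matrix, dtype=float)
    med = np.median(m)
    sd = m.std()
    if sd == 0:
        return np.zeros(m.shape[0], dtype=bool)
    frac_out = (np.abs(m - med) > outlier_sd * sd).mean(axis=1)
    return frac_out > outlier_frac


def preprocess_fluor(
    traces: list[FluorTrace],
    neuropil: list[np.ndarray] | None = None,
    r: float = 0.7,
    outlier_sd: float = 3.0,
    outlier_frac: float = 0.30,
) -> tuple[list[FluorTrace], np.ndarray]:
    """Neuropil-correct per-trial traces and flag outlier trials.

    Returns (corrected traces, keep-mask over trials).
    """
    if neuropil is not None:
        if len(neuropil) != len(traces):
            raise ValueError("need one neuropil trace per trial")
        traces = [
            FluorTrace(
                tr.frame_times,
                neuropil_correct(tr.values, npil, r=r),
                tr.trial_type,
                tr.correct,
                tr.epochs,
            )
            for tr, npil in zip(traces, neuropil)
        ]
    matrix = np.stack([tr.values for tr in traces])
    keep = ~flag_outlier_trials(matrix, outlier_sd, outlier_frac)
    return traces, keep


def subtract_baseline(values: np.ndarray, baseline_bins: int) -> np.ndarray:
    """Subtract the mean of the first ``baseline_bins`` samples.

    The forward model reports dF/F raw (including the nonzero readout at
    c = 0); this optional utility makes baseline handling explicit.
    """
    values = np.asarray(values, dtype=float)
    return values - values[:baseline_bins].mean()


def estimate_snr(
    values: np.ndarray, frame_interval: float = 0.067, min_len: int = 64
) -> float:
    """SNR used to rank neurons: peak signal range over a PSD-based noise
    level, the exponential of the mean log power spectral density in the
    upper half of the frequency band (converted to amplitude units)."""
    values = np.asarray(values, dtype=float)
    if values.size < min_len:
        raise ValueError(f"trace too short for PSD noise estimate (< {min_len} frames)")
    if np.ptp(values) == 0:
        return np.inf
    fs = 1.0 / frame_interval
    freqs, psd = sp_signal.periodogram(values, fs=fs, detrend="constant")
    band = freqs >= freqs[-1] / 2
    psd_band = psd[band]
    psd_band = psd_band[psd_band > 0]
    if psd_band.size == 0:
        return np.inf
    # mean log PSD -> amplitude: sqrt of power density times bandwidth
    noise = np.sqrt(np.exp(np.mean(np.log(psd_band))) * (freqs[-1] / 2))
    signal_range = values.max() - np.median(values)
    return float(signal_range / noise)
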