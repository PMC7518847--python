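"""Trial-structured containers shared by the ephys and imaging sides.

All times are in seconds, relative to trial start (0 = presample onset).
Intervals are half-open ``[start, end)``.  A spike train may start before 0
after pre-trial extension; its window is tracked by ``t_start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

TRIAL_TYPES = ("left", "right")

#: default imaging frame interval (one frame = 67 ms)
FRAME_INTERVAL = 0.067


@dataclass(frozen=True)
class EpochSchedule:
    """Behavioral epoch boundaries of the delayed-response task.

    Defaults: 1.0 s presample, 1.3 s sample, 1.3 s delay, 1.5 s response.
    Sample plus delay is 2.6 s, matching the task design; the other
    durations are configurable conventions.
    """

    presample_start: float = 0.0
    sample_start: float = 1.0
    delay_start: float = 2.3
    response_start: float = 3.6
    trial_end: float = 5.1

    def __post_init__(self) -> None:
        b = self.boundaries
        if not np.all(np.diff(b) > 0):
            raise ValueError(f"epoch boundaries must be strictly increasing, got {b}")

    @property
    def boundaries(self) -> np.ndarray:
        return np.array(
            [
                self.presample_start,
                self.sample_start,
                self.delay_start,
                self.response_start,
                self.trial_end,
            ]
        )

    @property
    def epoch_names(self) -> tuple[str, ...]:
        return ("presample", "sample", "delay", "response")

    def epoch_of(self, t: np.ndarray) -> np.ndarray:
        """Epoch index (0..3) of each time; -1 outside the trial."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.boundaries, t, side="right") - 1
        idx = np.where((t < self.presample_start) | (t >= self.trial_end), -1, idx)
        return np.clip(idx, -1, 3)

    def epoch_window(self, name: str) -> tuple[float, float]:
        i = self.epoch_names.index(name)
        return float(self.boundaries[i]), float(self.boundaries[i + 1])


@dataclass
class SpikeTrain:
    """Spike times of one neuron in one trial, with trial metadata."""

    spike_times: np.ndarray
    trial_type: str
    correct: bool = True
    epochs: EpochSchedule = field(default_factory=EpochSchedule)
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float).ravel()
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"trial_type must be one of {TRIAL_TYPES}")
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.spike_times.size:
            lo, hi = self.spike_times[0], self.spike_times[-1]
            if lo < self.t_start - 1e-9 or hi > self.epochs.trial_end + 1e-9:
                raise ValueError(
                    "spike times outside "
                    f"[{self.t_start}, {self.epochs.trial_end}]: [{lo}, {hi}]"
                )

    @property
    def t_end(self) -> float:
        return self.epochs.trial_end

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def shifted_window(self, new_t_start: float) -> "SpikeTrain":
        return replace(self, t_start=new_t_start)


@dataclass
class LatentTrace:
    """Latent calcium variable c(t) on a regular simulation grid."""

    times: np.ndarray
    values: np.ndarray
    noise_applied: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.times.size > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("latent grid step must be constant")
        if np.any(self.values < 0):
            raise ValueError("latent values must be >= 0 (zero-truncated)")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan


@dataclass
class FluorTrace:
    """Frame-sampled dF/F of one neuron in one trial.

    Carries the same trial metadata schema as :class:`SpikeTrain` so metric
    code is representation-agnostic.
    """

    frame_times: np.ndarray
    values: np.ndarray
    trial_type: str
    correct: bool = True
    epochs: EpochSchedule = field(default_factory=EpochSchedule)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_times.shape != self.values.shape:
            raise ValueError("frame_times and values must have the same shape")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"trial_type must be one of {TRIAL_TYPES}")
        if self.frame_times.size > 1:
            steps = np.diff(self.frame_times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame interval must be constant")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dF/F values must be finite")

    @property
    def frame_interval(self) -> float:
        if self.frame_times.size > 1:
            return float(self.frame_times[1] - self.frame_times[0])
        return np.nan


@dataclass
class TrialEnsemble:
    """All trials of one neuron (spike modality)."""

    trials: list[SpikeTrain]
    neuron_id: int | str = 0

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("TrialEnsemble needs at least one trial")

    def __len__(self) -> int:
        return len(self.trials)

    def by_type(self, trial_type: str) -> list[SpikeTrain]:
        return [t for t in self.trials if t.trial_type == trial_type]

    @property
    def epochs(self) -> EpochSchedule:
        return self.trials[0].epochs

    def n_trials_per_type(self) -> dict[str, int]:
        return {tt: len(self.by_type(tt)) for tt in TRIAL_TYPES}

    def mean_rate(self) -> float:
        """Mean firing rate (Hz) over the recorded windows of all trials."""
        total_time = sum(t.t_end - t.t_start for t in self.trials)
        total_spikes = sum(t.n_spikes for t in self.trials)
        return total_spikes / total_time if total_time > 0 else 0.0


@dataclass
class BinnedActivity:
    """Per-trial activity binned on a fixed grid (spike rates or dF/F).

    ``matrix`` is (n_trials, n_bins); bins start at trial start (presample
    onset) and a partial final bin is dropped.
    """

    bin_centers: np.ndarray
    matrix: np.ndarray
    trial_types: np.ndarray
    bin_width: float
    epochs: EpochSchedule = field(default_factory=EpochSchedule)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.trial_types = np.asarray(self.trial_types)
        if self.matrix.shape != (self.trial_types.size, self.bin_centers.size):
            raise ValueError("matrix must be (n_trials, n_bins)")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def by_type(self, trial_type: str) -> np.ndarray:
        return self.matrix[self.trial_types == trial_type]

    def trial_mean(self, trial_type: str) -> np.ndarray:
        return self.by_type(trial_type).mean(axis=0)

    def swap_labels(self) -> "BinnedActivity":
        swapped = np.where(self.trial_types == "left", "right", "left")
        return BinnedActivity(
            self.bin_centers, self.matrix.copy(), swapped, self.bin_width, self.epochs
        )


def bin_spike_ensemble(
    ensemble: TrialEnsemble,
    bin_width: float = FRAME_INTERVAL,
    as_rate: bool = True,
) -> BinnedActivity:
    """Bin spike counts (or rates, Hz) on [0, trial_end) in fixed-width bins."""
    epochs = ensemble.epochs
    n_bins = int(np.floor((epochs.trial_end - 0.0) / bin_width + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows, types = [], []
    for tr in ensemble.trials:
        counts, _ = np.histogram(tr.spike_times, bins=edges)
        rows.append(counts / bin_width if as_rate else counts)
        types.append(tr.trial_type)
    return BinnedActivity(centers, np.array(rows, dtype=float), np.array(types), bin_width, epochs)


def bin_fluor_trials(traces: Sequence[FluorTrace]) -> BinnedActivity:
    """View frame-sampled dF/F trials as binned activity (bins = frames)."""
    if not traces:
        raise ValueError("need at least one trace")
    t0 = traces[0]
    for tr in traces[1:]:
        if tr.values.size != t0.values.size:
            raise ValueError("all trials must have the same number of frames")
    matrix = np.stack([tr.values for tr in traces])
    types = np.array([tr.trial_type for tr in traces])
    return BinnedActivity(
        t0.frame_times.copy(), matrix, types, t0.frame_interval, t0.epochs
    )
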