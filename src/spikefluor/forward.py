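"""The spike-to-fluorescence (S2F) forward model.

Spikes at times ``{t_k}`` are convolved with an unnormalized
double-exponential kernel to a latent calcium variable

    c(t) = sum_{t_k < t} exp(-(t - t_k)/tau_d) (1 - exp(-(t - t_k)/tau_r)) + n_i(t)

(zero-truncated after internal noise), which is then pushed through the
readout nonlinearity and sampled at imaging-frame centers with external
Gaussian noise per frame.  The latent is computed on a fine simulation grid
(default 1 ms); frame sampling is an observation step.
"""

from __future__ import annotations

import numpy as np

from .params import S2FParams
from .trials import FRAME_INTERVAL, FluorTrace, LatentTrace, SpikeTrain

__all__ = [
    "latent_at",
    "convolve_spikes",
    "apply_readout",
    "simulate_fluorescence",
    "frame_centers",
]

_CHUNK = 256  # spikes per vectorized block


def latent_at(
    times: np.ndarray, spike_times: np.ndarray, tau_r: float, tau_d: float
) -> np.ndarray:
    """Noise-free latent c(t) evaluated exactly at arbitrary times."""
    times = np.asarray(times, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    out = np.zeros_like(times)
    for i in range(0, spike_times.size, _CHUNK):
        dt = times[None, :] - spike_times[i : i + _CHUNK, None]
        np.maximum(dt, 0.0, out=dt)  # kernel is 0 at and before the spike
        term = np.exp(-dt / tau_d) * (1.0 - np.exp(-dt / tau_r))
        out += term.sum(axis=0)
    return out


def frame_centers(t_start: float, t_end: float, frame_interval: float) -> np.ndarray:
    """Centers of imaging frames tiling [t_start, t_end)."""
    n = int(np.floor((t_end - t_start) / frame_interval + 1e-9))
    return t_start + (np.arange(n) + 0.5) * frame_interval


def convolve_spikes(
    spikes: SpikeTrain,
    params: S2FParams,
    dt: float = 0.001,
    rng_seed: int | np.random.Generator | None = None,
) -> LatentTrace:
    """Convolve a spike train with the double-exponential kernel on a
    regular grid, adding zero-truncated internal Gaussian noise.

    ``dt`` must resolve the kernel rise (dt <= tau_r / 5).
    """
    if dt > params.tau_r / 5 + 1e-12:
        raise ValueError(
            f"simulation step dt={dt} too coarse for tau_r={params.tau_r}; "
            f"need dt <= tau_r/5 = {params.tau_r / 5:.4g}"
        )
    times = np.arange(spikes.t_start, spikes.t_end + dt / 2, dt)
    values = latent_at(times, spikes.spike_times, params.tau_r, params.tau_d)
    noise_applied = False
    if params.sigma_i > 0:
        rng = np.random.default_rng(rng_seed)
        values = values + rng.normal(0.0, params.sigma_i, size=values.shape)
        noise_applied = True
    np.maximum(values, 0.0, out=values)  # truncate at zero after noise
    return LatentTrace(times, values, noise_applied=noise_applied)


def apply_readout(
    latent: LatentTrace,
    params: S2FParams,
    spikes: SpikeTrain | None = None,
    frame_interval: float = FRAME_INTERVAL,
    rng_seed: int | np.random.Generator | None = None,
    trial_type: str = "left",
    correct: bool = True,
    epochs=None,
) -> FluorTrace:
    """Evaluate the readout nonlinearity at frame centers and add external
    noise per frame.  Trial metadata is taken from ``spikes`` if given."""
    if spikes is not None:
        trial_type, correct, epochs = spikes.trial_type, spikes.correct, spikes.epochs
    t0, t1 = float(latent.times[0]), float(latent.times[-1])
    ft = frame_centers(t0, t1, frame_interval)
    c = np.interp(ft, latent.times, latent.values)
    values = params.readout(c)
    if params.sigma_e > 0:
        rng = np.random.default_rng(rng_seed)
        values = values + rng.normal(0.0, params.sigma_e, size=values.shape)
    kw = {} if epochs is None else {"epochs": epochs}
    return FluorTrace(ft, values, trial_type=trial_type, correct=correct, **kw)


def simulate_fluorescence(
    spikes: SpikeTrain,
    params: S2FParams,
    frame_interval: float = FRAME_INTERVAL,
    dt: float = 0.001,
    rng_seed: int | np.random.Generator | None = None,
) -> FluorTrace:
    """Full forward model: spikes -> latent -> synthetic dF/F.

    Deterministic given ``rng_seed``; noise-free when sigma_i = sigma_e = 0.
    """
    rng = np.random.default_rng(rng_seed)
    latent = convolve_spikes(spikes, params, dt=dt, rng_seed=rng)
    return apply_readout(
        latent, params, spikes=spikes, frame_interval=frame_interval, rng_seed=rng
    )
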