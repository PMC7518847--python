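import numpy as np
import pytest

import spikefluor as sf


@pytest.fixture
def epochs():
    return sf.EpochSchedule()


@pytest.fixture
def params_6s():
    """Deterministic slow-indicator-like parameters, noise-free."""
    return sf.S2FParams(tau_r=0.06, tau_d=1.2, F_m=3.0, k=1.3, c_half=1.6)


@pytest.fixture
def paired_recording(epochs, params_6s):
    """Paired spike/fluorescence trials generated by the forward model."""
    rng = np.random.default_rng(7)
    spikes, fluor = [], []
    for i in range(16):
        tt = "left" if i % 2 else "right"
        rate = 6.0 if i % 2 else 10.0
        st = sf.sample_poisson_train(rate, 0.0, epochs.trial_end, rng)
        s = sf.SpikeTrain(st, tt, True, epochs)
        spikes.append(s)
        fluor.append(sf.simulate_fluorescence(s, params_6s))
    return spikes, fluor


def make_selective_binned(
    rng,
    n_trials=200,
    n_bins=60,
    base=5.0,
    offset_right=0.0,
    offset_profile=None,
    noise_sd=1.0,
    bin_width=0.067,
):
    """Gaussian-noise binned activity with a controlled left/right offset.

    ``offset_profile`` (length n_bins) overrides the constant offset.
    """
    centers = (np.arange(n_bins) + 0.5) * bin_width
    types = np.array(["left", "right"] * (n_trials // 2))
    offs = (
        np.asarray(offset_profile, dtype=float)
        if offset_profile is not None
        else np.full(n_bins, offset_right)
    )
    mat = base + rng.normal(0, noise_sd, size=(types.size, n_bins))
    mat[types == "right"] += offs
    epochs = sf.EpochSchedule(0.0, 1.0, 2.3, 3.6, max(4.021, n_bins * bin_width))
    return sf.BinnedActivity(centers, mat, types, bin_width, epochs)
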