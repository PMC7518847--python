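"""Plotting helpers for the standard comparison figures."""

from __future__ import annotations

import numpy as np

from .population import PopulationTensor, heatmap_order


def plot_population_heatmap(tensor: PopulationTensor, ax=None, cmap="viridis"):
    """Heatmap of normalized trial-averaged activity, neurons grouped by
    preferred trial type and sorted by peak latency; the two trial types
    are shown side by side."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    order = heatmap_order(tensor)
    img = tensor.data[order].reshape(tensor.n_neurons, -1)
    t0, t1 = tensor.bin_centers[0], tensor.bin_centers[-1]
    ax.imshow(img, aspect="auto", cmap=cmap,
              extent=[t0, 2 * t1 - t0, tensor.n_neurons, 0])
    ax.axvline(t1, color="w", lw=1)
    ax.set_xlabel("time (s; left | right trials)")
    ax.set_ylabel("neuron (sorted)")
    return ax


def plot_decoder_accuracy(runs, ax=None, label=None, color=None, chance=0.5):
    """Mean +/- SD decodability over time across unit subsamples."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    acc = np.vstack([r.accuracy_over_time for r in runs])
    t = runs[0].bin_centers
    m, s = acc.mean(axis=0), acc.std(axis=0)
    (line,) = ax.plot(t, m, label=label, color=color)
    ax.fill_between(t, m - s, m + s, alpha=0.25, color=line.get_color())
    ax.axhline(chance, ls=":", color="gray", lw=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("decoding accuracy")
    ax.set_ylim(0, 1.02)
    if label:
        ax.legend(frameon=False)
    return ax


def plot_fit_overlay(results, trial_index: int, ax=None):
    """Measured dF/F of one trial overlaid with the fitted noise-free
    model prediction and the input spikes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    model = results.model
    f = model.fluor[trial_index]
    pred = model._predict_trial(trial_index, results.params.to_dict())
    ax.plot(f.frame_times, f.values, color="tab:blue", label="measured")
    ax.plot(f.frame_times, pred, color="tab:orange", label="model")
    spikes = model.spikes[trial_index].spike_times
    y0 = min(f.values.min(), pred.min())
    ax.plot(spikes, np.full(spikes.size, y0 - 0.05 * np.ptp(f.values)), "|",
            color="k", label="spikes")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\Delta$F/F")
    ax.legend(frameon=False)
    return ax
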