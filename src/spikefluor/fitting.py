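"""Estimating S2F parameters from paired spike/fluorescence recordings.

`S2FModel` follows the statsmodels convention: construct the model from
data, call :meth:`S2FModel.fit`, and inspect the returned
:class:`S2FResults` (parameter estimates, held-out explained variance,
per-parameter sensitivity, ``summary()``).

Fitting minimizes the mean squared error between the noise-free forward
model sampled at the measured frame times and the measured dF/F, over a
training subset of trials, with multi-start bounded local optimization
(rise/decay times in log space; decay > rise enforced by parameterizing
their log difference).  Quality is reported as explained variance
EV = 1 - SS_res / SS_tot on held-out validation trials.

`metric_distribution` propagates an empirical parameter distribution
P(theta) through the forward model into the distribution of any
registered population metric psi: for each draw, per-neuron parameters
are sampled, synthetic dF/F is generated for the whole population, and
psi is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .forward import latent_at, simulate_fluorescence
from .params import ParamDistribution, S2FParams
from .trials import (
    FRAME_INTERVAL,
    BinnedActivity,
    FluorTrace,
    LatentTrace,
    SpikeTrain,
    TrialEnsemble,
    bin_fluor_trials,
)

__all__ = [
    "S2FModel",
    "S2FResults",
    "fit_s2f",
    "parameter_sensitivity",
    "rematch_nonlinearity",
    "RematchResult",
    "MetricDistribution",
    "metric_distribution",
    "register_metric",
    "METRIC_REGISTRY",
]


# ---------------------------------------------------------------------------
# parameter transforms: optimizer space <-> physical space
# ---------------------------------------------------------------------------

def _pack(p: dict[str, float], variant: str) -> np.ndarray:
    x = [np.log(p["tau_r"]), np.log(p["tau_d"] - p["tau_r"])]
    if variant == "sigmoid":
        x += [np.log(p["F_m"]), np.log(p["k"]), p["c_half"]]
    elif variant == "linear":
        x += [p["F_max"], p["F_0"]]
    else:  # hill
        x += [np.log(p["F_max"]), np.log(p["n_hill"]), np.log(p["K_d"])]
    return np.array(x)


def _unpack(x: np.ndarray, variant: str) -> dict[str, float]:
    tau_r = np.exp(x[0])
    p = {"tau_r": tau_r, "tau_d": tau_r + np.exp(x[1])}
    if variant == "sigmoid":
        p.update(F_m=np.exp(x[2]), k=np.exp(x[3]), c_half=x[4])
    elif variant == "linear":
        p.update(F_max=x[2], F_0=x[3])
    else:
        p.update(F_max=np.exp(x[2]), n_hill=np.exp(x[3]), K_d=np.exp(x[4]))
    return p


def _bounds(variant: str) -> tuple[np.ndarray, np.ndarray]:
    lo = [np.log(2e-3), np.log(5e-3)]
    hi = [np.log(1.0), np.log(10.0)]
    if variant == "sigmoid":
        lo += [np.log(1e-3), np.log(1e-2), 0.0]
        hi += [np.log(1e3), np.log(1e3), 100.0]
    elif variant == "linear":
        lo += [-1e3, -1e3]
        hi += [1e3, 1e3]
    else:
        lo += [np.log(1e-3), np.log(0.2), np.log(1e-3)]
        hi += [np.log(1e3), np.log(10.0), np.log(1e4)]
    return np.array(lo), np.array(hi)


def _readout(c: np.ndarray, p: dict[str, float], variant: str) -> np.ndarray:
    if variant == "sigmoid":
        from scipy.special import expit

        return p["F_m"] * expit(p["k"] * (c - p["c_half"]))
    if variant == "linear":
        return p["F_max"] * c + p["F_0"]
    cn = np.power(np.maximum(c, 0.0), p["n_hill"])
    return p["F_max"] * cn / (cn + p["K_d"])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class S2FModel:
    """Forward model fitted to paired, time-aligned spike/dF/F trials.

    Parameters
    ----------
    spikes, fluor:
        Equal-length lists; ``fluor[i]`` is the measured dF/F of the trial
        whose spikes are ``spikes[i]``.
    variant:
        Readout nonlinearity: ``sigmoid`` (default), ``linear`` or ``hill``.
    """

    def __init__(
        self,
        spikes: Sequence[SpikeTrain],
        fluor: Sequence[FluorTrace],
        variant: str = "sigmoid",
    ):
        if len(spikes) != len(fluor) or not spikes:
            raise ValueError("need equal, non-empty lists of paired trials")
        for s, f in zip(spikes, fluor):
            if s.trial_type != f.trial_type:
                raise ValueError("misaligned trial pair (trial_type differs)")
        self.spikes = list(spikes)
        self.fluor = list(fluor)
        self.variant = variant
        self._frame_times = [f.frame_times for f in fluor]
        self._targets = [f.values for f in fluor]
        self._spike_times = [s.spike_times for s in spikes]

    # -- loss machinery ----------------------------------------------------

    def _predict_trial(self, i: int, p: dict[str, float]) -> np.ndarray:
        c = latent_at(self._frame_times[i], self._spike_times[i], p["tau_r"], p["tau_d"])
        return _readout(c, p, self.variant)

    def _residuals(self, x: np.ndarray, idx: Sequence[int]) -> np.ndarray:
        p = _unpack(x, self.variant)
        return np.concatenate(
            [self._predict_trial(i, p) - self._targets[i] for i in idx]
        )

    def ev(self, params: S2FParams, idx: Sequence[int]) -> float:
        """Explained variance of the noise-free model on the given trials."""
        p = {k: getattr(params, k) for k in
             ("tau_r", "tau_d", "F_m", "k", "c_half", "F_max", "F_0", "n_hill", "K_d")}
        res, y = [], []
        for i in idx:
            res.append(self._predict_trial(i, p) - self._targets[i])
            y.append(self._targets[i])
        res = np.concatenate(res)
        y = np.concatenate(y)
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            return np.nan
        return 1.0 - np.sum(res**2) / ss_tot

    def _initial_points(self, n_starts: int, rng: np.random.Generator) -> list[np.ndarray]:
        y = np.concatenate(self._targets)
        amp = max(np.ptp(y), 1e-3)
        rates = [
            st.size / max(ft[-1] - ft[0], 1e-6)
            for st, ft in zip(self._spike_times, self._frame_times)
        ]
        c_scale = max(np.mean(rates), 0.5)  # latent scale ~ rate * tau_d
        starts = []
        # heuristic first start
        if self.variant == "sigmoid":
            heur = dict(tau_r=0.05, tau_d=1.0, F_m=1.2 * amp, k=2.0 / c_scale,
                        c_half=c_scale)
        elif self.variant == "linear":
            heur = dict(tau_r=0.05, tau_d=1.0, F_max=amp / max(c_scale, 1e-3),
                        F_0=float(np.median(y)))
        else:
            heur = dict(tau_r=0.05, tau_d=1.0, F_max=1.2 * amp, n_hill=2.0,
                        K_d=c_scale**2)
        starts.append(_pack(heur, self.variant))
        lo, hi = _bounds(self.variant)
        for _ in range(n_starts - 1):
            x = lo + rng.random(lo.size) * (hi - lo)
            # keep random starts in a plausible kinetic range
            x[0] = np.log(10 ** rng.uniform(-2, -0.5))  # tau_r 10-300 ms
            x[1] = np.log(10 ** rng.uniform(-1, 0.5))  # tau_d - tau_r 0.1-3 s
            if self.variant == "sigmoid":
                x[2] = np.log(amp * 10 ** rng.uniform(-0.3, 0.7))
                x[3] = np.log(10 ** rng.uniform(-1, 1) / c_scale)
                x[4] = rng.uniform(0, 3) * c_scale
            elif self.variant == "linear":
                x[2] = amp / max(c_scale, 1e-3) * 10 ** rng.uniform(-0.5, 0.5)
                x[3] = np.median(y) + rng.normal(0, 0.1 * amp)
            else:
                x[2] = np.log(amp * 10 ** rng.uniform(-0.3, 0.7))
                x[3] = np.log(rng.uniform(0.8, 4.0))
                x[4] = np.log(max(c_scale, 1e-2) ** 2 * 10 ** rng.uniform(-1, 1))
            starts.append(x)
        return starts

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        split: float = 0.7,
        n_starts: int = 20,
        rng_seed: int | None = 0,
    ) -> "S2FResults":
        """Multi-start least-squares fit; 70/30 train/validation split by
        trials by default."""
        if not 0 < split < 1:
            raise ValueError("split must be in (0, 1)")
        rng = np.random.default_rng(rng_seed)
        n = len(self.spikes)
        order = rng.permutation(n)
        n_train = max(1, int(round(split * n)))
        if n_train == n and n > 1:
            n_train = n - 1
        train_idx = np.sort(order[:n_train])
        val_idx = np.sort(order[n_train:]) if n_train < n else train_idx

        lo, hi = _bounds(self.variant)
        best, best_loss, n_conv = None, np.inf, 0
        for x0 in self._initial_points(n_starts, rng):
            x0 = np.clip(x0, lo, hi)
            try:
                sol = optimize.least_squares(
                    self._residuals, x0, args=(train_idx,), bounds=(lo, hi),
                    method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            n_conv += 1
            if sol.cost < best_loss:
                best_loss, best = sol.cost, sol.x
        if best is None:
            raise RuntimeError(
                f"all {n_starts} optimization starts diverged (variant={self.variant})"
            )
        pdict = _unpack(best, self.variant)
        resid = self._residuals(best, train_idx)
        sigma_e = float(resid.std())
        params = S2FParams(variant=self.variant, sigma_e=sigma_e, **pdict)
        n_frames = sum(self._targets[i].size for i in train_idx)
        result = S2FResults(
            model=self,
            params=params,
            residual_loss=float(2 * best_loss / n_frames),
            n_starts_converged=n_conv,
            train_idx=train_idx,
            val_idx=val_idx,
        )
        result.train_ev = self.ev(params, train_idx)
        result.explained_variance = self.ev(params, val_idx)
        return result


@dataclass
class S2FResults:
    """Fit results: estimates, held-out explained variance, diagnostics."""

    model: S2FModel
    params: S2FParams
    residual_loss: float  # training MSE per frame
    n_starts_converged: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    train_ev: float = np.nan
    explained_variance: float = np.nan
    _sensitivity: dict[str, float] | None = field(default=None, repr=False)

    def predict(self, spikes: SpikeTrain, frame_interval: float = FRAME_INTERVAL):
        """Noise-free synthetic dF/F for a spike train under the fit."""
        p = self.params.replace(sigma_i=0.0, sigma_e=0.0)
        return simulate_fluorescence(spikes, p, frame_interval=frame_interval)

    def sensitivity(self, rel_step: float = 0.1) -> dict[str, float]:
        """Per-parameter sensitivity g = (dEV/EV) / (dP/P), cached."""
        if self._sensitivity is None:
            self._sensitivity = parameter_sensitivity(self, rel_step=rel_step)
        return self._sensitivity

    def summary(self) -> str:
        lines = [
            "S2F model fit".center(58),
            "=" * 58,
            f"variant:            {self.params.variant}",
            f"trials (train/val): {len(self.train_idx)}/{len(self.val_idx)}",
            f"starts converged:   {self.n_starts_converged}",
            f"EV (train):         {self.train_ev:.4f}",
            f"EV (validation):    {self.explained_variance:.4f}",
            f"MSE per frame:      {self.residual_loss:.5g}",
            "-" * 58,
            f"{'parameter':<12}{'estimate':>14}{'sensitivity g':>18}",
        ]
        sens = self._sensitivity or {}
        for name in self.params.active_names():
            g = sens.get(name)
            g_str = f"{g:18.4f}" if g is not None else f"{'--':>18}"
            lines.append(f"{name:<12}{getattr(self.params, name):>14.5g}{g_str}")
        lines.append(f"{'sigma_e':<12}{self.params.sigma_e:>14.5g}{'(residual std)':>18}")
        lines.append("=" * 58)
        return "\n".join(lines)


def fit_s2f(
    spikes: Sequence[SpikeTrain],
    fluor: Sequence[FluorTrace],
    variant: str = "sigmoid",
    split: float = 0.7,
    n_starts: int = 20,
    rng_seed: int | None = 0,
) -> S2FResults:
    """Functional wrapper: ``S2FModel(spikes, fluor, variant).fit(...)``."""
    return S2FModel(spikes, fluor, variant=variant).fit(
        split=split, n_starts=n_starts, rng_seed=rng_seed
    )


def parameter_sensitivity(
    results: S2FResults, rel_step: float = 0.1
) -> dict[str, float]:
    """Sensitivity g of each active parameter: relative EV decrease per
    relative parameter deviation, averaged over a symmetric +/- step."""
    if rel_step <= 0:
        raise ValueError("rel_step must be > 0")
    ev0 = results.explained_variance
    if not np.isfinite(ev0) or ev0 <= 0:
        raise ValueError(f"sensitivity undefined: validation EV = {ev0}")
    model, params = results.model, results.params
    out: dict[str, float] = {}
    # sigma_e is included for completeness: EV is evaluated on the
    # noise-free prediction, so its sensitivity is exactly zero
    for name in params.active_names() + ("sigma_e",):
        if name == "sigma_e" and params.sigma_e == 0:
            out[name] = 0.0
            continue
        drops = []
        for sgn in (+1, -1):
            value = getattr(params, name) * (1 + sgn * rel_step)
            try:
                pert = params.replace(**{name: value})
            except ValueError:
                continue  # perturbation left the valid domain (e.g. tau ordering)
            ev = model.ev(pert, results.val_idx)
            drops.append((ev0 - ev) / ev0 / rel_step)
        out[name] = float(np.mean(drops)) if drops else np.nan
    return out


# ---------------------------------------------------------------------------
# nonlinearity re-estimation by matching
# ---------------------------------------------------------------------------

@dataclass
class RematchResult:
    k: float
    c_half: float
    F_m: float
    spearman: float
    candidate_index: int


def rematch_nonlinearity(
    latent: LatentTrace | np.ndarray,
    candidate_traces: Sequence[np.ndarray],
    min_spearman: float = 0.7,
) -> RematchResult | None:
    """Re-estimate the sigmoid nonlinearity of a neuron by matching its
    mean latent c(t) to the mean dF/F of candidate imaging neurons.

    For each candidate, (F_m, k, c_half) minimizing the squared error of
    sigmoid(c) against the candidate is fitted; the best candidate is
    accepted if the Spearman rank correlation between its mean dF/F and
    the matched synthetic dF/F exceeds ``min_spearman``.  Returns None if
    no candidate qualifies (the caller decides the fallback).
    """
    if not len(candidate_traces):
        raise ValueError("candidate library is empty")
    c = latent.values if isinstance(latent, LatentTrace) else np.asarray(latent, float)
    c_scale = max(np.ptp(c), 1e-6)

    def sigmoid(x, F_m, k, c_half):
        return F_m / (1.0 + np.exp(-k * (x - c_half)))

    best: RematchResult | None = None
    best_loss = np.inf
    for j, y in enumerate(candidate_traces):
        y = np.asarray(y, dtype=float)
        if y.shape != c.shape:
            raise ValueError("candidate traces must match the latent length")
        if np.ptp(y) == 0:
            continue
        amp = np.ptp(y)
        fit_best, loss_best = None, np.inf
        for k0, ch0 in ((2.0 / c_scale, np.median(c)),
                        (8.0 / c_scale, np.median(c)),
                        (1.0 / c_scale, c.min() + 0.25 * c_scale)):
            try:
                sol = optimize.least_squares(
                    lambda q: sigmoid(c, np.exp(q[0]), np.exp(q[1]), q[2]) - y,
                    x0=[np.log(1.2 * amp), np.log(k0), ch0],
                    bounds=([np.log(1e-4), np.log(1e-3 / c_scale), 0.0],
                            [np.log(1e4), np.log(1e4 / c_scale), c.max() + 5 * c_scale]),
                )
            except Exception:
                continue
            if sol.cost < loss_best:
                loss_best, fit_best = sol.cost, sol.x
        if fit_best is None:
            continue
        F_m, k, c_half = np.exp(fit_best[0]), np.exp(fit_best[1]), fit_best[2]
        synth = sigmoid(c, F_m, k, c_half)
        if np.ptp(synth) == 0:
            continue
        rho = stats.spearmanr(y, synth).statistic
        if np.isnan(rho):
            continue
        # best match = lowest squared mismatch after amplitude fitting
        # (normalized per candidate); the Spearman threshold then gates it
        loss = loss_best / max(np.var(y) * y.size, 1e-12)
        if loss < best_loss:
            best_loss = loss
            best = RematchResult(float(k), float(c_half), float(F_m), float(rho), j)
    if best is None or best.spearman <= min_spearman:
        return None
    return best


# ---------------------------------------------------------------------------
# metric distributions
# ---------------------------------------------------------------------------

@dataclass
class MetricDistribution:
    """Empirical distribution of a population metric psi induced by
    sampling S2F parameters and noise."""

    metric_name: str
    samples: np.ndarray
    seeds: list[int]

    def mean(self) -> float:
        return float(np.mean(self.samples))

    def std(self) -> float:
        return float(np.std(self.samples))


MetricFn = Callable[[list[list[FluorTrace]]], float]
METRIC_REGISTRY: dict[str, MetricFn] = {}


def register_metric(name: str):
    def deco(fn: MetricFn) -> MetricFn:
        METRIC_REGISTRY[name] = fn
        return fn
    return deco


def _population_binned(fluor_population: list[list[FluorTrace]]) -> list[BinnedActivity]:
    return [bin_fluor_trials(traces) for traces in fluor_population]


@register_metric("mean_dff")
def _mean_dff(pop: list[list[FluorTrace]]) -> float:
    return float(np.mean([tr.values.mean() for traces in pop for tr in traces]))


@register_metric("fraction_selective")
def _fraction_selective(pop: list[list[FluorTrace]]) -> float:
    from .single_neuron import classify_selectivity

    labels = [classify_selectivity(b) for b in _population_binned(pop)]
    return float(np.mean([lab.category != "nonselective" for lab in labels]))


@register_metric("fraction_multiphasic")
def _fraction_multiphasic(pop: list[list[FluorTrace]]) -> float:
    from .single_neuron import classify_selectivity

    labels = [classify_selectivity(b) for b in _population_binned(pop)]
    return float(np.mean([lab.category == "multiphasic" for lab in labels]))


@register_metric("peakiness")
def _peakiness(pop: list[list[FluorTrace]]) -> float:
    from .population import build_tensor, peak_time_distribution, peakiness

    tensor = build_tensor(_population_binned(pop), normalize=True)
    _, P, _ = peak_time_distribution(tensor)
    return peakiness(P, n_boot=0).s


@register_metric("pc1_temporal_ev")
def _pc1_temporal_ev(pop: list[list[FluorTrace]]) -> float:
    from .population import build_tensor, pca_decompose

    tensor = build_tensor(_population_binned(pop))
    return float(pca_decompose(tensor, n_boot=0).ev_time[0])


def metric_distribution(
    spikes_population: list[TrialEnsemble],
    metric: str | MetricFn,
    param_dist: ParamDistribution,
    n_draws: int = 20,
    rng_seed: int | None = 0,
    frame_interval: float = FRAME_INTERVAL,
    dt: float = 0.001,
) -> MetricDistribution:
    """Empirical P(psi): for each draw, sample per-neuron parameters from
    ``param_dist``, generate synthetic dF/F for the whole spike population
    and evaluate the metric.  Per-draw seeds are recorded so any sample is
    reproducible."""
    if isinstance(metric, str):
        if metric not in METRIC_REGISTRY:
            raise KeyError(
                f"unknown metric {metric!r}; known: {sorted(METRIC_REGISTRY)}"
            )
        name, fn = metric, METRIC_REGISTRY[metric]
    else:
        name, fn = getattr(metric, "__name__", "custom"), metric
    ss = np.random.SeedSequence(rng_seed)
    draw_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_draws)]
    values = np.empty(n_draws)
    for d, seed in enumerate(draw_seeds):
        rng = np.random.default_rng(seed)
        thetas = param_dist.draw(len(spikes_population), rng)
        pop_fluor = []
        for ens, theta in zip(spikes_population, thetas):
            pop_fluor.append(
                [
                    simulate_fluorescence(
                        tr, theta, frame_interval=frame_interval, dt=dt, rng_seed=rng
                    )
                    for tr in ens.trials
                ]
            )
        values[d] = fn(pop_fluor)
    return MetricDistribution(name, values, draw_seeds)
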