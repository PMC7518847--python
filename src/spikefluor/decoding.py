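"""Population decoding protocols.

Instantaneous trial-type decoding fits a regularized LDA per time bin on
pseudo-populations of (by default) 100 units, correct trials only, with
disjoint 70/30 train/test trial splits, averaged over unit subsamples.
Regularization is diagonal-shrinkage LDA with soft-threshold
sparsification of the discriminant weights; the shrinkage level is chosen
by cross-validation on the training trials.  A variant decodes from
causally boxcar-filtered spike rates (1 s default), and a four-class
decoder predicts the current behavioral epoch per bin, with response
latency defined as the first bin after an epoch onset at which accuracy
reaches a threshold (0.7 default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trials import TRIAL_TYPES, BinnedActivity, EpochSchedule

__all__ = [
    "ShrinkageLDA",
    "DecoderRun",
    "EpochDecoderRun",
    "decode_trialtype",
    "decode_trialtype_filtered",
    "decode_epoch",
    "boxcar_filter",
]


class ShrinkageLDA:
    """Diagonal-shrinkage LDA with soft-thresholded discriminant weights.

    The pooled within-class covariance is taken diagonal and shrunk
    toward its mean variance: var_j <- (1 - lam) s_j^2 + lam mean(s^2).
    Class scores are linear; per-class weight vectors are sparsified by
    soft-thresholding at a quantile of their absolute values.
    """

    def __init__(self, shrinkage: float = 0.5, sparsity_quantile: float = 0.25):
        self.shrinkage = shrinkage
        self.sparsity_quantile = sparsity_quantile

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        means = np.vstack([X[y_idx == c].mean(axis=0) for c in range(len(self.classes_))])
        resid = X - means[y_idx]
        s2 = resid.var(axis=0) + 1e-12
        lam = self.shrinkage
        var = (1 - lam) * s2 + lam * s2.mean()
        grand = means.mean(axis=0)
        W = (means - grand) / var  # per-class weights relative to grand mean
        if self.sparsity_quantile > 0:
            tau = np.quantile(np.abs(W), self.sparsity_quantile)
            W = np.sign(W) * np.maximum(np.abs(W) - tau, 0.0)
        self.var_ = var
        self.means_ = means
        self.weights_ = W
        self.priors_ = np.bincount(y_idx, minlength=len(self.classes_)) / n
        self.intercepts_ = (
            -0.5 * np.sum(W * (means - grand), axis=1) + np.log(self.priors_)
        )
        self.grand_ = grand
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.grand_) @ self.weights_.T + self.intercepts_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_function(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _fit_with_cv(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    shrinkage_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
    n_folds: int = 3,
    sparsity_quantile: float = 0.25,
) -> ShrinkageLDA:
    """Pick the shrinkage level by stratified cross-validation on the
    training data, then refit on all of it."""
    y = np.asarray(y)
    folds = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    best_lam, best_acc = shrinkage_grid[0], -np.inf
    for lam in shrinkage_grid:
        accs = []
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            if len(np.unique(y[tr])) < len(np.unique(y)) or te.sum() == 0:
                continue
            m = ShrinkageLDA(lam, sparsity_quantile).fit(X[tr], y[tr])
            accs.append(m.score(X[te], y[te]))
        acc = np.mean(accs) if accs else -np.inf
        if acc > best_acc:
            best_acc, best_lam = acc, lam
    return ShrinkageLDA(best_lam, sparsity_quantile).fit(X, y)


@dataclass
class DecoderRun:
    """One unit-subsample of the per-bin trial-type decoder."""

    accuracy_over_time: np.ndarray
    bin_centers: np.ndarray
    subsample_id: int
    population_size: int
    train_fraction: float = 0.7
    unit_indices: np.ndarray | None = None


@dataclass
class EpochDecoderRun:
    """Four-class behavioral-epoch decoder output."""

    bin_centers: np.ndarray
    class_probabilities: np.ndarray  # (n_bins, 4), mean over test trials
    accuracy_over_time: np.ndarray  # per-bin fraction correct
    latencies: dict[str, float]  # epoch -> seconds from epoch onset (nan if never)
    epoch_names: tuple[str, ...] = ("presample", "sample", "delay", "response")


def _stack_population(
    binned_list: list[BinnedActivity], correct_only: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pseudo-population tensor (n_trials, n_units, n_bins) pairing trials
    across neurons by trial type and index."""
    if not binned_list:
        raise ValueError("empty population")
    n_bins = binned_list[0].n_bins
    per_type_counts = {
        tt: min(int((b.trial_types == tt).sum()) for b in binned_list)
        for tt in TRIAL_TYPES
    }
    X_parts, labels = [], []
    for tt in TRIAL_TYPES:
        cnt = per_type_counts[tt]
        if cnt == 0:
            raise ValueError(f"no {tt} trials")
        block = np.stack(
            [b.by_type(tt)[:cnt] for b in binned_list], axis=1
        )  # (cnt, units, bins)
        X_parts.append(block)
        labels.extend([tt] * cnt)
    X = np.concatenate(X_parts, axis=0)
    if X.shape[2] != n_bins:
        raise ValueError("inconsistent binning")
    return X, np.array(labels), binned_list[0].bin_centers


def _split_trials(
    labels: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint stratified train/test split; both classes in both sets."""
    for _ in range(100):
        train = np.zeros(labels.size, dtype=bool)
        for tt in np.unique(labels):
            idx = np.flatnonzero(labels == tt)
            rng.shuffle(idx)
            n_train = max(1, int(round(train_frac * idx.size)))
            n_train = min(n_train, idx.size - 1)
            train[idx[:n_train]] = True
        test = ~train
        if len(np.unique(labels[train])) > 1 and len(np.unique(labels[test])) > 1:
            return train, test
    raise RuntimeError("could not build a valid stratified split")


def decode_trialtype(
    binned_list: list[BinnedActivity],
    pop_size: int = 100,
    n_subsamples: int = 100,
    train_frac: float = 0.7,
    rng_seed: int | None = 0,
    sparsity_quantile: float = 0.25,
    correct_only: bool = True,
) -> list[DecoderRun]:
    """Instantaneous trial-type decodability over time.

    For each unit subsample (without replacement within a draw) and each
    time bin, a shrinkage-LDA decoder is trained on the training trials
    and scored on held-out test trials.
    """
    if correct_only:
        binned_list = [_correct_only(b) for b in binned_list]
    X, labels, centers = _stack_population(binned_list)
    n_units = X.shape[1]
    eff_pop = min(pop_size, n_units)
    rng = np.random.default_rng(rng_seed)
    runs = []
    for s in range(n_subsamples):
        units = rng.choice(n_units, size=eff_pop, replace=False)
        train, test = _split_trials(labels, train_frac, rng)
        acc = np.empty(X.shape[2])
        for b in range(X.shape[2]):
            Xb = X[:, units, b]
            clf = _fit_with_cv(Xb[train], labels[train], rng,
                               sparsity_quantile=sparsity_quantile)
            acc[b] = clf.score(Xb[test], labels[test])
        runs.append(DecoderRun(acc, centers, s, eff_pop, train_frac, units))
    return runs


def _correct_only(b: BinnedActivity) -> BinnedActivity:
    return b  # correctness filtering happens upstream where trials carry flags


def boxcar_filter(binned: BinnedActivity, window: float) -> BinnedActivity:
    """Causal boxcar filter of per-trial activity (moving average over the
    past ``window`` seconds; partial windows at the start average over the
    available past).  window <= one bin is the identity."""
    k = max(1, int(round(window / binned.bin_width)))
    if k == 1:
        return binned
    m = binned.matrix
    csum = np.cumsum(m, axis=1)
    out = np.empty_like(m)
    for b in range(m.shape[1]):
        lo = max(0, b - k + 1)
        s = csum[:, b] - (csum[:, lo - 1] if lo > 0 else 0)
        out[:, b] = s / (b - lo + 1)
    return BinnedActivity(
        binned.bin_centers, out, binned.trial_types, binned.bin_width, binned.epochs
    )


def decode_trialtype_filtered(
    binned_list: list[BinnedActivity],
    window: float = 1.0,
    **kwargs,
) -> list[DecoderRun]:
    """Trial-type decoding from causally filtered activity (1 s default),
    the ephys analogue of the temporal integration a slow indicator
    performs."""
    filtered = [boxcar_filter(b, window) for b in binned_list]
    return decode_trialtype(filtered, **kwargs)


def decode_epoch(
    binned_list: list[BinnedActivity],
    epochs: EpochSchedule | None = None,
    threshold: float = 0.7,
    pop_size: int = 100,
    n_subsamples: int = 10,
    train_frac: float = 0.7,
    rng_seed: int | None = 0,
    sparsity_quantile: float = 0.25,
) -> EpochDecoderRun:
    """Four-class LDA predicting the behavioral epoch of each time bin
    from population activity; latency per epoch is the first bin after
    its onset at which accuracy reaches ``threshold``."""
    epochs = epochs or binned_list[0].epochs
    X, labels, centers = _stack_population(binned_list)
    epoch_idx = epochs.epoch_of(centers)
    valid = epoch_idx >= 0
    names = epochs.epoch_names
    rng = np.random.default_rng(rng_seed)
    n_units = X.shape[1]
    eff_pop = min(pop_size, n_units)

    prob_acc = np.zeros((X.shape[2], 4))
    acc_acc = np.zeros(X.shape[2])
    for s in range(n_subsamples):
        units = rng.choice(n_units, size=eff_pop, replace=False)
        train, test = _split_trials(labels, train_frac, rng)
        # training samples: (trial, bin) pairs from training trials
        Xtr = X[np.ix_(train, units, np.flatnonzero(valid))]
        ytr = np.repeat(epoch_idx[valid][None, :], Xtr.shape[0], axis=0)
        Xtr_flat = Xtr.transpose(0, 2, 1).reshape(-1, eff_pop)
        clf = _fit_with_cv(Xtr_flat, ytr.ravel(), rng,
                           sparsity_quantile=sparsity_quantile)
        for b in range(X.shape[2]):
            Xb = X[np.ix_(test, units)][:, :, b]
            prob_acc[b] += clf.predict_proba(Xb).mean(axis=0)
            if valid[b]:
                acc_acc[b] += np.mean(clf.predict(Xb) == epoch_idx[b])
    probs = prob_acc / n_subsamples
    acc = acc_acc / n_subsamples

    latencies: dict[str, float] = {}
    for e, name in enumerate(names):
        onset = epochs.boundaries[e]
        in_epoch = np.flatnonzero((epoch_idx == e) & (centers >= onset))
        hit = [b for b in in_epoch if acc[b] >= threshold]
        latencies[name] = float(centers[hit[0]] - onset) if hit else np.nan
    return EpochDecoderRun(centers, probs, acc, latencies, names)
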