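"""S2F model parameters and empirical parameter distributions.

The forward model converts spikes to a latent calcium variable (rise time
``tau_r``, decay time ``tau_d``, internal noise ``sigma_i``) and then
through a readout nonlinearity to dF/F.  Three readout variants exist:

- ``sigmoid``: F = F_m / (1 + exp(-k (c - c_half)))  (default)
- ``linear``:  F = F_max * c + F_0
- ``hill``:    F = F_max * c**n / (c**n + K_d)

External measurement noise ``sigma_e`` is added per imaging frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np
import pandas as pd

VARIANTS = ("sigmoid", "linear", "hill")

# readout parameters that are active for each variant
_ACTIVE_READOUT = {
    "sigmoid": ("F_m", "k", "c_half"),
    "linear": ("F_max", "F_0"),
    "hill": ("F_max", "n_hill", "K_d"),
}


@dataclass(frozen=True)
class S2FParams:
    """Parameter vector of the spike-to-fluorescence forward model."""

    tau_r: float = 0.07
    tau_d: float = 1.3
    sigma_i: float = 0.0
    F_m: float = 3.0
    k: float = 1.2
    c_half: float = 1.5
    sigma_e: float = 0.0
    variant: str = "sigmoid"
    F_max: float = 1.0
    F_0: float = 0.0
    n_hill: float = 2.0
    K_d: float = 2.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not (self.tau_r > 0 and self.tau_d > 0):
            raise ValueError("tau_r and tau_d must be > 0")
        if self.tau_d <= self.tau_r:
            raise ValueError(
                f"decay must be slower than rise: tau_d={self.tau_d} <= tau_r={self.tau_r}"
            )
        if self.sigma_i < 0 or self.sigma_e < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for name in self.active_names():
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"active parameter {name} must be finite, got {v}")
        if self.variant == "sigmoid":
            if self.F_m <= 0 or self.k <= 0 or self.c_half < 0:
                raise ValueError("sigmoid requires F_m > 0, k > 0, c_half >= 0")
        if self.variant == "hill":
            if self.n_hill <= 0 or self.K_d <= 0:
                raise ValueError("hill requires n_hill > 0 and K_d > 0")

    def active_names(self) -> tuple[str, ...]:
        """Kinetic plus variant-specific readout parameter names."""
        return ("tau_r", "tau_d") + _ACTIVE_READOUT[self.variant]

    def readout(self, c: np.ndarray) -> np.ndarray:
        """Noise-free readout nonlinearity applied to latent values."""
        from scipy.special import expit

        c = np.asarray(c, dtype=float)
        if self.variant == "sigmoid":
            return self.F_m * expit(self.k * (c - self.c_half))
        if self.variant == "linear":
            return self.F_max * c + self.F_0
        cn = np.power(c, self.n_hill)
        return self.F_max * cn / (cn + self.K_d)

    def replace(self, **kw) -> "S2FParams":
        return replace(self, **kw)

    def to_dict(self) -> dict[str, float | str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ParamDistribution:
    """Empirical distribution of S2F parameters (one sample per fitted
    response set), used to propagate parameter uncertainty into metric
    distributions."""

    samples: list[S2FParams]
    indicator_label: str = ""

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("ParamDistribution needs at least one sample")

    def __len__(self) -> int:
        return len(self.samples)

    def draw(self, n: int, rng: np.random.Generator) -> list[S2FParams]:
        idx = rng.integers(0, len(self.samples), size=n)
        return [self.samples[i] for i in idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.to_dict() for p in self.samples])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, indicator_label: str = "") -> "ParamDistribution":
        samples = [S2FParams(**{k: row[k] for k in row.index}) for _, row in df.iterrows()]
        return cls(samples, indicator_label)

    @classmethod
    def from_csv(cls, path, indicator_label: str = "") -> "ParamDistribution":
        return cls.from_frame(pd.read_csv(path), indicator_label)


def default_distribution(
    indicator: str = "6s",
    n_samples: int = 200,
    seed: int | None = 0,
    sigma_i: float = 0.05,
    noise: bool = True,
) -> ParamDistribution:
    """Illustrative per-neuron parameter distributions for slow ("6s") and
    fast ("6f") indicators.

    These are synthetic distributions reflecting the known qualitative
    kinetics of the two indicator classes (slow indicators: decay on the
    order of a second, larger dF/F transients; fast indicators: several-fold
    faster decay, smaller and noisier transients) and the inverse
    association between half-activation and nonlinearity sharpness seen in
    fitted populations.  They are not fitted values from any recording.
    """
    rng = np.random.default_rng(seed)
    if indicator in ("6s", "6s-like", "gcamp6s"):
        med_tau_r, med_tau_d, med_Fm, med_chalf, med_k, rel_sigma_e = (
            0.07, 1.3, 3.0, 1.5, 1.2, 0.02)
    elif indicator in ("6f", "6f-like", "gcamp6f"):
        med_tau_r, med_tau_d, med_Fm, med_chalf, med_k, rel_sigma_e = (
            0.025, 0.35, 1.5, 2.0, 1.0, 0.05)
    else:
        raise ValueError(f"unknown indicator {indicator!r}")

    samples = []
    for _ in range(n_samples):
        tau_r = med_tau_r * np.exp(rng.normal(0, 0.3))
        tau_d = med_tau_d * np.exp(rng.normal(0, 0.25))
        tau_d = max(tau_d, tau_r * 1.5)
        F_m = med_Fm * np.exp(rng.normal(0, 0.3))
        # inverse c_half/k association: shared lognormal factor u
        u = np.exp(rng.normal(0, 0.35))
        c_half = med_chalf * u * np.exp(rng.normal(0, 0.1))
        k = med_k / u * np.exp(rng.normal(0, 0.1))
        samples.append(
            S2FParams(
                tau_r=tau_r,
                tau_d=tau_d,
                sigma_i=sigma_i if noise else 0.0,
                F_m=F_m,
                k=k,
                c_half=c_half,
                sigma_e=rel_sigma_e * F_m if noise else 0.0,
            )
        )
    label = f"{indicator}-like (synthetic, illustrative)"
    return ParamDistribution(samples, label)
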