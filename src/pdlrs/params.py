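"""Compound model parameters shared across the likelihood components."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .two_type_bd import BDRates

__all__ = ["RateModel", "ModelParams"]


@dataclass(frozen=True)
class RateModel:
    """Gamma distribution of per-edge substitution rates (relaxed clock).

    Parameterized by mean ``m`` and coefficient of variation ``c``:
    shape = 1/c^2, scale = m c^2.  An edge spanning time ``t`` with rate
    ``r`` has length ``l = r t``, so the induced length density is
    ``g(l, t) = rho(l / t) / t``.
    """

    mean: float
    cv: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.cv <= 0:
            raise ValueError("rate mean and CV must be positive")

    @property
    def shape(self) -> float:
        return 1.0 / self.cv**2

    @property
    def scale(self) -> float:
        return self.mean * self.cv**2

    def log_rate_density(self, r):
        a, th = self.shape, self.scale
        r = np.asarray(r, dtype=float)
        with np.errstate(divide="ignore"):
            return (a - 1) * np.log(r) - r / th - gammaln(a) - a * np.log(th)

    def rate_density(self, r):
        return np.exp(self.log_rate_density(r))

    def length_density(self, l: float, t):
        """g(l, t): density of length ``l`` over a span of time ``t``."""
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.exp(self.log_rate_density(l / t)) / t
        return np.where(t > 0, out, 0.0)


@dataclass
class ModelParams:
    """The compound parameter theta of the generative model.

    Holds the duplication/loss/pseudogenization rates, the edge-rate mean
    and CV of the relaxed clock, and the codon-model scalars kappa and
    omega (omega applies to the gene mode; the pseudogene mode is neutral).
    """

    rates: BDRates
    rate_model: RateModel
    kappa: float = 2.0
    omega: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.omega):
            raise ValueError("omega must be nonnegative")
        if not (0 <= self.kappa):
            raise ValueError("kappa must be nonnegative")

    @property
    def delta(self) -> float:
        return self.rates.delta

    @property
    def mu(self) -> float:
        return self.rates.mu

    @property
    def psi(self) -> float:
        return self.rates.psi
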