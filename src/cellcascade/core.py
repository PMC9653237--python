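"""Parameter objects and the truncated-pmf carrier shared by all modules.

A *compartment* is a cell stage in which every cell, independently, meets one
of four fates: symmetric division (probability ``p_b``, two daughters stay in
the compartment), death (``p_d``), exit to the next compartment or to the
product population (``p_e``), or asymmetric division (``p_a``, one daughter
stays, one exits; both daughters advance one generation).  The compartment is
*subcritical* when the mean number of daughters that remain in it,
``2 p_b + p_a``, is strictly below one; only then is the progeny of a single
founder finite with probability one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

#: tolerance used when validating that probabilities sum to one
PROB_TOL = 1e-9


class ParameterError(ValueError):
    """Invalid model parameters (probabilities out of range, bad shapes...)."""


class SupercriticalError(ParameterError):
    """Raised when 2*p_b + p_a >= 1: the mean family size would be infinite."""


class PGFDomainError(ParameterError):
    """Generating-function argument beyond the square-root singularity."""


class TruncationError(RuntimeError):
    """A series did not converge within the allowed truncation order."""


class ConfigError(ValueError):
    """Malformed chain configuration (file or mapping)."""


class InfeasibleError(ParameterError):
    """Optimization constraints cannot be met with valid probabilities."""


@dataclass(frozen=True)
class Rates:
    """Per-day event rates of the continuous-time birth-death-migration picture.

    ``lam`` is the division rate, ``mu`` the death rate and ``nu`` the exit
    (migration/differentiation) rate.  With exponential waiting times the
    embedded fate probabilities are the normalized rates.
    """

    lam: float
    mu: float
    nu: float

    def __post_init__(self) -> None:
        for name in ("lam", "mu", "nu"):
            if getattr(self, name) < 0:
                raise ParameterError(f"rate {name!r} must be non-negative")
        if self.lam + self.mu + self.nu <= 0:
            raise ParameterError("at least one rate must be strictly positive")

    @property
    def total(self) -> float:
        return self.lam + self.mu + self.nu


@dataclass(frozen=True)
class FateProbs:
    """One compartment's fate law (p_b, p_d, p_e, p_a).

    ``p_e`` may be omitted, in which case it is the complement
    ``1 - p_b - p_d - p_a``; published values are typically rounded, so
    requiring all four to sum to one at machine precision would be hostile.
    Construction enforces subcriticality (``2 p_b + p_a < 1``).
    """

    p_b: float
    p_d: float
    p_e: float = None  # type: ignore[assignment]
    p_a: float = 0.0

    def __post_init__(self) -> None:
        if self.p_e is None:
            object.__setattr__(self, "p_e", 1.0 - self.p_b - self.p_d - self.p_a)
        for name in ("p_b", "p_d", "p_e", "p_a"):
            v = getattr(self, name)
            if not (-PROB_TOL <= v <= 1.0 + PROB_TOL):
                raise ParameterError(f"{name} = {v} is not a probability")
            object.__setattr__(self, name, float(min(max(v, 0.0), 1.0)))
        total = self.p_b + self.p_d + self.p_e + self.p_a
        if abs(total - 1.0) > PROB_TOL:
            raise ParameterError(
                f"fate probabilities sum to {total}, expected 1 within {PROB_TOL}"
            )
        if 2.0 * self.p_b + self.p_a >= 1.0:
            raise SupercriticalError(
                f"2*p_b + p_a = {2 * self.p_b + self.p_a} >= 1: "
                "infinite mean family size"
            )

    @classmethod
    def from_rates(cls, rates: Rates) -> "FateProbs":
        """Embedded fate probabilities of the continuous-time process."""
        t = rates.total
        return cls(p_b=rates.lam / t, p_d=rates.mu / t, p_e=rates.nu / t)

    @classmethod
    def from_N_pd(cls, N: float, p_d: float) -> "FateProbs":
        """Reparametrize a three-fate compartment by its amplification N and p_d.

        Inverts N = p_e / (1 - 2 p_b) together with p_b + p_d + p_e = 1:
        p_b = (N - 1 + p_d) / (2N - 1), p_e = N (1 - 2 p_d) / (2N - 1).
        """
        if N <= 0:
            raise ParameterError(f"amplification N = {N} must be positive")
        if abs(2.0 * N - 1.0) < 1e-12:
            raise ParameterError("N = 1/2 is a removable singularity of the map")
        p_b = (N - 1.0 + p_d) / (2.0 * N - 1.0)
        p_e = N * (1.0 - 2.0 * p_d) / (2.0 * N - 1.0)
        if not (0.0 <= p_b < 0.5) or not (0.0 <= p_e <= 1.0):
            raise ParameterError(
                f"(N={N}, p_d={p_d}) maps to p_b={p_b}, p_e={p_e} outside [0,1]"
            )
        return cls(p_b=p_b, p_d=p_d, p_e=p_e)

    @property
    def mean_offspring_in_compartment(self) -> float:
        """Mean daughters staying in the compartment per cell, 2 p_b + p_a."""
        return 2.0 * self.p_b + self.p_a


class TruncatedPMF:
    """Probabilities over k = 0..K with explicitly tracked tail mass.

    Carrier for the family-size distribution q_k, its chain analogue Q_k(C)
    and the generation-number distribution P(G = n).  Entries must be
    non-negative and sum to at most one (within tolerance); the remainder is
    the tail mass beyond the truncation order K.
    """

    __slots__ = ("probs",)

    def __init__(self, probs: Iterable[float]) -> None:
        arr = np.asarray(probs, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ParameterError("probs must be a non-empty 1-D array")
        if arr.min() < -PROB_TOL:
            raise ParameterError(f"negative probability {arr.min()}")
        arr = np.clip(arr, 0.0, None)
        if arr.sum() > 1.0 + 1e-7:
            raise ParameterError(f"probabilities sum to {arr.sum()} > 1")
        self.probs = arr

    @property
    def K(self) -> int:
        return self.probs.size - 1

    @property
    def tail_mass(self) -> float:
        return max(0.0, 1.0 - float(self.probs.sum()))

    def __len__(self) -> int:
        return self.probs.size

    def __getitem__(self, k):
        return self.probs[k]

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    def mean(self) -> float:
        """First moment over the truncated support (no tail correction)."""
        return float(np.dot(self.support, self.probs))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot(self.support**2, self.probs)) - m * m

    def sf(self, k: int) -> float:
        """P(X > k), attributing the entire tail mass beyond K to the event."""
        inside = float(self.probs[k + 1 :].sum()) if k < self.K else 0.0
        return inside + self.tail_mass

    def __repr__(self) -> str:  # pragma: no cover
        return f"TruncatedPMF(K={self.K}, tail_mass={self.tail_mass:.3g})"
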