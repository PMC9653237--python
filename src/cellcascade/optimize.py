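"""Optimal compartment design: minimize divisions for a target amplification.

Given a target overall amplification N*, a number of compartments C and fixed
per-compartment death probabilities, choose the division probabilities
p_b(c) so that the mean generation number D of a product cell is minimal.
A Lagrange-multiplier argument on D = sum_c (alpha_c N_c - beta_c) subject to
prod_c N_c = N*, with alpha_c = 2/(1 - 2 p_d(c)) and beta_c = 1 + alpha_c/2,
yields the stationarity condition alpha_1 N_1 = ... = alpha_C N_C, hence
N_c = N*^(1/C) alpha~ / alpha_c with alpha~ the geometric mean of the
alpha_c, and

    D_min = C (alpha~ N*^(1/C) - alpha_bar/2 - 1).

If the death probability is uniform the optimum puts the same amplification
N*^(1/C) in every compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import FateProbs, InfeasibleError, ParameterError

__all__ = ["OptimizationResult", "optimize_chain", "dmin_uniform"]


@dataclass(frozen=True)
class OptimizationResult:
    """Optimal allocation of amplification across compartments."""

    Nc: tuple[float, ...]
    fate_probs: tuple[FateProbs, ...]
    Dmin: float
    alphas: tuple[float, ...]
    alpha_bar: float
    alpha_tilde: float


def optimize_chain(N_star: float, p_d: Sequence[float]) -> OptimizationResult:
    """Division probabilities minimizing D at fixed overall amplification.

    ``p_d`` fixes the death probability of each of the C compartments (each
    must be below 1/2); the optimizer allocates the per-compartment
    amplifications N_c = N*^(1/C) alpha~/alpha_c and rebuilds each
    compartment's fate law from (N_c, p_d(c)).  Raises
    :class:`InfeasibleError` when any implied p_b falls outside (0, 1/2).
    """
    pd = np.asarray(list(p_d), dtype=float)
    if pd.size < 1:
        raise ParameterError("need at least one compartment")
    if np.any(pd >= 0.5) or np.any(pd < 0.0):
        raise ParameterError("every p_d(c) must lie in [0, 1/2)")
    if N_star <= 1.0:
        raise ParameterError(f"target amplification N* = {N_star} must exceed 1")
    C = pd.size
    alphas = 2.0 / (1.0 - 2.0 * pd)
    alpha_bar = float(alphas.mean())
    alpha_tilde = float(np.exp(np.log(alphas).mean()))
    root = N_star ** (1.0 / C)
    nc = root * alpha_tilde / alphas
    dmin = C * (alpha_tilde * root - 0.5 * alpha_bar - 1.0)
    fps = []
    for n_c, pd_c in zip(nc, pd):
        try:
            fp = FateProbs.from_N_pd(float(n_c), float(pd_c))
        except ParameterError as err:
            raise InfeasibleError(
                f"optimal N_c = {n_c} with p_d = {pd_c} is not realizable"
            ) from err
        if not (0.0 < fp.p_b < 0.5):
            raise InfeasibleError(
                f"optimal p_b = {fp.p_b} outside (0, 1/2) for N_c = {n_c}"
            )
        fps.append(fp)
    return OptimizationResult(
        Nc=tuple(float(x) for x in nc),
        fate_probs=tuple(fps),
        Dmin=float(dmin),
        alphas=tuple(float(a) for a in alphas),
        alpha_bar=alpha_bar,
        alpha_tilde=alpha_tilde,
    )


def dmin_uniform(N_star: float, C: int, p_d: float = 0.0) -> float:
    """Closed-form D_min = 2C/(1 - 2 p_d) (N*^(1/C) - 1 + p_d), uniform death.

    Decreasing in C and increasing in p_d; as C grows without bound it
    approaches 2 log N* (at p_d = 0), the depth of a balanced binary tree.
    """
    if not (0.0 <= p_d < 0.5):
        raise ParameterError(f"p_d = {p_d} must lie in [0, 1/2)")
    if C < 1:
        raise ParameterError(f"C = {C} must be >= 1")
    if N_star <= 0.0:
        raise ParameterError(f"N* = {N_star} must be positive")
    return 2.0 * C / (1.0 - 2.0 * p_d) * (N_star ** (1.0 / C) - 1.0 + p_d)
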