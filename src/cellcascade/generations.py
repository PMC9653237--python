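"""Distribution of the generation number G of a random product cell.

The founder is generation 0; each division (symmetric or asymmetric) advances
both daughters one generation; a cell keeps its generation number when it
transits between compartments.  Within one compartment the generation gain of
an exiting cell is geometric-like, and for a chain the gains in successive
compartments are independent, so the chain-level law of G is the convolution
of per-compartment increments and its mean D is the sum of per-compartment
means D_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chain import CompartmentChain
from .core import FateProbs, ParameterError, TruncatedPMF
from . import single

__all__ = [
    "GenerationDistribution",
    "generation_increment_moments",
    "generation_pmf_single",
    "mean_generation_chain",
    "var_generation_chain",
    "generation_pmf_chain",
    "D_from_N_single",
    "invert_N_D",
]


@dataclass(frozen=True)
class GenerationDistribution:
    """pmf of G over n = 0..K plus its exact mean D and variance varG."""

    pmf: TruncatedPMF
    D: float
    varG: float


def _increment_weights(fp: FateProbs, K: int) -> np.ndarray:
    """Unnormalized mean exit counts y_n per entering cell, n = 0..K.

    With m = 2 p_b + p_a staying daughters per cell on average, the expected
    number of generation-n cells in the compartment is m^n, so
        y_n = p_e m^n + p_a m^(n-1)   (n >= 1),   y_0 = p_e:
    symmetric exits leave at their own generation, while the exiting daughter
    of an asymmetric division at generation n-1 leaves carrying generation n.
    Summing y_n over n recovers the amplification (p_e + p_a)/(1 - m).
    """
    m = fp.mean_offspring_in_compartment
    n = np.arange(K + 1)
    y = fp.p_e * m**n.astype(float)
    if fp.p_a != 0.0 and K >= 1:
        y[1:] += fp.p_a * m ** (n[1:] - 1.0)
    return y


def generation_increment_moments(fp: FateProbs) -> tuple[float, float]:
    """Mean D_c and variance of the generation gain in one compartment.

    Closed forms from the geometric-like weights y_n:
        D_c   = (p_e m + p_a) / ((1 - m)(p_e + p_a)),
        E G^2 = (1 + m)(p_e m + p_a) / ((1 - m)^2 (p_e + p_a)),
    with m = 2 p_b + p_a.  For p_a = 0 these reduce to D_c = 2p_b/(1 - 2p_b)
    and var = D_c (D_c + 1).
    """
    m = fp.mean_offspring_in_compartment
    w = fp.p_e + fp.p_a
    if w == 0.0:
        # no exit route at all: every family is empty, the law of G is vacuous
        return 0.0, 0.0
    d = (fp.p_e * m + fp.p_a) / ((1.0 - m) * w)
    second = (1.0 + m) * (fp.p_e * m + fp.p_a) / ((1.0 - m) ** 2 * w)
    return d, second - d * d


def _auto_K(chain_like, tol: float = 1e-12) -> int:
    comps = (
        chain_like.compartments
        if isinstance(chain_like, CompartmentChain)
        else (chain_like,)
    )
    m_max = max(fp.mean_offspring_in_compartment for fp in comps)
    if m_max <= 0.0:
        return max(8, len(comps))
    per = int(math.ceil(math.log(tol) / math.log(m_max))) + 8
    return per * len(comps)


def generation_pmf_single(fp: FateProbs, K: int | None = None) -> GenerationDistribution:
    """P(G = n) for one compartment: normalized y_n, with exact moments.

    For p_a = 0 this is the geometric law P(G = n) = (1 - 2p_b)(2p_b)^n with
    mean D = 2p_b/(1 - 2p_b) and var(G) = D(D + 1).
    """
    if K is None:
        K = _auto_K(fp)
    y = _increment_weights(fp, K)
    n_total = single.amplification(fp)
    probs = y / n_total if n_total > 0 else y
    d, var = generation_increment_moments(fp)
    return GenerationDistribution(pmf=TruncatedPMF(probs), D=d, varG=var)


def mean_generation_chain(chain: CompartmentChain) -> float:
    """Mean generation number D = D_1 + ... + D_C of a random product cell."""
    return sum(generation_increment_moments(fp)[0] for fp in chain.compartments)


def var_generation_chain(chain: CompartmentChain) -> float:
    """var(G) for the chain: per-compartment gains are independent, so sum."""
    return sum(generation_increment_moments(fp)[1] for fp in chain.compartments)


def generation_pmf_chain(
    chain: CompartmentChain, K: int | None = None
) -> GenerationDistribution:
    """Chain-level law of G: convolution of the per-compartment increments.

    The generating function of G factorizes over compartments
    (Xi(z) = xi_1(z) ... xi_C(z) with xi_c(z) = (1 - 2p_b)/(1 - 2p_b z) in
    the three-fate case), so the pmf is the C-fold convolution.  For C
    identical symmetric compartments this is a negative-binomial-type law.
    """
    if K is None:
        K = _auto_K(chain)
    acc = np.zeros(K + 1)
    acc[0] = 1.0
    for fp in chain.compartments:
        inc = generation_pmf_single(fp, K).pmf.probs
        acc = np.convolve(acc, inc)[: K + 1]
    return GenerationDistribution(
        pmf=TruncatedPMF(acc),
        D=mean_generation_chain(chain),
        varG=var_generation_chain(chain),
    )


def D_from_N_single(N: float, p_d: float) -> float:
    """Linear relation D = (2N - 1)/(1 - 2 p_d) - 1 for one compartment.

    At p_d = 0 this is the minimum D = 2(N - 1) attainable for a given N.
    """
    if 1.0 - 2.0 * p_d <= 0.0:
        raise ParameterError(f"p_d = {p_d} must be below 1/2")
    return (2.0 * N - 1.0) / (1.0 - 2.0 * p_d) - 1.0


def invert_N_D(N: float, D: float) -> FateProbs:
    """Recover (p_b, p_d, p_e) from the measurable pair (N, D).

    p_b = D/(2(D+1)) and p_e = N/(D+1); the implied p_d must land in [0, 1]
    or the measurements are mutually inconsistent.
    """
    if D < 0.0:
        raise ParameterError(f"D = {D} must be non-negative")
    p_b = 0.5 * D / (D + 1.0)
    p_e = N / (D + 1.0)
    p_d = 1.0 - p_b - p_e
    if not (-1e-12 <= p_d <= 1.0):
        raise ParameterError(
            f"(N={N}, D={D}) implies p_d = {p_d}: inconsistent measurements"
        )
    return FateProbs(p_b=p_b, p_d=max(p_d, 0.0), p_e=p_e)
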