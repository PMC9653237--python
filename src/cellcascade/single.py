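"""Exact single-compartment quantities.

A founder cell enters one compartment; every cell there independently dies
(p_d), divides (p_b), exits (p_e) or divides asymmetrically (p_a).  The number
R of cells that ultimately exit is the total "family size" of the founder.
This module carries the closed forms for the distribution of R and its
summaries: the amplification factor N = E(R), the no-exit extinction
probability q_0, the probability generating function phi, the variance V,
the geometric tail constant gamma_1 of q_k ~ gamma_1^k k^(-3/2), and the
clonality statistic k50.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    FateProbs,
    ParameterError,
    PGFDomainError,
    Rates,
    TruncatedPMF,
    TruncationError,
)

__all__ = [
    "fate_probs_from_rates",
    "fate_probs_from_N_pd",
    "amplification",
    "discriminant",
    "extinction_no_exit",
    "pgf_phi",
    "family_size_pmf",
    "variance_R",
    "tail_constant_gamma1",
    "tail_asymptote",
    "k50",
    "k50_analytic_bound",
]

#: hard cap on the number of q_k terms examined when locating k50
K50_HARD_CAP = 10**7


def fate_probs_from_rates(rates: Rates) -> FateProbs:
    """Convert continuous-time rates (lam, mu, nu) to fate probabilities.

    With exponential waiting times the embedded jump chain chooses each fate
    with probability proportional to its rate.
    """
    return FateProbs.from_rates(rates)


def fate_probs_from_N_pd(N: float, p_d: float) -> FateProbs:
    """Build a three-fate compartment from its amplification N and p_d."""
    return FateProbs.from_N_pd(N, p_d)


def amplification(fp: FateProbs) -> float:
    """Mean number of exiting cells per founder, N = (p_e + p_a)/(1 - 2p_b - p_a).

    First-step argument: conditioning on the founder's fate,
    N = p_e * 1 + p_b * 2N + p_a * (1 + N).  With p_a = 0 this is the familiar
    N = p_e / (1 - 2 p_b).
    """
    return (fp.p_e + fp.p_a) / (1.0 - 2.0 * fp.p_b - fp.p_a)


def discriminant(fp: FateProbs) -> float:
    """Delta = sqrt(1 - 4 p_d p_b), the square root of the pgf discriminant at z=0."""
    return math.sqrt(1.0 - 4.0 * fp.p_d * fp.p_b)


def extinction_no_exit(fp: FateProbs) -> float:
    """Probability q_0 that the family produces no exiting cell at all.

    q_0 solves q_0 = p_d + p_b q_0^2 (asymmetric division always produces an
    exiting daughter, so it contributes no path to R = 0); the root in [0, 1]
    is written in the cancellation-free form 2 p_d / (1 + Delta).
    """
    return 2.0 * fp.p_d / (1.0 + discriminant(fp))


def pgf_phi(fp: FateProbs, z: float) -> float:
    """Probability generating function phi(z) = E(z^R) of the exit count.

    phi satisfies the first-step fixed point
    ``phi = p_d + p_e z + p_b phi^2 + p_a z phi``;
    the root with phi(1) = 1 is the branch through
    ``phi = 2 (p_d + p_e z) / (b + sqrt(b^2 - 4 p_b (p_d + p_e z)))`` with
    b = 1 - p_a z, which degrades gracefully to the linear solution
    (p_d + p_e z)/(1 - p_a z) as p_b -> 0.  Arguments slightly above one are
    accepted up to the square-root singularity.
    """
    if z < 0.0:
        raise PGFDomainError(f"z = {z} must be non-negative")
    b = 1.0 - fp.p_a * z
    c = fp.p_d + fp.p_e * z
    disc = b * b - 4.0 * fp.p_b * c
    if disc < -1e-12:
        raise PGFDomainError(
            f"z = {z} lies beyond the radius of convergence (discriminant {disc})"
        )
    return 2.0 * c / (b + math.sqrt(max(disc, 0.0)))


def family_size_pmf(fp: FateProbs, K: int) -> TruncatedPMF:
    """Exact pmf q_k = P(R = k), k = 0..K, for a three-fate compartment.

    q_0 = 2 p_d / (1 + Delta), q_1 = p_e / Delta, and successive terms follow
    the stable ratio recursion
    ``q_{k+1} = (2k - 1)/(k + 1) * 2 p_b p_e / Delta^2 * q_k``
    (equivalently the Catalan closed form
    q_k = (p_b/Delta)^(k-1) (p_e/Delta)^k c_{k-1}).  Terms below the double
    underflow threshold flush to zero; they are beyond any meaningful tail.
    """
    if fp.p_a != 0.0:
        raise ParameterError(
            "family_size_pmf covers the three-fate compartment; "
            "with p_a > 0 use chain.product_pmf on a single-compartment chain"
        )
    if K < 0:
        raise ParameterError(f"truncation order K = {K} must be >= 0")
    delta = discriminant(fp)
    q = np.zeros(K + 1)
    q[0] = extinction_no_exit(fp)
    if K >= 1:
        q[1] = fp.p_e / delta
    if K >= 2:
        k = np.arange(1, K)
        ratios = (2.0 * k - 1.0) / (k + 1.0) * (2.0 * fp.p_b * fp.p_e / delta**2)
        q[2:] = q[1] * np.cumprod(ratios)
    return TruncatedPMF(q)


def variance_R(fp: FateProbs) -> float:
    """Variance of the exit count R, via phi''(1) + N - N^2.

    Implicit differentiation of the pgf fixed point gives
    ``phi''(1) = (2 p_b N^2 + 2 p_a N) / (1 - 2 p_b - p_a)``,
    which avoids the p_e = 0 singularity of the textbook form
    V = (2 p_b / p_e) N^3 + N - N^2 and covers asymmetric division.
    """
    n = amplification(fp)
    phi2 = (2.0 * fp.p_b * n * n + 2.0 * fp.p_a * n) / (1.0 - 2.0 * fp.p_b - fp.p_a)
    return phi2 + n - n * n


def tail_constant_gamma1(fp: FateProbs) -> float:
    """Geometric decay constant gamma_1 = 4 p_b p_e / (1 - 4 p_b p_d).

    For large k, q_k ~ const * gamma_1^k k^(-3/2); for N >> 1,
    gamma_1 ~= 1 - (1 - 2 p_d)/(4 N^2).
    """
    if fp.p_a != 0.0:
        raise ParameterError("gamma_1 is defined for the three-fate compartment")
    return 4.0 * fp.p_b * fp.p_e / (1.0 - 4.0 * fp.p_b * fp.p_d)


def tail_asymptote(fp: FateProbs, k) -> np.ndarray:
    """Large-k form (p_e/(sqrt(pi) Delta)) gamma_1^(k-1) k^(-3/2) of q_k.

    q_k approaches this expression from above as k grows (it is the leading
    term of the Stirling expansion of the Catalan closed form, not a uniform
    upper bound at small k).
    """
    k = np.asarray(k, dtype=float)
    g = tail_constant_gamma1(fp)
    return fp.p_e / (math.sqrt(math.pi) * discriminant(fp)) * g ** (k - 1.0) * k**-1.5


def k50(fp_or_pmf, N: float | None = None, cap: int = K50_HARD_CAP) -> int:
    """Clonality statistic: smallest K with sum_{k<=K} k q_k strictly above N/2.

    Half of all product cells (cell-weighted, not family-weighted) belong to
    families of fewer than k50 cells.  Accepts either a three-fate
    :class:`FateProbs` (the series is extended on the fly) or a precomputed
    :class:`TruncatedPMF` whose truncation must already cross the target;
    for a pmf the mean ``N`` may be supplied exactly, otherwise the truncated
    first moment stands in for it.
    """
    if isinstance(fp_or_pmf, TruncatedPMF):
        pmf = fp_or_pmf
        target = 0.5 * (pmf.mean() if N is None else N)
        partial = np.cumsum(pmf.support * pmf.probs)
        hits = np.nonzero(partial > target)[0]
        if hits.size == 0:
            raise TruncationError("pmf truncation too short to locate k50")
        return int(hits[0])
    fp: FateProbs = fp_or_pmf
    if fp.p_a != 0.0:
        raise ParameterError("k50 on FateProbs assumes the three-fate compartment")
    target = 0.5 * amplification(fp)
    delta2 = 1.0 - 4.0 * fp.p_b * fp.p_d
    rho = 2.0 * fp.p_b * fp.p_e / delta2
    qk = fp.p_e / math.sqrt(delta2)  # q_1
    partial = qk  # sum of k*q_k so far (k = 1)
    k = 1
    while partial <= target:
        qk *= (2.0 * k - 1.0) / (k + 1.0) * rho
        k += 1
        partial += k * qk
        if k > cap:
            raise TruncationError(f"k50 did not converge within {cap} terms")
    return k


def k50_analytic_bound(N: float, p_d: float = 0.0) -> float:
    """Closed-form lower bound (pi/16) Delta^2/(1-2p_d)^2 (2N-1)^2 on k50.

    Delta is evaluated at the (N, p_d) parametrization of the compartment.
    The true k50 always exceeds this value; at p_d = 0 it reduces to
    (pi/16)(2N-1)^2.
    """
    if N <= 1.0:
        raise ParameterError(f"the bound requires N > 1, got {N}")
    fp = FateProbs.from_N_pd(N, p_d)
    delta2 = 1.0 - 4.0 * fp.p_b * fp.p_d
    return math.pi / 16.0 * delta2 / (1.0 - 2.0 * p_d) ** 2 * (2.0 * N - 1.0) ** 2
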