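"""Multi-compartment machinery.

Cells travel through an ordered sequence of C compartments; cells exiting
compartment c enter compartment c+1, and cells exiting the last compartment
are *product* cells.  Because each cell acts independently, the generating
function of the product-cell count is the nested composition
``Phi_C(z) = phi_1(phi_2(...phi_C(z)))`` — outermost is the FIRST
compartment.  This module extracts the coefficients Q_k(C) of Phi_C by an
order-by-order recursion on the first compartment's fixed-point equation,
and provides the overall amplification, the compound variance of R, the
geometric tail constant gamma_C, and the chain-level clonality statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    FateProbs,
    ParameterError,
    Rates,
    TruncatedPMF,
    TruncationError,
)
from . import single

__all__ = [
    "CompartmentChain",
    "TailConstant",
    "equal_chain",
    "overall_amplification",
    "pgf_chain",
    "product_pmf",
    "tail_constant",
    "variance_R_chain",
    "k50_chain",
]

#: hard cap on the truncation order of the chain coefficient recursion
CHAIN_K_CAP = 1 << 18


@dataclass(frozen=True)
class CompartmentChain:
    """Ordered sequence of compartments; index 0 is where the founder starts.

    Each compartment must individually be subcritical (enforced by
    :class:`FateProbs` on construction).  ``rates`` optionally carries the
    continuous-time rates each compartment was derived from, enabling the
    Gillespie simulation mode.
    """

    compartments: tuple[FateProbs, ...]
    rates: Optional[tuple[Rates, ...]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        comps = tuple(self.compartments)
        if len(comps) < 1:
            raise ParameterError("a chain needs at least one compartment")
        for fp in comps:
            if not isinstance(fp, FateProbs):
                raise ParameterError(f"not a FateProbs: {fp!r}")
        object.__setattr__(self, "compartments", comps)
        if self.rates is not None:
            r = tuple(self.rates)
            if len(r) != len(comps):
                raise ParameterError("rates and compartments must align")
            object.__setattr__(self, "rates", r)

    @classmethod
    def from_rates(cls, rates: Sequence[Rates]) -> "CompartmentChain":
        comps = tuple(FateProbs.from_rates(r) for r in rates)
        return cls(comps, rates=tuple(rates))

    @property
    def C(self) -> int:
        return len(self.compartments)

    def __len__(self) -> int:
        return len(self.compartments)

    def __getitem__(self, c: int) -> FateProbs:
        return self.compartments[c]


@dataclass(frozen=True)
class TailConstant:
    """Geometric decay constant of Q_k(C) ~ gamma_C^k k^(-3/2).

    ``gammaC`` is the exact value located from the square-root singularity of
    the composed generating function; ``approx`` the large-N approximation
    1 - (1 - 2 p_d(1)) / (4 N_1 N).
    """

    gammaC: float
    approx: float


def equal_chain(N: float, C: int, p_d: float = 0.0) -> CompartmentChain:
    """C identical compartments, each with amplification N**(1/C) and death p_d."""
    if C < 1:
        raise ParameterError(f"C = {C} must be >= 1")
    fp = FateProbs.from_N_pd(N ** (1.0 / C), p_d)
    return CompartmentChain((fp,) * C)


def overall_amplification(chain: CompartmentChain) -> float:
    """Mean product cells per founder: the product of per-compartment N_c."""
    n = 1.0
    for fp in chain.compartments:
        n *= single.amplification(fp)
    return n


def pgf_chain(chain: CompartmentChain, z: float) -> float:
    """Nested scalar evaluation Phi_C(z) = phi_1(phi_2(...phi_C(z)))."""
    val = z
    for fp in reversed(chain.compartments):
        val = single.pgf_phi(fp, val)
    return val


def _compose_coeffs(fp: FateProbs, psi: np.ndarray) -> np.ndarray:
    """Coefficients of phi_fp(Psi(z)) given the coefficients ``psi`` of Psi.

    phi_fp composed with Psi inherits the first-step fixed point
    ``Phi = p_d + p_e Psi + p_b Phi^2 + p_a Psi Phi``.  Matching powers of z:
    the k-th equation is linear in Phi_k once lower orders are known, with
    pivot s = sqrt((1 - p_a Psi_0)^2 - 4 p_b (p_d + p_e Psi_0)), so

        Phi_k = (p_e Psi_k + p_b * sum_{j=1}^{k-1} Phi_j Phi_{k-j}
                           + p_a * sum_{j=0}^{k-1} Psi_{k-j} Phi_j) / s.

    The constant term is the stable small root Phi_0 = 2 c / (b + s), which
    also covers p_b = 0 (where the fixed point is linear).
    """
    K = psi.size - 1
    b = 1.0 - fp.p_a * psi[0]
    c = fp.p_d + fp.p_e * psi[0]
    s = math.sqrt(max(b * b - 4.0 * fp.p_b * c, 0.0))
    if s <= 0.0:
        raise ParameterError("chain is critical: composed pgf has no stable root")
    phi = np.zeros(K + 1)
    phi[0] = 2.0 * c / (b + s)
    for k in range(1, K + 1):
        acc = fp.p_e * psi[k]
        if fp.p_b != 0.0 and k >= 2:
            acc += fp.p_b * np.dot(phi[1:k], phi[k - 1 : 0 : -1])
        if fp.p_a != 0.0:
            acc += fp.p_a * np.dot(psi[1 : k + 1], phi[k - 1 :: -1])
        phi[k] = acc / s
    return phi


def product_pmf(chain: CompartmentChain, K: int) -> TruncatedPMF:
    """Exact pmf Q_k(C) = P(R = k) of the product-cell count, k = 0..K.

    Built innermost-first: starting from the identity series (Psi = z for the
    virtual stage after compartment C), each compartment's generating
    function is composed on the outside via the coefficient recursion.  Cost
    is O(C K^2).  For C = 1 with p_a = 0 this reproduces
    :func:`single.family_size_pmf` exactly.
    """
    if K < 0:
        raise ParameterError(f"truncation order K = {K} must be >= 0")
    if K > CHAIN_K_CAP:
        raise TruncationError(f"requested K = {K} exceeds the cap {CHAIN_K_CAP}")
    psi = np.zeros(K + 1)
    if K >= 1:
        psi[1] = 1.0
    for fp in reversed(chain.compartments):
        psi = _compose_coeffs(fp, psi)
    return TruncatedPMF(psi)


def tail_constant(chain: CompartmentChain) -> TailConstant:
    """Exact gamma_C from the singularity of the composed generating function.

    The square-root singularity lives in the first compartment's phi_1;
    composing with the subchain and expanding about z = 1 gives
        gamma_C = (1 + (1 - gamma_1) / (gamma_1 N / N_1))^(-1),
    with gamma_1 and N_1 of the first compartment and N the overall mean.
    Defined for a three-fate first compartment (p_a(1) = 0).
    """
    first = chain.compartments[0]
    if first.p_a != 0.0:
        raise ParameterError(
            "gamma_C requires a three-fate first compartment (p_a(1) = 0)"
        )
    g1 = single.tail_constant_gamma1(first)
    n1 = single.amplification(first)
    n = overall_amplification(chain)
    gamma_c = 1.0 / (1.0 + (1.0 - g1) / (g1 * n / n1))
    approx = 1.0 - (1.0 - 2.0 * first.p_d) / (4.0 * n1 * n)
    return TailConstant(gammaC=gamma_c, approx=approx)


def variance_R_chain(chain: CompartmentChain) -> float:
    """Variance of the product-cell count via the compound-sum recursion.

    Walking the chain backwards, if the subchain from compartment c+1 yields
    progeny with mean m and variance v per entering cell, then one cell in
    compartment c yields mean n_c m and variance n_c v + v_c m^2 (variance of
    a random sum), with (n_c, v_c) the single-compartment exit moments.
    For identical equal-amplification compartments with p_d = 0 this grows
    like N^(2 + 1/C) as the overall N grows.
    """
    m, v = 1.0, 0.0
    for fp in reversed(chain.compartments):
        n_c = single.amplification(fp)
        v_c = single.variance_R(fp)
        v = n_c * v + v_c * m * m
        m = n_c * m
    return v


def k50_chain(chain: CompartmentChain, K_start: int = 2048) -> int:
    """Chain-level clonality statistic with the same strict-crossing rule.

    Smallest K with sum_{k<=K} k Q_k(C) strictly above N/2, where N is the
    overall amplification.  The truncation starts at ``K_start`` and doubles
    until the partial sum crosses, up to the module cap.
    """
    target = 0.5 * overall_amplification(chain)
    K = K_start
    while True:
        pmf = product_pmf(chain, K)
        partial = np.cumsum(pmf.support * pmf.probs)
        hits = np.nonzero(partial > target)[0]
        if hits.size:
            return int(hits[0])
        if K >= CHAIN_K_CAP:
            raise TruncationError(f"k50 not reached within K = {K}")
        K = min(2 * K, CHAIN_K_CAP)
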