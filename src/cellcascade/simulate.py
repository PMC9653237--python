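"""Monte-Carlo simulation of families: the oracle for every closed form.

Two modes reproduce the same embedded law:

* ``discrete`` draws each cell's fate directly from (p_d, p_b, p_e, p_a);
  since only ultimate counts matter, inter-event times are irrelevant and
  the whole ensemble can be advanced compartment-by-compartment and
  generation-by-generation with multinomial draws.
* ``continuous`` runs the Gillespie picture: each cell races independent
  exponential death/division/exit clocks and its fate is the minimum.  It
  requires the chain to carry rates and exists to confirm that the ultimate
  counts do not depend on the waiting-time distributions.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .chain import CompartmentChain
from .core import ConfigError, ParameterError, TruncatedPMF
from . import chain as chain_mod

__all__ = [
    "FamilyRealization",
    "SimulationSummary",
    "simulate_family",
    "simulate_summary",
    "race_fates",
]

#: safety cap on single-family event counts (unreachable for valid chains)
EVENT_CAP = 10**7

_FATE_DEATH, _FATE_DIVIDE, _FATE_EXIT, _FATE_ASYM = range(4)


@dataclass(frozen=True)
class FamilyRealization:
    """Outcome of one founder: product count R and product-cell generations."""

    R: int
    generations: tuple[int, ...]
    per_compartment_exits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.R != len(self.generations):
            raise ParameterError("R must equal the number of recorded generations")


@dataclass(frozen=True)
class SimulationSummary:
    """Aggregated ensemble of families simulated with one seed."""

    n_families: int
    empirical_R_pmf: TruncatedPMF
    empirical_G_pmf: TruncatedPMF
    mean_R: float
    var_R: float
    mean_G: float
    seed: int


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_family(
    chain: CompartmentChain, rng_seed, discipline: str = "lifo"
) -> FamilyRealization:
    """Event-driven realization of one family through the chain.

    A work queue holds (compartment, generation) cells; each pop draws one
    fate: death removes the cell, symmetric division pushes two cells at
    generation+1 in the same compartment, exit moves the cell (same
    generation) to the next compartment or records it as a product cell,
    and asymmetric division pushes one daughter at generation+1 in the same
    compartment while the other daughter (also generation+1) exits.  Because
    fates are independent, the queue discipline ("lifo" or "fifo") does not
    change the law of the outcome.
    """
    if discipline not in ("lifo", "fifo"):
        raise ParameterError(f"unknown queue discipline {discipline!r}")
    rng = _as_rng(rng_seed)
    C = chain.C
    cum = [np.cumsum([fp.p_d, fp.p_b, fp.p_e, fp.p_a]) for fp in chain.compartments]
    queue: deque = deque()
    queue.append((0, 0))
    product_gens: list[int] = []
    exits = [0] * C
    events = 0
    while queue:
        c, g = queue.pop() if discipline == "lifo" else queue.popleft()
        events += 1
        if events > EVENT_CAP:
            raise RuntimeError(f"family exceeded {EVENT_CAP} events; chain misuse?")
        u = rng.random()
        fate = int(np.searchsorted(cum[c], u, side="right"))
        if fate == _FATE_DEATH:
            continue
        if fate == _FATE_DIVIDE:
            queue.append((c, g + 1))
            queue.append((c, g + 1))
        elif fate == _FATE_EXIT:
            exits[c] += 1
            if c + 1 < C:
                queue.append((c + 1, g))
            else:
                product_gens.append(g)
        else:  # asymmetric division: one stays, one exits, both at g+1
            queue.append((c, g + 1))
            exits[c] += 1
            if c + 1 < C:
                queue.append((c + 1, g + 1))
            else:
                product_gens.append(g + 1)
    return FamilyRealization(
        R=len(product_gens),
        generations=tuple(product_gens),
        per_compartment_exits=tuple(exits),
    )


def _sweep_discrete_batch(
    chain: CompartmentChain, n_families: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ensemble: per-family product counts and pooled G histogram.

    Families are advanced compartment-by-compartment; within a compartment,
    generation-by-generation with multinomial fate draws over all families at
    once.  Returns (R per family, product-cell counts per generation).
    """
    F = n_families
    entering = np.zeros((F, 1), dtype=np.int64)
    entering[:, 0] = 1
    for fp in chain.compartments:
        p = np.array([fp.p_d, fp.p_b, fp.p_e, fp.p_a])
        p = p / p.sum()
        g_in = entering.shape[1]
        out = np.zeros((F, g_in + 16), dtype=np.int64)
        stay = np.zeros(F, dtype=np.int64)
        g = 0
        while True:
            active = stay.copy()
            if g < g_in:
                active += entering[:, g]
            if g >= g_in and not active.any():
                break
            if g + 1 >= out.shape[1]:
                out = np.concatenate(
                    [out, np.zeros((F, out.shape[1]), np.int64)], axis=1
                )
            if active.any():
                draws = rng.multinomial(active, p)
                out[:, g] += draws[:, _FATE_EXIT]
                out[:, g + 1] += draws[:, _FATE_ASYM]
                stay = 2 * draws[:, _FATE_DIVIDE] + draws[:, _FATE_ASYM]
            else:
                stay[:] = 0
            g += 1
            if g > 10**6:
                raise RuntimeError("generation sweep failed to terminate")
        nz = np.nonzero(out.any(axis=0))[0]
        entering = out[:, : nz[-1] + 1] if nz.size else out[:, :1]
    return entering.sum(axis=1), entering.sum(axis=0)


def _gillespie_family(
    chain: CompartmentChain, rng: np.random.Generator
) -> tuple[int, list[int]]:
    """One continuous-time family: exponential clock races per cell."""
    C = chain.C
    rates = chain.rates
    queue: list[tuple[int, int]] = [(0, 0)]
    product_gens: list[int] = []
    events = 0
    while queue:
        c, g = queue.pop()
        events += 1
        if events > EVENT_CAP:
            raise RuntimeError(f"family exceeded {EVENT_CAP} events")
        r = rates[c]
        taus = [
            rng.exponential(1.0 / r.mu) if r.mu > 0 else math.inf,
            rng.exponential(1.0 / r.lam) if r.lam > 0 else math.inf,
            rng.exponential(1.0 / r.nu) if r.nu > 0 else math.inf,
        ]
        fate = int(np.argmin(taus))
        if fate == _FATE_DEATH:
            continue
        if fate == _FATE_DIVIDE:
            queue.append((c, g + 1))
            queue.append((c, g + 1))
        else:
            if c + 1 < C:
                queue.append((c + 1, g))
            else:
                product_gens.append(g)
    return len(product_gens), product_gens


def simulate_summary(
    chain: CompartmentChain,
    n_families: int,
    rng_seed: int,
    mode: str = "discrete",
    batch_size: int = 20000,
) -> SimulationSummary:
    """Simulate an ensemble of families and aggregate R and G statistics.

    Reproducible for a fixed seed; the ``discrete`` and ``continuous`` modes
    agree on all ultimate-count statistics within Monte-Carlo error, because
    the embedded fate probabilities coincide.  ``continuous`` requires the
    chain to have been built from rates and has no asymmetric-division
    analogue.
    """
    if n_families < 1:
        raise ParameterError(f"n_families = {n_families} must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if mode == "discrete":
        all_R: list[np.ndarray] = []
        g_counts = np.zeros(1, dtype=np.int64)
        done = 0
        while done < n_families:
            b = min(batch_size, n_families - done)
            r_batch, g_batch = _sweep_discrete_batch(chain, b, rng)
            all_R.append(r_batch)
            if g_batch.size > g_counts.size:
                g_counts = np.pad(g_counts, (0, g_batch.size - g_counts.size))
            g_counts[: g_batch.size] += g_batch
            done += b
        R = np.concatenate(all_R)
    elif mode == "continuous":
        if chain.rates is None:
            raise ConfigError("continuous mode requires a chain built from rates")
        if any(fp.p_a != 0.0 for fp in chain.compartments):
            raise ConfigError("continuous mode covers the three-fate chain only")
        R = np.empty(n_families, dtype=np.int64)
        g_list: list[int] = []
        for i in range(n_families):
            R[i], gens = _gillespie_family(chain, rng)
            g_list.extend(gens)
        g_counts = (
            np.bincount(np.asarray(g_list, dtype=np.int64))
            if g_list
            else np.zeros(1, dtype=np.int64)
        )
    else:
        raise ConfigError(f"unknown simulation mode {mode!r}")
    r_counts = np.bincount(R)
    total_products = int(g_counts.sum())
    mean_g = (
        float(np.dot(np.arange(g_counts.size), g_counts)) / total_products
        if total_products
        else float("nan")
    )
    g_probs = (
        g_counts / total_products if total_products else np.ones(1)
    )
    return SimulationSummary(
        n_families=n_families,
        empirical_R_pmf=TruncatedPMF(r_counts / n_families),
        empirical_G_pmf=TruncatedPMF(g_probs),
        mean_R=float(R.mean()),
        var_R=float(R.var(ddof=1)) if n_families > 1 else 0.0,
        mean_G=mean_g,
        seed=int(rng_seed),
    )


def race_fates(tau_d, tau_b, tau_e, size: int | None = None):
    """Fate as the argmin of three waiting-time samplers.

    Each sampler is called with ``size`` (or with no argument when ``size``
    is None) and must return positive reals.  Returns the label(s)
    ``"death"``/``"divide"``/``"exit"``; exact ties resolve in that fixed
    priority order (a probability-zero event for continuous samplers).  With
    exponential samplers of rates (mu, lam, nu) the induced fate frequencies
    are the normalized rates.
    """
    labels = np.array(["death", "divide", "exit"])
    if size is None:
        times = np.array([tau_d(), tau_b(), tau_e()], dtype=float)
        if np.any(times <= 0):
            raise ParameterError("waiting times must be positive")
        return str(labels[int(np.argmin(times))])
    times = np.stack(
        [np.asarray(tau_d(size)), np.asarray(tau_b(size)), np.asarray(tau_e(size))]
    )
    if np.any(times <= 0):
        raise ParameterError("waiting times must be positive")
    return labels[np.argmin(times, axis=0)]


def extinction_frequency(summary: SimulationSummary) -> float:
    """Empirical P(R = 0); converges to the composed pgf at z = 0."""
    return float(summary.empirical_R_pmf.probs[0])


def expected_extinction(chain: CompartmentChain) -> float:
    """Exact P(R = 0) = Phi_C(0) by nested scalar pgf evaluation."""
    return chain_mod.pgf_chain(chain, 0.0)
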