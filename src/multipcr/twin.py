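"""Stochastic digital twin of serial multi-template PCR.

The simulated workflow mirrors a serial amplification protocol: an oligo pool
with synthesis-biased initial abundances is repeatedly diluted, amplified for
a fixed number of PCR cycles, and sequenced.  Amplification is a Galton-Watson
branching process -- each molecule duplicates per cycle with probability
``p_i`` -- so small per-template differences in ``p_i`` compound exponentially
over cycles.  Sequencing is multinomial sampling of a fixed read budget.

A noiseless mode evaluates the two-parameter exponential model
``x_i(c) = x_i(0) * eps_i**c`` directly, providing the exact oracle for the
efficiency estimator.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .pool import OligoPool


@dataclasses.dataclass
class TwinParameters:
    """Parameters of the serial-amplification digital twin.

    synthesis_bias_sigma
        Log-scale sigma of the (mean-normalised) lognormal initial-abundance
        distribution produced by array synthesis.
    absolute_efficiency_mean
        Mean per-cycle duplication probability (PCR efficiency) of the pool.
    relative_efficiency_sigma
        Log-scale sigma of benign per-design efficiency variation.
    low_tail_fraction
        Fraction of designs carrying a deliberate efficiency penalty.
    penalty_range
        Relative-efficiency deficit interval for the low tail: a penalty d
        drawn from this interval gives relative efficiency 1 - d (down to 0.80
        at the default upper end).
    cycles_per_iteration, n_iterations
        Serial protocol: ``n_iterations`` consecutive amplifications of
        ``cycles_per_iteration`` cycles each (defaults 6 x 15 = 90 cycles).
    dilution_factor
        Dilution applied between iterations (default 3800x; 7600x is the
        plateau-avoidance variant).
    reads_per_design
        Mean sequencing depth per design and iteration.
    molecules_per_design
        Mean molecule count per design in the starting reaction (~5e4 for a
        0.1 ng template aliquot spread over 12,000 149-mers).
    resource_cap
        Optional total-molecule cap emulating the PCR plateau; duplication
        probabilities are scaled down once the pool would exceed it.
    """

    synthesis_bias_sigma: float = 0.30
    absolute_efficiency_mean: float = 0.90
    relative_efficiency_sigma: float = 0.01
    low_tail_fraction: float = 0.02
    penalty_range: tuple[float, float] = (0.05, 0.20)
    cycles_per_iteration: int = 15
    n_iterations: int = 6
    dilution_factor: float = 3800.0
    reads_per_design: float = 50.0
    molecules_per_design: float = 50000.0
    resource_cap: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.absolute_efficiency_mean <= 1.0):
            raise ValueError("absolute_efficiency_mean must be in (0, 1]")
        if self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must be >= 1")
        if self.low_tail_fraction < 0 or self.low_tail_fraction >= 1:
            raise ValueError("low_tail_fraction must be in [0, 1)")


@dataclasses.dataclass
class MoleculePopulation:
    counts: np.ndarray  # per-design molecule counts, int64
    cycle: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("molecule counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass
class TwinRun:
    """Output of one serial-amplification simulation."""

    ids: list[str]
    cycles: np.ndarray  # cumulative cycle numbers, shape (M,)
    read_counts: np.ndarray  # raw reads, shape (N, M)
    coverage: np.ndarray  # mean-normalised coverage, shape (N, M)
    relative_efficiency: np.ndarray  # ground-truth relative per-cycle factor
    initial_counts: np.ndarray  # molecule counts after synthesis


def sample_relative_efficiencies(
    n: int, params: TwinParameters, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-design relative efficiencies: benign lognormal spread plus a
    penalised low tail, normalised to mean 1."""
    eps = np.exp(rng.normal(0.0, params.relative_efficiency_sigma, size=n))
    n_low = int(round(params.low_tail_fraction * n))
    if n_low:
        low_idx = rng.choice(n, size=n_low, replace=False)
        lo, hi = params.penalty_range
        eps[low_idx] *= 1.0 - rng.uniform(lo, hi, size=n_low)
    return eps / eps.mean()


def simulate_synthesis(
    pool: OligoPool | int,
    params: TwinParameters,
    rng: np.random.Generator | int | None = None,
) -> MoleculePopulation:
    """Initial molecule counts after synthesis: mean-normalised lognormal
    abundances scaled to the configured molecule budget."""
    n = pool if isinstance(pool, int) else len(pool)
    if n < 1:
        raise ValueError("pool is empty")
    if params.molecules_per_design <= 0:
        raise ValueError("molecule budget must be positive")
    rng = np.random.default_rng(rng if rng is not None else params.seed)
    if params.synthesis_bias_sigma == 0:
        rel = np.ones(n)
    else:
        rel = np.exp(rng.normal(0.0, params.synthesis_bias_sigma, size=n))
        rel /= rel.mean()
    counts = np.round(rel * params.molecules_per_design).astype(np.int64)
    return MoleculePopulation(counts=counts, cycle=0)


def simulate_pcr_cycle(
    population: MoleculePopulation,
    duplication_prob: np.ndarray | float,
    rng: np.random.Generator,
    resource_cap: Optional[float] = None,
) -> MoleculePopulation:
    """One PCR cycle: each molecule duplicates with probability ``p_i``.

    Near a resource cap the duplication probabilities are scaled down linearly
    so the expected total does not exceed the cap (plateau emulation).
    """
    p = np.broadcast_to(np.asarray(duplication_prob, dtype=float), population.counts.shape)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("duplication probabilities must be in (0, 1]")
    total = population.total
    if resource_cap is not None and total > 0:
        expected_new = float((population.counts * p).sum())
        headroom = max(resource_cap - total, 0.0)
        if expected_new > headroom:
            p = p * (headroom / expected_new)
            p = np.clip(p, 0.0, 1.0)
    new = rng.binomial(population.counts, p)
    return MoleculePopulation(counts=population.counts + new, cycle=population.cycle + 1)


def _multinomial_subsample(
    counts: np.ndarray, n_draw: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial sample of ``n_draw`` molecules proportional to ``counts``."""
    total = counts.sum()
    if total <= 0:
        raise RuntimeError("population went extinct during simulation")
    return rng.multinomial(n_draw, counts / total)


def normalize_columns(counts: np.ndarray) -> np.ndarray:
    """Divide each column by its mean over rows (the coverage normalisation)."""
    counts = np.asarray(counts, dtype=float)
    means = counts.mean(axis=0)
    if (means <= 0).any():
        raise ValueError("an experiment has zero total counts")
    return counts / means


def simulate_serial_protocol(
    pool: OligoPool | int,
    params: TwinParameters,
    relative_efficiency: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    ids: Sequence[str] | None = None,
) -> TwinRun:
    """Run the full dilute-amplify-sequence serial protocol.

    Returns read counts and mean-normalised coverage at cumulative cycle
    numbers ``j * cycles_per_iteration``.
    """
    n = pool if isinstance(pool, int) else len(pool)
    rng = np.random.default_rng(rng if rng is not None else params.seed)
    if ids is None:
        ids = pool.ids if isinstance(pool, OligoPool) else [f"SEQ_{i:05d}" for i in range(n)]

    if relative_efficiency is None:
        relative_efficiency = sample_relative_efficiencies(n, params, rng)
    eps = np.asarray(relative_efficiency, dtype=float)
    if eps.shape != (n,) or (eps <= 0).any():
        raise ValueError("relative_efficiency must be positive with one entry per design")

    # Per-cycle duplication probability realising the requested relative
    # per-cycle growth factor: g_i = eps_i * (1 + p_mean), p_i = g_i - 1.
    g = eps * (1.0 + params.absolute_efficiency_mean)
    p = np.clip(g - 1.0, 1e-6, 1.0)

    popn = simulate_synthesis(n, params, rng)
    initial_counts = popn.counts.copy()
    depth = int(round(params.reads_per_design * n))

    cycles = []
    reads = []
    for it in range(1, params.n_iterations + 1):
        if it > 1 and params.dilution_factor > 1.0:
            n_keep = min(int(round(popn.total / params.dilution_factor)), popn.total)
            if n_keep <= 0:
                raise RuntimeError("population went extinct during simulation")
            popn = MoleculePopulation(
                counts=_multinomial_subsample(popn.counts, n_keep, rng),
                cycle=popn.cycle,
            )
        for _ in range(params.cycles_per_iteration):
            popn = simulate_pcr_cycle(popn, p, rng, params.resource_cap)
        if popn.total <= 0:
            raise RuntimeError("population went extinct during simulation")
        reads.append(_multinomial_subsample(popn.counts, depth, rng))
        cycles.append(it * params.cycles_per_iteration)

    read_counts = np.stack(reads, axis=1)
    coverage = normalize_columns(read_counts)
    # True relative per-cycle factor actually simulated (after clipping).
    g_real = 1.0 + p
    return TwinRun(
        ids=list(ids),
        cycles=np.asarray(cycles),
        read_counts=read_counts,
        coverage=coverage,
        relative_efficiency=g_real / g_real.mean(),
        initial_counts=initial_counts,
    )


def noiseless_trajectory(
    x0: np.ndarray, eps: np.ndarray, cycles: Sequence[int]
) -> np.ndarray:
    """Exact model trajectory ``x_i(c) = x0_i * eps_i**c``, mean-normalised per
    cycle point.  Shape (N, M)."""
    x0 = np.asarray(x0, dtype=float)
    eps = np.asarray(eps, dtype=float)
    cycles = np.asarray(list(cycles))
    if cycles.size == 0:
        raise ValueError("cycles must be non-empty")
    if (eps <= 0).any():
        raise ValueError("eps must be positive")
    x = x0[:, None] * eps[:, None] ** cycles[None, :]
    return x / x.mean(axis=0, keepdims=True)
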