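"""Coalescent simulation of site frequency spectra.

Three samplers cover the recombination regimes:

* :func:`simulate_kingman_sfs` — a native Kingman-coalescent sampler for
  rho = 0.  The genealogy is built by repeated uniform pairwise merging with
  level times ``T_k ~ Exp(k(k-1)/2)``; mutations are Poisson-thinned onto the
  total branch length ancestral to exactly ``i`` leaves
  (``S_i ~ Poisson(theta * ell_i / 2)``), which is distributionally identical
  to per-site simulation under infinitely many sites.
* :func:`simulate_unlinked_sfs` — the free-recombination limit, where the SFS
  entries are independent with ``S_k ~ Poisson(theta / k)``.
* :func:`simulate_recomb_sfs` — intermediate recombination through an adapter
  to the msprime coalescent-with-recombination simulator.

The msprime adapter works in coalescent time units (haploid samples,
population size 1), so a target scaled mutation rate theta and scaled
recombination rate ``rho = 4 N_e r L`` translate into per-site rates
``theta / (2L)`` and ``rho / (2L)``.

Randomness follows one master seed; per-replicate streams are derived
deterministically via :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sfs import SFSDataset

__all__ = [
    "CoalescentParams",
    "RecombinationMap",
    "simulate_kingman_sfs",
    "simulate_unlinked_sfs",
    "simulate_recomb_sfs",
    "build_training_set",
    "build_stratified_set",
    "make_block_recomb_map",
    "SimulatorUnavailableError",
]

#: Scaled recombination rate used (as a label and, when simulated through the
#: adapter, as the rate) for the high-recombination component of composite
#: training sets.
HIGH_RHO = 1000.0


class SimulatorUnavailableError(RuntimeError):
    """The external coalescent-with-recombination simulator is missing.

    The adapter contract expects a library providing (i) ancestry simulation
    for ``n`` haploid samples over ``L`` sites with per-site recombination
    rate and seed, and (ii) infinite-sites mutation dropping at a per-site
    rate, returning a polarised allele-frequency spectrum (msprime/tskit
    fulfil it).
    """


@dataclass(frozen=True)
class CoalescentParams:
    """Parameters of one simulation condition.

    ``theta`` and ``rho`` are the population-scaled mutation and recombination
    rates of the whole simulated segment (``rho = 4 N_e r L``); ``rho = inf``
    denotes the unlinked-loci limit.  ``seq_length`` only matters when
    ``rho > 0``.
    """

    n: int
    theta: float
    rho: float = 0.0
    seq_length: float = 100_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2, got {self.n}")
        if self.theta < 0 or self.rho < 0:
            raise ValueError("theta and rho must be non-negative")


@dataclass
class RecombinationMap:
    """Piecewise-constant scaled recombination rate along a chromosome.

    ``breakpoints`` are strictly increasing 0-based positions delimiting
    half-open intervals ``[b_k, b_{k+1})``; ``rates`` holds one scaled rate
    per interval, expressed per base pair (so the scaled rho of an interval is
    ``rate * length``).
    """

    breakpoints: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.rates) != len(self.breakpoints) - 1:
            raise ValueError("need len(rates) == len(breakpoints) - 1")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def length(self) -> float:
        return float(self.breakpoints[-1] - self.breakpoints[0])

    def window_rho(self, start: float, end: float) -> float:
        """Total scaled rho accumulated over ``[start, end)``."""
        lo = np.maximum(self.breakpoints[:-1], start)
        hi = np.minimum(self.breakpoints[1:], end)
        return float(np.sum(self.rates * np.clip(hi - lo, 0.0, None)))

    def to_tsv(self, path) -> None:
        """Write as 3-column TSV: start, end, rate (0-based half-open)."""
        pd.DataFrame(
            {
                "start": self.breakpoints[:-1].astype(int),
                "end": self.breakpoints[1:].astype(int),
                "rate": self.rates,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RecombinationMap":
        df = pd.read_csv(path, sep="\t")
        if np.any(df["start"].to_numpy()[1:] != df["end"].to_numpy()[:-1]):
            raise ValueError("map intervals must be contiguous")
        breaks = np.append(df["start"].to_numpy(), df["end"].to_numpy()[-1])
        return cls(breaks, df["rate"].to_numpy())


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def kingman_branch_lengths(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Sample total branch lengths by leaf class under Kingman's coalescent.

    Returns an array of shape ``(reps, n - 1)`` whose column ``i-1`` holds the
    total length (coalescent units) of branches ancestral to exactly ``i`` of
    the ``n`` leaves, one genealogy per row.
    """
    counts = np.ones((reps, n), dtype=np.int64)
    ell = np.zeros(reps * (n - 1))
    rows = np.arange(reps)
    row_offset = rows * (n - 1)
    for k in range(n, 1, -1):
        t_k = rng.exponential(2.0 / (k * (k - 1)), size=reps)
        idx = (row_offset[:, None] + counts[:, :k] - 1).ravel()
        ell += np.bincount(idx, weights=np.repeat(t_k, k), minlength=ell.size)
        i = rng.integers(0, k, size=reps)
        j = rng.integers(0, k - 1, size=reps)
        j = np.where(j >= i, j + 1, j)
        counts[rows, i] += counts[rows, j]
        counts[rows, j] = counts[rows, k - 1]
    return ell.reshape(reps, n - 1)


def simulate_kingman_sfs(
    params: CoalescentParams,
    reps: int,
    theta: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SFSDataset:
    """Simulate SFS replicates under the Kingman coalescent (rho = 0).

    ``theta`` optionally supplies one mutation rate per replicate (overriding
    ``params.theta``).  Given ``S_i | ell_i ~ Poisson(theta * ell_i / 2)``,
    every entry has mean ``theta / i``.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    if params.rho != 0:
        raise ValueError("simulate_kingman_sfs requires rho = 0")
    rng = _rng_from(rng if rng is not None else params.seed)
    thetas = np.broadcast_to(
        params.theta if theta is None else np.asarray(theta, dtype=float), (reps,)
    )
    ell = kingman_branch_lengths(params.n, reps, rng)
    sfs = rng.poisson(0.5 * thetas[:, None] * ell)
    return SFSDataset(sfs, thetas, np.zeros(reps))


def simulate_unlinked_sfs(
    params: CoalescentParams,
    reps: int,
    theta: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SFSDataset:
    """Simulate SFS replicates in the unlinked-loci (free recombination) limit.

    Entries are independent, ``S_k ~ Poisson(theta / k)``; labelled
    ``rho = inf``.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    rng = _rng_from(rng if rng is not None else params.seed)
    thetas = np.broadcast_to(
        params.theta if theta is None else np.asarray(theta, dtype=float), (reps,)
    )
    k = np.arange(1, params.n)
    sfs = rng.poisson(thetas[:, None] / k[None, :])
    return SFSDataset(sfs, thetas, np.full(reps, np.inf))


def simulate_recomb_sfs(
    params: CoalescentParams,
    reps: int,
    rate_map: RecombinationMap | None = None,
    theta: np.ndarray | None = None,
    rho: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SFSDataset:
    """Simulate SFS replicates at positive recombination rates via msprime.

    Either a uniform scaled rate (``params.rho`` or the per-replicate ``rho``
    vector) over ``params.seq_length`` sites, or a :class:`RecombinationMap`,
    defines recombination.  Mutations follow the infinitely-many-sites
    approximation (continuous genome, infinite-alleles sites).
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    try:
        import msprime
    except ImportError as exc:  # pragma: no cover - msprime is a hard dep here
        raise SimulatorUnavailableError(SimulatorUnavailableError.__doc__) from exc

    rng = _rng_from(rng if rng is not None else params.seed)
    n = params.n
    length = params.seq_length if rate_map is None else rate_map.length
    thetas = np.broadcast_to(
        params.theta if theta is None else np.asarray(theta, dtype=float), (reps,)
    )
    rhos = np.broadcast_to(
        params.rho if rho is None else np.asarray(rho, dtype=float), (reps,)
    )
    if rate_map is not None:
        shift = rate_map.breakpoints[0]
        ms_map = msprime.RateMap(
            position=rate_map.breakpoints - shift, rate=rate_map.rates / 2.0
        )
        rho_labels = np.full(reps, rate_map.window_rho(
            rate_map.breakpoints[0], rate_map.breakpoints[-1]))
    else:
        rho_labels = rhos

    sfs = np.zeros((reps, n - 1), dtype=np.int64)
    seeds = rng.integers(1, 2**31 - 1, size=(reps, 2))
    for r in range(reps):
        recomb = ms_map if rate_map is not None else rhos[r] / (2.0 * length)
        ts = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=1.0,
            sequence_length=length if rate_map is None else None,
            recombination_rate=recomb,
            random_seed=int(seeds[r, 0]),
        )
        if thetas[r] > 0:
            ts = msprime.sim_mutations(
                ts,
                rate=thetas[r] / (2.0 * length),
                random_seed=int(seeds[r, 1]),
                discrete_genome=False,
            )
        afs = ts.allele_frequency_spectrum(polarised=True, span_normalise=False)
        sfs[r] = afs[1:n].astype(np.int64)
    return SFSDataset(sfs, thetas, rho_labels)


def build_training_set(
    n: int,
    theta_range: tuple[float, float] = (0.0, 100.0),
    rho_spec: float | tuple[float, float] | str = 0.0,
    size: int = 200_000,
    seed: int | None = None,
    seq_length: float = 100_000.0,
    high_rho_mode: str = "unlinked",
) -> SFSDataset:
    """Build a labelled training set of SFS replicates.

    ``rho_spec`` may be a fixed value (0 uses the native Kingman sampler,
    ``inf`` the unlinked sampler, anything else the msprime adapter), an
    interval ``(lo, hi)`` sampled uniformly per row, or ``"composite"``:
    equal thirds at rho = 0, high recombination, and rho ~ U(0, 50).  With the
    default ``high_rho_mode="unlinked"`` the high-recombination third is drawn
    from the free-recombination limit (labelled ``rho = inf``);
    ``high_rho_mode="msprime"`` simulates it at rho = 1000 instead.

    theta is drawn uniformly on ``theta_range`` per row.
    """
    if size < 1:
        raise ValueError("need size >= 1")
    lo, hi = theta_range
    if not hi > lo:
        raise ValueError(f"empty theta range {theta_range}")
    rng = np.random.default_rng(seed)

    if isinstance(rho_spec, str):
        if rho_spec != "composite":
            raise ValueError(f"unknown rho_spec {rho_spec!r}")
        part = size // 3
        sizes = [part, part, size - 2 * part]
        high = np.inf if high_rho_mode == "unlinked" else HIGH_RHO
        parts = [
            build_training_set(n, theta_range, 0.0, sizes[0], rng.integers(2**31)),
            build_training_set(n, theta_range, high, sizes[1],
                               rng.integers(2**31), seq_length, high_rho_mode),
            build_training_set(n, theta_range, (0.0, 50.0), sizes[2],
                               rng.integers(2**31), seq_length),
        ]
        return SFSDataset.concat(parts)

    thetas = rng.uniform(lo, hi, size=size)
    if isinstance(rho_spec, tuple):
        rhos = rng.uniform(rho_spec[0], rho_spec[1], size=size)
        params = CoalescentParams(n, 0.0, rho_spec[1], seq_length)
        return simulate_recomb_sfs(params, size, theta=thetas, rho=rhos, rng=rng)
    rho = float(rho_spec)
    if rho == 0.0:
        return simulate_kingman_sfs(CoalescentParams(n, 0.0), size, thetas, rng)
    if np.isinf(rho):
        return simulate_unlinked_sfs(CoalescentParams(n, 0.0), size, thetas, rng)
    params = CoalescentParams(n, 0.0, rho, seq_length)
    return simulate_recomb_sfs(params, size, theta=thetas, rng=rng)


def build_stratified_set(
    n: int,
    boundaries: np.ndarray,
    rho_spec: float | tuple[float, float] | str = "composite",
    rows_per_subset: int = 1500,
    seed: int | None = None,
    seq_length: float = 100_000.0,
) -> SFSDataset:
    """Build a validation set with equal rows in every theta subset.

    With theta uniform on (0, 100) the lowest subsets receive only a handful
    of rows, making per-subset error estimates noisy; drawing theta uniformly
    *within* each subset interval ``(t_{k-1}, t_k]`` equalizes the
    conditional sample sizes without biasing per-subset statistics.
    """
    rng = np.random.default_rng(seed)
    parts = [
        build_training_set(
            n, (float(lo), float(hi)), rho_spec, rows_per_subset,
            int(rng.integers(2**31)), seq_length,
        )
        for lo, hi in zip(boundaries[:-1], boundaries[1:])
    ]
    return SFSDataset.concat(parts)


def make_block_recomb_map(
    n_blocks: int,
    block_length: float = 70_000.0,
    rho_high: float = 5e-4,
    seed: int | None = None,
    jitter: float = 0.0,
) -> RecombinationMap:
    """Build an artificial block recombination map.

    Alternates ``n_blocks`` zero-recombination blocks with blocks of per-bp
    scaled rate ``rho_high`` (2 * n_blocks intervals in total, starting with a
    cold block).  With ``jitter > 0`` and a seed, block lengths are perturbed
    uniformly by up to ``jitter * block_length``.
    """
    if n_blocks < 1:
        raise ValueError("need n_blocks >= 1")
    if block_length <= 0:
        raise ValueError("block_length must be positive")
    if rho_high < 0:
        raise ValueError("rho_high must be non-negative")
    lengths = np.full(2 * n_blocks, float(block_length))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        lengths *= 1.0 + rng.uniform(-jitter, jitter, size=lengths.size)
    breakpoints = np.concatenate([[0.0], np.cumsum(np.round(lengths))])
    rates = np.zeros(2 * n_blocks)
    rates[1::2] = rho_high
    return RecombinationMap(breakpoints, rates)
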