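"""Serial coalescent simulation of microsatellite genotypes.

Temporal samples enter the genealogy at their generation offsets; lineages
coalesce backwards in time under a piecewise-constant diploid Ne trajectory
(continuous-time approximation, exact piecewise-exponential waiting times
across epoch boundaries).  Mutations follow the generalized stepwise model
(GSM): symmetric geometric multi-repeat steps with reflecting bounds over a
contiguous window of allele states (40 states by default), which degenerates
to the strict single-step SMM when the geometric parameter is zero.

Each locus is an independent genealogy; per-locus mutation rates are either
Gamma-distributed around a mean rate or shared.  Gene copies are paired at
random within each temporal sample to form diploid individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .io import GenotypeDataset, TemporalSample
from .scenarios import ParameterDraw, Trajectory, to_trajectory

__all__ = [
    "SampleConfig",
    "MutationModel",
    "Genealogy",
    "simulate_genealogy",
    "drop_mutations",
    "draw_locus_rates",
    "simulate_dataset",
    "dataset_summaries",
    "summary_names",
    "default_bounds",
]

#: half-width of the default reflecting allele-state window
_DEFAULT_HALF_WINDOW = 20


def default_bounds(founder: int) -> tuple[int, int]:
    """Default 40-state reflecting window centred on the founder allele."""
    lo = max(1, founder - _DEFAULT_HALF_WINDOW)
    return lo, lo + 2 * _DEFAULT_HALF_WINDOW - 1


@dataclass(frozen=True)
class SampleConfig:
    """Temporal sampling design: (generation offset, diploid count) pairs,
    oldest sample first, plus the locus count and founder allele size."""

    samples: tuple[tuple[int, int], ...]
    n_loci: int
    founder: int = 30

    def __post_init__(self):
        if not self.samples:
            raise ValueError("need at least one temporal sample")
        for off, nd in self.samples:
            if off < 0 or nd < 1:
                raise ValueError("offsets must be >= 0 and diploid counts >= 1")
        offs = [off for off, _ in self.samples]
        if len(offs) > 1 and any(np.diff(offs) >= 0):
            raise ValueError("samples must be ordered oldest first (strictly decreasing offsets)")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if self.founder < 1:
            raise ValueError("founder allele size must be positive")

    @property
    def offsets(self) -> np.ndarray:
        return np.array([off for off, _ in self.samples], dtype=float)

    @property
    def gene_copies(self) -> np.ndarray:
        return np.array([2 * nd for _, nd in self.samples], dtype=np.int64)

    @property
    def n_copies_total(self) -> int:
        return int(self.gene_copies.sum())


@dataclass(frozen=True)
class MutationModel:
    """GSM parameters for a single locus: rate, geometric step parameter,
    and the reflecting allele-state bounds."""

    mu: float
    gsm_p: float = 0.0
    lo: int = 10
    hi: int = 49

    def __post_init__(self):
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mutation rate must lie in [0, 1)")
        if not 0.0 <= self.gsm_p < 1.0:
            raise ValueError("GSM geometric parameter must lie in [0, 1)")
        if self.hi - self.lo < 1:
            raise ValueError("allele-state bounds must span at least 2 states")


@dataclass(frozen=True)
class Genealogy:
    """Array-encoded genealogy: ``parent[i]`` and ``time[i]`` (gbp) per node.

    Tips are nodes ``0..n_tips-1`` grouped by temporal sample;
    ``tip_sample[i]`` maps each tip to its sample index.  The root is the
    last node.  Every tip's time equals its sample's generation offset.
    """

    parent: np.ndarray
    time: np.ndarray
    tip_sample: np.ndarray
    n_tips: int

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    @property
    def total_branch_length(self) -> float:
        nonroot = np.arange(len(self.parent) - 1)
        return float(np.sum(self.time[self.parent[nonroot]] - self.time[nonroot]))


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_genealogy(
    trajectory: Trajectory, sample_config: SampleConfig, rng: np.random.Generator
) -> Genealogy:
    """Simulate one serial-coalescent genealogy for all gene copies."""
    n = sample_config.n_copies_total
    if n < 2:
        raise ValueError("need at least two gene copies to coalesce")
    parent = np.empty(2 * n - 1, dtype=np.int64)
    node_time = np.empty(2 * n - 1, dtype=np.float64)
    _kernels.k_sim_tree(
        _kernel_seed(rng),
        sample_config.offsets,
        sample_config.gene_copies,
        np.asarray(trajectory.breaks, dtype=float),
        np.asarray(trajectory.sizes, dtype=float),
        parent,
        node_time,
    )
    tip_sample = np.repeat(
        np.arange(len(sample_config.samples)), sample_config.gene_copies
    )
    return Genealogy(parent=parent, time=node_time, tip_sample=tip_sample, n_tips=n)


def drop_mutations(
    tree: Genealogy,
    model: MutationModel,
    founder: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop GSM mutations on a genealogy; returns tip allele sizes."""
    if not model.lo <= founder <= model.hi:
        raise ValueError("founder allele outside the state bounds")
    alleles = np.empty(tree.n_tips, dtype=np.int64)
    _kernels.k_drop_mutations(
        _kernel_seed(rng), tree.parent, tree.time, tree.n_tips,
        float(model.mu), float(model.gsm_p), founder, model.lo, model.hi,
        alleles,
    )
    return alleles


def draw_locus_rates(
    mu_mean: float, n_loci: int, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-locus mutation rates, Gamma with mean ``mu_mean`` and the given
    shape; an infinite shape means every locus shares the mean rate."""
    if mu_mean <= 0:
        raise ValueError("mean mutation rate must be positive")
    if not np.isfinite(shape):
        return np.full(n_loci, mu_mean, dtype=float)
    if shape <= 0:
        raise ValueError("Gamma shape must be positive")
    rates = rng.gamma(shape, mu_mean / shape, size=n_loci)
    # a zero rate is harmless but keep rates strictly positive for sanity
    return np.maximum(rates, 1e-12)


def _resolve_rates(draw: ParameterDraw, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    if draw.locus_rates is not None:
        if len(draw.locus_rates) != n_loci:
            raise ValueError("draw carries locus rates for a different locus count")
        return np.asarray(draw.locus_rates, dtype=float)
    return np.full(n_loci, draw.mu_mean, dtype=float)


def simulate_dataset(
    draw: ParameterDraw,
    sample_config: SampleConfig,
    rng: np.random.Generator,
    loci: list[str] | None = None,
) -> GenotypeDataset:
    """Simulate a full temporally sampled microsatellite dataset.

    Independent genealogy and mutations per locus; gene copies are paired
    at random within each temporal sample into diploid individuals.
    """
    nl = sample_config.n_loci
    loci = loci or [f"L{k + 1:02d}" for k in range(nl)]
    rates = _resolve_rates(draw, nl, rng)
    lo, hi = default_bounds(sample_config.founder)
    traj = to_trajectory(draw)
    n = sample_config.n_copies_total
    locus_seeds = rng.integers(1, 2**31 - 1, size=nl)
    parent = np.empty(2 * n - 1, dtype=np.int64)
    node_time = np.empty(2 * n - 1, dtype=np.float64)
    buf = np.empty(n, dtype=np.int64)
    alleles = np.empty((nl, n), dtype=np.int64)
    for l in range(nl):
        _kernels.k_sim_locus(
            int(locus_seeds[l]), sample_config.offsets,
            sample_config.gene_copies,
            np.asarray(traj.breaks, dtype=float),
            np.asarray(traj.sizes, dtype=float),
            float(rates[l]), float(draw.gsm_p), sample_config.founder,
            lo, hi, parent, node_time, buf,
        )
        alleles[l] = buf
    samples = []
    start = 0
    for si, (off, nd) in enumerate(sample_config.samples):
        stop = start + 2 * nd
        # gene copies are exchangeable; an explicit shuffle realizes random
        # union of gametes within the sample
        perm = rng.permutation(stop - start) + start
        block = alleles[:, perm].T.reshape(nd, 2, nl).transpose(0, 2, 1)
        samples.append(
            TemporalSample(
                label=f"t{si}",
                genotypes=block.astype(np.int32),
                generation_offset=int(off),
            )
        )
        start = stop
    return GenotypeDataset(loci=list(loci), samples=samples)


def summary_names(sample_config: SampleConfig) -> tuple[str, ...]:
    """Statistic names of the fast-path summary vector, matching
    :func:`serialabc.stats.summary_vector` on an exported dataset."""
    from .stats import DEFAULT_STATISTICS

    names = [
        f"{stat}_s{si}"
        for si in range(len(sample_config.samples))
        for stat in DEFAULT_STATISTICS
    ]
    if len(sample_config.samples) >= 2:
        names.append(f"fst_s0_s{len(sample_config.samples) - 1}")
    return tuple(names)


def dataset_summaries(
    draw: ParameterDraw, sample_config: SampleConfig, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one dataset and return its summary vector without
    materializing genotypes (the reference-table fast path).

    Consumes the caller's RNG exactly like :func:`simulate_dataset` does for
    the per-locus seeds, so the same generator state yields the summaries of
    the same simulated alleles.
    """
    nl = sample_config.n_loci
    rates = _resolve_rates(draw, nl, rng)
    lo, hi = default_bounds(sample_config.founder)
    traj = to_trajectory(draw)
    ns = len(sample_config.samples)
    out = np.empty(4 * ns + (1 if ns >= 2 else 0), dtype=float)
    locus_seeds = rng.integers(1, 2**31 - 1, size=nl)
    _kernels.k_dataset_summaries(
        locus_seeds.astype(np.int64), sample_config.offsets,
        sample_config.gene_copies,
        np.asarray(traj.breaks, dtype=float),
        np.asarray(traj.sizes, dtype=float),
        rates, float(draw.gsm_p), sample_config.founder, lo, hi, out,
    )
    return out
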