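"""Within- and between-sample microsatellite summary statistics.

These serve two purposes: descriptive temporal-trend tables (expected
heterozygosity, rarefied allelic richness, effective allele number, with
paired t-tests between time points) and the summary vector compared between
observed and simulated data in the ABC analysis.

Per-locus statistics operate on :class:`AlleleCounts` (gene-copy counts per
allele size); missing genotypes are excluded locus by locus (pairwise
deletion), so ``n_copies`` varies across loci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import MISSING, GenotypeDataset

__all__ = [
    "AlleleCounts",
    "SummaryVector",
    "allele_counts",
    "unbiased_heterozygosity",
    "effective_alleles",
    "rarefied_allelic_richness",
    "allele_size_variance",
    "m_index",
    "pairwise_fst",
    "paired_t_test",
    "summary_vector",
    "trend_report",
    "DEFAULT_STATISTICS",
]

#: one-sample statistics computed per temporal sample (locus-averaged), in
#: fixed order; "fst" is the between-sample statistic (earliest vs latest).
DEFAULT_STATISTICS = ("het", "n_alleles", "size_var", "m_index")


@dataclass(frozen=True)
class AlleleCounts:
    """Observed gene-copy counts per allele size at one locus in one sample."""

    locus: str
    counts: Mapping[int, int]

    @property
    def n_copies(self) -> int:
        return int(sum(self.counts.values()))

    def frequencies(self) -> np.ndarray:
        n = self.n_copies
        if n == 0:
            raise ValueError(f"locus {self.locus!r}: no observed gene copies")
        return np.array(list(self.counts.values()), dtype=float) / n


@dataclass(frozen=True)
class SummaryVector:
    """Named, ordered vector of summary statistics."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("summary vector contains non-finite entries")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def allele_counts(dataset: GenotypeDataset, sample_idx: int, locus_idx: int) -> AlleleCounts:
    """Tabulate gene-copy counts for one locus in one temporal sample."""
    g = dataset.samples[sample_idx].genotypes[:, locus_idx, :].ravel()
    g = g[g != MISSING]
    sizes, cnt = np.unique(g, return_counts=True)
    return AlleleCounts(
        locus=dataset.loci[locus_idx],
        counts={int(s): int(c) for s, c in zip(sizes, cnt)},
    )


def unbiased_heterozygosity(counts: AlleleCounts) -> float:
    """Nei's unbiased expected heterozygosity, (n/(n-1)) (1 - sum p_i^2)."""
    n = counts.n_copies
    if n < 2:
        raise ValueError(
            f"locus {counts.locus!r}: heterozygosity undefined for n_copies={n}"
        )
    p = counts.frequencies()
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def effective_alleles(counts: AlleleCounts) -> float:
    """Effective number of alleles, 1 / sum p_i^2."""
    p = counts.frequencies()
    return float(1.0 / np.sum(p**2))


def rarefied_allelic_richness(counts: AlleleCounts, g: int) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    Hypergeometric rarefaction: sum over alleles of
    ``1 - C(n - c_i, g) / C(n, g)``.  Equals the observed allele count at
    ``g = n_copies``.
    """
    n = counts.n_copies
    if not 2 <= g <= n:
        raise ValueError(
            f"locus {counts.locus!r}: rarefaction size g={g} outside [2, {n}]"
        )
    denom = math.comb(n, g)
    total = 0.0
    for c in counts.counts.values():
        total += 1.0 - math.comb(n - c, g) / denom
    return total


def allele_size_variance(counts: AlleleCounts) -> float:
    """Unbiased variance of allele size over gene copies."""
    n = counts.n_copies
    if n < 2:
        raise ValueError(
            f"locus {counts.locus!r}: variance undefined for n_copies={n}"
        )
    sizes = np.repeat(
        np.fromiter(counts.counts.keys(), dtype=float),
        np.fromiter(counts.counts.values(), dtype=int),
    )
    return float(np.var(sizes, ddof=1))


def m_index(counts: AlleleCounts) -> float:
    """Garza–Williamson M: observed allele count over (size range + 1).

    Drops below 1 when a bottleneck thins intermediate allele sizes faster
    than it contracts the size range.
    """
    if counts.n_copies < 1:
        raise ValueError(f"locus {counts.locus!r}: no observed gene copies")
    sizes = np.fromiter(counts.counts.keys(), dtype=int)
    return float(len(sizes) / (sizes.max() - sizes.min() + 1))


def _wc_components(c1: AlleleCounts, c2: AlleleCounts):
    """Per-locus Weir–Cockerham numerator/denominator sums over alleles.

    Gene copies are treated as the sampling unit (allele-frequency form of
    the theta estimator for r = 2 samples); components are summed over
    alleles, then over loci, and the ratio of sums is reported.
    """
    n1, n2 = c1.n_copies, c2.n_copies
    alleles = sorted(set(c1.counts) | set(c2.counts))
    if len(alleles) < 2 or n1 < 2 or n2 < 2:
        return 0.0, 0.0
    n_t = n1 + n2
    n_c = (n_t - (n1 * n1 + n2 * n2) / n_t) / 1.0  # r - 1 = 1
    num = den = 0.0
    for a in alleles:
        p1 = c1.counts.get(a, 0) / n1
        p2 = c2.counts.get(a, 0) / n2
        pbar = (n1 * p1 + n2 * p2) / n_t
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_t - 2)
        num += msp - msg
        den += msp + (n_c - 1) * msg
    return num, den


def pairwise_fst(
    sample_a: Sequence[AlleleCounts], sample_b: Sequence[AlleleCounts]
) -> float:
    """Multi-locus Weir–Cockerham theta between two temporal samples.

    Ratio-of-sums over loci and alleles; may be slightly negative when the
    samples are effectively undifferentiated.
    """
    if len(sample_a) != len(sample_b):
        raise ValueError("the two samples must cover the same loci")
    num = den = 0.0
    for ca, cb in zip(sample_a, sample_b):
        a, b = _wc_components(ca, cb)
        num += a
        den += b
    if den == 0.0:
        raise ValueError("no usable polymorphic locus shared by the samples")
    return num / den


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired t-test P value on per-locus differences.

    Degenerate inputs are made total: all-zero differences give P = 1; zero
    variance of differences with a nonzero mean gives P = 0 (with a warning),
    as the t statistic diverges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 2:
        raise ValueError("paired t-test needs at least two loci")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 1.0
        warnings.warn(
            "paired t-test degenerate: constant nonzero difference", stacklevel=2
        )
        return 0.0
    return float(sps.ttest_rel(x, y).pvalue)


def _sample_counts(dataset: GenotypeDataset, si: int) -> list[AlleleCounts]:
    return [allele_counts(dataset, si, li) for li in range(dataset.n_loci)]


def _one_sample_stats(counts: Sequence[AlleleCounts]) -> dict[str, float]:
    """Locus-averaged one-sample statistics; monomorphic loci contribute
    H=0, one allele, zero variance, M=1 (the map must be total because
    simulated loci can be monomorphic)."""
    het, na, var, m = [], [], [], []
    for c in counts:
        n = c.n_copies
        if n < 2:
            continue
        het.append(unbiased_heterozygosity(c))
        na.append(float(len(c.counts)))
        var.append(allele_size_variance(c))
        m.append(m_index(c))
    if not het:
        raise ValueError("no locus with at least two gene copies")
    return {
        "het": float(np.mean(het)),
        "n_alleles": float(np.mean(na)),
        "size_var": float(np.mean(var)),
        "m_index": float(np.mean(m)),
    }


def summary_vector(
    dataset: GenotypeDataset,
    statistics: Sequence[str] = DEFAULT_STATISTICS,
    pairs: str = "extremes",
) -> SummaryVector:
    """ABC summary vector: per-sample locus means plus temporal F_ST.

    One-sample block per temporal sample, in dataset order; then Weir–
    Cockerham F_ST for each requested ordered sample pair (default the
    earliest vs latest pair only; ``pairs="all"`` adds every ordered pair).
    """
    if not dataset.samples or not dataset.loci:
        raise ValueError("dataset must have at least one sample and one locus")
    unknown = set(statistics) - set(DEFAULT_STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics requested: {sorted(unknown)}")
    names: list[str] = []
    values: list[float] = []
    per_sample = [_sample_counts(dataset, si) for si in range(len(dataset.samples))]
    for si, counts in enumerate(per_sample):
        one = _one_sample_stats(counts)
        for stat in statistics:
            names.append(f"{stat}_s{si}")
            values.append(one[stat])
    if len(dataset.samples) >= 2:
        if pairs == "extremes":
            pair_idx = [(0, len(dataset.samples) - 1)]
        elif pairs == "all":
            k = len(dataset.samples)
            pair_idx = [(i, j) for i in range(k) for j in range(i + 1, k)]
        else:
            raise ValueError(f"unknown pair mode {pairs!r}")
        for i, j in pair_idx:
            names.append(f"fst_s{i}_s{j}")
            try:
                theta = pairwise_fst(per_sample[i], per_sample[j])
            except ValueError:
                theta = 0.0  # undifferentiated monomorphic pair
            values.append(theta)
    return SummaryVector(names=tuple(names), values=np.array(values))


def trend_report(dataset: GenotypeDataset, rarefy_g: int | None = None):
    """Temporal-trend table: per time point mean H_E, A_R, A_e with standard
    errors across loci, and paired-t P values comparing each later time point
    with the earliest one (the P_(EL) convention).

    ``rarefy_g`` defaults to the smallest per-locus gene-copy count across
    all time points (standard rarefaction practice), floored at 2.
    """
    import pandas as pd

    per_sample = [_sample_counts(dataset, si) for si in range(len(dataset.samples))]
    if rarefy_g is None:
        rarefy_g = max(
            2, min(c.n_copies for counts in per_sample for c in counts)
        )
    he = []  # per sample: per-locus H_E
    ar = []
    ae = []
    for counts in per_sample:
        he.append([unbiased_heterozygosity(c) for c in counts if c.n_copies >= 2])
        ar.append(
            [
                rarefied_allelic_richness(c, min(rarefy_g, c.n_copies))
                for c in counts
                if c.n_copies >= 2
            ]
        )
        ae.append([effective_alleles(c) for c in counts if c.n_copies >= 1])
    rows = []
    for si, s in enumerate(dataset.samples):
        date = (
            f"{s.collection_date[0]}-{s.collection_date[1]:02d}"
            if s.collection_date
            else s.label
        )
        row = {
            "Year": date,
            "N": s.n_individuals,
            "HEXP": np.mean(he[si]),
            "SE_HEXP": sps.sem(he[si]),
            "P_EL_HEXP": np.nan,
            "A_R": np.mean(ar[si]),
            "SE_AR": sps.sem(ar[si]),
            "P_EL_AR": np.nan,
            "A_e": np.mean(ae[si]),
        }
        if si > 0 and len(he[si]) == len(he[0]):
            row["P_EL_HEXP"] = paired_t_test(he[0], he[si])
            row["P_EL_AR"] = paired_t_test(ar[0], ar[si])
        rows.append(row)
    return pd.DataFrame(rows)
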