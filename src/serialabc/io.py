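"""Reading and writing temporally structured microsatellite genotype data.

Genotypes travel in GenePop text files in which each ``POP`` block is one
temporal sample of a single population.  Calendar metadata (collection
year/month per sample) is attached separately and converted to generation
offsets ("generations before present", gbp) assuming a fixed number of
mosquito generations per calendar year.

Internally alleles are repeat-number integers; ``MISSING`` (-1) flags a
failed call.  Zero-coded GenePop alleles become ``MISSING`` on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "TemporalSample",
    "GenotypeDataset",
    "StudyConfig",
    "GenePopParseError",
    "read_genepop",
    "write_genepop",
    "assign_generations",
]

MISSING = -1

_POP_MARKERS = {"pop"}


class GenePopParseError(ValueError):
    """Raised when a GenePop file violates the dialect; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(eq=False)
class TemporalSample:
    """One temporal sample: a block of diploid individuals collected together.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)`` with allele sizes in
    repeat units and ``MISSING`` for failed calls.  ``generation_offset`` is in
    generations before the most recent sample (0 for the most recent).
    """

    label: str
    genotypes: np.ndarray
    collection_date: tuple[int, int] | None = None  # (year, month)
    generation_offset: int | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, TemporalSample):
            return NotImplemented
        return (
            self.label == other.label
            and self.collection_date == other.collection_date
            and self.generation_offset == other.generation_offset
            and self.genotypes.shape == other.genotypes.shape
            and bool(np.array_equal(self.genotypes, other.genotypes))
        )


@dataclass(eq=False)
class GenotypeDataset:
    """Diploid microsatellite genotypes partitioned into temporal samples."""

    loci: list[str]
    samples: list[TemporalSample]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return sum(s.n_individuals for s in self.samples)

    def validate(self) -> None:
        for s in self.samples:
            g = np.asarray(s.genotypes)
            if g.ndim != 3 or g.shape[1] != self.n_loci or g.shape[2] != 2:
                raise ValueError(
                    f"sample {s.label!r}: genotype array shape {g.shape} does "
                    f"not match {self.n_loci} loci"
                )
            observed = g[g != MISSING]
            if observed.size and observed.min() <= 0:
                raise ValueError(
                    f"sample {s.label!r}: allele sizes must be positive integers"
                )
        offsets = [s.generation_offset for s in self.samples]
        if all(o is not None for o in offsets) and offsets:
            if min(offsets) != 0:
                raise ValueError("the most recent sample must have offset 0")
            if any(o < 0 for o in offsets):
                raise ValueError("generation offsets must be >= 0")

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return self.loci == other.loci and self.samples == other.samples


@dataclass(frozen=True)
class StudyConfig:
    """Study-level settings mapping calendar time onto mosquito generations.

    24 generations per calendar year is the conventional figure for tropical
    *Anopheles* populations breeding year-round.
    """

    generations_per_year: float = 24.0
    intervention_start_date: tuple[int, int] | None = None
    exclude_loci: tuple[str, ...] = ()

    def __post_init__(self):
        if self.generations_per_year <= 0:
            raise ValueError("generations_per_year must be > 0")


def _tokenize_genotypes(parts: Sequence[str], lineno: int) -> list[str]:
    toks = []
    for p in parts:
        p = p.strip()
        if p:
            toks.append(p)
    return toks


def read_genepop(path) -> GenotypeDataset:
    """Parse a GenePop file; each POP block becomes a :class:`TemporalSample`.

    Accepts 2- or 3-digit allele coding (inferred from the first genotype
    token); all-zero alleles are missing calls.  Individual identifiers are
    kept only as the sample label (the identifier of the first individual of
    each block, a common GenePop convention).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenePopParseError("empty file", 1)

    # header: title line, then locus names (one per line, or comma-separated)
    loci: list[str] = []
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if line.lower() in _POP_MARKERS:
            break
        if line:
            if "," in line:
                loci.extend(x.strip() for x in line.split(",") if x.strip())
            else:
                loci.append(line)
        i += 1
    if i == len(lines):
        raise GenePopParseError("no POP block found", len(lines))
    if not loci:
        raise GenePopParseError("no locus names before first POP", i + 1)

    samples: list[TemporalSample] = []
    width: int | None = None
    cur_rows: list[np.ndarray] = []
    cur_label: str | None = None
    pop_line = i + 1

    def flush(lineno: int):
        nonlocal cur_rows, cur_label
        if cur_label is None:
            return
        if not cur_rows:
            raise GenePopParseError("empty POP block", lineno)
        samples.append(
            TemporalSample(label=cur_label, genotypes=np.stack(cur_rows))
        )
        cur_rows = []
        cur_label = None

    for j in range(i, len(lines)):
        raw = lines[j]
        line = raw.strip()
        lineno = j + 1
        if not line:
            continue
        if line.lower() in _POP_MARKERS:
            flush(lineno)
            pop_line = lineno
            cur_rows = []
            cur_label = ""  # open block awaiting its first row
            continue
        if cur_label is None:
            raise GenePopParseError("genotype row outside POP block", lineno)
        if "," not in line:
            raise GenePopParseError(
                "expected 'identifier , genotypes' row", lineno
            )
        ident, _, geno = line.partition(",")
        ident = ident.strip()
        if cur_label == "":
            cur_label = ident or f"pop{len(samples) + 1}"
        toks = _tokenize_genotypes(geno.split(), lineno)
        if len(toks) != len(loci):
            raise GenePopParseError(
                f"expected {len(loci)} genotypes, found {len(toks)}", lineno
            )
        row = np.empty((len(loci), 2), dtype=np.int32)
        for k, tok in enumerate(toks):
            if not tok.isdigit():
                raise GenePopParseError(f"non-numeric genotype {tok!r}", lineno)
            if width is None:
                if len(tok) not in (4, 6):
                    raise GenePopParseError(
                        f"genotype {tok!r} is neither 2- nor 3-digit coded",
                        lineno,
                    )
                width = len(tok) // 2
            if len(tok) != 2 * width:
                raise GenePopParseError(
                    f"genotype {tok!r} inconsistent with {width}-digit coding",
                    lineno,
                )
            a, b = int(tok[:width]), int(tok[width:])
            row[k, 0] = a if a != 0 else MISSING
            row[k, 1] = b if b != 0 else MISSING
        cur_rows.append(row)
    flush(len(lines))
    if not samples:
        raise GenePopParseError("empty POP block", pop_line)

    ds = GenotypeDataset(loci=loci, samples=samples)
    ds.validate()
    return ds


def write_genepop(dataset: GenotypeDataset, path, title: str = "serialabc export") -> None:
    """Write a dataset as GenePop text; re-parses to an equal dataset.

    The allele digit width (2 or 3) is chosen from the largest allele; sizes
    above 999 do not fit the dialect and are refused.
    """
    if not dataset.samples or not dataset.loci:
        raise ValueError("cannot write an empty dataset (no samples or no loci)")
    dataset.validate()
    max_allele = 0
    for s in dataset.samples:
        observed = s.genotypes[s.genotypes != MISSING]
        if observed.size:
            max_allele = max(max_allele, int(observed.max()))
    if max_allele > 999:
        raise ValueError(
            f"allele size {max_allele} exceeds the 3-digit GenePop width"
        )
    width = 2 if max_allele <= 99 else 3
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in dataset.loci:
            fh.write(locus + "\n")
        for s in dataset.samples:
            fh.write("POP\n")
            for ind in range(s.n_individuals):
                codes = []
                for k in range(dataset.n_loci):
                    a, b = s.genotypes[ind, k]
                    a = 0 if a == MISSING else int(a)
                    b = 0 if b == MISSING else int(b)
                    codes.append(f"{a:0{width}d}{b:0{width}d}")
                fh.write(f"{s.label} , " + " ".join(codes) + "\n")


def _fractional_year(date: tuple[int, int]) -> float:
    year, month = date
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in date {date}")
    return year + (month - 1) / 12.0


def assign_generations(
    dataset: GenotypeDataset, config: StudyConfig | None = None
) -> GenotypeDataset:
    """Attach generation offsets (gbp) computed from collection dates.

    The offset of each sample is ``round(generations_per_year * years before
    the most recent sample)``; the most recent sample gets offset 0.  Dates
    carry month resolution, so offsets are computed on fractional years and
    rounded to the nearest integer generation.
    """
    config = config or StudyConfig()
    for s in dataset.samples:
        if s.collection_date is None:
            raise ValueError(f"sample {s.label!r} has no collection date")
    frac = [_fractional_year(s.collection_date) for s in dataset.samples]
    latest = max(frac)
    new_samples = [
        dataclasses.replace(
            s,
            generation_offset=int(
                round(config.generations_per_year * (latest - f))
            ),
        )
        for s, f in zip(dataset.samples, frac)
    ]
    out = GenotypeDataset(loci=list(dataset.loci), samples=new_samples)
    out.validate()
    return out
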