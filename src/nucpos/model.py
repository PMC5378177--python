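"""Shared domain containers for the nucleosome-positioning pipeline.

Coordinate convention: everything internal is 0-based, half-open
``[start, end)``. 1-based closed coordinates (GFF3, SAM POS) exist only at
the parse/serialize boundary in :mod:`nucpos.genome_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterator, Mapping

import numpy as np

__all__ = [
    "Anchor",
    "FragmentRecord",
    "FragmentSet",
    "GeneModel",
    "GeneSet",
    "DyadTrack",
    "AlignedProfile",
]


class Anchor(str, Enum):
    """Alignment anchor for gene-oriented profiles."""

    ATG = "ATG"
    STOP = "STOP"
    PLUS_ONE = "PLUS_ONE"


@dataclass(frozen=True)
class FragmentRecord:
    """One MNase-protected fragment inferred from a properly paired read pair.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    end-to-end span of the pair (SAM ISIZE).
    """

    chrom: str
    start: int
    end: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """Column-oriented fragment container for a single reference sequence.

    Behaves as an iterable of :class:`FragmentRecord` but keeps coordinates
    in numpy arrays so dyad binning and size selection stay vectorized.
    """

    def __init__(self, chrom: str, starts, ends, sample_id: str = "") -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have identical shape")
        if np.any(ends <= starts):
            raise ValueError("all fragments must satisfy end > start")
        self.chrom = chrom
        self.starts = starts
        self.ends = ends
        self.sample_id = sample_id

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self) -> Iterator[FragmentRecord]:
        for s, e in zip(self.starts.tolist(), self.ends.tolist()):
            yield FragmentRecord(self.chrom, s, e, self.sample_id)

    def filter_length(self, lo: int, hi: int) -> "FragmentSet":
        keep = (self.lengths >= lo) & (self.lengths <= hi)
        return FragmentSet(self.chrom, self.starts[keep], self.ends[keep], self.sample_id)

    @staticmethod
    def concat(sets: list["FragmentSet"]) -> "FragmentSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        chroms = {s.chrom for s in sets}
        if len(chroms) != 1:
            raise ValueError("FragmentSet.concat requires a single chromosome")
        return FragmentSet(
            sets[0].chrom,
            np.concatenate([s.starts for s in sets]),
            np.concatenate([s.ends for s in sets]),
            sets[0].sample_id,
        )


@dataclass(frozen=True)
class GeneModel:
    """Protein-coding gene anchor coordinates.

    ``atg`` is the 0-based position of the first base of the start codon,
    ``stop`` the 0-based position of the last base of the stop codon. For a
    minus-strand gene ``atg > stop``.
    """

    gene_id: str
    chrom: str
    strand: str
    atg: int
    stop: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and not self.atg < self.stop:
            raise ValueError(f"{self.gene_id}: + strand requires atg < stop")
        if self.strand == "-" and not self.atg > self.stop:
            raise ValueError(f"{self.gene_id}: - strand requires atg > stop")

    @property
    def length(self) -> int:
        """Coding-span length in bp (ATG through stop, inclusive)."""
        return abs(self.stop - self.atg) + 1

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open genomic interval covered by the coding span."""
        lo = min(self.atg, self.stop)
        return lo, lo + self.length


@dataclass(frozen=True)
class GeneSet:
    label: str
    gene_ids: frozenset

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class DyadTrack:
    """Per-base dyad-midpoint counts (1-bp bins), one vector per chromosome.

    ``counts`` arrays may be floats when the track has been transformed
    (e.g. footprint-extended occupancy); raw dyad tracks are integral.
    """

    counts: Dict[str, np.ndarray]
    sample_id: str = ""

    def __post_init__(self) -> None:
        for chrom, v in self.counts.items():
            v = np.asarray(v)
            if v.ndim != 1:
                raise ValueError(f"{chrom}: track vector must be 1-D")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: dyad counts must be non-negative")
            self.counts[chrom] = v

    @property
    def total_dyads(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def chrom_length(self, chrom: str) -> int:
        return int(self.counts[chrom].size)

    def __add__(self, other: "DyadTrack") -> "DyadTrack":
        if set(self.counts) != set(other.counts):
            raise ValueError("tracks cover different chromosome sets")
        return DyadTrack(
            {c: self.counts[c] + other.counts[c] for c in self.counts},
            sample_id=f"{self.sample_id}+{other.sample_id}",
        )


@dataclass
class AlignedProfile:
    """Gene-strand-oriented signal over a fixed offset window around an anchor.

    Offsets run ``lo..hi`` inclusive with downstream of the gene positive.
    ``values[i]`` is the signal at offset ``lo + i``; ``mask[i]`` flags bins
    that fall inside the reference sequence (aggregates: bins with >=1
    contributing gene).
    """

    anchor: Anchor
    lo: int
    hi: int
    values: np.ndarray
    mask: np.ndarray
    n_genes: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.hi - self.lo + 1
        if self.values.shape != (n,) or self.mask.shape != (n,):
            raise ValueError("values/mask length must equal hi - lo + 1")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("profile has non-finite values inside the mask")

    @property
    def window(self) -> tuple[int, int]:
        return self.lo, self.hi

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def index(self, offset: int) -> int:
        if not self.lo <= offset <= self.hi:
            raise IndexError(f"offset {offset} outside window [{self.lo}, {self.hi}]")
        return offset - self.lo

    def value_at(self, offset: int) -> float:
        return float(self.values[self.index(offset)])

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "AlignedProfile":
        return AlignedProfile(
            anchor=self.anchor,
            lo=self.lo,
            hi=self.hi,
            values=values,
            mask=self.mask.copy() if mask is None else mask,
            n_genes=self.n_genes,
        )
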