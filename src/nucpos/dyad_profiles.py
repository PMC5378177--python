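"""Fragments -> dyad tracks -> gene-anchored normalized profiles.

Dyad midpoints of size-selected (150 +- 30 bp) MNase-protected fragments are
binned at 1 bp; per-gene windows are cut around the ATG, the stop codon, or
the +1 nucleosome in gene-strand orientation (downstream positive), averaged
across genes, and normalized to the window mean. A naked-DNA control divides
out sequence/mappability structure (CHR/DNA ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .model import AlignedProfile, Anchor, DyadTrack, FragmentRecord, FragmentSet, GeneModel

log = logging.getLogger(__name__)

__all__ = [
    "SizeFilter",
    "select_nucleosomal",
    "dyads_from_fragments",
    "occupancy_from_dyads",
    "gene_profile",
    "aggregate_profiles",
    "normalize_profile",
    "chr_dna_ratio",
    "at_content_track",
]

NUCLEOSOME_FOOTPRINT = 147  # bp of DNA in core-particle contact


@dataclass(frozen=True)
class SizeFilter:
    """Inclusive fragment-length window, default 150 +- 30 bp (120..180)."""

    center: int = 150
    halfwidth: int = 30

    def __post_init__(self) -> None:
        if self.halfwidth < 0:
            raise ValueError("halfwidth must be >= 0")

    @property
    def lo(self) -> int:
        return self.center - self.halfwidth

    @property
    def hi(self) -> int:
        return self.center + self.halfwidth

    def accepts(self, length: int) -> bool:
        return self.lo <= length <= self.hi


def select_nucleosomal(
    fragments: Iterable[FragmentRecord] | FragmentSet,
    size_filter: SizeFilter = SizeFilter(),
):
    """Keep fragments whose span length falls inside the size window."""
    if isinstance(fragments, FragmentSet):
        return fragments.filter_length(size_filter.lo, size_filter.hi)

    def _gen() -> Iterator[FragmentRecord]:
        for f in fragments:
            if size_filter.accepts(f.length):
                yield f

    return _gen()


def dyads_from_fragments(
    fragments: Iterable[FragmentRecord] | FragmentSet,
    chrom_sizes: Mapping[str, int],
    sample_id: str = "",
) -> DyadTrack:
    """Bin fragment midpoints (putative dyads) into per-base counts.

    The dyad of ``[start, end)`` is ``floor((start + end - 1) / 2)`` — the
    midpoint of the closed base interval, rounded down for even lengths.
    Fragments off known chromosomes or out of bounds are skipped and logged.
    """
    counts = {c: np.zeros(int(n), dtype=np.int64) for c, n in chrom_sizes.items()}
    skipped = 0
    if isinstance(fragments, FragmentSet):
        if fragments.chrom not in counts:
            raise ValueError(f"unknown chromosome {fragments.chrom!r}")
        size = chrom_sizes[fragments.chrom]
        mids = (fragments.starts + fragments.ends - 1) // 2
        ok = (fragments.starts >= 0) & (fragments.ends <= size)
        skipped = int((~ok).sum())
        counts[fragments.chrom] += np.bincount(mids[ok], minlength=size)
        sample_id = sample_id or fragments.sample_id
    else:
        for f in fragments:
            v = counts.get(f.chrom)
            if v is None or f.start < 0 or f.end > v.size:
                skipped += 1
                continue
            v[(f.start + f.end - 1) // 2] += 1
    if skipped:
        log.warning("dyads_from_fragments: skipped %d out-of-bounds fragments", skipped)
    return DyadTrack(counts, sample_id=sample_id)


def occupancy_from_dyads(
    track: DyadTrack, footprint: int = NUCLEOSOME_FOOTPRINT
) -> DyadTrack:
    """Extend each dyad to its nucleosome footprint (coverage-style occupancy).

    Each count at position p contributes 1 to every base within
    ``footprint // 2`` of p. Used for nucleosome-free-region measurement,
    where footprint edges — not dyad density tails — define depletion.
    """
    if footprint < 1 or footprint % 2 == 0:
        raise ValueError("footprint must be odd and >= 1")
    kernel = np.ones(footprint)
    occ = {
        c: np.convolve(v.astype(float), kernel, mode="same")
        for c, v in track.counts.items()
    }
    return DyadTrack(occ, sample_id=track.sample_id)


def gene_profile(
    track: DyadTrack,
    gene: GeneModel,
    anchor: Anchor = Anchor.ATG,
    window: tuple[int, int] = (-600, 600),
    plus_one_pos: int | None = None,
) -> AlignedProfile:
    """Cut a gene-oriented window of the track around an anchor.

    ``values[i]`` is the track value at genomic position
    ``anchor_pos + s * (lo + i)`` with s = +1 on the plus strand and -1 on
    the minus strand, so positive offsets always point downstream of the
    gene. Bins beyond the chromosome ends are masked invalid.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("window must satisfy lo <= hi")
    anchor = Anchor(anchor)
    if anchor is Anchor.ATG:
        pos = gene.atg
    elif anchor is Anchor.STOP:
        pos = gene.stop
    else:
        if plus_one_pos is None:
            raise ValueError(f"gene {gene.gene_id}: +1 anchor requested but not assigned")
        pos = plus_one_pos
    v = track.counts[gene.chrom]
    s = 1 if gene.strand == "+" else -1
    genomic = pos + s * np.arange(lo, hi + 1)
    mask = (genomic >= 0) & (genomic < v.size)
    values = np.zeros(hi - lo + 1, dtype=float)
    values[mask] = v[genomic[mask]]
    return AlignedProfile(anchor=anchor, lo=lo, hi=hi, values=values, mask=mask, n_genes=1)


def aggregate_profiles(profiles: Sequence[AlignedProfile]) -> AlignedProfile:
    """Per-bin mean over genes, using only each gene's valid bins."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    first = profiles[0]
    for p in profiles[1:]:
        if p.anchor != first.anchor or p.window != first.window:
            raise ValueError("profiles disagree on anchor or window")
    vals = np.stack([p.values for p in profiles])
    masks = np.stack([p.mask for p in profiles])
    n_valid = masks.sum(axis=0)
    total = (vals * masks).sum(axis=0)
    out = np.zeros_like(total)
    np.divide(total, n_valid, out=out, where=n_valid > 0)
    return AlignedProfile(
        anchor=first.anchor,
        lo=first.lo,
        hi=first.hi,
        values=out,
        mask=n_valid > 0,
        n_genes=sum(p.n_genes for p in profiles),
    )


def normalize_profile(p: AlignedProfile) -> AlignedProfile:
    """Divide valid bins by their mean so the masked mean becomes 1."""
    if not p.mask.any():
        raise ValueError("profile has no valid bins")
    mean = p.values[p.mask].mean()
    if mean <= 0:
        raise ValueError("profile mean is zero; nothing to normalize")
    values = p.values.copy()
    values[p.mask] = values[p.mask] / mean
    return p.copy_with(values)


def chr_dna_ratio(
    chromatin: AlignedProfile,
    naked: AlignedProfile,
    floor: float = 0.05,
) -> AlignedProfile:
    """Mappability-corrected ratio of normalized chromatin over naked-DNA signal.

    Both inputs must be window-mean normalized; bins where the naked control
    falls below ``floor`` (default 0.05 of its mean, i.e. 0.05 after
    normalization) are masked rather than divided.
    """
    if chromatin.window != naked.window or chromatin.anchor != naked.anchor:
        raise ValueError("chromatin and naked profiles disagree on anchor/window")
    for name, p in (("chromatin", chromatin), ("naked", naked)):
        if abs(p.values[p.mask].mean() - 1.0) > 1e-6:
            raise ValueError(f"{name} profile is not window-mean normalized")
    mask = chromatin.mask & naked.mask & (naked.values >= floor)
    values = np.zeros_like(chromatin.values)
    np.divide(chromatin.values, naked.values, out=values, where=mask)
    return AlignedProfile(
        anchor=chromatin.anchor,
        lo=chromatin.lo,
        hi=chromatin.hi,
        values=values,
        mask=mask,
        n_genes=chromatin.n_genes,
    )


def at_content_track(seq: str, window_bp: int) -> np.ndarray:
    """Centered moving A/T fraction (case-insensitive); N bases excluded.

    Returns one value per base in [0, 1]; positions whose window contains
    only N are NaN. Near sequence ends the window is truncated.
    """
    if window_bp < 1 or window_bp % 2 == 0:
        raise ValueError("window_bp must be odd and >= 1")
    if window_bp > len(seq):
        raise ValueError("window_bp larger than the sequence")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(float)
    known = ((arr == ord("A")) | (arr == ord("T")) | (arr == ord("G")) | (arr == ord("C"))).astype(float)
    kern = np.ones(window_bp)
    num = np.convolve(is_at, kern, mode="same")
    den = np.convolve(known, kern, mode="same")
    out = np.full(arr.size, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out
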