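"""Differential nucleosome positioning between two conditions.

Per-gene peak sets from two samples are paired summit-to-summit; a pair is
"nonmatching" when summits disagree by more than 10 bp or peak heights by
more than twofold (or when a peak has no partner at all). A gene is called
remodeled (WT growth vs development) or mismodeled (WT vs remodeler null)
when every replicate comparison finds at least three nonmatching nucleosomes
within 1000 bp 3' of the ATG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .dyad_profiles import gene_profile, normalize_profile
from .model import Anchor, DyadTrack, GeneModel
from .nucleosome_calling import Peak, PeakSet, call_peaks, smooth_profile

log = logging.getLogger(__name__)

__all__ = [
    "PeakMatch",
    "RemodelCall",
    "match_peaks",
    "count_nonmatching",
    "classify_gene",
    "compare_conditions",
]

_UNPAIRABLE = 1e9  # cost sentinel for pairs beyond the pairing cap


@dataclass(frozen=True)
class PeakMatch:
    peak_a: Peak | None
    peak_b: Peak | None
    summit_delta: int | None  # b - a, bp
    height_ratio: float | None  # max/min, >= 1
    nonmatching: bool

    @property
    def reference_summit(self) -> int:
        p = self.peak_a if self.peak_a is not None else self.peak_b
        return p.summit


@dataclass(frozen=True)
class RemodelCall:
    gene_id: str
    condition_pair: tuple[str, str]
    per_replicate_nonmatching: tuple[int, ...]
    called: bool
    window_used: tuple[int, int]


def _is_nonmatching(
    delta: int, ratio: float, max_summit_delta: float, max_height_ratio: float
) -> bool:
    # strict inequalities: a 10-bp shift or exactly twofold change still matches
    return abs(delta) > max_summit_delta or ratio > max_height_ratio


def match_peaks(
    a: PeakSet,
    b: PeakSet,
    max_pair_dist: int = 85,
    max_summit_delta: float = 10.0,
    max_height_ratio: float = 2.0,
) -> list[PeakMatch]:
    """Pair summits between two peak sets; flag nonmatching nucleosomes.

    Pairing maximizes the number of pairs within ``max_pair_dist`` bp
    (about half an NRL) and, among those, minimizes the total summit
    distance (Hungarian assignment). Unpaired peaks become one-sided
    matches, which are nonmatching by definition. Matches are returned in
    reference-summit order.
    """
    pa, pb = a.peaks, b.peaks
    matches: list[PeakMatch] = []
    used_a, used_b = set(), set()
    if pa and pb:
        sa = np.array([p.summit for p in pa])[:, None]
        sb = np.array([p.summit for p in pb])[None, :]
        cost = np.abs(sa - sb).astype(float)
        cost[cost > max_pair_dist] = _UNPAIRABLE
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] >= _UNPAIRABLE:
                continue
            used_a.add(int(i))
            used_b.add(int(j))
            delta = pb[j].summit - pa[i].summit
            hs = sorted((pa[i].height, pb[j].height))
            ratio = hs[1] / hs[0]
            matches.append(
                PeakMatch(
                    peak_a=pa[i],
                    peak_b=pb[j],
                    summit_delta=delta,
                    height_ratio=ratio,
                    nonmatching=_is_nonmatching(
                        delta, ratio, max_summit_delta, max_height_ratio
                    ),
                )
            )
    for i, p in enumerate(pa):
        if i not in used_a:
            matches.append(PeakMatch(p, None, None, None, True))
    for j, p in enumerate(pb):
        if j not in used_b:
            matches.append(PeakMatch(None, p, None, None, True))
    matches.sort(key=lambda m: m.reference_summit)
    return matches


def count_nonmatching(
    matches: Sequence[PeakMatch], window: tuple[int, int] = (0, 1000)
) -> int:
    """Nonmatching matches whose reference summit lies inside the window.

    The reference summit is side a's where present, else side b's; the
    window is inclusive on both ends.
    """
    lo, hi = window
    return sum(
        1 for m in matches if m.nonmatching and lo <= m.reference_summit <= hi
    )


def classify_gene(
    gene_id: str,
    per_replicate_matches: Sequence[Sequence[PeakMatch]],
    min_nonmatching: int = 3,
    window: tuple[int, int] = (0, 1000),
    condition_pair: tuple[str, str] = ("A", "B"),
) -> RemodelCall:
    """Call a gene differentially positioned when every replicate agrees.

    Each replicate comparison must show at least ``min_nonmatching``
    nonmatching nucleosomes inside the window.
    """
    if not per_replicate_matches:
        raise ValueError(f"{gene_id}: no replicate comparisons supplied")
    counts = tuple(count_nonmatching(m, window) for m in per_replicate_matches)
    return RemodelCall(
        gene_id=gene_id,
        condition_pair=condition_pair,
        per_replicate_nonmatching=counts,
        called=all(c >= min_nonmatching for c in counts),
        window_used=window,
    )


def _gene_peaks(
    track: DyadTrack,
    gene: GeneModel,
    window: tuple[int, int],
    bandwidth: int,
    noise_frac: float,
    noise_ref: str,
) -> PeakSet:
    prof = gene_profile(track, gene, Anchor.ATG, window)
    if not prof.mask.any() or prof.values[prof.mask].sum() <= 0:
        return PeakSet(peaks=[], noise_threshold=0.0, anchor=Anchor.ATG)
    prof = normalize_profile(prof)  # per-gene, depth-free
    prof = smooth_profile(prof, bandwidth)
    return call_peaks(prof, noise_frac, noise_ref)


def compare_conditions(
    genes: Sequence[GeneModel],
    tracks: Mapping[tuple[str, int], DyadTrack],
    cond_a: str,
    cond_b: str,
    replicates: Sequence[int] = (1, 2),
    window: tuple[int, int] = (0, 1000),
    bandwidth: int = 30,
    noise_frac: float = 0.05,
    noise_ref: str = "max",
    max_pair_dist: int = 85,
    max_summit_delta: float = 10.0,
    max_height_ratio: float = 2.0,
    min_nonmatching: int = 3,
    mode: str = "paired",
) -> pd.DataFrame:
    """Classify every gene between two conditions with replicate support.

    ``tracks`` maps (condition, replicate) to a dyad track. Per-gene peak
    sets use the profile-maximum noise reference (see `call_peaks`): on
    sparse single-gene profiles a mean-scaled floor does not separate
    background density maxima from nucleosome peaks. In ``paired``
    mode replicate r of condition A is compared with replicate r of B and
    the call must hold in every pair; in ``pooled`` mode replicates are
    summed per condition first and a single comparison decides. Genes
    shorter than the window use (0, gene length - 1).

    Returns a table with per-replicate nonmatching counts and the call;
    the complement of the called set is the non-remodeled set.
    """
    if mode not in ("paired", "pooled"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    for cond in (cond_a, cond_b):
        for rep in replicates:
            if (cond, rep) not in tracks:
                raise ValueError(f"missing track for condition {cond!r} replicate {rep}")
    if mode == "pooled":
        pooled_a = _pool([tracks[(cond_a, r)] for r in replicates])
        pooled_b = _pool([tracks[(cond_b, r)] for r in replicates])
        pairs = [(pooled_a, pooled_b)]
    else:
        pairs = [(tracks[(cond_a, r)], tracks[(cond_b, r)]) for r in replicates]

    rows = []
    for gene in genes:
        win = (window[0], min(gene.length - 1, window[1]))
        rep_matches = []
        for ta, tb in pairs:
            peaks_a = _gene_peaks(ta, gene, win, bandwidth, noise_frac, noise_ref)
            peaks_b = _gene_peaks(tb, gene, win, bandwidth, noise_frac, noise_ref)
            rep_matches.append(
                match_peaks(
                    peaks_a,
                    peaks_b,
                    max_pair_dist=max_pair_dist,
                    max_summit_delta=max_summit_delta,
                    max_height_ratio=max_height_ratio,
                )
            )
        call = classify_gene(
            gene.gene_id,
            rep_matches,
            min_nonmatching=min_nonmatching,
            window=win,
            condition_pair=(cond_a, cond_b),
        )
        row = {
            "gene_id": gene.gene_id,
            "condition_a": cond_a,
            "condition_b": cond_b,
            "window_lo": win[0],
            "window_hi": win[1],
            "called": call.called,
        }
        for k, c in enumerate(call.per_replicate_nonmatching, 1):
            row[f"nonmatching_rep{k}"] = c
        rows.append(row)
    df = pd.DataFrame(rows)
    n_called = int(df["called"].sum())
    log.info(
        "compare_conditions %s vs %s: %d/%d genes called, %d non-remodeled",
        cond_a,
        cond_b,
        n_called,
        len(df),
        len(df) - n_called,
    )
    return df


def _pool(tracks: Sequence[DyadTrack]) -> DyadTrack:
    out = tracks[0]
    for t in tracks[1:]:
        out = out + t
    return out
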