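"""End-to-end orchestration helpers shared by the CLI and analysis scripts.

These functions wire the stages together in the order the study runs them:
simulate (or load) fragments -> size-select -> dyad tracks -> gene-anchored
aggregate profiles -> smooth/call peaks -> +1 and NRL -> NDR metrics ->
per-gene differential classification -> set statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import compare_conditions
from .dyad_profiles import (
    SizeFilter,
    aggregate_profiles,
    chr_dna_ratio,
    dyads_from_fragments,
    gene_profile,
    normalize_profile,
    occupancy_from_dyads,
    select_nucleosomal,
)
from .model import AlignedProfile, Anchor, DyadTrack, GeneModel
from .nucleosome_calling import (
    NRLEstimate,
    assign_plus_one,
    call_peaks,
    estimate_nrl,
    ndr_metrics,
    smooth_profile,
)
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    simulate_chromatin_fragments,
    simulate_genome,
    simulate_naked_fragments,
)

log = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "simulate_cohort",
    "atg_aggregate",
    "condition_nrl",
    "measure_ndr",
    "profile_matrix",
    "classification_metrics",
]


@dataclass
class Cohort:
    """A fully simulated study: truth, annotation, and dyad tracks."""

    truth: GroundTruth
    genes: List[GeneModel]
    genome: Dict[str, str]
    tracks: Dict[tuple, DyadTrack]  # (condition, replicate) -> size-selected dyads
    naked_track: DyadTrack | None
    n_fragments: Dict[tuple, int] = field(default_factory=dict)
    n_selected: Dict[tuple, int] = field(default_factory=dict)

    @property
    def config(self) -> SimulationConfig:
        return self.truth.config

    def pooled_track(self, condition: str) -> DyadTrack:
        reps = [
            t for (c, _r), t in sorted(self.tracks.items()) if c == condition
        ]
        out = reps[0]
        for t in reps[1:]:
            out = out + t
        return out


def simulate_cohort(
    config: SimulationConfig,
    size_filter: SizeFilter = SizeFilter(),
    with_naked: bool = True,
) -> Cohort:
    """Simulate genome + libraries and reduce them to dyad tracks."""
    genome, genes, truth = simulate_genome(config, make_sequence=with_naked)
    tracks: Dict[tuple, DyadTrack] = {}
    n_fragments: Dict[tuple, int] = {}
    n_selected: Dict[tuple, int] = {}
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            frags = simulate_chromatin_fragments(truth, cond, rep)
            n_fragments[(cond, rep)] = len(frags)
            kept = select_nucleosomal(frags, size_filter)
            n_selected[(cond, rep)] = len(kept)
            tracks[(cond, rep)] = dyads_from_fragments(kept, truth.chrom_sizes)
    naked_track = None
    if with_naked:
        naked = select_nucleosomal(simulate_naked_fragments(genome, config), size_filter)
        naked_track = dyads_from_fragments(naked, truth.chrom_sizes)
    return Cohort(
        truth=truth,
        genes=genes,
        genome=genome,
        tracks=tracks,
        naked_track=naked_track,
        n_fragments=n_fragments,
        n_selected=n_selected,
    )


def atg_aggregate(
    track: DyadTrack,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (-600, 600),
    anchor: Anchor = Anchor.ATG,
    plus_one_by_gene: Mapping[str, int] | None = None,
) -> AlignedProfile:
    """Figure-style aggregate: mean of per-gene raw counts, then normalized."""
    profiles = []
    for g in genes:
        p1 = plus_one_by_gene.get(g.gene_id) if plus_one_by_gene else None
        if anchor is Anchor.PLUS_ONE and p1 is None:
            continue
        profiles.append(gene_profile(track, g, anchor, window, plus_one_pos=p1))
    return normalize_profile(aggregate_profiles(profiles))


def condition_nrl(
    track: DyadTrack,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (-600, 1200),
    bandwidth: int = 30,
    noise_frac: float = 0.05,
    n_nucs: int = 5,
) -> NRLEstimate:
    """Aggregate-profile NRL for one condition (smoothed, +1-anchored OLS)."""
    agg = atg_aggregate(track, genes, window)
    peaks = call_peaks(smooth_profile(agg, bandwidth), noise_frac)
    plus_one = assign_plus_one(peaks)
    if plus_one is None:
        raise ValueError("aggregate profile has no +1 nucleosome")
    return estimate_nrl(peaks, n_nucs=n_nucs, plus_one=plus_one)


def measure_ndr(
    chromatin: DyadTrack,
    naked: DyadTrack,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (-600, 600),
    threshold: float = 0.8,
    bandwidth: int = 30,
    noise_frac: float = 0.05,
) -> tuple[float | None, int]:
    """Promoter NDR (center, width) from the occupancy-level CHR/DNA ratio.

    Dyad tracks are footprint-extended to occupancy before division so the
    depleted run measures nucleosome-free DNA; the +1 boundary comes from
    the smoothed dyad-level aggregate.
    """
    agg_dyad = atg_aggregate(chromatin, genes, window)
    plus_one = assign_plus_one(call_peaks(smooth_profile(agg_dyad, bandwidth), noise_frac))
    occ_chr = atg_aggregate(occupancy_from_dyads(chromatin), genes, window)
    occ_naked = atg_aggregate(occupancy_from_dyads(naked), genes, window)
    ratio = chr_dna_ratio(occ_chr, occ_naked)
    return ndr_metrics(
        ratio,
        plus_one_offset=plus_one.summit if plus_one else None,
        threshold=threshold,
    )


def profile_matrix(
    track: DyadTrack,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (-600, 600),
) -> pd.DataFrame:
    """Gene x offset matrix of per-gene normalized profiles (clustering input).

    Genes with no signal in the window are dropped.
    """
    rows, ids = [], []
    for g in genes:
        p = gene_profile(track, g, Anchor.ATG, window)
        if not p.mask.any() or p.values[p.mask].sum() <= 0:
            continue
        rows.append(normalize_profile(p).values)
        ids.append(g.gene_id)
    return pd.DataFrame(np.stack(rows), index=ids, columns=np.arange(window[0], window[1] + 1))


def classification_metrics(
    calls: pd.DataFrame, truth: GroundTruth
) -> dict[str, float]:
    """Sensitivity / false-positive rate of remodel calls against the truth."""
    remodeled = truth.remodeled_ids()
    called = set(calls.loc[calls["called"], "gene_id"])
    all_ids = set(calls["gene_id"])
    pos = remodeled & all_ids
    neg = all_ids - remodeled
    tp = len(called & pos)
    fp = len(called & neg)
    return {
        "sensitivity": tp / len(pos) if pos else float("nan"),
        "fpr": fp / len(neg) if neg else float("nan"),
        "n_called": float(len(called)),
        "n_true_remodeled": float(len(pos)),
    }
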