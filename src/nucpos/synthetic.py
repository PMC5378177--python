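"""Synthetic MNase-seq cohorts with known ground truth.

The generator emits a gene-dense genome of alternating AT-rich intergenic
blocks (~87% AT) and genes (~70% AT), a nucleosome architecture per gene and
condition (+1 dyad at +60 bp after the ATG, genic array spaced one NRL
apart, -1 at -250 across the promoter NDR), paired-end-style fragment sets
per condition/replicate (lengths ~N(150, 12), per-cell positional jitter),
a naked-DNA control with AT-driven dropout, and differential-expression gene
sets optionally coupled to the planted remodeled genes.

Everything is deterministic given ``SimulationConfig.seed``: each product
draws from its own integer-keyed ``numpy.random.default_rng`` stream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping

import numpy as np

from .model import FragmentSet, GeneModel, GeneSet

__all__ = [
    "SimulationConfig",
    "GeneTruth",
    "GroundTruth",
    "simulate_genome",
    "simulate_chromatin_fragments",
    "simulate_naked_fragments",
    "simulate_expression_sets",
]

REMODEL_MODES = ("summit_shift", "nrl_expand", "height_change", "phase_scramble")


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults emulate the system analysed.

    NRLs default to 170 bp (growth) and 173 bp (loose mound), with 181 bp
    for the remodeled/mismodeled arrays under ``nrl_expand``; the +1 dyad
    sits at +60 bp after the ATG and the -1 at -250 bp, flanking a ~170 bp
    promoter NDR over >85% AT intergenic DNA.
    """

    seed: int = 1
    n_genes: int = 300
    gene_length_mean: float = 1500.0
    gene_length_sd: float = 400.0
    gene_length_min: int = 800
    upstream_length: int = 600  # promoter/intergenic block ahead of each ATG
    spacer_length: int = 100
    intergenic_at_fraction: float = 0.87
    genic_at_fraction: float = 0.70
    nrl_by_condition: Dict[str, float] = field(
        default_factory=lambda: {"growth": 170.0, "mound": 173.0}
    )
    altered_condition: str = "mound"  # condition receiving the remodel modes
    nrl_remodeled: float = 181.0
    plus_one_offset: int = 60
    minus_one_offset: int = -250
    ndr_width: int = 170
    positional_jitter_sd: float = 15.0  # per-fragment (cell-to-cell) dyad jitter
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 12.0
    fragment_length_bounds: tuple = (100, 220)
    fragments_per_gene: int = 200
    background_fraction: float = 0.02
    n_replicates: int = 2
    remodeled_fraction: float = 0.15
    remodel_mode: str = "summit_shift"
    summit_shift_bp: int = 20
    n_shifted_nucs: int = 3
    height_change_factor: float = 3.0
    phase_scramble_bp: int = 50
    naked_at_dropout: float = 0.3
    de_fraction: float = 0.25
    de_coupling: float = 0.6
    de_up_fraction: float = 0.585  # matches a ~939:667 up/down split
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        for name in (
            "intergenic_at_fraction",
            "genic_at_fraction",
            "background_fraction",
            "remodeled_fraction",
            "de_fraction",
            "de_coupling",
            "de_up_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for cond, nrl in self.nrl_by_condition.items():
            if nrl <= 146:
                raise ValueError(f"NRL for {cond!r} must exceed the 146 bp core, got {nrl}")
        if self.nrl_remodeled <= 146:
            raise ValueError("nrl_remodeled must exceed 146 bp")
        if self.remodel_mode not in REMODEL_MODES:
            raise ValueError(f"remodel_mode must be one of {REMODEL_MODES}")
        if self.altered_condition not in self.nrl_by_condition:
            raise ValueError("altered_condition must be a key of nrl_by_condition")
        if self.gene_length_min < self.plus_one_offset + 73 + 1:
            raise ValueError("genes shorter than one nucleosome after the +1 are infeasible")

    @property
    def conditions(self) -> List[str]:
        return list(self.nrl_by_condition)


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    atg: int  # 0-based genomic
    stop: int
    length: int
    cassette: tuple  # 0-based half-open genomic span owned by this gene
    remodeled: bool
    de: bool | None = None
    summit_offsets: Dict[str, List[int]] = field(default_factory=dict)  # ATG-relative
    weights: Dict[str, List[float]] = field(default_factory=dict)

    def genomic_summits(self, condition: str) -> List[int]:
        s = 1 if self.strand == "+" else -1
        return [self.atg + s * off for off in self.summit_offsets[condition]]

    def to_gene_model(self) -> GeneModel:
        return GeneModel(self.gene_id, self.chrom, self.strand, self.atg, self.stop)


@dataclass
class GroundTruth:
    config: SimulationConfig
    chrom_sizes: Dict[str, int]
    genes: List[GeneTruth]

    @property
    def conditions(self) -> List[str]:
        return self.config.conditions

    def gene_models(self) -> List[GeneModel]:
        return [g.to_gene_model() for g in self.genes]

    def remodeled_ids(self) -> frozenset:
        return frozenset(g.gene_id for g in self.genes if g.remodeled)

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "chrom_sizes": self.chrom_sizes,
            "genes": [asdict(g) for g in self.genes],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def from_json(path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["nrl_by_condition"] = dict(cfg["nrl_by_condition"])
        cfg["fragment_length_bounds"] = tuple(cfg["fragment_length_bounds"])
        config = SimulationConfig(**cfg)
        genes = [
            GeneTruth(**{**g, "cassette": tuple(g["cassette"])})
            for g in payload["genes"]
        ]
        return GroundTruth(config=config, chrom_sizes=payload["chrom_sizes"], genes=genes)


# ---------------------------------------------------------------------------


def _gene_architecture(
    config: SimulationConfig, length: int, condition: str, remodeled: bool, rng
) -> tuple[List[int], List[float]]:
    """ATG-relative dyad offsets and relative occupancies for one gene."""
    spacing = float(config.nrl_by_condition[condition])
    altered = remodeled and condition == config.altered_condition
    if altered and config.remodel_mode == "nrl_expand":
        spacing = float(config.nrl_remodeled)

    offsets: List[int] = []
    # upstream (-1, -2, ...) nucleosomes across the NDR boundary
    off = config.minus_one_offset
    while off - 73 >= -config.upstream_length:
        offsets.append(int(round(off)))
        off -= spacing
    offsets.reverse()
    n_upstream = len(offsets)
    # genic array: +1 at plus_one_offset, then one NRL apart inside the gene
    k = 0
    while True:
        off = config.plus_one_offset + k * spacing
        if off + 73 > length:
            break
        offsets.append(int(round(off)))
        k += 1
    weights = [1.0] * len(offsets)

    if altered:
        genic = range(n_upstream, len(offsets))
        if config.remodel_mode == "summit_shift":
            # shift nucleosomes +2..+(1+n_shifted) downstream by a fixed step
            for j in range(n_upstream + 1, min(n_upstream + 1 + config.n_shifted_nucs, len(offsets))):
                offsets[j] += config.summit_shift_bp
        elif config.remodel_mode == "height_change":
            for j in range(n_upstream + 1, min(n_upstream + 1 + config.n_shifted_nucs, len(offsets))):
                weights[j] *= config.height_change_factor
        elif config.remodel_mode == "phase_scramble":
            for j in genic:
                offsets[j] += int(rng.integers(-config.phase_scramble_bp, config.phase_scramble_bp + 1))
    return offsets, weights


def simulate_genome(
    config: SimulationConfig, make_sequence: bool = True
) -> tuple[Dict[str, str], List[GeneModel], GroundTruth]:
    """Generate the genome (FASTA-ready), annotation, and ground truth.

    One chromosome of per-gene cassettes: an AT-rich upstream block holding
    the NDR and upstream nucleosomes, the gene body, and a short spacer.
    Strands are drawn 50/50 and minus-strand cassettes are mirrored. With
    ``make_sequence=False`` only coordinates and truth are produced (used
    for large set-statistics cohorts where sequence is irrelevant).
    """
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_genes
    lengths = np.maximum(
        np.rint(rng.normal(config.gene_length_mean, config.gene_length_sd, n)),
        config.gene_length_min,
    ).astype(int)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    n_remod = int(round(config.remodeled_fraction * n))
    remod_idx = set(rng.choice(n, size=n_remod, replace=False).tolist())

    width = len(str(n))
    genes: List[GeneTruth] = []
    pos = 0
    for i in range(n):
        L = int(lengths[i])
        cass_len = config.upstream_length + L + config.spacer_length
        strand = str(strands[i])
        if strand == "+":
            atg = pos + config.upstream_length
            stop = atg + L - 1
        else:
            atg = pos + cass_len - 1 - config.upstream_length
            stop = atg - (L - 1)
        g = GeneTruth(
            gene_id=f"g{str(i + 1).zfill(width)}",
            chrom=config.chrom_name,
            strand=strand,
            atg=atg,
            stop=stop,
            length=L,
            cassette=(pos, pos + cass_len),
            remodeled=i in remod_idx,
        )
        for cond in config.conditions:
            offs, wts = _gene_architecture(config, L, cond, g.remodeled, rng)
            g.summit_offsets[cond] = offs
            g.weights[cond] = wts
        genes.append(g)
        pos += cass_len
    chrom_sizes = {config.chrom_name: pos}

    genome: Dict[str, str] = {}
    if make_sequence:
        at_prob = np.full(pos, config.intergenic_at_fraction)
        for g in genes:
            lo = min(g.atg, g.stop)
            at_prob[lo : lo + g.length] = config.genic_at_fraction
        is_at = rng.random(pos) < at_prob
        pick = rng.integers(0, 2, pos)
        bases = np.empty(pos, dtype="U1")
        bases[is_at & (pick == 0)] = "A"
        bases[is_at & (pick == 1)] = "T"
        bases[~is_at & (pick == 0)] = "G"
        bases[~is_at & (pick == 1)] = "C"
        genome[config.chrom_name] = "".join(bases.tolist())

    truth = GroundTruth(config=config, chrom_sizes=chrom_sizes, genes=genes)
    return genome, truth.gene_models(), truth


def simulate_chromatin_fragments(
    truth: GroundTruth, condition: str, replicate: int
) -> FragmentSet:
    """Fragments for one condition/replicate library.

    Each nucleosome emits fragments whose centers are its dyad plus Gaussian
    per-cell jitter and whose lengths are N(mean, sd) truncated to the
    configured bounds; a small uniform background is added. Replicates
    differ only by their RNG stream.
    """
    config = truth.config
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = config.conditions.index(condition)
    rng = np.random.default_rng([config.seed, 101, cond_idx, int(replicate)])
    chrom = config.chrom_name
    chrom_len = truth.chrom_sizes[chrom]

    centers: List[np.ndarray] = []
    n_bg_total = 0
    for g in truth.genes:
        summits = np.array(g.genomic_summits(condition), dtype=float)
        w = np.array(g.weights[condition], dtype=float)
        n_bg = rng.binomial(config.fragments_per_gene, config.background_fraction)
        n_bg_total += int(n_bg)
        n_nuc = config.fragments_per_gene - n_bg
        counts = rng.multinomial(n_nuc, w / w.sum())
        centers.append(np.repeat(summits, counts))
    c = np.concatenate(centers)
    c = c + rng.normal(0.0, config.positional_jitter_sd, c.size)
    c = np.concatenate([c, rng.uniform(0, chrom_len, n_bg_total)])

    lo, hi = config.fragment_length_bounds
    lens = np.clip(
        np.rint(rng.normal(config.fragment_length_mean, config.fragment_length_sd, c.size)),
        lo,
        hi,
    ).astype(np.int64)
    starts = np.rint(c).astype(np.int64) - lens // 2
    ends = starts + lens
    ok = (starts >= 0) & (ends <= chrom_len)
    return FragmentSet(
        chrom, starts[ok], ends[ok], sample_id=f"{condition}_rep{replicate}"
    )


def simulate_naked_fragments(
    genome: Mapping[str, str],
    config: SimulationConfig,
    n_fragments: int | None = None,
) -> FragmentSet:
    """Naked-DNA (protein-free) control fragments.

    Positions are uniform, then thinned with retention probability
    ``1 - naked_at_dropout * AT_fraction(fragment span)``, emulating
    AT-driven cleavage/mappability loss; a zero coefficient gives uniform
    coverage.
    """
    rng = np.random.default_rng([config.seed, 202])
    chrom = config.chrom_name
    seq = genome[chrom]
    chrom_len = len(seq)
    if n_fragments is None:
        n_fragments = config.n_genes * config.fragments_per_gene
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    at_cum = np.concatenate(([0], np.cumsum((arr == ord("A")) | (arr == ord("T")))))

    lo, hi = config.fragment_length_bounds
    lens = np.clip(
        np.rint(rng.normal(config.fragment_length_mean, config.fragment_length_sd, n_fragments)),
        lo,
        hi,
    ).astype(np.int64)
    starts = rng.integers(0, np.maximum(chrom_len - lens, 1))
    ends = starts + lens
    at_frac = (at_cum[ends] - at_cum[starts]) / lens
    retention = np.clip(1.0 - config.naked_at_dropout * at_frac, 0.0, 1.0)
    keep = rng.random(n_fragments) < retention
    return FragmentSet(chrom, starts[keep], ends[keep], sample_id="naked")


def simulate_expression_sets(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> tuple[GeneSet, GeneSet]:
    """Draw DE flags coupled to the planted remodeled genes; emit up/down sets.

    With coupling c, remodeled genes are DE with probability
    q + c (1 - q) and all others with the baseline q (= ``de_fraction``), so
    c = 0 gives exact independence and c = 1 makes the remodeled set a
    subset of the DE set. Flags are stored back onto the truth.
    """
    if config is None:
        config = truth.config
    rng = np.random.default_rng([config.seed, 303])
    q = config.de_fraction
    p = np.array(
        [q + config.de_coupling * (1.0 - q) if g.remodeled else q for g in truth.genes]
    )
    de = rng.random(len(truth.genes)) < p
    up_draw = rng.random(len(truth.genes)) < config.de_up_fraction
    up, down = [], []
    for g, flag, is_up in zip(truth.genes, de.tolist(), up_draw.tolist()):
        g.de = flag
        if flag:
            (up if is_up else down).append(g.gene_id)
    return (
        GeneSet(label="up", gene_ids=frozenset(up)),
        GeneSet(label="down", gene_ids=frozenset(down)),
    )
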