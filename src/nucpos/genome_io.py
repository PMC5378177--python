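"""Readers and writers for the pipeline's external formats.

SAM/BAM paired alignments in (pysam), GFF3 gene models in (gffutils), FASTA
in/out (Biopython), bedGraph dyad tracks out/in, TSV gene sets and result
tables. All coordinates are converted to the internal 0-based half-open
convention at this boundary and back on write.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

from .model import DyadTrack, FragmentRecord, FragmentSet, GeneModel, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "AlignmentStats",
    "iter_paired_alignments",
    "read_paired_alignments",
    "write_fragments_sam",
    "read_gene_models",
    "write_gene_models_gff3",
    "read_fasta",
    "write_fasta",
    "write_dyad_track",
    "read_dyad_track",
    "read_gene_set",
    "write_gene_set",
]


# ---------------------------------------------------------------------------
# paired-end alignments


@dataclass
class AlignmentStats:
    """Per-file accounting for `read_paired_alignments`."""

    proper_fragments: int = 0
    skipped_secondary: int = 0
    skipped_unpaired: int = 0
    skipped_low_mapq: int = 0
    skipped_no_tlen: int = 0

    @property
    def skipped_total(self) -> int:
        return (
            self.skipped_secondary
            + self.skipped_unpaired
            + self.skipped_low_mapq
            + self.skipped_no_tlen
        )


def iter_paired_alignments(
    path,
    min_mapq: int = 0,
    sample_id: str = "",
    stats: AlignmentStats | None = None,
) -> Iterator[FragmentRecord]:
    """Yield one FragmentRecord per properly paired fragment in a SAM/BAM file.

    The fragment span is the leftmost mate start plus the template length
    (SAM ISIZE), emitted once per pair from the mate with positive TLEN.
    Secondary/supplementary records and pairs without usable mate
    information are skipped and counted. ``min_mapq`` defaults to 0 (no
    mapping-quality filter).
    """
    if stats is None:
        stats = AlignmentStats()
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignment file {path}: {exc}") from exc
    with af:
        for aln in af.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                stats.skipped_secondary += 1
                continue
            if (
                aln.is_unmapped
                or not aln.is_paired
                or aln.mate_is_unmapped
                or not aln.is_proper_pair
            ):
                stats.skipped_unpaired += 1
                continue
            tlen = aln.template_length
            if tlen < 0:
                # rightmost mate of a pair already emitted from the leftmost
                continue
            if tlen == 0:
                stats.skipped_no_tlen += 1
                continue
            if aln.mapping_quality < min_mapq:
                stats.skipped_low_mapq += 1
                continue
            start = aln.reference_start  # pysam is already 0-based
            stats.proper_fragments += 1
            yield FragmentRecord(
                chrom=aln.reference_name,
                start=start,
                end=start + tlen,
                sample_id=sample_id,
            )


def read_paired_alignments(
    path, min_mapq: int = 0, sample_id: str = ""
) -> tuple[list[FragmentRecord], AlignmentStats]:
    """Materialize `iter_paired_alignments` together with its skip counters."""
    stats = AlignmentStats()
    frags = list(iter_paired_alignments(path, min_mapq, sample_id, stats))
    if stats.skipped_total:
        log.warning(
            "%s: skipped %d records (secondary=%d unpaired=%d low_mapq=%d no_tlen=%d)",
            path,
            stats.skipped_total,
            stats.skipped_secondary,
            stats.skipped_unpaired,
            stats.skipped_low_mapq,
            stats.skipped_no_tlen,
        )
    return frags, stats


def write_fragments_sam(
    fragments: Iterable[FragmentRecord] | FragmentSet,
    chrom_sizes: Mapping[str, int],
    path,
    read_length: int = 36,
) -> int:
    """Write fragments as properly paired SAM records (two reads per fragment).

    Reads carry a fixed clipped read length; the fragment span is encoded in
    POS/PNEXT/TLEN, which is what `read_paired_alignments` consumes.
    Returns the number of fragments written.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_sizes.items()],
    }
    tids = {c: i for i, c in enumerate(chrom_sizes)}
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for frag in fragments:
            rlen = min(read_length, frag.length)
            for is_r1 in (True, False):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{n}"
                a.query_sequence = "N" * rlen
                a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                a.reference_id = tids[frag.chrom]
                a.next_reference_id = tids[frag.chrom]
                a.mapping_quality = 60
                a.cigarstring = f"{rlen}M"
                if is_r1:
                    a.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate rev, read1
                    a.reference_start = frag.start
                    a.next_reference_start = frag.end - rlen
                    a.template_length = frag.length
                else:
                    a.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, rev, read2
                    a.reference_start = frag.end - rlen
                    a.next_reference_start = frag.start
                    a.template_length = -frag.length
                out.write(a)
            n += 1
    return n


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path, on_no_cds: str = "warn") -> list[GeneModel]:
    """Parse protein-coding gene anchors (ATG/stop) from a GFF3 annotation.

    ATG and stop are derived from the CDS extremes of each gene, respecting
    strand; genes without CDS children are skipped with a warning (or raise
    when ``on_no_cds='raise'``).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        cds = list(db.children(g, featuretype="CDS"))
        if not cds:
            msg = f"gene {g.id} has no CDS feature; skipped"
            if on_no_cds == "raise":
                raise ValueError(msg)
            warnings.warn(msg)
            continue
        lo = min(c.start for c in cds) - 1  # GFF3 1-based closed -> 0-based
        hi = max(c.end for c in cds) - 1  # 0-based position of last CDS base
        if g.strand == "+":
            atg, stop = lo, hi
        elif g.strand == "-":
            atg, stop = hi, lo
        else:
            raise ValueError(f"gene {g.id} lacks a usable strand ({g.strand!r})")
        genes.append(GeneModel(g.id, g.seqid, g.strand, atg, stop))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in annotation")
    return genes


def write_gene_models_gff3(genes: Iterable[GeneModel], path) -> None:
    """Serialize gene models as GFF3 (gene + mRNA + single-CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span  # 0-based half-open
            start1, end1 = lo + 1, hi  # GFF3 1-based closed
            common = f"{g.chrom}\tnucpos\t"
            fh.write(
                f"{common}gene\t{start1}\t{end1}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{common}mRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{common}CDS\t{start1}\t{end1}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph dyad tracks


def write_dyad_track(track: DyadTrack, path) -> None:
    """Write a per-base track as run-length-merged bedGraph (0-based half-open).

    Every base is covered (zero runs included), so a round-trip read
    reproduces the per-base vectors exactly.
    """
    with open(path, "w") as fh:
        name = track.sample_id or "dyads"
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom in sorted(track.counts):
            v = track.counts[chrom]
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{chrom}: track contains non-finite values")
            if v.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [v.size]))
            is_int = np.issubdtype(v.dtype, np.integer)
            for s, e in zip(starts.tolist(), ends.tolist()):
                val = v[s]
                sval = str(int(val)) if is_int else repr(float(val))
                fh.write(f"{chrom}\t{s}\t{e}\t{sval}\n")


def read_dyad_track(path, sample_id: str | None = None) -> DyadTrack:
    """Read a bedGraph written by `write_dyad_track` back to per-base vectors."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    name = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "browser")):
                continue
            if line.startswith("track"):
                if 'name="' in line:
                    name = line.split('name="', 1)[1].split('"', 1)[0]
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
            chrom, s, e, val = parts
            spans.setdefault(chrom, []).append((int(s), int(e), float(val)))
    counts: dict[str, np.ndarray] = {}
    for chrom, ivs in spans.items():
        length = max(e for _, e, _ in ivs)
        vals = [v for _, _, v in ivs]
        integral = all(float(v).is_integer() for v in vals)
        v = np.zeros(length, dtype=np.int64 if integral else float)
        for s, e, val in ivs:
            v[s:e] = int(val) if integral else val
        counts[chrom] = v
    return DyadTrack(counts, sample_id=sample_id if sample_id is not None else name)


# ---------------------------------------------------------------------------
# gene sets and tables


def read_gene_set(
    path,
    label: str,
    annotation: Iterable[GeneModel] | set | None = None,
    on_missing: str = "warn",
) -> GeneSet:
    """Read a one-gene-id-per-line TSV (optional ``gene_id`` header) as a GeneSet.

    Ids absent from ``annotation`` (when given) trigger a warning or, with
    ``on_missing='raise'``, an error.
    """
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip().split("\t")[0]
            if not tok or tok.startswith("#"):
                continue
            if not ids and tok.lower() in ("gene_id", "gene", "id"):
                continue  # header
            ids.append(tok)
    unique = frozenset(ids)
    if not unique:
        warnings.warn(f"{path}: empty gene set {label!r}")
    if annotation is not None:
        known = {
            g.gene_id if isinstance(g, GeneModel) else g for g in annotation
        }
        missing = sorted(unique - known)
        if missing:
            msg = f"{label}: {len(missing)} ids absent from annotation (e.g. {missing[:3]})"
            if on_missing == "raise":
                raise ValueError(msg)
            warnings.warn(msg)
    return GeneSet(label=label, gene_ids=unique)


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\n")
        for gid in sorted(gene_set.gene_ids):
            fh.write(f"{gid}\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV serialization used by all result tables."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
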