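"""Stage 1: candidate cluster definition.

Strand-specific expression contigs (maximal islands of nonzero read
coverage) are merged across short gaps, thresholded on total read
support, length-filtered, and extended by a fixed flank F on both sides
to form candidate clusters. The gap-merge happens on raw islands first
and the read-count threshold is applied to the merged contig.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .config import Config
from .genomio import AlignedRead, Genome


@dataclass(frozen=True)
class Contig:
    chrom: str
    strand: str
    start: int
    end: int
    read_count: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Cluster:
    """A contig plus its 5'/3' flanks, clamped to the chromosome."""

    contig: Contig
    flank_start: int
    flank_end: int

    @property
    def id(self) -> str:
        c = self.contig
        return f"{c.chrom}:{c.strand}:{c.start}-{c.end}"


def find_contigs(reads: Sequence[AlignedRead], chrom: str, strand: str,
                 cluster_min_reads: int = 1) -> list[Contig]:
    """Maximal islands of nonzero coverage on (chrom, strand), keeping
    islands whose summed overlapping-read multiplicity meets the threshold."""
    selected = sorted((r for r in reads
                       if r.chrom == chrom and r.strand == strand),
                      key=lambda r: (r.start, r.end))
    contigs: list[Contig] = []
    cur_start = cur_end = None
    cur_count = 0
    for r in selected:
        if cur_end is not None and r.start <= cur_end:
            cur_end = max(cur_end, r.end)
            cur_count += r.multiplicity
        else:
            if cur_end is not None and cur_count >= cluster_min_reads:
                contigs.append(Contig(chrom, strand, cur_start, cur_end, cur_count))
            cur_start, cur_end, cur_count = r.start, r.end, r.multiplicity
    if cur_end is not None and cur_count >= cluster_min_reads:
        contigs.append(Contig(chrom, strand, cur_start, cur_end, cur_count))
    return contigs


def merge_contigs(contigs: Sequence[Contig], cluster_gap_size: int) -> list[Contig]:
    """Transitively merge neighbours whose gap is strictly below
    ``cluster_gap_size``; merged read counts are summed."""
    if not contigs:
        return []
    for prev, nxt in zip(contigs, contigs[1:]):
        if (prev.chrom, prev.strand) != (nxt.chrom, nxt.strand):
            raise ValueError("merge_contigs requires a single (chrom, strand)")
        if nxt.start < prev.end:
            raise ValueError("merge_contigs requires sorted, non-overlapping input")
    merged: list[Contig] = [contigs[0]]
    for nxt in contigs[1:]:
        prev = merged[-1]
        if nxt.start - prev.end < cluster_gap_size:
            merged[-1] = Contig(prev.chrom, prev.strand, prev.start, nxt.end,
                                prev.read_count + nxt.read_count)
        else:
            merged.append(nxt)
    return merged


def filter_contigs(contigs: Iterable[Contig], cluster_max_length: int) -> list[Contig]:
    """Discard contigs strictly longer than ``cluster_max_length``."""
    return [c for c in contigs if c.length <= cluster_max_length]


def extend_cluster(contig: Contig, cluster_flank_size: int,
                   chrom_length: int) -> Cluster:
    return Cluster(
        contig,
        flank_start=max(0, contig.start - cluster_flank_size),
        flank_end=min(chrom_length, contig.end + cluster_flank_size),
    )


def build_clusters(reads: Sequence[AlignedRead], genome: Genome,
                   config: Config) -> list[Cluster]:
    """Full stage-1 chain: islands -> gap merge -> read threshold ->
    length filter -> flank extension, independently per (chrom, strand)."""
    clusters: list[Cluster] = []
    keys = sorted({(r.chrom, r.strand) for r in reads})
    for chrom, strand in keys:
        islands = find_contigs(reads, chrom, strand, cluster_min_reads=1)
        merged = merge_contigs(islands, config.cluster_gap_size)
        supported = [c for c in merged if c.read_count >= config.cluster_min_reads]
        kept = filter_contigs(supported, config.cluster_max_length)
        chrom_length = len(genome.sequences[chrom])
        clusters.extend(extend_cluster(c, config.cluster_flank_size, chrom_length)
                        for c in kept)
    clusters.sort(key=lambda cl: (cl.contig.chrom, cl.contig.start,
                                  cl.contig.strand))
    return clusters


_CLUSTER_COLUMNS = ("id", "chrom", "strand", "contig_start", "contig_end",
                    "flank_start", "flank_end", "read_count")


def write_clusters(clusters: Sequence[Cluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CLUSTER_COLUMNS) + "\n")
        for cl in clusters:
            c = cl.contig
            fh.write("\t".join(map(str, (cl.id, c.chrom, c.strand, c.start,
                                         c.end, cl.flank_start, cl.flank_end,
                                         c.read_count))) + "\n")


def read_clusters(path: str | Path) -> list[Cluster]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "\t".join(_CLUSTER_COLUMNS):
        raise ValueError(f"{path} is not a cluster table")
    out = []
    for line in lines[1:]:
        (_, chrom, strand, cs, ce, fs, fe, rc) = line.split("\t")
        out.append(Cluster(Contig(chrom, strand, int(cs), int(ce), int(rc)),
                           int(fs), int(fe)))
    return out
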