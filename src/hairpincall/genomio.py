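"""Reference genome (FASTA) and strand-specific alignment (SAM) input.

All internal coordinates are 0-based half-open; conversion from SAM's
1-based convention happens here and nowhere else. Identical alignments
(chrom, start, end, strand) are collapsed into one record with a
multiplicity count -- the read model every downstream stage consumes.
"""

from __future__ import annotations

import logging
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


class GenomeError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class Genome:
    """Uppercase, DNA-alphabet (U normalized to T) reference sequences."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True, order=True)
class AlignedRead:
    """A collapsed alignment: identical placements share one record."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str  # '+' or '-'
    multiplicity: int = 1


def read_genome(path: str | Path) -> Genome:
    """Load a FASTA reference; headers are parsed up to the first whitespace.

    Sequences are uppercased and U->T normalized; characters outside
    {A,C,G,T,N} are mapped to N with a warning. Duplicate names and empty
    files are hard errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise GenomeError(f"duplicate sequence name '{name}' in {path}")
        seq = str(record.seq).upper().replace("U", "T")
        if not set(seq) <= _VALID:
            bad = sorted(set(seq) - _VALID)
            log.warning("genome %s: mapping non-IUPAC characters %s to N in %s",
                        path, bad, name)
            seq = "".join(c if c in _VALID else "N" for c in seq)
        sequences[name] = seq
    if not sequences:
        raise GenomeError(f"no FASTA records found in {path}")
    return Genome(sequences)


def _open_sam(path: str | Path, genome: Genome) -> pysam.AlignmentFile:
    has_sq = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("@"):
                break
            if line.startswith("@SQ"):
                has_sq = True
                break
    if not has_sq:
        # headerless SAM: synthesize @SQ lines from the reference genome
        header = "".join(f"@SQ\tSN:{name}\tLN:{length}\n"
                         for name, length in genome.lengths.items())
        tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
        tmp.write(header)
        tmp.write(Path(path).read_text())
        tmp.close()
        path = tmp.name
    return pysam.AlignmentFile(str(path), "r", check_sq=False)


def read_alignments(path: str | Path, genome: Genome,
                    primary_only: bool = False) -> list[AlignedRead]:
    """Read a SAM file into collapsed :class:`AlignedRead` records.

    Unmapped records (flag 0x4) are skipped; the strand comes from flag
    0x10; the aligned span is the reference-consuming CIGAR extent.
    Secondary/supplementary alignments are kept unless ``primary_only``
    (small RNA reads are frequently multi-mapping).
    """
    counts: Counter[tuple[str, int, int, str]] = Counter()
    with _open_sam(path, genome) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            if rec.cigarstring is None:
                log.warning("mapped record %s has CIGAR '*'; skipped",
                            rec.query_name)
                continue
            chrom = rec.reference_name
            if chrom not in genome:
                raise AlignmentError(
                    f"alignment references unknown chromosome '{chrom}'")
            start = rec.reference_start
            end = rec.reference_end  # CIGAR M/D/N/=/X extent
            if end is None or not (0 <= start < end <= len(genome.sequences[chrom])):
                raise AlignmentError(
                    f"alignment span [{start},{end}) outside '{chrom}'")
            strand = "-" if rec.is_reverse else "+"
            counts[(chrom, start, end, strand)] += 1
    return sorted(AlignedRead(c, s, e, st, m)
                  for (c, s, e, st), m in counts.items())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_sequence(genome: Genome, chrom: str, start: int, end: int,
                   strand: str = "+") -> str:
    """Extract [start, end) on ``strand``; minus-strand requests are
    reverse-complemented so the result reads 5'->3' on its own strand."""
    if chrom not in genome:
        raise GenomeError(f"unknown chromosome '{chrom}'")
    seq = genome.sequences[chrom]
    if not (0 <= start <= end <= len(seq)):
        raise GenomeError(
            f"interval [{start},{end}) out of bounds for '{chrom}' "
            f"(length {len(seq)})")
    sub = seq[start:end]
    return sub if strand == "+" else reverse_complement(sub)


def total_multiplicity(reads: Iterable[AlignedRead]) -> int:
    return sum(r.multiplicity for r in reads)
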