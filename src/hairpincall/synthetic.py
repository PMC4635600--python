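"""Ground-truthed synthetic data: genomes with implanted hairpin
precursors, sharply stacked mature/star reads, and diffuse degradation
background.

The generator gives exact truth geometry: each implanted precursor is a
GC-biased stem-loop whose mature locus sits on the 5' arm and whose star
follows from the 2-nt 3'-overhang rule on the constructed pairing. Point
defects (substitutions breaking single pairs) are placed on the 3' arm
*outside* the mature/star duplex, emulating the bulges real precursors
carry elsewhere in the stem while keeping the duplex geometry clean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .genomio import Genome, fetch_sequence, reverse_complement

DEFAULT_SPACING = 400  # >= 2 x default flank, so clusters never merge

_BASES = np.array(list("ACGT"))
_GC_BIASED = np.array([0.15, 0.35, 0.35, 0.15])  # A C G T
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class PrecursorTruth:
    """A constructed stem-loop with its duplex geometry (precursor-relative)."""

    sequence: str
    dot_bracket: str
    mature: tuple[int, int]  # 0-based half-open
    star: tuple[int, int]


@dataclass(frozen=True)
class ImplantedPrecursor:
    chrom: str
    start: int
    end: int
    strand: str
    mature_genomic: tuple[int, int]
    star_genomic: tuple[int, int]
    truth: PrecursorTruth


@dataclass
class SyntheticTruth:
    genome: Genome
    precursors: list[ImplantedPrecursor]
    background_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    seed: int | None = None


def _random_seq(n: int, rng: np.random.Generator,
                probs: np.ndarray | None = None) -> str:
    return "".join(rng.choice(_BASES, size=n, p=probs))


def make_precursor(arm_length: int, loop_length: int, n_defects: int,
                   rng: np.random.Generator, mature_length: int = 21,
                   mature_offset: int | None = None) -> PrecursorTruth:
    """Build a hairpin: GC-biased 5' arm, loop, reverse-complement 3' arm
    with ``n_defects`` pair-breaking substitutions outside the duplex."""
    if loop_length < 3:
        raise SyntheticError("loop_length >= 3 required")
    if arm_length < mature_length + 4:
        raise SyntheticError("arm too short for a mature locus")
    if mature_offset is None:
        mature_offset = int(rng.integers(2, arm_length - mature_length))
    if not 2 <= mature_offset <= arm_length - mature_length:
        raise SyntheticError("mature_offset leaves no room for the 3' overhangs")
    arm = _random_seq(arm_length, rng, _GC_BIASED)
    loop = _random_seq(loop_length, rng)
    seq = list(arm + loop + reverse_complement(arm))
    total = 2 * arm_length + loop_length
    mature = (mature_offset, mature_offset + mature_length)
    # 2-nt 3'-overhang star on the constructed pairing i <-> total-1-i
    star = (total - mature[1] + 2, total - mature[0] + 2)
    protected_lo, protected_hi = star[0] - 3, star[1] + 3
    available = [j for j in range(arm_length + loop_length, total)
                 if not protected_lo <= j < protected_hi]
    if n_defects > len(available):
        raise SyntheticError(
            f"infeasible: {n_defects} defects exceed the {len(available)} "
            "positions outside the mature/star duplex")
    for j in rng.choice(len(available), size=n_defects, replace=False):
        pos = available[int(j)]
        complement_base = seq[pos]
        choices = [b for b in "ACGT"
                   if b != complement_base
                   and b != _COMPLEMENT[seq[total - 1 - pos]]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    dot_bracket = "(" * arm_length + "." * loop_length + ")" * arm_length
    return PrecursorTruth("".join(seq), dot_bracket, mature, star)


def build_genome(length: int, n_precursors: int, gc: float = 0.5,
                 seed: int | np.random.Generator = 0,
                 arm_length: int = 60, loop_length: int = 8,
                 n_defects: int = 1, mature_length: int = 21,
                 spacing: int = DEFAULT_SPACING,
                 chrom: str = "chrS") -> SyntheticTruth:
    """Random background genome with disjoint implanted precursors on
    random strands, separated by at least ``spacing`` nt."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    plen = 2 * arm_length + loop_length
    needed = n_precursors * plen + (n_precursors + 1) * spacing
    if length < needed:
        raise SyntheticError(
            f"genome length {length} too small for {n_precursors} implants "
            f"with {spacing} nt spacing (need >= {needed})")
    background = list(_random_seq(length, rng, probs))
    # distribute the slack uniformly over the n+1 gaps
    slack = length - needed
    extra = np.sort(rng.integers(0, slack + 1, size=n_precursors)) if slack else \
        np.zeros(n_precursors, dtype=int)
    implants: list[ImplantedPrecursor] = []
    cursor = 0
    prev_extra = 0
    for i in range(n_precursors):
        cursor += spacing + (int(extra[i]) - prev_extra)
        prev_extra = int(extra[i])
        truth = make_precursor(arm_length, loop_length, n_defects, rng,
                               mature_length=mature_length)
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = cursor, cursor + plen
        implanted_seq = (truth.sequence if strand == "+"
                         else reverse_complement(truth.sequence))
        background[start:end] = list(implanted_seq)

        def to_genomic(rel: tuple[int, int]) -> tuple[int, int]:
            if strand == "+":
                return (start + rel[0], start + rel[1])
            return (end - rel[1], end - rel[0])

        implants.append(ImplantedPrecursor(
            chrom, start, end, strand,
            mature_genomic=to_genomic(truth.mature),
            star_genomic=to_genomic(truth.star),
            truth=truth))
        cursor = end
    genome = Genome({chrom: "".join(background)})
    return SyntheticTruth(genome=genome, precursors=implants,
                          seed=None if isinstance(seed, np.random.Generator)
                          else int(seed))


def simulate_reads(truth: SyntheticTruth, mature_depth: int, star_depth: int,
                   background_reads: int, jitter: int,
                   rng: np.random.Generator, sam_path: str | Path) -> int:
    """Write a SAM file: exact-coordinate mature/star stacks (with +-jitter
    on at most 10 % of reads) plus uniformly placed 18-26 nt background
    reads over non-implanted regions. Returns the record count."""
    genome = truth.genome
    chrom = next(iter(genome.sequences))
    chrom_len = len(genome.sequences[chrom])
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": name, "LN": ln}
                     for name, ln in genome.lengths.items()]}
    implant_intervals = [(p.start, p.end) for p in truth.precursors]

    def emit(out, name, start, end, strand):
        rec = pysam.AlignedSegment(out.header)
        rec.query_name = name
        rec.flag = 16 if strand == "-" else 0
        rec.reference_id = 0
        rec.reference_start = start
        rec.mapping_quality = 255
        rec.cigartuples = [(0, end - start)]
        rec.query_sequence = fetch_sequence(genome, chrom, start, end, strand)
        out.write(rec)

    def stack(out, prefix, interval, strand, depth):
        count = 0
        for i in range(depth):
            shift = 0
            if jitter > 0 and rng.random() < 0.10:
                shift = int(rng.integers(-jitter, jitter + 1))
            s = max(0, min(chrom_len - 1, interval[0] + shift))
            e = s + (interval[1] - interval[0])
            emit(out, f"{prefix}_{i}", s, e, strand)
            count += 1
        return count

    n_records = 0
    truth.background_loci = []
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for idx, pre in enumerate(truth.precursors):
            n_records += stack(out, f"mat{idx}", pre.mature_genomic,
                               pre.strand, mature_depth)
            n_records += stack(out, f"star{idx}", pre.star_genomic,
                               pre.strand, star_depth)
        for i in range(background_reads):
            while True:
                rlen = int(rng.integers(18, 27))
                s = int(rng.integers(0, chrom_len - rlen))
                if not any(s < e and s + rlen > b for b, e in implant_intervals):
                    break
            strand = "+" if rng.random() < 0.5 else "-"
            emit(out, f"bg{i}", s, s + rlen, strand)
            truth.background_loci.append((chrom, s, s + rlen, strand))
            n_records += 1
    return n_records


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "chromosomes": truth.genome.lengths,
        "precursors": [
            {"chrom": p.chrom, "start": p.start, "end": p.end,
             "strand": p.strand,
             "mature": list(p.mature_genomic), "star": list(p.star_genomic),
             "dot_bracket": p.truth.dot_bracket}
            for p in truth.precursors],
        "background_loci": [list(b) for b in truth.background_loci],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def simulate(out_dir: str | Path, seed: int = 42,
             genome_length: int = 100_000, n_precursors: int = 20,
             arm_length: int = 60, loop_length: int = 8, n_defects: int = 1,
             gc: float = 0.5, mature_depth: int = 100, star_depth: int = 10,
             background_reads: int = 2000, jitter: int = 1,
             mature_length: int = 21) -> SyntheticTruth:
    """One-call fixture generation: genome.fa + reads.sam + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth = build_genome(genome_length, n_precursors, gc=gc, seed=rng,
                         arm_length=arm_length, loop_length=loop_length,
                         n_defects=n_defects, mature_length=mature_length)
    truth.seed = seed
    simulate_reads(truth, mature_depth, star_depth, background_reads,
                   jitter, rng, out / "reads.sam")
    write_fasta(truth.genome, out / "genome.fa")
    write_truth_json(truth, out / "truth.json")
    return truth
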