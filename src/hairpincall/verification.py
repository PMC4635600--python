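"""Stage 3: coverage-based mature/star duplex verification.

A surviving candidate precursor is accepted only if its read coverage is
consistent with Dicer-like processing: at least one sharp read stack
(identical 5'/3' ends) holding more than ``min_coverage`` of the
precursor's reads, of mature length, whose star partner -- placed by the
2-nt 3'-overhang rule on the precursor's pair table -- also has duplex
length and satisfies the pairing constraints. Star *expression* is never
required; only star geometry is. Several disjoint mature loci on one
precursor are allowed (heterogeneous precursors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import Config
from .genomio import AlignedRead
from .significance import SignificanceResult
from .structure import FoldCandidate, StructureStats, pair_table

ANCHOR_SEARCH = 3  # nt an unpaired overhang anchor may move inward


class StarError(ValueError):
    """Star segment cannot be placed; message names the reason."""


@dataclass(frozen=True)
class MatureLocus:
    rel_start: int   # precursor-relative, 0-based half-open, 5'->3'
    rel_end: int
    read_support: int
    support_fraction: float
    arm: str         # '5p', '3p' or 'loop-spanning'

    @property
    def length(self) -> int:
        return self.rel_end - self.rel_start


@dataclass
class DuplexCall:
    mature: MatureLocus
    star_start: int  # precursor-relative half-open
    star_end: int
    checks: dict[str, bool]

    @property
    def star_length(self) -> int:
        return self.star_end - self.star_start

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


@dataclass
class PrecursorCall:
    cluster_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    dot_bracket: str
    mfe: float
    mfe_per_nt: float
    p_value: float
    null_mean: float
    null_sd: float
    stats: StructureStats
    duplexes: list[DuplexCall]
    total_reads: int
    flags: list[str] = field(default_factory=list)
    id: str = ""


@dataclass
class Rejection:
    cluster_id: str
    chrom: str
    strand: str
    start: int
    end: int
    reason: str


def _relative(read: AlignedRead, start: int, end: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return read.start - start, read.end - start
    return end - read.end, end - read.start


def _hairpin_loops(dot_bracket: str) -> list[tuple[int, int]]:
    """Unpaired spans enclosed by each innermost pair (terminal loops)."""
    loops = []
    last_open = -1
    for i, c in enumerate(dot_bracket):
        if c == "(":
            last_open = i
        elif c == ")" and last_open >= 0:
            loops.append((last_open + 1, i))
            last_open = -1
    return loops


def _arm(rel_start: int, rel_end: int, dot_bracket: str) -> str:
    loops = _hairpin_loops(dot_bracket)
    if not loops:
        return "loop-spanning"
    for ls, le in loops:
        if rel_start <= ls and rel_end >= le:
            return "loop-spanning"
    first_mid = sum(loops[0]) / 2
    return "5p" if (rel_start + rel_end) / 2 < first_mid else "3p"


def detect_mature_loci(reads: Sequence[AlignedRead], candidate: FoldCandidate,
                       config: Config) -> list[MatureLocus]:
    """Sharp read stacks qualifying as mature loci, greedily accepted by
    support (ties: 5'-most); overlapping weaker stacks are suppressed."""
    within = [r for r in reads
              if r.chrom == candidate.chrom and r.strand == candidate.strand
              and r.start < candidate.end and r.end > candidate.start]
    total = sum(r.multiplicity for r in within)
    if total == 0:
        return []
    # reads are already collapsed: each record is one exact-coordinate stack
    stacks = {(r.start, r.end): r.multiplicity for r in within}
    if config.edge_tolerance > 0:
        tol = config.edge_tolerance
        merged: dict[tuple[int, int], int] = {}
        for (s, e), m in sorted(stacks.items(),
                                key=lambda kv: (-kv[1], kv[0])):
            home = next((k for k in merged
                         if abs(k[0] - s) <= tol and abs(k[1] - e) <= tol), None)
            if home is not None:
                merged[home] += m
            else:
                merged[(s, e)] = m
        stacks = merged
    rel_stacks = []
    for (s, e), m in stacks.items():
        rs, re = _relative(AlignedRead(candidate.chrom, s, e, candidate.strand),
                           candidate.start, candidate.end, candidate.strand)
        rel_stacks.append((m, rs, re))
    rel_stacks.sort(key=lambda t: (-t[0], t[1]))
    accepted: list[MatureLocus] = []
    for m, rs, re in rel_stacks:
        fraction = m / total
        if not fraction > config.min_coverage:
            continue
        length = re - rs
        if not config.min_duplex_length <= length < config.max_duplex_length:
            continue
        if not (0 <= rs and re <= candidate.length):
            continue  # stack sticking out of the precursor window
        if any(rs < a.rel_end and re > a.rel_start for a in accepted):
            continue  # suppressed by a stronger overlapping stack
        accepted.append(MatureLocus(rs, re, m, fraction,
                                    _arm(rs, re, candidate.dot_bracket)))
    accepted.sort(key=lambda a: a.rel_start)
    return accepted


def _anchored_partner(partner: np.ndarray, anchor: int, inward: int) -> int:
    """Partner at ``anchor``, allowing the anchor to slide up to
    ANCHOR_SEARCH nt inward (direction ``inward`` = +1/-1) when unpaired."""
    for delta in range(ANCHOR_SEARCH + 1):
        pos = anchor + inward * delta
        if 0 <= pos < len(partner) and partner[pos] >= 0:
            return int(partner[pos])
    raise StarError("no star: duplex anchor unpaired beyond "
                    f"{ANCHOR_SEARCH} nt at position {anchor}")


def compute_star(mature: tuple[int, int], partner: np.ndarray) -> tuple[int, int]:
    """Place the star segment for a mature interval (precursor-relative,
    half-open) using the 2-nt 3'-overhang processing rule:

    star 5' end = partner(mature 3' end - 2),
    star 3' end = partner(mature 5' end) + 2.
    """
    m_start, m_end = mature
    m5, m3 = m_start, m_end - 1  # inclusive ends
    star5 = _anchored_partner(partner, m3 - 2, inward=-1)
    star3 = _anchored_partner(partner, m5, inward=+1) + 2
    if star5 > star3:
        raise StarError("no star: anchors map to a reversed interval")
    star = (star5, star3 + 1)
    n = len(partner)
    if star[0] < 0 or star[1] > n:
        raise StarError("no star: star interval outside precursor bounds")
    if star[0] < m_end and star[1] > m_start:
        raise StarError("no star: star overlaps the mature locus")
    return star


def _unpaired_runs(partner: np.ndarray, start: int, end: int) -> list[tuple[int, int]]:
    """Maximal runs of adjacent unpaired positions within [start, end),
    as (run_start, run_end) half-open."""
    runs = []
    i = start
    while i < end:
        if partner[i] < 0:
            j = i
            while j < end and partner[j] < 0:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def validate_duplex(mature: MatureLocus, star: tuple[int, int],
                    partner: np.ndarray, dot_bracket: str,
                    config: Config) -> DuplexCall:
    """Evaluate the processing-accuracy checks; verdicts, not exceptions."""
    m_start, m_end = mature.rel_start, mature.rel_end
    length = mature.length
    checks: dict[str, bool] = {}
    checks["mature_length"] = (config.min_duplex_length <= length
                               < config.max_duplex_length)
    star_len = star[1] - star[0]
    checks["star_length"] = (config.min_duplex_length <= star_len
                             < config.max_duplex_length)
    mature_partners = partner[m_start:m_end]
    paired = int((mature_partners >= 0).sum())
    checks["paired_fraction"] = paired / length >= config.min_paired_fraction
    checks["fold_back"] = not any(
        m_start <= p < m_end for p in mature_partners if p >= 0)
    runs = _unpaired_runs(partner, m_start, m_end)
    if config.allow_three_mismatches:
        # interior zone: 1-based mature positions 3 .. L-3
        ok = True
        for rs, re in runs:
            p1, p2 = rs - m_start + 1, re - m_start  # 1-based inclusive
            if p1 >= 3 and p2 <= length - 3 and (re - rs) >= 4:
                ok = False
        checks["interior_mismatch_run"] = ok
    if config.allow_two_terminal_mismatches:
        ok = True
        for rs, re in runs:
            p1, p2 = rs - m_start + 1, re - m_start
            touches_end = p1 <= 2 or p2 >= length - 1
            if touches_end and (re - rs) >= 3:
                ok = False
        checks["terminal_mismatch_run"] = ok
    return DuplexCall(mature=mature, star_start=star[0], star_end=star[1],
                      checks=checks)


def verify_precursor(candidate: FoldCandidate, stats: StructureStats,
                     significance: SignificanceResult,
                     reads: Sequence[AlignedRead], config: Config,
                     flags: Sequence[str] = ()) -> PrecursorCall | Rejection:
    """Run mature detection, star placement and duplex validation; emit a
    call iff at least one duplex passes every enabled check."""
    def reject(reason: str) -> Rejection:
        return Rejection(candidate.cluster_id, candidate.chrom,
                         candidate.strand, candidate.start, candidate.end,
                         reason)

    within = [r for r in reads
              if r.chrom == candidate.chrom and r.strand == candidate.strand
              and r.start < candidate.end and r.end > candidate.start]
    total = sum(r.multiplicity for r in within)
    if total == 0:
        return reject("no reads over precursor in verification alignment")
    matures = detect_mature_loci(within, candidate, config)
    if not matures:
        return reject("no qualifying mature read stack")
    partner = pair_table(candidate.dot_bracket)
    matures = sorted(matures, key=lambda m: (-m.read_support, m.rel_start))
    accepted: list[DuplexCall] = []
    failures: list[str] = []
    for mature in matures:
        try:
            star = compute_star((mature.rel_start, mature.rel_end), partner)
        except StarError as exc:
            failures.append(f"mature@{mature.rel_start}: {exc}")
            continue
        duplex = validate_duplex(mature, star, partner,
                                 candidate.dot_bracket, config)
        if not duplex.passed:
            first_fail = next(k for k, v in duplex.checks.items() if not v)
            failures.append(f"mature@{mature.rel_start}: failed {first_fail}")
            continue
        span = (min(mature.rel_start, star[0]), max(mature.rel_end, star[1]))
        overlap = any(
            span[0] < max(d.mature.rel_end, d.star_end)
            and span[1] > min(d.mature.rel_start, d.star_start)
            for d in accepted)
        if overlap:
            failures.append(f"mature@{mature.rel_start}: overlaps an "
                            "accepted duplex")
            continue
        accepted.append(duplex)
    if not accepted:
        return reject("; ".join(failures))
    accepted.sort(key=lambda d: d.mature.rel_start)
    return PrecursorCall(
        cluster_id=candidate.cluster_id, chrom=candidate.chrom,
        strand=candidate.strand, start=candidate.start, end=candidate.end,
        sequence=candidate.sequence, dot_bracket=candidate.dot_bracket,
        mfe=candidate.mfe, mfe_per_nt=candidate.mfe_per_nt,
        p_value=significance.p_value, null_mean=significance.null_mean,
        null_sd=significance.null_sd, stats=stats, duplexes=accepted,
        total_reads=total, flags=list(flags))
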