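"""Stage 2a: candidate-window folding, optimum selection, structure statistics.

Candidate precursor windows have their start in the cluster's 5' flank
and their end in the 3' flank; each is folded and scored by its
per-nucleotide minimum free energy (MFE/nt). The window with the lowest
MFE/nt is the candidate precursor, which must then satisfy three
structure constraints: MFE/nt at most ``min_mfe_per_nt``, fewer than
``max_hairpin_count`` terminal loops (N_term), and a longest
double-stranded segment (L_ds,max, tolerating two defects) of at least
``min_double_strand_length`` nt.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import Cluster
from .config import Config
from .fold import FoldBackend, FoldError, MIN_FOLD_LENGTH
from .genomio import Genome, fetch_sequence

log = logging.getLogger(__name__)

MAX_FLANK_SPAN = 3000  # cost guard: clusters wider than this are skipped


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class FoldCandidate:
    """One folded candidate precursor window."""

    cluster_id: str
    chrom: str
    strand: str
    start: int  # genomic, 0-based half-open
    end: int
    sequence: str       # 5'->3' on the precursor strand
    dot_bracket: str
    mfe: float          # kcal/mol

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mfe_per_nt(self) -> float:
        return self.mfe / self.length


@dataclass(frozen=True)
class StructureStats:
    n_terminal_loops: int
    l_ds_max: int
    paired_fraction: float
    length: int


@dataclass
class FilterVerdict:
    passed: bool
    reasons: list[str] = field(default_factory=list)


def pair_table(dot_bracket: str) -> np.ndarray:
    """Partner index per position (-1 when unpaired); errors on unbalanced
    or non dot-bracket input."""
    if not set(dot_bracket) <= set("()."):
        raise StructureError("structure is not plain dot-bracket")
    partner = np.full(len(dot_bracket), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return partner


def count_terminal_loops(dot_bracket: str) -> int:
    """N_term: hairpin loops, i.e. '(' followed (across dots) by ')'."""
    pair_table(dot_bracket)  # validation only
    count = 0
    last_bracket = ""
    for c in dot_bracket:
        if c == "(":
            last_bracket = "("
        elif c == ")":
            if last_bracket == "(":
                count += 1
            last_bracket = ")"
    return count


def longest_duplex(dot_bracket: str, max_interruptions: int = 2) -> int:
    """L_ds,max: longest single-helix run on either strand, in nt
    including interruptions.

    A run starts and ends on paired positions of the same bracket
    direction whose partners decrease monotonically; every unpaired
    position inside the run and every skipped position on the partner
    strand counts as one defect, with at most ``max_interruptions``
    defects in total.
    """
    partner = pair_table(dot_bracket)
    n = len(dot_bracket)
    best = 0
    for a in range(n):
        if partner[a] < 0:
            continue
        direction = dot_bracket[a]
        defects = 0
        pending = 0
        last = a
        best = max(best, 1)
        for q in range(a + 1, n):
            if partner[q] < 0:
                pending += 1
                continue
            if dot_bracket[q] != direction:
                break
            partner_gap = partner[last] - partner[q] - 1
            if partner_gap < 0:
                break  # different helix (non-monotonic partners)
            new_defects = defects + pending + partner_gap
            if new_defects > max_interruptions:
                break
            defects = new_defects
            pending = 0
            last = q
            best = max(best, last - a + 1)
    return best


def compute_stats(dot_bracket: str) -> StructureStats:
    partner = pair_table(dot_bracket)
    n = len(dot_bracket)
    paired = int((partner >= 0).sum())
    return StructureStats(
        n_terminal_loops=count_terminal_loops(dot_bracket),
        l_ds_max=longest_duplex(dot_bracket),
        paired_fraction=paired / n if n else 0.0,
        length=n,
    )


# ---------------------------------------------------------------------------
# candidate-window enumeration and optimum selection
# ---------------------------------------------------------------------------

def window_grid(cluster: Cluster, step: int) -> list[tuple[int, int]]:
    """All (start, end) windows: starts step through the 5' flank up to
    the contig start, ends from the contig end through the 3' flank."""
    c = cluster.contig
    starts = range(cluster.flank_start, c.start + 1, step)
    ends = range(c.end, cluster.flank_end + 1, step)
    return [(s, e) for s in starts for e in ends]


def _fold_windows(cluster: Cluster, genome: Genome, windows: Sequence[tuple[int, int]],
                  backend: FoldBackend, min_length: int) -> list[FoldCandidate]:
    c = cluster.contig
    out: list[FoldCandidate] = []
    for ws, we in windows:
        if we - ws < min_length:
            continue
        seq = fetch_sequence(genome, c.chrom, ws, we, c.strand)
        try:
            db, mfe = backend.fold(seq)
        except FoldError as exc:
            log.debug("cluster %s window [%d,%d): %s", cluster.id, ws, we, exc)
            continue
        out.append(FoldCandidate(cluster.id, c.chrom, c.strand, ws, we,
                                 seq, db, mfe))
    return out


def enumerate_candidates(cluster: Cluster, genome: Genome, config: Config,
                         backend: FoldBackend) -> list[FoldCandidate]:
    """Fold every grid window of the cluster (exhaustive enumeration)."""
    if cluster.flank_end - cluster.flank_start > MAX_FLANK_SPAN:
        log.warning("cluster %s spans %d nt (> %d); skipped", cluster.id,
                    cluster.flank_end - cluster.flank_start, MAX_FLANK_SPAN)
        return []
    windows = window_grid(cluster, config.window_step)
    return _fold_windows(cluster, genome, windows, backend,
                         max(2 * config.min_duplex_length, MIN_FOLD_LENGTH))


def _jaccard(a: FoldCandidate, b: FoldCandidate) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union if union else 1.0


def select_optimal(candidates: Sequence[FoldCandidate],
                   uniqueness_tolerance: float) -> tuple[FoldCandidate, bool]:
    """Minimum-MFE/nt candidate plus a uniqueness flag.

    Deterministic tie-break: lower MFE/nt, then longer window, then
    smaller start. The optimum is flagged non-unique when another
    candidate lies within ``uniqueness_tolerance`` kcal/mol/nt of it and
    covers a genomically different interval (Jaccard overlap < 0.5).
    """
    if not candidates:
        raise StructureError("select_optimal on empty candidate list")
    best = min(candidates,
               key=lambda c: (c.mfe_per_nt, -c.length, c.start))
    unique = True
    for other in candidates:
        if other is best or (other.start, other.end) == (best.start, best.end):
            continue
        if (other.mfe_per_nt <= best.mfe_per_nt + uniqueness_tolerance
                and _jaccard(best, other) < 0.5):
            unique = False
            break
    return best, unique


def locate_optimal(cluster: Cluster, genome: Genome, config: Config,
                   backend: FoldBackend) -> tuple[FoldCandidate, bool] | None:
    """Pipeline search for the optimal window without exhaustive folding.

    When the backend offers a local sliding-window scan, locally stable
    structures spanning the contig anchor a fine grid refinement at
    ``window_step``; otherwise a coarse grid is folded first and refined
    around its argmin. Returns None when the cluster yields no foldable
    window.
    """
    span = cluster.flank_end - cluster.flank_start
    if span > MAX_FLANK_SPAN:
        log.warning("cluster %s spans %d nt (> %d); skipped", cluster.id,
                    span, MAX_FLANK_SPAN)
        return None
    c = cluster.contig
    step = config.window_step
    min_len = max(2 * config.min_duplex_length, MIN_FOLD_LENGTH)
    folded: dict[tuple[int, int], FoldCandidate] = {}

    def fold_some(windows: Sequence[tuple[int, int]]) -> None:
        fresh = [w for w in windows if w not in folded]
        for cand in _fold_windows(cluster, genome, fresh, backend, min_len):
            folded[(cand.start, cand.end)] = cand

    def grid_near(anchor_start: int, anchor_end: int,
                  radius: int) -> list[tuple[int, int]]:
        starts = [s for s in range(cluster.flank_start, c.start + 1, step)
                  if abs(s - anchor_start) <= radius]
        ends = [e for e in range(c.end, cluster.flank_end + 1, step)
                if abs(e - anchor_end) <= radius]
        return [(s, e) for s in starts for e in ends]

    anchors: list[tuple[int, int]] = []
    if hasattr(backend, "local_scan"):
        seq = fetch_sequence(genome, c.chrom, cluster.flank_start,
                             cluster.flank_end, c.strand)
        hits = backend.local_scan(seq)
        spanning = []
        for h in hits:
            if c.strand == "+":
                gs, ge = cluster.flank_start + h.start, cluster.flank_start + h.end
            else:
                gs, ge = cluster.flank_end - h.end, cluster.flank_end - h.start
            if gs <= c.start and ge >= c.end:
                spanning.append((h.energy / (h.end - h.start), gs, ge))
        spanning.sort()
        anchors = [(gs, ge) for _, gs, ge in spanning[:3]]

    if anchors:
        for gs, ge in anchors:
            fold_some(grid_near(gs, ge, 2 * step))
    if not folded:
        # coarse-to-fine grid fallback
        def coarse_step(extent: int) -> int:
            return step * max(1, math.ceil((extent / step + 1) / 9))
        cs = max(coarse_step(c.start - cluster.flank_start),
                 coarse_step(cluster.flank_end - c.end), step)
        coarse = [(s, e)
                  for s in range(cluster.flank_start, c.start + 1, cs)
                  for e in range(c.end, cluster.flank_end + 1, cs)]
        fold_some(coarse)
        if folded:
            rough, _ = select_optimal(list(folded.values()),
                                      config.uniqueness_tolerance)
            fold_some(grid_near(rough.start, rough.end, cs))
    if not folded:
        log.info("cluster %s: no foldable candidate window", cluster.id)
        return None
    return select_optimal(list(folded.values()), config.uniqueness_tolerance)


def apply_structure_filters(candidate: FoldCandidate,
                            config: Config) -> tuple[FilterVerdict, StructureStats]:
    """The three structure constraints; stats are returned regardless."""
    stats = compute_stats(candidate.dot_bracket)
    reasons: list[str] = []
    if not candidate.mfe_per_nt <= config.min_mfe_per_nt:
        reasons.append(
            f"mfe_per_nt {candidate.mfe_per_nt:.4f} > {config.min_mfe_per_nt}")
    if not stats.n_terminal_loops < config.max_hairpin_count:
        reasons.append(f"hairpin count {stats.n_terminal_loops} >= "
                       f"{config.max_hairpin_count}")
    if not stats.l_ds_max >= config.min_double_strand_length:
        reasons.append(f"l_ds_max {stats.l_ds_max} < "
                       f"{config.min_double_strand_length}")
    return FilterVerdict(passed=not reasons, reasons=reasons), stats


def profile_precursors(fasta_path: str | Path, backend: FoldBackend) -> pd.DataFrame:
    """Fold each precursor sequence in a FASTA and tabulate MFE/nt,
    L_ds,max, N_term, paired fraction and length (feature profiling of a
    known precursor set)."""
    from Bio import SeqIO

    rows = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        try:
            db, mfe = backend.fold(seq)
        except FoldError as exc:
            log.warning("profile: skipping %s (%s)", record.id, exc)
            continue
        stats = compute_stats(db)
        rows.append({
            "id": record.id,
            "length": len(seq),
            "mfe": mfe,
            "mfe_per_nt": mfe / len(seq),
            "l_ds_max": stats.l_ds_max,
            "n_terminal_loops": stats.n_terminal_loops,
            "paired_fraction": stats.paired_fraction,
        })
    return pd.DataFrame(rows, columns=["id", "length", "mfe", "mfe_per_nt",
                                       "l_ds_max", "n_terminal_loops",
                                       "paired_fraction"])
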