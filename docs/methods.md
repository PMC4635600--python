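# Methods

## Overview

`hairpincall` identifies miRNA precursor loci from strand-specific small
RNA-seq alignments and a reference genome, without using cross-species
sequence conservation or existing annotation. It targets plants and
algae, whose precursor populations are heterogeneous: precursors can be
several hundred nt long, contain extra sub-hairpins and bulges, and
express more than one mature miRNA. The pipeline therefore scores every
candidate locus on three independent lines of evidence:

1. **Expression clustering.** Mapped reads are collapsed by identical
   (chromosome, start, end, strand) and scanned per strand for maximal
   islands of nonzero coverage. Islands closer than `cluster_gap_size`
   (default 10 nt, strictly less-than) are merged; the merged contig must
   carry at least `cluster_min_reads` (default 10) total read
   multiplicity and be at most `cluster_max_length` (default 2000 nt).
   The threshold is applied *after* gap merging, so two weak adjacent
   peaks can jointly qualify. Each surviving contig is extended by
   `cluster_flank_size` F (default 200 nt) on both sides, clamped to the
   chromosome, forming the candidate cluster. F should be at least the
   expected precursor length for the organism.

2. **Secondary structure.** Within a cluster, candidate precursor
   windows start in the 5' flank and end in the 3' flank. Each window is
   folded and scored by its length-normalised minimum free energy MFE/nt
   (kcal/mol/nt); the window minimising MFE/nt is the candidate
   precursor. Because |MFE/nt| grows as windows absorb more pairable
   sequence and shrinks roughly as 1/L with unpairable padding, the
   minimum localises the hairpin. The selected structure must satisfy
   three constraints: MFE/nt ≤ `min_mfe_per_nt`; number of terminal
   (hairpin) loops N_term < `max_hairpin_count` (default 4 — tolerant of
   the short spurious sub-hairpins long plant precursors acquire); and
   longest double-stranded segment L_ds,max ≥
   `min_double_strand_length`, where L_ds,max is the longest
   single-helix run on either strand, counted in nt including
   interruptions, allowing at most two defects (an unpaired position or
   one skipped partner-strand position each count as one defect; run
   ends must be paired, all paired positions must share bracket
   direction and have monotonically decreasing partners).

3. **Shuffle significance.** For each structurally qualifying candidate
   a per-sequence null distribution of MFE/nt is built from
   `permutation_count` (default 100) mono-nucleotide shuffles
   (Fisher-Yates; exact composition preserved), each refolded. The
   p-value is the add-one empirical estimate
   p = (1 + #{null ≤ observed}) / (n + 1), i.e. the empirical mass of
   the null at or below the observed MFE/nt; the pseudocount prevents
   p = 0 and ties count conservatively. No distributional assumption is
   made. A di-nucleotide (Eulerian-path) shuffle is available
   (`dinucleotide_shuffle`); for sequences ≳100 nt it produces
   indistinguishable nulls. p ≤ `max_pvalue` (default 0.05) is required;
   no multiple-testing correction is applied by default because the
   threshold is a fixed per-candidate constraint (`bh_correction`
   enables Benjamini-Hochberg).

4. **Duplex verification.** Reads over the candidate precursor (which
   may come from an independent alignment file for cross-verification)
   are grouped into exact-coordinate stacks — Dicer-like processing
   yields homogeneous 5'/3' ends, so sharp stacks are the signature of a
   mature miRNA (`edge_tolerance`, default 0, can absorb stacks whose
   ends differ by ≤2 nt). A stack is a mature locus candidate if it
   holds strictly more than `min_coverage` (default 0.10) of the
   precursor's total read multiplicity and its length L satisfies
   `min_duplex_length` ≤ L < `max_duplex_length` (defaults 20 and 25 —
   the 20–24 nt mature band). Stacks are accepted greedily by support
   (ties 5'-most); overlapping weaker stacks are suppressed; disjoint
   stacks may all be accepted, allowing multi-mature precursors. For
   each mature locus the star segment follows from the 2-nt 3'-overhang
   rule on the precursor pair table: star 5' = partner(mature 3' − 2),
   star 3' = partner(mature 5') + 2; an unpaired anchor may slide up to
   3 nt inward. The duplex then must pass: mature paired fraction ≥
   `min_paired_fraction` (default 0.67); no fold-back (no mature
   position paired within the mature); if `allow_three_mismatches`, no
   run of ≥4 adjacent unpaired mature positions lying entirely within
   1-based positions 3…L−3; if `allow_two_terminal_mismatches`, no run
   of ≥3 adjacent unpaired positions touching the two first or two last
   duplex positions; and star length within the duplex band. Star
   *expression* is never required — precursors whose star arm is
   unexpressed remain callable. A precursor is reported iff at least one
   duplex passes every enabled check; accepted duplexes may not overlap.

## Organism presets

Two presets capture the known contrast between plant and algal
precursor populations (algal precursors have longer double-stranded
segments and lower MFE/nt): `plants` sets `min_mfe_per_nt = -0.2`,
`min_double_strand_length = 18`; `algae` sets `-0.4` and `24`. These are
package defaults calibrated to that qualitative contrast, not
transcriptions of any published per-organism table, and every value is
user-overridable (`--set key=value`).

## Window search

The optimal window is defined over the grid {flank_start + i·step} ×
{contig_end + j·step} (`window_step` default 5 nt); windows shorter than
two duplex lengths are skipped, and clusters whose flank span exceeds
3000 nt are skipped with a warning (cost guard). Folding every grid
window is exhaustive but O((F/step)²) thermodynamic folds per cluster —
prohibitive on long flanks. The pipeline therefore locates the optimum
hierarchically: a sliding-window local-structure scan of the whole
cluster (RNALfold-style, one call) proposes locally stable structures
spanning the contig; fine grid windows within two steps of the best
anchors are folded and the minimum taken. Backends without a local scan
fall back to a coarse grid (≤9 positions per axis) refined around its
argmin at `window_step`. The exhaustive enumeration remains available
(`enumerate_candidates`) and the hierarchical search is pinned against
it on small clusters in the tests.

**Uniqueness.** The paper-style requirement that the optimum be unique
is recorded as a flag, not a rejection: the optimum is marked non-unique
when another evaluated window lies within `uniqueness_tolerance`
(default 0.01 kcal/mol/nt) of it *and* covers a genomically different
interval, operationalised as Jaccard overlap < 0.5 — neighbouring grid
windows of the same hairpin differ trivially and must not void
uniqueness.

## Folding backends

The default backend is the ViennaRNA thermodynamic MFE engine
(kcal/mol; pseudoknot-free dot-brackets). A bundled fallback
(`maxpair`) implements weighted base-pair maximization (GC=3, AU=2,
GU=1, +1 per stacked pair, minimum hairpin loop 3, numba-compiled) and
reports pseudo-energies of −0.35 per score unit. The fallback is
deliberately non-thermodynamic: it lets the library and test suite run
without the thermodynamics package, and published free-energy thresholds
are meaningless against it.

## Determinism and parallelism

Folding is embarrassingly parallel over clusters (`worker_count`).
Every per-cluster random stream is seeded from
(`seed`, crc32(cluster id)), results are assembled in input order, and
all intermediate files use fixed-precision formatting, so output is
byte-identical across runs, worker counts and stage-wise vs. full
execution. The three stages communicate only through plain-text
intermediates (`clusters.tsv`, `candidates.tsv`), making every stage
restartable.

Calls located twice — the mature-stack cluster and the star-stack
cluster of one precursor both anchor the same hairpin — are collapsed:
same-strand calls overlapping more than half of the shorter interval
keep the lowest-MFE/nt representative. Final ids are assigned in
(chromosome, start) order.

## Synthetic data generator

The generator emulates the structure of real small RNA libraries at
desk scale: a random background genome (configurable GC), implanted
stem-loop precursors (GC-biased arms, configurable arm/loop lengths) on
random strands with ≥400 nt spacing, exact-coordinate mature read
stacks (default depth 100) and star stacks (default 10), end jitter of
±1 nt on at most 10 % of stack reads (isomiR-like end heterogeneity),
and 18–26 nt background reads placed uniformly over non-implanted
regions (default 2000 per 100 kb — a degradation mimic). Pair-breaking
point defects (default 1 per precursor) are placed on the 3' arm
outside the mature/star duplex, emulating stem bulges while keeping the
truth duplex geometry exact, so `compute_star` on the constructed pair
table reproduces the constructed star by construction.

What the generator does **not** model: sequencing errors and quality
values, transcriptome-shaped background (real degradation tracks gene
models), multi-mapping read ambiguity, overlapping precursor families,
and true thermodynamic variability of precursor structures (arms are
near-perfect complements). Passing the end-to-end recovery test
therefore demonstrates the pipeline's mechanics — clustering, optimum
location, filtering, significance, duplex verification, strand handling
— not its recall on real libraries, where precursor structures are
weaker and background is structured.

## Problem sizes and numerical choices

The shipped end-to-end scenario uses a 100-kb genome with 20 implanted
precursors (arm 60, loop 8, 1 defect) and 2000 background reads; the
calibration checks use 50 random 150-nt sequences and 50 designed
hairpins with 99 shuffles each. These sizes make the full suite and the
acceptance script reproducible on a single CPU in minutes while keeping
every statistic away from small-number degeneracy. Energies are
float64 in memory and written with fixed precision (MFE 4 decimals,
MFE/nt and p 6 decimals). Degenerate inputs: empty read sets yield
empty cluster tables; unfoldable windows (e.g. poly-A) fold to the
all-unpaired structure at 0.0 kcal/mol; clusters with no foldable
window are dropped with a log message.

## Known limitations

* Pseudoknots are not representable; backends emitting pseudoknot
  annotation are rejected at the adapter boundary.
* Multi-mapping reads count once per alignment record (no fractional
  weighting); `primary_only` restricts to primary alignments.
* The hierarchical window search can in principle miss a global grid
  optimum whose basin escapes both the local scan and the coarse grid;
  the exhaustive enumeration is available when that risk matters.
* Expression is reported as raw read support, not normalised counts;
  isomiR cataloguing is out of scope.
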