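"""Stage orchestration with restartable plain-text intermediates.

Stages:

* ``cluster``  SAM + FASTA -> ``clusters.tsv``
* ``fold``     FASTA + clusters.tsv -> ``candidates.tsv`` (structure
  selection, constraint filtering and shuffle significance)
* ``coverage`` SAM + candidates.tsv -> final call table (BED/GTF/CSV/JSON)
  -- the SAM here may differ from the clustering SAM for independent
  cross-verification
* ``full``     chains the three stages through the same intermediates,
  so a stage-wise run and a full run are byte-identical.

Folding work is embarrassingly parallel over clusters; results are
collected in input order and every per-cluster random stream is seeded
from (config.seed, crc32(cluster id)), so output is independent of
worker count and scheduling.
"""

from __future__ import annotations

import csv
import logging
import time
import zlib
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path
from typing import Sequence

import numpy as np

from . import clustering, outputs, significance, structure, verification
from .clustering import Cluster
from .config import Config
from .fold import get_backend
from .genomio import Genome, read_alignments, read_genome

log = logging.getLogger(__name__)

STAGES = ("cluster", "fold", "coverage", "full")

CLUSTERS_FILE = "clusters.tsv"
CANDIDATES_FILE = "candidates.tsv"

_CAND_COLUMNS = (
    "cluster_id", "chrom", "strand", "start", "end", "length",
    "sequence", "dot_bracket", "mfe", "mfe_per_nt",
    "n_terminal_loops", "l_ds_max", "paired_fraction",
    "struct_pass", "fail_reasons", "unique",
    "p_value", "null_mean", "null_sd", "sig_pass",
)


class PipelineError(RuntimeError):
    pass


def _cluster_rng(config: Config, cluster_id: str) -> np.random.Generator:
    crc = zlib.crc32(cluster_id.encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, crc]))


def _process_cluster(args: tuple[Cluster, Genome, Config]) -> dict | None:
    """Fold one cluster, filter, and (when passing) score significance."""
    cluster, genome, config = args
    backend = get_backend(config.fold_backend)
    located = structure.locate_optimal(cluster, genome, config, backend)
    if located is None:
        return None
    candidate, unique = located
    verdict, stats = structure.apply_structure_filters(candidate, config)
    row = {
        "cluster_id": cluster.id,
        "chrom": candidate.chrom, "strand": candidate.strand,
        "start": candidate.start, "end": candidate.end,
        "length": candidate.length,
        "sequence": candidate.sequence, "dot_bracket": candidate.dot_bracket,
        "mfe": f"{candidate.mfe:.4f}",
        "mfe_per_nt": f"{candidate.mfe_per_nt:.6f}",
        "n_terminal_loops": stats.n_terminal_loops,
        "l_ds_max": stats.l_ds_max,
        "paired_fraction": f"{stats.paired_fraction:.6f}",
        "struct_pass": int(verdict.passed),
        "fail_reasons": " | ".join(verdict.reasons),
        "unique": int(unique),
        "p_value": "", "null_mean": "", "null_sd": "", "sig_pass": "",
    }
    if verdict.passed:
        rng = _cluster_rng(config, cluster.id)
        null = significance.null_distribution(
            candidate.sequence, config.permutation_count, backend, rng,
            dinucleotide=config.dinucleotide_shuffle)
        result = significance.empirical_p(candidate.mfe_per_nt, null)
        row["p_value"] = f"{result.p_value:.6f}"
        row["null_mean"] = f"{result.null_mean:.6f}"
        row["null_sd"] = f"{result.null_sd:.6f}"
        row["sig_pass"] = int(result.p_value <= config.max_pvalue)
    return row


def stage_cluster(config: Config, sam: str | Path, fasta: str | Path,
                  out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_genome(fasta)
    reads = read_alignments(sam, genome, primary_only=config.primary_only)
    clusters = clustering.build_clusters(reads, genome, config)
    path = out / CLUSTERS_FILE
    clustering.write_clusters(clusters, path)
    log.info("cluster stage: %d clusters -> %s", len(clusters), path)
    return path


def stage_fold(config: Config, fasta: str | Path, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    clusters_path = out / CLUSTERS_FILE
    if not clusters_path.exists():
        raise PipelineError("missing clusters.tsv: run cluster first")
    genome = read_genome(fasta)
    clusters = clustering.read_clusters(clusters_path)
    jobs = [(cl, genome, config) for cl in clusters]
    if config.worker_count > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.worker_count) as pool:
            results = list(pool.map(_process_cluster, jobs, chunksize=1))
    else:
        results = [_process_cluster(job) for job in jobs]
    rows = [r for r in results if r is not None]
    if config.bh_correction:
        scored = [r for r in rows if r["p_value"] != ""]
        adjusted = significance.bh_adjust(
            [float(r["p_value"]) for r in scored])
        for r, adj in zip(scored, adjusted):
            r["p_value"] = f"{adj:.6f}"
            r["sig_pass"] = int(adj <= config.max_pvalue)
    path = out / CANDIDATES_FILE
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CAND_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    log.info("fold stage: %d/%d clusters yielded candidates -> %s",
             len(rows), len(clusters), path)
    return path


def _load_candidates(path: Path):
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != list(_CAND_COLUMNS):
            raise PipelineError(f"{path} is not a candidate table")
        return list(reader)


def stage_coverage(config: Config, sam: str | Path, fasta: str | Path,
                   out_dir: str | Path) -> list[verification.PrecursorCall]:
    out = Path(out_dir)
    cand_path = out / CANDIDATES_FILE
    if not cand_path.exists():
        raise PipelineError("missing candidates.tsv: run fold first")
    genome = read_genome(fasta)
    reads = read_alignments(sam, genome, primary_only=config.primary_only)
    calls: list[verification.PrecursorCall] = []
    rejections: list[verification.Rejection] = []
    for row in _load_candidates(cand_path):
        if not (row["struct_pass"] == "1" and row["sig_pass"] == "1"):
            continue
        candidate = structure.FoldCandidate(
            cluster_id=row["cluster_id"], chrom=row["chrom"],
            strand=row["strand"], start=int(row["start"]),
            end=int(row["end"]), sequence=row["sequence"],
            dot_bracket=row["dot_bracket"], mfe=float(row["mfe"]))
        stats = structure.StructureStats(
            n_terminal_loops=int(row["n_terminal_loops"]),
            l_ds_max=int(row["l_ds_max"]),
            paired_fraction=float(row["paired_fraction"]),
            length=int(row["length"]))
        sig = significance.SignificanceResult(
            p_value=float(row["p_value"]),
            observed_mfe_per_nt=float(row["mfe_per_nt"]),
            null_mean=float(row["null_mean"]),
            null_sd=float(row["null_sd"]))
        flags = [] if row["unique"] == "1" else ["non-unique optimum"]
        outcome = verification.verify_precursor(candidate, stats, sig,
                                               reads, config, flags)
        if isinstance(outcome, verification.PrecursorCall):
            calls.append(outcome)
        else:
            rejections.append(outcome)
    table = outputs.build_call_table(calls, dedup=True)
    outputs.write_bed(table, out / "calls.bed")
    outputs.write_gtf(table, out / "calls.gtf")
    outputs.write_report(table, out / "calls.csv", out / "calls.json",
                         rejections)
    outputs.write_rejections(rejections, out / "rejections.csv")
    log.info("coverage stage: %d calls, %d rejections", len(table),
             len(rejections))
    return table


def run_stage(stage: str, config: Config, sam: str | Path | None = None,
              fasta: str | Path | None = None,
              out_dir: str | Path = ".",
              verify_sam: str | Path | None = None):
    """Dispatch one pipeline stage (or ``full`` for the whole chain).

    ``verify_sam`` lets the coverage stage use an alignment file
    different from the clustering input (independent cross-verification).
    """
    if stage not in STAGES:
        raise PipelineError(f"unknown stage '{stage}' (choose from {STAGES})")
    t0 = time.perf_counter()
    if stage in ("cluster", "full"):
        if sam is None or fasta is None:
            raise PipelineError("cluster stage needs --sam and --fasta")
        stage_cluster(config, sam, fasta, out_dir)
    if stage in ("fold", "full"):
        if fasta is None:
            raise PipelineError("fold stage needs --fasta")
        stage_fold(config, fasta, out_dir)
    result = None
    if stage in ("coverage", "full"):
        cov_sam = verify_sam or sam
        if cov_sam is None or fasta is None:
            raise PipelineError("coverage stage needs --sam and --fasta")
        result = stage_coverage(config, cov_sam, fasta, out_dir)
    log.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
    return result
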