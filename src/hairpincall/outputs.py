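"""Serialization of verified precursor calls: BED6, GTF2.2, CSV, JSON.

BED uses 0-based half-open coordinates, GTF 1-based inclusive; for every
feature GTF start = BED start + 1 and GTF end = BED end. The JSON report
mirrors the call table losslessly (including dot-brackets) plus a
rejection summary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .structure import StructureStats
from .verification import DuplexCall, MatureLocus, PrecursorCall, Rejection

TRACK_HEADER = 'track name="hairpincall" description="miRNA precursor calls"'


def _genomic(call: PrecursorCall, rel: tuple[int, int]) -> tuple[int, int]:
    if call.strand == "+":
        return call.start + rel[0], call.start + rel[1]
    return call.end - rel[1], call.end - rel[0]


def _score(call: PrecursorCall) -> int:
    return max(0, min(1000, int(round(-call.mfe_per_nt * 1000))))


def merge_overlapping_calls(calls: Sequence[PrecursorCall],
                            min_overlap: float = 0.5) -> list[PrecursorCall]:
    """Collapse near-duplicate calls of one locus (e.g. located once from
    the mature-stack cluster and once from the star-stack cluster): calls
    on one strand overlapping more than ``min_overlap`` of the shorter
    interval keep only the lowest-MFE/nt representative."""
    ranked = sorted(calls, key=lambda c: (c.mfe_per_nt, c.chrom, c.start))
    kept: list[PrecursorCall] = []
    for call in ranked:
        duplicate = False
        for other in kept:
            if (other.chrom, other.strand) != (call.chrom, call.strand):
                continue
            inter = min(other.end, call.end) - max(other.start, call.start)
            shorter = min(other.end - other.start, call.end - call.start)
            if inter > min_overlap * shorter:
                duplicate = True
                break
        if not duplicate:
            kept.append(call)
    return kept


def build_call_table(calls: Sequence[PrecursorCall],
                     dedup: bool = True) -> list[PrecursorCall]:
    """Stable ids, sorted by (chrom, start)."""
    table = merge_overlapping_calls(calls) if dedup else list(calls)
    table.sort(key=lambda c: (c.chrom, c.start, c.strand))
    per_chrom: dict[str, int] = {}
    for call in table:
        per_chrom[call.chrom] = per_chrom.get(call.chrom, 0) + 1
        call.id = f"mir-{call.chrom}-{per_chrom[call.chrom]}"
    return table


def _features(call: PrecursorCall):
    """(feature_type, name, genomic_start, genomic_end) per BED/GTF line."""
    yield "precursor", f"{call.id}.pre", call.start, call.end
    for k, duplex in enumerate(call.duplexes, start=1):
        ms, me = _genomic(call, (duplex.mature.rel_start, duplex.mature.rel_end))
        ss, se = _genomic(call, (duplex.star_start, duplex.star_end))
        tag = "" if len(call.duplexes) == 1 else f".d{k}"
        yield "mature", f"{call.id}{tag}.mature", ms, me
        yield "star", f"{call.id}{tag}.star", ss, se


def write_bed(table: Sequence[PrecursorCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(TRACK_HEADER + "\n")
        for call in table:
            score = _score(call)
            for _, name, start, end in _features(call):
                fh.write(f"{call.chrom}\t{start}\t{end}\t{name}\t{score}"
                         f"\t{call.strand}\n")


def write_gtf(table: Sequence[PrecursorCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for call in table:
            support = sum(d.mature.read_support for d in call.duplexes)
            attrs = (f'gene_id "{call.id}"; transcript_id "{call.id}"; '
                     f'p_value "{call.p_value:.6f}"; '
                     f'mfe_per_nt "{call.mfe_per_nt:.6f}"; '
                     f'read_support "{support}";')
            for feature, name, start, end in _features(call):
                fh.write(f"{call.chrom}\thairpincall\t{feature}\t{start + 1}"
                         f"\t{end}\t.\t{call.strand}\t.\t{attrs} "
                         f'feature_name "{name}";\n')


def _call_to_dict(call: PrecursorCall) -> dict:
    return {
        "id": call.id,
        "cluster_id": call.cluster_id,
        "chrom": call.chrom,
        "strand": call.strand,
        "start": call.start,
        "end": call.end,
        "sequence": call.sequence,
        "dot_bracket": call.dot_bracket,
        "mfe": call.mfe,
        "mfe_per_nt": call.mfe_per_nt,
        "p_value": call.p_value,
        "null_mean": call.null_mean,
        "null_sd": call.null_sd,
        "stats": dataclasses.asdict(call.stats),
        "total_reads": call.total_reads,
        "flags": list(call.flags),
        "duplexes": [
            {"mature": dataclasses.asdict(d.mature),
             "star_start": d.star_start,
             "star_end": d.star_end,
             "checks": dict(d.checks)}
            for d in call.duplexes],
    }


def _call_from_dict(data: dict) -> PrecursorCall:
    duplexes = [
        DuplexCall(mature=MatureLocus(**d["mature"]),
                   star_start=d["star_start"], star_end=d["star_end"],
                   checks=dict(d["checks"]))
        for d in data["duplexes"]]
    return PrecursorCall(
        cluster_id=data["cluster_id"], chrom=data["chrom"],
        strand=data["strand"], start=data["start"], end=data["end"],
        sequence=data["sequence"], dot_bracket=data["dot_bracket"],
        mfe=data["mfe"], mfe_per_nt=data["mfe_per_nt"],
        p_value=data["p_value"], null_mean=data["null_mean"],
        null_sd=data["null_sd"], stats=StructureStats(**data["stats"]),
        duplexes=duplexes, total_reads=data["total_reads"],
        flags=list(data["flags"]), id=data["id"])


def calls_to_json(table: Sequence[PrecursorCall],
                  rejections: Sequence[Rejection] = ()) -> str:
    summary: dict[str, int] = {}
    for rej in rejections:
        key = rej.reason.split(":")[0].split(";")[0].strip()
        summary[key] = summary.get(key, 0) + 1
    payload = {
        "calls": [_call_to_dict(c) for c in table],
        "rejection_summary": dict(sorted(summary.items())),
    }
    return json.dumps(payload, indent=1, sort_keys=True) + "\n"


def calls_from_json(text: str) -> tuple[list[PrecursorCall], dict[str, int]]:
    payload = json.loads(text)
    return ([_call_from_dict(c) for c in payload["calls"]],
            payload["rejection_summary"])


def write_report(table: Sequence[PrecursorCall], csv_path: str | Path,
                 json_path: str | Path,
                 rejections: Sequence[Rejection] = ()) -> pd.DataFrame:
    """CSV: one row per mature/star duplex with full statistics; JSON:
    lossless call table plus rejection summary counts."""
    rows = []
    for call in table:
        for k, duplex in enumerate(call.duplexes, start=1):
            ms, me = _genomic(call, (duplex.mature.rel_start,
                                     duplex.mature.rel_end))
            ss, se = _genomic(call, (duplex.star_start, duplex.star_end))
            rows.append({
                "id": call.id, "duplex": k, "chrom": call.chrom,
                "strand": call.strand,
                "precursor_start": call.start, "precursor_end": call.end,
                "precursor_length": call.end - call.start,
                "mfe": call.mfe, "mfe_per_nt": call.mfe_per_nt,
                "p_value": call.p_value,
                "n_terminal_loops": call.stats.n_terminal_loops,
                "l_ds_max": call.stats.l_ds_max,
                "paired_fraction": call.stats.paired_fraction,
                "mature_start": ms, "mature_end": me,
                "mature_length": duplex.mature.length,
                "mature_arm": duplex.mature.arm,
                "mature_reads": duplex.mature.read_support,
                "mature_fraction": duplex.mature.support_fraction,
                "star_start": ss, "star_end": se,
                "star_length": duplex.star_length,
                "total_reads": call.total_reads,
                "flags": ";".join(call.flags),
            })
    frame = pd.DataFrame(rows)
    frame.to_csv(csv_path, index=False)
    Path(json_path).write_text(calls_to_json(table, rejections))
    return frame


def write_rejections(rejections: Sequence[Rejection], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in rejections]
    pd.DataFrame(rows, columns=["cluster_id", "chrom", "strand", "start",
                                "end", "reason"]).to_csv(path, index=False)
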