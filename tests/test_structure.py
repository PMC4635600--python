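import random

import numpy as np
import pytest

from hairpincall.clustering import Cluster, Contig
from hairpincall.config import load_config
from hairpincall.fold import FoldError
from hairpincall.genomio import Genome
from hairpincall.structure import (FoldCandidate, StructureError,
                                   apply_structure_filters, compute_stats,
                                   count_terminal_loops, enumerate_candidates,
                                   locate_optimal, longest_duplex, pair_table,
                                   profile_precursors, select_optimal,
                                   window_grid)
from hairpincall.synthetic import make_precursor

from _oracles import brute_longest_duplex, brute_terminal_loops, \
    random_dot_bracket


def _candidate(start, end, mfe, cluster="c"):
    n = end - start
    return FoldCandidate(cluster, "chr1", "+", start, end, "A" * n,
                         "." * n, mfe)


# --- fold backend contract ----------------------------------------------

def test_fold_contract(maxpair):
    db, mfe = maxpair.fold("A" * 20)
    assert db == "." * 20 and mfe == 0.0
    stem = "G" * 20 + "AAAA" + "C" * 20
    db, mfe = maxpair.fold(stem)
    assert len(db) == len(stem)
    assert db.count("(") == 20 and db.count(")") == 20
    assert mfe < 0


def test_fold_rejects_bad_input(maxpair):
    with pytest.raises(FoldError, match="short"):
        maxpair.fold("ACGT")
    with pytest.raises(FoldError, match="non-nucleotide"):
        maxpair.fold("ACGTACGTXX")


def test_backends_agree_on_forced_stem(maxpair, vienna):
    stem = "G" * 20 + "AAAA" + "C" * 20
    for backend in (maxpair, vienna):
        db, mfe = backend.fold(stem)
        assert db == "(" * 20 + "...." + ")" * 20
        assert mfe < -10


# --- pair table and structure statistics --------------------------------

def test_pair_table_involution_and_errors():
    partner = pair_table("((((...))))")
    for i, p in enumerate(partner):
        if p >= 0:
            assert partner[p] == i and p != i
    for bad in ("(((", "())", "(a)"):
        with pytest.raises(StructureError):
            pair_table(bad)


@pytest.mark.parametrize("db,expected", [
    ("((((...))))", 1),
    ("((...))..((...))", 2),
    (".....", 0),
])
def test_terminal_loop_examples(db, expected):
    assert count_terminal_loops(db) == expected


@pytest.mark.parametrize("db,expected", [
    ("(" * 20 + "...." + ")" * 20, 20),
    ("((((.((((....))))))))", 9),
    ("......", 0),
])
def test_longest_duplex_examples(db, expected):
    assert longest_duplex(db) == expected


def test_structure_statistics_match_brute_force():
    rng = random.Random(2024)
    for _ in range(200):
        db = random_dot_bracket(rng.randint(10, 200), rng)
        assert count_terminal_loops(db) == brute_terminal_loops(db), db
        assert longest_duplex(db) == brute_longest_duplex(db), db


def test_terminal_loops_equal_tree_leaves():
    # for nested structures N_term is the leaf count of the pairing tree
    db = "((..((...))..((...((...))..((...))..))..))"
    assert count_terminal_loops(db) == 3  # three leaves in the pairing tree


# --- window enumeration and optimum selection ---------------------------

def _cluster(contig_start=300, contig_end=321, flank_start=100, flank_end=521):
    return Cluster(Contig("chr1", "+", contig_start, contig_end, 10),
                   flank_start, flank_end)


def test_window_grid_counts():
    grid = window_grid(_cluster(), step=100)
    assert len(grid) == 9
    assert {s for s, _ in grid} == {100, 200, 300}
    assert {e for _, e in grid} == {321, 421, 521}
    # degenerate: step spanning the whole flank -> single full window
    assert window_grid(_cluster(), step=1000) == [(100, 321)]


def test_enumerate_candidates_contract(maxpair):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    genome = Genome({"chr1": seq})
    cfg = load_config(overrides={"window_step": 100,
                                 "fold_backend": "maxpair"})
    cands = enumerate_candidates(_cluster(), genome, cfg, maxpair)
    # 9 grid windows, minus the contig-only one (21 nt, too short to hold
    # a mature/star duplex pair)
    assert len(cands) == 8
    for c in cands:
        assert len(c.dot_bracket) == len(c.sequence) == c.length
        assert c.mfe_per_nt * c.length == pytest.approx(c.mfe)


def test_select_optimal_minimum_and_uniqueness():
    lone = _candidate(0, 100, -30.0)
    assert select_optimal([lone], 0.01) == (lone, True)
    cands = [_candidate(0, 100, -30.0), _candidate(300, 400, -45.0),
             _candidate(600, 700, -42.0)]
    best, unique = select_optimal(cands, 0.01)
    assert best.mfe_per_nt == -0.45 and unique
    # exact tie over disjoint intervals: flagged non-unique
    tied = [_candidate(0, 100, -45.0), _candidate(300, 400, -45.0)]
    best, unique = select_optimal(tied, 0.01)
    assert best.start == 0 and not unique
    # a near-optimal window covering the SAME locus does not void uniqueness
    nested = [_candidate(0, 100, -45.0), _candidate(0, 105, -47.2)]
    _, unique = select_optimal(nested, 0.01)
    assert unique


def test_select_optimal_empty_errors():
    with pytest.raises(StructureError):
        select_optimal([], 0.01)


def test_locate_optimal_matches_exhaustive_on_small_grid(maxpair):
    rng = np.random.default_rng(3)
    pre = make_precursor(30, 6, 0, rng)
    seq = ("".join(rng.choice(list("ACGT"), size=40)) + pre.sequence
           + "".join(rng.choice(list("ACGT"), size=40)))
    genome = Genome({"chr1": seq})
    cluster = Cluster(Contig("chr1", "+", 45, 95, 10), 5, 135)
    cfg = load_config(overrides={"window_step": 5, "fold_backend": "maxpair"})
    exhaustive = enumerate_candidates(cluster, genome, cfg, maxpair)
    expected, _ = select_optimal(exhaustive, cfg.uniqueness_tolerance)
    located = locate_optimal(cluster, genome, cfg, maxpair)
    assert located is not None
    got, _ = located
    assert (got.start, got.end) == (expected.start, expected.end)
    assert got.mfe == pytest.approx(expected.mfe)


def test_mfe_per_nt_magnitude_shrinks_with_padding(vienna):
    rng = np.random.default_rng(8)
    stem = make_precursor(30, 6, 0, rng).sequence
    values = []
    for pad in (0, 10, 20, 40):
        seq = stem + "A" * pad
        _, mfe = vienna.fold(seq)
        values.append(mfe / len(seq))
    assert all(b >= a for a, b in zip(values, values[1:]))  # toward zero


# --- structure filters ---------------------------------------------------

def test_filter_hairpin_count_boundary(plants_config):
    db = "((...))" * 4
    cand = FoldCandidate("c", "chr1", "+", 0, len(db), "A" * len(db), db,
                         -20.0)
    verdict, stats = apply_structure_filters(cand, plants_config)
    assert stats.n_terminal_loops == 4
    assert not verdict.passed
    assert any("hairpin count" in r for r in verdict.reasons)


def test_filter_mfe_threshold():
    cfg = load_config(preset="algae")  # min_mfe_per_nt = -0.4
    db = "(" * 30 + "...." + ")" * 30
    cand = FoldCandidate("c", "chr1", "+", 0, 64, "G" * 30 + "AAAA" + "C" * 30,
                         db, -0.45 * 64)
    verdict, _ = apply_structure_filters(cand, cfg)
    assert not any("mfe_per_nt" in r for r in verdict.reasons)


def test_designed_hairpin_passes_all_filters(maxpair, plants_config, rng):
    pre = make_precursor(40, 6, 0, rng)
    db, mfe = maxpair.fold(pre.sequence)
    cand = FoldCandidate("c", "chr1", "+", 0, len(pre.sequence),
                         pre.sequence, db, mfe)
    verdict, stats = apply_structure_filters(cand, plants_config)
    assert verdict.passed, verdict.reasons
    assert stats.n_terminal_loops == 1
    assert stats.l_ds_max >= 18


# --- precursor profiling -------------------------------------------------

def test_profile_precursors_shape_and_determinism(tmp_path, maxpair, rng):
    seqs = [make_precursor(30, 5, 0, rng).sequence for _ in range(2)]
    fasta = tmp_path / "pre.fa"
    fasta.write_text(f">p1\n{seqs[0]}\n>p2\n{seqs[1]}\n>polyA\n{'A' * 40}\n")
    frame = profile_precursors(fasta, maxpair)
    assert list(frame["id"]) == ["p1", "p2", "polyA"]
    assert set(frame.columns) >= {"mfe_per_nt", "l_ds_max", "length"}
    assert frame.loc[2, "mfe_per_nt"] == 0.0  # unfoldable poly-A
    again = profile_precursors(fasta, maxpair)
    assert frame.equals(again)
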