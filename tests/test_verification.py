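import numpy as np
import pytest

from hairpincall.config import load_config
from hairpincall.genomio import AlignedRead
from hairpincall.significance import SignificanceResult
from hairpincall.structure import FoldCandidate, StructureStats, pair_table
from hairpincall.synthetic import make_precursor
from hairpincall.verification import (MatureLocus, PrecursorCall, Rejection,
                                      StarError, compute_star,
                                      detect_mature_loci, validate_duplex,
                                      verify_precursor)

from _oracles import perfect_partner


def _stem_partner():
    """Pair table: precursor length 60, pairs i <-> 59-i for i in [5,25]."""
    partner = np.full(60, -1, dtype=np.int64)
    for i in range(5, 26):
        partner[i] = 59 - i
        partner[59 - i] = i
    return partner


def test_star_from_overhang_rule():
    partner = _stem_partner()
    assert compute_star((5, 26), partner) == (36, 57)
    assert compute_star((36, 57), partner) == (5, 26)


def test_star_fails_in_terminal_loop():
    partner = _stem_partner()
    with pytest.raises(StarError, match="unpaired"):
        compute_star((27, 33), partner)  # loop positions have no partners


def test_star_involution_and_overhangs_on_random_hairpins():
    rng = np.random.default_rng(11)
    for _ in range(100):
        arm = int(rng.integers(28, 45))
        loop = int(rng.integers(3, 9))
        partner = np.array(perfect_partner(arm, loop))
        m_len = int(rng.integers(20, 25))
        m_start = int(rng.integers(2, arm - m_len))
        mature = (m_start, m_start + m_len)
        star = compute_star(mature, partner)
        assert compute_star(star, partner) == mature
        # each 3' end extends 2 nt past the partner of the other arm's run
        assert star[1] - 1 == partner[mature[0]] + 2
        assert mature[1] - 1 == partner[star[0]] + 2
        assert star[1] - star[0] == m_len


def _cand(sequence, dot_bracket, start=0, chrom="chr1", strand="+"):
    return FoldCandidate("cl", chrom, strand, start, start + len(sequence),
                         sequence, dot_bracket, -40.0)


def _stack(start, end, mult, chrom="chr1", strand="+"):
    return AlignedRead(chrom, start, end, strand, mult)


def test_detect_mature_loci_dominant_stack(plants_config):
    cand = _cand("A" * 120, "." * 120, start=1000)
    reads = [_stack(1010, 1031, 90)]
    reads += [_stack(1040 + 3 * i, 1040 + 3 * i + 22, 1) for i in range(10)]
    loci = detect_mature_loci(reads, cand, plants_config)
    dominant = [l for l in loci if l.read_support == 90]
    assert len(dominant) == 1
    assert dominant[0].support_fraction == pytest.approx(0.9)
    assert (dominant[0].rel_start, dominant[0].rel_end) == (10, 31)


def test_detect_mature_loci_length_bounds(plants_config):
    cand = _cand("A" * 100, "." * 100)
    short = [_stack(10, 29, 50)]  # 19 nt: below min_duplex_length
    assert detect_mature_loci(short, cand, plants_config) == []
    long_ = [_stack(10, 35, 50)]  # 25 nt: max_duplex_length is exclusive
    assert detect_mature_loci(long_, cand, plants_config) == []


def test_detect_mature_loci_two_disjoint_stacks(plants_config):
    cand = _cand("A" * 120, "." * 120)
    reads = [_stack(5, 26, 45), _stack(60, 81, 40)]
    reads += [_stack(90 + i, 90 + i + 20, 1) for i in range(15)]
    loci = detect_mature_loci(reads, cand, plants_config)
    assert [(l.rel_start, l.rel_end) for l in loci] == [(5, 26), (60, 81)]


def test_detect_mature_loci_suppresses_overlapping_weaker(plants_config):
    cand = _cand("A" * 100, "." * 100)
    reads = [_stack(10, 31, 60), _stack(15, 36, 30)]
    loci = detect_mature_loci(reads, cand, plants_config)
    assert len(loci) == 1 and loci[0].read_support == 60


def test_detect_mature_loci_minus_strand_coordinates(plants_config):
    cand = _cand("A" * 100, "." * 100, start=1000, strand="-")
    loci = detect_mature_loci([_stack(1070, 1091, 20, strand="-")],
                              cand, plants_config)
    assert [(l.rel_start, l.rel_end) for l in loci] == [(9, 30)]


def test_raising_min_coverage_never_adds_loci():
    cand = _cand("A" * 120, "." * 120)
    reads = [_stack(5, 26, 45), _stack(60, 81, 40), _stack(90, 111, 15)]
    counts = []
    for cov in (0.05, 0.10, 0.20, 0.40, 0.45):
        cfg = load_config(overrides={"min_coverage": cov})
        counts.append(len(detect_mature_loci(reads, cand, cfg)))
    assert counts == sorted(counts, reverse=True)


def _knockout(partner, positions):
    partner = partner.copy()
    for pos in positions:
        if partner[pos] >= 0:
            partner[partner[pos]] = -1
            partner[pos] = -1
    return partner


def _mature(start, end, support=50, fraction=0.5):
    return MatureLocus(start, end, support, fraction, "5p")


def test_validate_duplex_perfect_stem(plants_config):
    partner = np.array(perfect_partner(30, 6))
    mature = _mature(2, 23)
    star = compute_star((2, 23), partner)
    duplex = validate_duplex(mature, star, partner, "", plants_config)
    assert duplex.passed and duplex.checks["paired_fraction"]


def test_validate_duplex_interior_run_of_four_fails(plants_config):
    partner = np.array(perfect_partner(30, 6))
    # unpaired run at mature 1-based positions 8-11 (interior zone 3..L-3)
    partner = _knockout(partner, range(9, 13))
    mature = _mature(2, 23)
    star = compute_star((2, 23), partner)
    duplex = validate_duplex(mature, star, partner, "", plants_config)
    assert duplex.checks["interior_mismatch_run"] is False
    # a run of three interior mismatches is tolerated
    partner3 = _knockout(np.array(perfect_partner(30, 6)), range(9, 12))
    duplex3 = validate_duplex(mature, compute_star((2, 23), partner3),
                              partner3, "", plants_config)
    assert duplex3.checks["interior_mismatch_run"] is True


def test_validate_duplex_terminal_run_of_three_fails(plants_config):
    partner = _knockout(np.array(perfect_partner(30, 6)), range(2, 5))
    mature = _mature(2, 23)  # run touches mature 5' positions 1-3
    star = compute_star((2, 23), partner)
    duplex = validate_duplex(mature, star, partner, "", plants_config)
    assert duplex.checks["terminal_mismatch_run"] is False
    two = _knockout(np.array(perfect_partner(30, 6)), range(2, 4))
    duplex2 = validate_duplex(_mature(2, 23), compute_star((2, 23), two),
                              two, "", plants_config)
    assert duplex2.checks["terminal_mismatch_run"] is True


def test_validate_duplex_fold_back(plants_config):
    n = 66
    partner = np.full(n, -1, dtype=np.int64)
    # mature [2, 23) folds back on itself: internal hairpin 2..22
    for k in range(8):
        partner[2 + k] = 22 - k
        partner[22 - k] = 2 + k
    # give the remaining mature span partners on the 3' arm so a star exists
    for pos in range(11, 14):
        partner[pos] = n - 1 - pos
        partner[n - 1 - pos] = pos
    mature = _mature(2, 23)
    duplex = validate_duplex(mature, (40, 61), partner, "", plants_config)
    assert duplex.checks["fold_back"] is False


def test_disabled_mismatch_checks_are_not_evaluated():
    cfg = load_config(overrides={"allow_three_mismatches": False,
                                 "allow_two_terminal_mismatches": False})
    partner = _knockout(np.array(perfect_partner(30, 6)), range(9, 13))
    duplex = validate_duplex(_mature(2, 23), compute_star((2, 23), partner),
                             partner, "", cfg)
    assert "interior_mismatch_run" not in duplex.checks
    assert "terminal_mismatch_run" not in duplex.checks


def _verified_fixture(rng, star_reads=10):
    pre = make_precursor(40, 6, 0, rng, mature_offset=5)
    db = pre.dot_bracket
    cand = _cand(pre.sequence, db, start=500)
    sig = SignificanceResult(0.01, -0.5, -0.2, 0.05)
    stats = StructureStats(1, 40, 0.9, len(pre.sequence))
    reads = [_stack(500 + pre.mature[0], 500 + pre.mature[1], 80)]
    if star_reads:
        reads.append(_stack(500 + pre.star[0], 500 + pre.star[1], star_reads))
    return cand, stats, sig, reads, pre


def test_verify_precursor_end_to_end(plants_config, rng):
    cand, stats, sig, reads, pre = _verified_fixture(rng)
    call = verify_precursor(cand, stats, sig, reads, plants_config)
    assert isinstance(call, PrecursorCall)
    assert len(call.duplexes) == 1
    duplex = call.duplexes[0]
    assert (duplex.mature.rel_start, duplex.mature.rel_end) == pre.mature
    assert (duplex.star_start, duplex.star_end) == pre.star


def test_verify_precursor_without_star_expression(plants_config, rng):
    cand, stats, sig, reads, _ = _verified_fixture(rng, star_reads=0)
    call = verify_precursor(cand, stats, sig, reads, plants_config)
    assert isinstance(call, PrecursorCall)  # star reads are never required


def test_verify_precursor_loop_stack_rejected(plants_config, rng):
    pre = make_precursor(40, 21, 0, rng)  # wide loop to host a 21-nt stack
    cand = _cand(pre.sequence, pre.dot_bracket)
    sig = SignificanceResult(0.01, -0.5, -0.2, 0.05)
    stats = StructureStats(1, 40, 0.8, len(pre.sequence))
    reads = [_stack(40, 61, 50)]  # entirely inside the terminal loop
    outcome = verify_precursor(cand, stats, sig, reads, plants_config)
    assert isinstance(outcome, Rejection)
    assert "no star" in outcome.reason


def test_verify_precursor_zero_reads(plants_config, rng):
    cand, stats, sig, _, _ = _verified_fixture(rng)
    outcome = verify_precursor(cand, stats, sig, [], plants_config)
    assert isinstance(outcome, Rejection)
    assert "no reads" in outcome.reason
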