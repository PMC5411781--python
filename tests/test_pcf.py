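"""PCF module tests: physical coverage against a brute-force oracle,
scaffold splitting/retention rules, threshold calibration against
exhaustive search, refinement, and assembly statistics."""

import numpy as np
import pandas as pd
import pytest

from pcfkit import pcf as pcfm
from pcfkit import simdata, synteny
from pcfkit.pcf import (
    AdjacencyOracle,
    PhysicalCoverageTrack,
    SplitJoint,
    assembly_stats,
    build_pcfs,
    calibrate_threshold,
    physical_coverage,
    refine_pcfs,
)


def standard_scenario(seed, chimera_rate=0.1, p_chim_zero=1.0, n_pairs=60_000):
    """Full desk-scale simulation: 20 Mb, 10 inversions, 3 fusions,
    2 fissions, shredded with chimeras."""
    anc = simdata.default_ancestor()
    rng = np.random.default_rng(seed)
    plan = simdata.random_plan(anc, 10, 3, 2, rng)
    kary, truth = simdata.apply_rearrangements(anc, plan)
    scaffolds, pairs = simdata.shred_to_scaffolds(
        kary, truth, rng, chimera_rate=chimera_rate, n_pairs=n_pairs,
        p_chim_zero=p_chim_zero,
    )
    return anc, plan, kary, truth, scaffolds, pairs, rng


def make_pairs(rows):
    return pd.DataFrame(rows, columns=["scaffold", "start1", "end1", "start2",
                                       "end2", "orientation"])


# ---------------------------------------------------------------------------
# physical coverage


def test_no_pairs_gives_zero_everywhere():
    pairs = make_pairs([])
    assert physical_coverage(pairs, "s1", [0, 100, 10_000]).tolist() == [0, 0, 0]


def test_hand_counted_coverage():
    pairs = make_pairs([
        ("s1", 0, 10, 90, 100, "+-"),    # fragment [0, 100)
        ("s1", 50, 60, 140, 150, "+-"),  # fragment [50, 150)
    ])
    assert physical_coverage(pairs, "s1", [75])[0] == 2
    assert physical_coverage(pairs, "s1", [25])[0] == 1
    assert physical_coverage(pairs, "s1", [149])[0] == 1
    assert physical_coverage(pairs, "s1", [150])[0] == 0


def test_coverage_matches_brute_force_on_random_pairs(rng):
    n = 1_000
    starts = rng.integers(0, 90_000, size=n)
    inserts = rng.integers(300, 5_000, size=n)
    pairs = make_pairs([
        ("s1", s, s + 100, s + i - 100, s + i, "+-")
        for s, i in zip(starts, inserts)
    ])
    positions = rng.integers(0, 100_000, size=200)
    got = physical_coverage(pairs, "s1", positions)
    lo, hi = starts, starts + inserts
    for p, g in zip(positions, got):
        assert g == int(((lo <= p) & (p < hi)).sum())


def test_pairs_on_other_scaffolds_ignored():
    pairs = make_pairs([("s2", 0, 10, 90, 100, "+-")])
    assert physical_coverage(pairs, "s1", [50])[0] == 0


# ---------------------------------------------------------------------------
# threshold calibration


def joint(cov, status):
    sf = synteny.SynFrag("x", "s", 0, 1, "c", 0, 1, "+")
    j = SplitJoint("s", 0, 0, cov, sf, sf)
    if status != "untested":
        j.set_status(status)
    return j


def brute_force_threshold(confirmed, refuted):
    best_c, best_a = 0, -1
    for c in range(0, max(confirmed + refuted) + 2):
        a = sum(v >= c for v in confirmed) + sum(v < c for v in refuted)
        if a > best_a:
            best_a, best_c = a, c
    return best_c


def test_calibration_example():
    joints = [joint(c, "confirmed") for c in (5, 6, 7)] + \
        [joint(c, "refuted") for c in (0, 1)]
    assert calibrate_threshold(joints) == 2


def test_calibration_degenerate_all_confirmed():
    joints = [joint(c, "confirmed") for c in (4, 9, 2)]
    assert calibrate_threshold(joints) == 2


def test_calibration_all_untested_raises():
    with pytest.raises(ValueError, match="calibrate"):
        calibrate_threshold([joint(3, "untested")])


def test_calibration_ties_break_toward_smallest():
    # perfectly interleaved: several c maximize agreement; smallest wins
    joints = [joint(c, "confirmed") for c in (1, 3, 5)] + \
        [joint(c, "refuted") for c in (2, 4, 6)]
    expected = brute_force_threshold([1, 3, 5], [2, 4, 6])
    assert calibrate_threshold(joints) == expected


def test_calibration_equals_brute_force_on_random_sets():
    rng = np.random.default_rng(0)
    for _ in range(1_000):
        n_conf = int(rng.integers(1, 12))
        n_ref = int(rng.integers(1, 12))
        confirmed = rng.integers(0, 15, size=n_conf).tolist()
        refuted = rng.integers(0, 15, size=n_ref).tolist()
        joints = [joint(c, "confirmed") for c in confirmed] + \
            [joint(c, "refuted") for c in refuted]
        assert calibrate_threshold(joints) == brute_force_threshold(confirmed, refuted)


def test_status_transitions_only_from_untested():
    j = joint(3, "confirmed")
    with pytest.raises(ValueError, match="transitions only"):
        j.set_status("refuted")


# ---------------------------------------------------------------------------
# assembly statistics


def test_n50_single_member():
    assert assembly_stats([10])["n50"] == 10


def test_n50_hand_example():
    stats = assembly_stats([8, 5, 4, 3])
    assert stats["n50"] == 5
    assert stats["total_bp"] == 20
    assert stats["count"] == 4


def test_n50_matches_cumulative_sum_oracle(rng):
    for _ in range(100):
        lengths = rng.integers(1, 10_000, size=int(rng.integers(1, 40))).tolist()
        got = assembly_stats(lengths)["n50"]
        desc = sorted(lengths, reverse=True)
        acc, expect = 0, None
        for length in desc:
            acc += length
            if 2 * acc >= sum(lengths):
                expect = length
                break
        assert got == expect


def test_empty_input_gives_zeros():
    stats = assembly_stats([])
    assert stats["count"] == 0 and stats["n50"] == 0 and stats["total_bp"] == 0


def test_accuracy_ratio_is_scaffolds_over_sfs():
    stats = assembly_stats([100], n_sfs=40, n_scaffolds=34)
    assert stats["sf_scaffold_ratio"] == pytest.approx(0.85)


# ---------------------------------------------------------------------------
# build_pcfs behavior on constructed SF sets


def sf(sf_id, scaf, ts, te, chrom, rs, re, o="+"):
    return synteny.SynFrag(sf_id, scaf, ts, te, chrom, rs, re, o)


def uniform_pairs(scaffold, length, n=2_000, insert=3_000, rng=None):
    rng = rng or np.random.default_rng(1)
    starts = rng.integers(0, length - insert, size=n)
    return make_pairs([
        (scaffold, s, s + 100, s + insert - 100, s + insert, "+-") for s in starts
    ])


def test_two_colinear_scaffolds_chain_into_one_pcf():
    sfs = [
        sf("a", "s1", 0, 400_000, "chr1", 0, 400_000),
        sf("b", "s2", 0, 400_000, "chr1", 410_000, 810_000),
    ]
    cov = PhysicalCoverageTrack(make_pairs([]))
    adj = AdjacencyOracle.from_sfs(sfs, max_gap=150_000)
    pcfs, joints = build_pcfs(sfs, adj, adj, cov, threshold_c=1)
    assert len(pcfs) == 1
    assert [m.scaffold_id for m in pcfs[0].members] == ["s1", "s2"]
    assert joints == []


def test_internal_inversion_with_coverage_kept_intact(rng):
    # scaffold with a reference-order-preserving flank pair around an
    # inverted middle: comparative evidence holds at both joints, and
    # coverage is high; scaffold must stay intact
    sfs = [
        sf("a", "s1", 0, 300_000, "chr1", 0, 300_000, "+"),
        sf("b", "s1", 300_000, 600_000, "chr1", 300_000, 600_000, "-"),
        sf("c", "s1", 600_000, 900_000, "chr1", 600_000, 900_000, "+"),
    ]
    pairs = uniform_pairs("s1", 900_000, rng=rng)
    cov = PhysicalCoverageTrack(pairs)
    adj = AdjacencyOracle.from_sfs(sfs, max_gap=150_000)
    pcfs, joints = build_pcfs(sfs, adj, adj, cov, threshold_c=3)
    assert len(pcfs) == 1
    assert len(pcfs[0].members) == 1
    assert joints == []


def test_chimeric_scaffold_with_zero_coverage_split():
    sfs = [
        sf("a", "s1", 0, 500_000, "chr1", 0, 500_000),
        sf("b", "s1", 500_000, 1_000_000, "chr5", 2_000_000, 2_500_000),
    ]
    cov = PhysicalCoverageTrack(make_pairs([]))  # zero coverage everywhere
    adj = AdjacencyOracle.from_sfs(sfs, max_gap=150_000)
    pcfs, joints = build_pcfs(sfs, adj, adj, cov, threshold_c=1)
    assert len(joints) == 1
    assert joints[0].scaffold_id == "s1"
    members = sorted(m.scaffold_id for p in pcfs for m in p.members)
    assert len(members) == 2


def test_raising_threshold_never_reduces_split_joints(rng):
    _, _, kary, truth, scaffolds, pairs, _ = standard_scenario(31)
    blocks = simdata.alignment_blocks_from_scaffolds(scaffolds, kary, rng)
    sfs = synteny.detect_sfs(blocks, 150_000)
    cov = PhysicalCoverageTrack(pairs)
    adj = AdjacencyOracle.from_sfs(sfs, max_gap=150_000)
    counts = []
    for c in (0, 2, 5, 9, 14, 10**9):
        _, joints = build_pcfs(sfs, adj, adj, cov, threshold_c=c)
        counts.append(len(joints))
    assert counts == sorted(counts)


def test_no_base_loss_through_pcf_construction(rng):
    _, _, kary, truth, scaffolds, pairs, _ = standard_scenario(32)
    blocks = simdata.alignment_blocks_from_scaffolds(scaffolds, kary, rng)
    sfs = synteny.detect_sfs(blocks, 150_000)
    cov = PhysicalCoverageTrack(pairs)
    adj = AdjacencyOracle.from_sfs(sfs, max_gap=150_000)
    pcfs, joints = build_pcfs(sfs, adj, adj, cov, threshold_c=2)
    sf_span = {(s.target_seq, s.t_start, s.t_end) for s in sfs}
    covered = set()
    for p in pcfs:
        for m in p.members:
            for s in m.sfs:
                covered.add((s.target_seq, s.t_start, s.t_end))
    assert covered == sf_span


# ---------------------------------------------------------------------------
# split-joint narrowing


def test_abutting_sfs_give_testable_zero_gap():
    left = sf("a", "s1", 0, 100_000, "chr1", 0, 100_000)
    right = sf("b", "s1", 100_000, 200_000, "chr9", 0, 100_000)
    j = SplitJoint("s1", 100_000, 100_000, 0, left, right, testable=True)
    out = pcfm.find_split_joints([j], [])
    assert out[0].gap_len == 0
    assert out[0].testable


def test_gap_narrowed_by_fine_blocks_to_testable():
    left = sf("a", "s1", 0, 100_000, "chr1", 0, 100_000)
    right = sf("b", "s1", 120_000, 220_000, "chr9", 50_000, 150_000)
    j = SplitJoint("s1", 100_000, 120_000, 0, left, right, testable=False)
    fine = [
        synteny.AlignmentBlock("s1", 100_000, 108_000, "chr1", 100_000, 108_000, "+"),
        synteny.AlignmentBlock("s1", 112_000, 120_000, "chr9", 42_000, 50_000, "+"),
    ]
    out = pcfm.find_split_joints([j], fine)
    assert (out[0].gap_start, out[0].gap_end) == (108_000, 112_000)
    assert out[0].testable  # 4 kb < 6 kb


def test_gap_without_narrowing_stays_untestable():
    left = sf("a", "s1", 0, 100_000, "chr1", 0, 100_000)
    right = sf("b", "s1", 120_000, 220_000, "chr9", 50_000, 150_000)
    j = SplitJoint("s1", 100_000, 120_000, 0, left, right, testable=False)
    out = pcfm.find_split_joints([j], [])
    assert out[0].gap_len == 20_000
    assert not out[0].testable


# ---------------------------------------------------------------------------
# refinement


def _split_scenario():
    sfs = [
        sf("a", "s1", 0, 500_000, "chr1", 0, 500_000),
        sf("b", "s1", 500_000, 1_000_000, "chr5", 2_000_000, 2_500_000),
    ]
    cov = PhysicalCoverageTrack(make_pairs([]))
    adj = AdjacencyOracle.from_sfs(sfs, max_gap=150_000)
    return build_pcfs(sfs, adj, adj, cov, threshold_c=1)


def test_all_confirmed_welds_back_to_one_pcf():
    pcfs, joints = _split_scenario()
    joints[0].set_status("confirmed")
    refined = refine_pcfs(pcfs, joints)
    assert len(refined) == 1
    assert [m.scaffold_id for m in refined[0].members] == ["s1", "s1"]
    assert [m.start for m in refined[0].members] == [0, 500_000]


def test_refuted_joint_stays_split():
    pcfs, joints = _split_scenario()
    joints[0].set_status("refuted")
    refined = refine_pcfs(pcfs, joints)
    assert len(refined) == 2


def test_alternative_confirmed_swaps_member_order():
    pcfs, joints = _split_scenario()
    joints[0].set_status("alternative_confirmed")
    refined = refine_pcfs(pcfs, joints)
    assert len(refined) == 1
    assert [m.start for m in refined[0].members] == [500_000, 0]


def test_map_conflict_splits_at_weakest_junction():
    pcfs, joints = _split_scenario()
    joints[0].set_status("confirmed")
    welded = refine_pcfs(pcfs, joints)
    assert len(welded) == 1
    split_again = refine_pcfs(welded, [], map_conflicts=[welded[0].pcf_id])
    assert len(split_again) == 2
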