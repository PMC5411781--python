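"""Simulator tests: rearrangement bookkeeping against a per-base replay
oracle, shredding/chimera registration, coverage realism, feature-track
densities and probe maps."""

import numpy as np
import pandas as pd
import pytest

from pcfkit import simdata
from pcfkit.simdata import (
    AncestorGenome,
    RearrangementPlan,
    apply_rearrangements,
    karyotype_length,
)


# ---------------------------------------------------------------------------
# per-base replay oracle: apply the same ops on explicit base-label arrays


def _oracle_genome(ancestor):
    """Unique integer label per ancestor base (disjoint ranges per chromosome)."""
    return {
        name: np.arange(length, dtype=np.int64) + k * 10_000_000
        for k, (name, length) in enumerate(ancestor.chromosomes)
    }


def _oracle_apply(genome, plan):
    g = {k: v.copy() for k, v in genome.items()}
    for op in plan.ops:
        if op.kind == "inversion":
            chrom, start, end = op.args
            g[chrom][start:end] = g[chrom][start:end][::-1]
        elif op.kind == "fission":
            chrom, pos = op.args
            arr = g.pop(chrom)
            g[f"{chrom}.a"] = arr[:pos]
            g[f"{chrom}.b"] = arr[pos:]
        elif op.kind == "fusion":
            a, end_a, b, end_b = op.args
            arr_a = g.pop(a)
            arr_b = g.pop(b)
            if end_a == "start":
                arr_a = arr_a[::-1]
            if end_b == "end":
                arr_b = arr_b[::-1]
            g[f"{a}+{b}"] = np.concatenate([arr_a, arr_b])
    return g


def _expand(karyotype, genome):
    """Base labels implied by segment bookkeeping."""
    out = {}
    for chrom, segs in karyotype.items():
        parts = []
        for seg in segs:
            arr = genome[seg.chrom][seg.start:seg.end]
            parts.append(arr if seg.strand == 1 else arr[::-1])
        out[chrom] = np.concatenate(parts)
    return out


def test_empty_plan_is_identity(tiny_ancestor):
    kary, truth = apply_rearrangements(tiny_ancestor, RearrangementPlan())
    assert list(kary) == ["A", "B"]
    assert karyotype_length(kary["A"]) == 500_000
    assert truth.ebrs == []


def test_single_fusion_merges_two_chromosomes(tiny_ancestor):
    plan = RearrangementPlan().fusion("A", "end", "B", "start")
    kary, truth = apply_rearrangements(tiny_ancestor, plan)
    assert list(kary) == ["A+B"]
    assert karyotype_length(kary["A+B"]) == 1_000_000
    fusions = [r for r in truth.ebrs if r.ebr_type == "fusion"]
    assert len(fusions) == 1
    assert fusions[0].descendant_pos == ("A+B", 500_000)
    # both ancestor flanks recorded
    assert set(fusions[0].anc_positions) == {("A", 500_000), ("B", 0)}


def test_random_plan_matches_per_base_replay_oracle(tiny_ancestor):
    rng = np.random.default_rng(7)
    plan = simdata.random_plan(
        tiny_ancestor, n_inversions=10, n_fusions=0, n_fissions=2, rng=rng,
        min_event_bp=20_000, max_event_bp=60_000, margin_bp=15_000,
        min_separation_bp=10_000,
    )
    kary, _ = apply_rearrangements(tiny_ancestor, plan)
    genome = _oracle_genome(tiny_ancestor)
    expected = _oracle_apply(genome, plan)
    got = _expand(kary, genome)
    assert set(got) == set(expected)
    for chrom in got:
        np.testing.assert_array_equal(got[chrom], expected[chrom])


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_conservation_of_total_length(tiny_ancestor, seed):
    rng = np.random.default_rng(seed)
    plan = simdata.random_plan(
        tiny_ancestor, 5, 1, 1, rng, min_event_bp=20_000, max_event_bp=50_000,
        margin_bp=15_000, min_separation_bp=10_000,
    )
    kary, truth = apply_rearrangements(tiny_ancestor, plan)
    assert sum(karyotype_length(s) for s in kary.values()) == tiny_ancestor.total_bp
    assert truth.ebr_counts() == {"intra": 5, "fusion": 1, "fission": 1}


def test_invalid_op_rejected_with_index(tiny_ancestor):
    plan = RearrangementPlan().inversion("A", 100, 600_001)
    with pytest.raises(ValueError, match="op 0"):
        apply_rearrangements(tiny_ancestor, plan)


def test_determinism_identical_seeds(desk_ancestor):
    def run(seed):
        rng = np.random.default_rng(seed)
        plan = simdata.random_plan(desk_ancestor, 6, 2, 1, rng)
        kary, truth = apply_rearrangements(desk_ancestor, plan)
        scaf, pairs = simdata.shred_to_scaffolds(kary, truth, rng, chimera_rate=0.2)
        return plan.ops, kary, pairs

    ops1, kary1, pairs1 = run(99)
    ops2, kary2, pairs2 = run(99)
    assert ops1 == ops2
    assert list(kary1) == list(kary2)
    for c in kary1:
        assert kary1[c] == kary2[c]
    pd.testing.assert_frame_equal(pairs1, pairs2)


# ---------------------------------------------------------------------------
# shredding


def test_chimera_rate_zero_gives_contiguous_scaffolds(tiny_ancestor, rng):
    kary, truth = apply_rearrangements(tiny_ancestor, RearrangementPlan())
    scaffolds, _ = simdata.shred_to_scaffolds(
        kary, truth, rng, mean_scaffold_bp=100_000, chimera_rate=0.0, n_pairs=1_000,
    )
    assert all(not s.is_chimeric for s in scaffolds)
    assert truth.chimeric_joints == []


def test_chimera_rate_one_registers_joints(tiny_ancestor, rng):
    kary, truth = apply_rearrangements(tiny_ancestor, RearrangementPlan())
    scaffolds, _ = simdata.shred_to_scaffolds(
        kary, truth, rng, mean_scaffold_bp=100_000, chimera_rate=1.0, n_pairs=1_000,
    )
    chimeric = [s for s in scaffolds if s.is_chimeric]
    assert chimeric, "chimera_rate 1 must produce chimeric scaffolds"
    for s in chimeric:
        assert len(s.pieces) == 2
    joints_by_scaffold = {j.scaffold_id for j in truth.chimeric_joints}
    assert {s.scaffold_id for s in chimeric} == joints_by_scaffold


def test_mean_physical_coverage_matches_lander_waterman(tiny_ancestor):
    rng = np.random.default_rng(42)
    kary, truth = apply_rearrangements(tiny_ancestor, RearrangementPlan())
    n_pairs, insert_mean = 20_000, 3_000.0
    scaffolds, pairs = simdata.shred_to_scaffolds(
        kary, truth, rng, mean_scaffold_bp=250_000, chimera_rate=0.0,
        n_pairs=n_pairs, insert_mean=insert_mean,
    )
    genome = sum(s.length for s in scaffolds)
    expected = n_pairs * insert_mean / genome
    # empirical coverage at interior positions of each scaffold
    spans = pairs.assign(
        lo=pairs[["start1", "start2"]].min(axis=1),
        hi=pairs[["end1", "end2"]].max(axis=1),
    )
    covs = []
    for s in scaffolds:
        sub = spans[spans["scaffold"] == s.scaffold_id]
        for p in range(10_000, s.length - 10_000, 25_000):
            covs.append(((sub["lo"] <= p) & (p < sub["hi"])).sum())
    assert covs
    assert abs(np.mean(covs) - expected) / expected < 0.10


def test_scaffold_below_insert_warns(tiny_ancestor, rng):
    kary, truth = apply_rearrangements(tiny_ancestor, RearrangementPlan())
    with pytest.warns(UserWarning, match="calibration unreliable"):
        simdata.shred_to_scaffolds(
            kary, truth, rng, mean_scaffold_bp=2_000, insert_mean=3_000.0,
            n_pairs=100,
        )


# ---------------------------------------------------------------------------
# feature tracks


def _fission_scenario(ancestor, seed=5):
    rng = np.random.default_rng(seed)
    plan = simdata.random_plan(
        ancestor, 0, 0, 2, rng, margin_bp=120_000, min_separation_bp=60_000,
    )
    kary, truth = apply_rearrangements(ancestor, plan)
    return rng, kary, truth


def test_zero_density_gives_empty_cne_track(tiny_ancestor):
    rng, kary, truth = _fission_scenario(tiny_ancestor)
    tracks = simdata.simulate_feature_tracks(
        tiny_ancestor, kary, truth, rng,
        cne_density_mshsb=0.0, cne_density_background=0.0,
    )
    assert tracks["cne"].empty


def test_fission_deserts_have_zero_cne_bases(tiny_ancestor):
    rng, kary, truth = _fission_scenario(tiny_ancestor)
    halfwidth = 50_000
    tracks = simdata.simulate_feature_tracks(
        tiny_ancestor, kary, truth, rng, desert_halfwidth_bp=halfwidth,
    )
    cne = tracks["cne"]
    fission_sites = [
        (c, p) for r in truth.ebrs if r.ebr_type == "fission"
        for c, p in r.anc_positions
    ]
    assert fission_sites
    for chrom, pos in fission_sites:
        lo, hi = pos - halfwidth, pos + halfwidth
        inside = cne[(cne["chrom"] == chrom) & (cne["start"] < hi) & (cne["end"] > lo)]
        bases = int((np.minimum(inside["end"], hi) - np.maximum(inside["start"], lo)).sum()) \
            if len(inside) else 0
        assert bases == 0


def test_realized_densities_within_3sd_of_element_draw_binomial(tiny_ancestor):
    rng = np.random.default_rng(11)
    kary, truth = apply_rearrangements(tiny_ancestor, RearrangementPlan())
    p_ms, p_bg = 0.11, 0.02
    tracks = simdata.simulate_feature_tracks(
        tiny_ancestor, kary, truth, rng,
        cne_density_mshsb=p_ms, cne_density_background=p_bg,
    )
    cne = tracks["cne"]
    el, cell = simdata.CNE_ELEMENT_BP, simdata.CNE_CELL_BP
    for chrom, start, end in tiny_ancestor.mshsb_intervals:
        sub = cne[(cne["chrom"] == chrom) & (cne["start"] >= start) & (cne["end"] <= end)]
        bases = int((sub["end"] - sub["start"]).sum())
        n_cells = (end - start) // cell
        q = p_ms * cell / el
        sd = np.sqrt(n_cells * q * (1 - q)) * el
        assert abs(bases - n_cells * q * el) < 3 * sd


# ---------------------------------------------------------------------------
# probes


def test_probe_map_order_equals_genomic_order_without_noise(tiny_ancestor, rng):
    kary, _ = apply_rearrangements(tiny_ancestor, RearrangementPlan())
    probes, cmap = simdata.plant_probes(kary, rng, spacing_bp=50_000,
                                        position_noise_sd=0.0)
    truth_order = probes.sort_values(["chrom", "true_pos"])
    for chrom, grp in cmap.groupby("chrom"):
        expected = truth_order[truth_order["chrom"] == chrom]["probe_id"].tolist()
        got = grp.sort_values("order_index")["probe_id"].tolist()
        assert got == expected


def test_probe_count_is_one_per_window_midpoint(rng):
    anc = AncestorGenome([("C", 10_000_000)])
    kary, _ = apply_rearrangements(anc, RearrangementPlan())
    probes, _ = simdata.plant_probes(kary, rng, spacing_bp=1_000_000)
    assert len(probes) == 10


def test_feature_distribution_pass_fraction_binomial(rng):
    from pcfkit.probes import classify_universal

    anc = AncestorGenome([("C", 400_000_000)])
    kary, _ = apply_rearrangements(anc, RearrangementPlan())
    # half of probes alignable enough, always a long CE: pass rate 0.5
    dists = {
        "alignable_fraction": ("choice", [0.90, 0.95], [0.5, 0.5]),
        "max_ce_len": ("constant", 400),
        "total_repeat_len": ("constant", 0),
        "has_ce_ge_3bp": ("constant", True),
    }
    rng3 = np.random.default_rng(3)
    probes, _ = simdata.plant_probes(kary, rng3, spacing_bp=1_000_000,
                                     feature_distributions=dists)
    assert len(probes) == 400
    passed = sum(
        classify_universal({
            "alignable_fraction": r.alignable_fraction, "max_ce_len": r.max_ce_len,
            "total_repeat_len": r.total_repeat_len, "has_ce_ge_3bp": r.has_ce_ge_3bp,
        }) == "universal_candidate"
        for r in probes.itertuples(index=False)
    )
    sd = np.sqrt(400 * 0.25)
    assert abs(passed - 200) < 3 * sd
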