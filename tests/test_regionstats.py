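"""Window-statistics tests: per-base oracles for densities, profiles
and distances; exact Mann-Whitney against independent enumeration; and
TE enrichment null/alternative behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pcfkit.ebr import EBR
from pcfkit import regionstats
from pcfkit.regionstats import (
    WindowTrack,
    compare_groups,
    flank_density_profile,
    mannwhitney_exact_p,
    te_enrichment,
    window_scan,
    zero_window_distances,
)


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# flank profiles


def test_flank_profile_hand_arithmetic():
    size = 10_000
    rec = EBR("c", 50_000, 60_000, "intra")
    # 1 kb of CNE inside each flank, none inside the EBR
    track = bed([("c", 31_000, 32_000), ("c", 42_000, 43_000),
                 ("c", 61_000, 62_000), ("c", 75_000, 76_000)])
    prof = flank_density_profile(rec, track, chrom_length=200_000)
    assert prof.densities == [0.1, 0.1, 0.0, 0.1, 0.1]


def test_flank_profile_chromosome_start_boundary():
    rec = EBR("c", 0, 10_000, "intra")
    prof = flank_density_profile(rec, bed([]), chrom_length=200_000)
    assert prof.densities[0] is None and prof.densities[1] is None
    assert prof.densities[2] == 0.0


def test_zero_length_ebr_rejected():
    with pytest.raises(ValueError, match="zero-length"):
        flank_density_profile(EBR("c", 5, 5, "intra"), bed([]), 1_000)


@pytest.mark.parametrize("seed", range(5))
def test_flank_profile_matches_per_base_oracle(seed):
    rng = np.random.default_rng(seed)
    L = 500_000
    starts = np.sort(rng.integers(0, L - 500, size=60))
    ends = starts + rng.integers(1, 500, size=60)
    ends[:-1] = np.minimum(ends[:-1], starts[1:])
    keep = ends > starts
    track = pd.DataFrame({"chrom": "c", "start": starts[keep], "end": ends[keep]})
    size = int(rng.integers(2_000, 30_000))
    start = int(rng.integers(2 * size, L - 3 * size))
    rec = EBR("c", start, start + size, "intra")
    prof = flank_density_profile(rec, track, L)

    mask = np.zeros(L, dtype=bool)
    for s, e in track[["start", "end"]].itertuples(index=False):
        mask[s:e] = True
    for k, d in zip((-2, -1, 0, 1, 2), prof.densities):
        lo = start + k * size
        assert d == pytest.approx(mask[lo:lo + size].sum() / size)


# ---------------------------------------------------------------------------
# window scan


def test_uniform_mshsb_genome_mean_density_recovered(rng):
    # one 2-Mb chromosome fully inside an msHSB with known density
    from pcfkit import simdata
    anc = simdata.AncestorGenome([("c", 2_000_000)],
                                 [("c", 0, 2_000_000)])
    kary, truth = simdata.apply_rearrangements(anc, simdata.RearrangementPlan())
    tracks = simdata.simulate_feature_tracks(anc, kary, truth, rng,
                                             cne_density_mshsb=0.11)
    track = window_scan({"c": 2_000_000}, tracks["cne"],
                        [("c", 0, 2_000_000)], [])
    means = track.class_means()
    assert set(track.table["class"]) == {"msHSB"}
    q = 0.11 * 1_000 / 200
    sd = np.sqrt(q * (1 - q) / 2_000) * 0.2
    assert abs(means["msHSB"] - 0.11) < 3 * sd


def test_windows_below_half_coverage_excluded():
    cov = bed([("c", 0, 2_500)])  # window 2 covered 500/1000 -> unusable
    track = window_scan({"c": 4_000}, bed([]), [], [], w=1_000,
                        coverage_track=cov)
    assert track.table["usable"].tolist() == [True, True, False, False]


def test_ebr_label_wins_over_mshsb():
    rec = EBR("c", 2_000_000, 2_050_000, "fission")
    track = window_scan({"c": 4_000_000}, bed([]),
                        [("c", 0, 4_000_000)], [rec])
    sub = track.table[(track.table["start"] >= 2_000_000)
                      & (track.table["end"] <= 2_050_000)]
    assert set(sub["class"]) == {"fission_EBR"}


def test_short_mshsb_not_labeled():
    track = window_scan({"c": 3_000_000}, bed([]),
                        [("c", 0, 1_400_000)], [])
    assert set(track.table["class"]) == {"rest"}


def test_terminal_short_window_dropped():
    track = window_scan({"c": 2_500}, bed([]), [], [], w=1_000)
    assert len(track.table) == 2


# ---------------------------------------------------------------------------
# zero-window distances


def windows(densities, chrom="c", w=1_000, classes=None):
    n = len(densities)
    table = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * w,
        "end": (np.arange(n) + 1) * w,
        "covered_bases": w,
        "cne_bases": (np.asarray(densities) * w).astype(int),
        "te_bases": 0,
        "class": classes if classes is not None else ["rest"] * n,
        "usable": True,
    })
    table["cne_density"] = table["cne_bases"] / w
    return WindowTrack(width=w, table=table)


def test_distance_hand_example():
    track = windows([0.11, 0.0, 0.0, 0.12])
    dist, _ = zero_window_distances(track, mshsb_mean_density=0.11)
    assert sorted(dist["rest"].tolist()) == [1, 1]


def test_chromosome_without_qualifying_window_excluded_and_tallied():
    track = windows([0.0, 0.05, 0.0])
    dist, excluded = zero_window_distances(track, mshsb_mean_density=0.11)
    assert dist["rest"].size == 0
    assert excluded["rest"] == 2


def test_uniform_high_density_gives_empty_distance_set():
    track = windows([0.2, 0.3, 0.25])
    dist, excluded = zero_window_distances(track, mshsb_mean_density=0.11)
    assert all(v.size == 0 for v in dist.values())
    assert all(v == 0 for v in excluded.values())


@pytest.mark.parametrize("seed", range(10))
def test_distances_match_brute_force_search(seed):
    rng = np.random.default_rng(seed)
    dens = rng.choice([0.0, 0.05, 0.12, 0.3], size=200,
                      p=[0.5, 0.2, 0.2, 0.1])
    track = windows(dens)
    dist, _ = zero_window_distances(track, mshsb_mean_density=0.11)
    qualify = np.where(dens >= 0.11)[0]
    expected = []
    for i in np.where(dens == 0.0)[0]:
        if qualify.size:
            expected.append(int(np.abs(qualify - i).min()))
    assert sorted(dist["rest"].tolist()) == sorted(expected)


def test_distance_symmetric_under_coordinate_reversal(rng):
    dens = rng.choice([0.0, 0.12], size=100, p=[0.7, 0.3])
    fwd, _ = zero_window_distances(windows(dens), mshsb_mean_density=0.11)
    rev, _ = zero_window_distances(windows(dens[::-1]), mshsb_mean_density=0.11)
    assert sorted(fwd["rest"].tolist()) == sorted(rev["rest"].tolist())


# ---------------------------------------------------------------------------
# group comparisons


def _enumeration_p(x, y):
    """Independent oracle: exhaustive relabeling p for |U - nm/2|."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, m = len(x), len(y)
    center = n * m / 2
    obs = abs(ranks[:n].sum() - n * (n + 1) / 2 - center)
    hits = total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        hits += abs(u - center) >= obs - 1e-9
        total += 1
    return hits / total


@pytest.mark.parametrize("seed", range(8))
def test_exact_mannwhitney_equals_full_enumeration(seed):
    rng = np.random.default_rng(seed)
    n, m = int(rng.integers(2, 9)), int(rng.integers(2, 9))
    x = rng.integers(0, 6, size=n).astype(float)  # ties likely
    y = rng.integers(0, 6, size=m).astype(float)
    assert mannwhitney_exact_p(x, y) == pytest.approx(_enumeration_p(x, y))


def test_exact_mannwhitney_matches_scipy_without_ties():
    rng = np.random.default_rng(33)
    for _ in range(10):
        x = rng.permutation(20)[:6].astype(float)
        y = (rng.permutation(20)[:5] + 100).astype(float) \
            if rng.random() < 0.5 else rng.permutation(40)[6:12].astype(float) + 0.5
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert mannwhitney_exact_p(x, y) == pytest.approx(res.pvalue)


def test_identical_groups_omnibus_p_near_one():
    g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    comp = compare_groups({"a": g, "b": g.copy(), "c": g.copy()})
    assert comp.omnibus_p > 0.9
    assert comp.pairwise.empty  # no pairwise tests without omnibus signal


def test_shifted_groups_recover_median_ordering():
    rng = np.random.default_rng(5)
    shift = {"msHSB": 4, "intra": 19, "fusion": 23, "fission": 35}
    samples = {k: rng.exponential(5.0, size=200) + v for k, v in shift.items()}
    comp = compare_groups(samples)
    assert comp.omnibus_p < 0.05
    medians = {k: v["median"] for k, v in comp.groups.items()}
    assert medians["msHSB"] < medians["intra"] < medians["fusion"] < medians["fission"]
    assert len(comp.pairwise) == 6
    assert "p_adj" in comp.pairwise


def test_undersized_group_excluded_with_warning():
    with pytest.warns(UserWarning, match="excluded"):
        comp = compare_groups({"a": np.arange(10.0), "b": np.arange(10.0) + 5,
                               "c": np.array([1.0])})
    assert "c" not in comp.groups


# ---------------------------------------------------------------------------
# TE enrichment


def _te_track(rng, chrom_len, density, family="LTR-ERV1", boost=None):
    rows = []
    n_cells = chrom_len // 1_000
    q = np.full(n_cells, density * 1_000 / 500)
    if boost is not None:
        lo, hi, factor = boost
        cells = slice(lo // 1_000, hi // 1_000)
        q[cells] = np.minimum(q[cells] * factor, 1.0)
    hit = rng.random(n_cells) < q
    for c in np.where(hit)[0]:
        s = c * 1_000
        rows.append(("t1", s, s + 500, family))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


def _intra_ebrs(intervals):
    out = []
    for lo, hi in intervals:
        rec = EBR("refc", lo, hi, "intra", target_chrom="t1")
        rec.extra["target_interval"] = ("t1", lo, hi)
        out.append(rec)
    return out


def test_uniform_te_placement_not_significant():
    rng = np.random.default_rng(2)
    track = _te_track(rng, 3_000_000, 0.03)
    ebrs = _intra_ebrs([(500_000, 540_000), (1_500_000, 1_540_000)])
    out = te_enrichment(track, ebrs, {"t1": 3_000_000})
    assert len(out) == 1
    assert not out["significant"].any()


def test_doubled_density_in_ebr_windows_detected():
    rng = np.random.default_rng(9)
    intervals = [(i * 300_000, i * 300_000 + 50_000) for i in range(1, 10)]
    q_track = _te_track(rng, 3_000_000, 0.03)
    boosted = []
    for lo, hi in intervals:
        boosted.append(_te_track(rng, hi - lo, 0.09).assign(
            start=lambda d: d["start"] + lo, end=lambda d: d["end"] + lo))
    track = pd.concat([q_track[~q_track.apply(
        lambda r: any(lo <= r["start"] < hi for lo, hi in intervals), axis=1)]]
        + boosted).sort_values("start").reset_index(drop=True)
    out = te_enrichment(track, _intra_ebrs(intervals), {"t1": 3_000_000})
    assert out.iloc[0]["mean_density_ebr"] > out.iloc[0]["mean_density_other"]
    assert out.iloc[0]["p_adj"] < 0.05


def test_short_element_family_skipped():
    track = pd.DataFrame({"chrom": ["t1"] * 5,
                          "start": [0, 10_000, 20_000, 30_000, 40_000],
                          "end": [50, 10_050, 20_050, 30_050, 40_050],
                          "family": "SINE-short"})
    out = te_enrichment(track, _intra_ebrs([(100_000, 140_000)]), {"t1": 1_000_000})
    assert out.empty
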