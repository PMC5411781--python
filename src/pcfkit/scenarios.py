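"""Canned desk-scale study scenarios.

Each function builds a complete simulated dataset sized to run in
seconds on one CPU, wired to the analysis functions the scenario is
meant to exercise: event recovery, chimera verification, anchoring, and
CNE-desert statistics.  They are the same conditions the package's
validation and the worked examples in the documentation use.
"""

from __future__ import annotations

import numpy as np

from . import ebr as ebrm
from . import pcf as pcfm
from . import regionstats, simdata, synteny

__all__ = [
    "recovery_scenario",
    "chimera_scenario",
    "anchoring_scenario",
    "cne_desert_scenario",
]

RESOLUTION = 150_000


def recovery_scenario(seed: int):
    """5-chromosome, 20-Mb ancestor with 10 inversions, 3 fusions and
    2 fissions; returns (truth, typed EBR records, homeology map)."""
    anc = simdata.default_ancestor()
    rng = np.random.default_rng(seed)
    plan = simdata.random_plan(anc, 10, 3, 2, rng)
    kary, truth = simdata.apply_rearrangements(anc, plan)
    blocks = simdata.alignment_blocks_from_karyotype(kary, rng)
    homeology = synteny.build_homeology_map(blocks, resolution=RESOLUTION)
    typed = ebrm.classify_ebrs(ebrm.detect_ebrs(homeology), homeology)
    return truth, typed, homeology


def chimera_scenario(seed: int, chimera_rate: float = 0.1):
    """Shredded 20-Mb genome with zero-coverage chimeric joints; runs the
    initial build, in-silico verification, calibration and the final
    build.  Returns a dict with the pieces needed to score splitting.

    The benchmark's precondition is that at least one chimera was
    planted; at a 10% rate a small genome occasionally draws none, in
    which case the shredding is redrawn with a perturbed stream."""
    anc = simdata.default_ancestor()
    rng = np.random.default_rng(seed)
    plan = simdata.random_plan(anc, 10, 3, 2, rng)
    kary, truth = simdata.apply_rearrangements(anc, plan)
    for attempt in range(20):
        truth.chimeric_joints = []
        scaffolds, pairs = simdata.shred_to_scaffolds(
            kary, truth, np.random.default_rng(seed + 7919 * attempt),
            chimera_rate=chimera_rate, n_pairs=60_000, p_chim_zero=1.0,
        )
        if truth.chimeric_joints:
            break
    rng = np.random.default_rng(seed + 13)
    blocks = simdata.alignment_blocks_from_scaffolds(scaffolds, kary, rng)
    sfs = synteny.detect_sfs(blocks, RESOLUTION)
    coverage = pcfm.PhysicalCoverageTrack(pairs)
    adjacency = pcfm.AdjacencyOracle.from_sfs(sfs, max_gap=RESOLUTION)

    _, initial_joints = pcfm.build_pcfs(sfs, adjacency, adjacency, coverage,
                                        threshold_c=10**9)
    chim_positions = {}
    for j in truth.chimeric_joints:
        chim_positions.setdefault(j.scaffold_id, []).append(j.position)

    def is_chimeric(joint):
        return any(
            joint.gap_start - RESOLUTION <= p <= joint.gap_end + RESOLUTION
            for p in chim_positions.get(joint.scaffold_id, [])
        )

    # a joint is only detectable by alignment evidence when SFs flank it
    # on both sides (a tiny unaligned piece leaves no SF adjacency to cut)
    sf_by_scaffold: dict[str, list] = {}
    for s in sfs:
        sf_by_scaffold.setdefault(s.target_seq, []).append(s)
    detectable_joints = [
        j for j in truth.chimeric_joints
        if j.zero_coverage
        and any(s.t_start < j.position for s in sf_by_scaffold.get(j.scaffold_id, []))
        and any(s.t_end > j.position for s in sf_by_scaffold.get(j.scaffold_id, []))
    ]

    for joint in initial_joints:
        joint.set_status("refuted" if is_chimeric(joint) else "confirmed")
    threshold = pcfm.calibrate_threshold(initial_joints)
    pcfs, final_joints = pcfm.build_pcfs(sfs, adjacency, adjacency, coverage,
                                         threshold_c=threshold)
    return {
        "truth": truth,
        "scaffolds": scaffolds,
        "sfs": sfs,
        "threshold": threshold,
        "initial_joints": initial_joints,
        "final_joints": final_joints,
        "pcfs": pcfs,
        "is_chimeric": is_chimeric,
        "detectable_joints": detectable_joints,
    }


def anchoring_scenario(seed: int, n_chromosomes: int = 50):
    """Direct anchoring benchmark: ``n_chromosomes`` chromosomes of 3
    PCFs each with 2-4 noise-free probes per PCF, plus one single-probe
    PCF per fifth chromosome.  Returns (map table, probe->PCF table,
    PCF lengths, truth builds)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    map_rows, ptp_rows = [], []
    truth: dict[str, list[tuple[str, str]]] = {}
    lengths: dict[str, int] = {}
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        order_index = 0
        truth[chrom] = []
        n_pcfs = 3 + (c % 2)
        for k in range(n_pcfs):
            pcf_id = f"pcf_{c}_{k}"
            length = int(rng.integers(2_000_000, 6_000_000))
            lengths[pcf_id] = length
            single = (c % 5 == 0) and k == 1
            orient = "?" if single else str(rng.choice(["+", "-"]))
            truth[chrom].append((pcf_id, orient))
            n_probes = 1 if single else int(rng.integers(2, 5))
            pos = np.sort(rng.choice(
                np.arange(100_000, length - 100_000, 50_000),
                size=n_probes, replace=False))
            ordered = pos if orient != "-" else pos[::-1]
            for p in ordered:
                pid = f"{pcf_id}_pr{order_index}"
                map_rows.append((chrom, order_index, pid, order_index / 30))
                ptp_rows.append((pid, pcf_id, int(p)))
                order_index += 1
    cyto = pd.DataFrame(map_rows, columns=["chrom", "order_index", "probe_id",
                                           "map_position"])
    ptp = pd.DataFrame(ptp_rows, columns=["probe_id", "pcf_id", "pcf_pos"])
    return cyto, ptp, lengths, truth


def cne_desert_scenario(seed: int, n_per_class: int = 200):
    """CNE-desert statistics at scale: a 48-Mb genome with 20 inversions,
    11 fusions and 10 fissions (breakpoints kept out of msHSBs), window
    scan, and per-class zero-window distances subsampled to
    ``n_per_class``.  Returns (distances, medians, comparison)."""
    anc = simdata.default_ancestor(n_chromosomes=12, chrom_bp=4_000_000,
                                   mshsb_bp=1_600_000)
    rng = np.random.default_rng(seed)
    plan = simdata.random_plan(
        anc, 20, 11, 10, rng, min_event_bp=150_000, max_event_bp=350_000,
        margin_bp=150_000, min_separation_bp=120_000,
        avoid_anc_intervals=anc.mshsb_intervals, avoid_pad_bp=60_000,
    )
    kary, truth = simdata.apply_rearrangements(anc, plan)
    tracks = simdata.simulate_feature_tracks(anc, kary, truth, rng)
    blocks = simdata.alignment_blocks_from_karyotype(kary, rng)
    homeology = synteny.build_homeology_map(blocks, resolution=RESOLUTION)
    typed = ebrm.classify_ebrs(ebrm.detect_ebrs(homeology), homeology)
    track = regionstats.window_scan(dict(anc.chromosomes), tracks["cne"],
                                    anc.mshsb_intervals, typed)
    distances, _ = regionstats.zero_window_distances(track)
    classes = ("msHSB", "intra_EBR", "fusion_EBR", "fission_EBR")
    sub_rng = np.random.default_rng(seed + 1)
    samples = {}
    for cls in classes:
        d = distances[cls]
        if len(d) > n_per_class:
            d = sub_rng.choice(d, size=n_per_class, replace=False)
        samples[cls] = d
    comparison = regionstats.compare_groups(samples)
    medians = {cls: float(np.median(samples[cls])) for cls in classes}
    return {
        "track": track,
        "distances": distances,
        "samples": samples,
        "medians": medians,
        "comparison": comparison,
        "truth": truth,
        "typed": typed,
    }
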