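"""End-to-end orchestration: simulate -> SFs -> PCFs -> verification ->
probe panel -> anchoring -> EBRs -> CNE/TE statistics.

Every stage consumes files written by the previous stage (and writes its
own), so stages can be re-run individually from the same output
directory.  With a fixed seed the whole run is deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromassembly, ebr as ebr_mod, io, pcf as pcf_mod, probes as probes_mod
from . import regionstats, simdata, synteny
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "STAGES"]


def _rng(cfg: RunConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed * 1_000_003 + salt) % (2**31))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    ancestor = simdata.default_ancestor(
        n_chromosomes=cfg.n_chromosomes, chrom_bp=cfg.chrom_bp,
        mshsb_per_chrom=cfg.mshsb_per_chrom, mshsb_bp=cfg.mshsb_bp, seed=cfg.seed,
    )
    plan = simdata.random_plan(
        ancestor, cfg.n_inversions, cfg.n_fusions, cfg.n_fissions, _rng(cfg, 1),
    )
    karyotype, truth = simdata.apply_rearrangements(ancestor, plan)
    scaffolds, pairs = simdata.shred_to_scaffolds(
        karyotype, truth, _rng(cfg, 2),
        mean_scaffold_bp=cfg.mean_scaffold_bp, chimera_rate=cfg.chimera_rate,
        n_pairs=cfg.n_pairs, insert_mean=cfg.insert_mean, insert_sd=cfg.insert_sd,
        p_chim_zero=cfg.p_chim_zero,
    )
    tracks = simdata.simulate_feature_tracks(
        ancestor, karyotype, truth, _rng(cfg, 3),
        cne_density_mshsb=cfg.cne_density_mshsb,
        cne_density_background=cfg.cne_density_background,
        desert_halfwidth_bp=cfg.desert_halfwidth_bp,
    )
    probe_table, cyto_map = simdata.plant_probes(
        karyotype, _rng(cfg, 4), spacing_bp=cfg.probe_spacing_bp,
        position_noise_sd=cfg.probe_position_noise_sd,
    )
    blocks = simdata.alignment_blocks_from_scaffolds(
        scaffolds, karyotype, _rng(cfg, 5),
        block_bp=cfg.block_bp, edge_erosion_bp=cfg.edge_erosion_bp,
    )

    io.write_json(outdir / "ancestor.json", {
        "chromosomes": ancestor.chromosomes,
        "mshsb_intervals": ancestor.mshsb_intervals,
    })
    io.write_karyotype(outdir / "karyotype.tsv", karyotype)
    io.write_agp(outdir / "karyotype.agp", [
        (chrom, [(s.chrom, s.start, s.end, "+" if s.strand == 1 else "-") for s in segs])
        for chrom, segs in karyotype.items()
    ])
    io.write_truth(outdir, truth)
    io.write_scaffolds(outdir / "scaffolds.tsv", scaffolds)
    io.write_tsv(outdir / "read_pairs.tsv", pairs)
    io.write_bed(outdir / "cne.bed", tracks["cne"])
    io.write_bed(outdir / "ce.bed", tracks["ce"])
    io.write_bed(outdir / "te.bed", tracks["te"])
    io.write_tsv(outdir / "probes.tsv", probe_table)
    io.write_tsv(outdir / "cyto_map.tsv", cyto_map)
    io.write_tsv(outdir / "blocks.tsv", blocks)
    return {
        "n_chromosomes": len(karyotype),
        "genome_bp": ancestor.total_bp,
        "n_scaffolds": len(scaffolds),
        "n_read_pairs": int(len(pairs)),
        "n_truth_events": len({r.event_id for r in truth.ebrs}),
        "n_chimeric_joints": len(truth.chimeric_joints),
        "n_probes": int(len(probe_table)),
    }


def stage_sf(cfg: RunConfig, outdir: Path) -> dict:
    blocks = io.read_tsv(outdir / "blocks.tsv")
    sfs = synteny.detect_sfs(blocks, resolution=cfg.resolution, min_block_bp=cfg.min_block_bp)
    io.write_tsv(outdir / "sfs.tsv", synteny.sfs_to_dataframe(sfs))
    return {"n_blocks": int(len(blocks)), "n_sfs": len(sfs)}


def _load_sfs(outdir: Path) -> list[synteny.SynFrag]:
    df = io.read_tsv(outdir / "sfs.tsv")
    return [
        synteny.SynFrag(str(r.sf_id), str(r.target_seq), int(r.t_start), int(r.t_end),
                        str(r.ref_chrom), int(r.r_start), int(r.r_end),
                        str(r.orientation), int(r.n_blocks))
        for r in df.itertuples(index=False)
    ]


def _verify_joints_in_silico(joints, truth, slack: int) -> None:
    """Assign verification outcomes from simulator truth: a split joint
    matching a planted chimeric junction is refuted (the split was
    right), anything else is confirmed — the computational stand-in for
    PCR across the split region."""
    chim = {}
    for j in truth.chimeric_joints:
        chim.setdefault(j.scaffold_id, []).append(j.position)
    for joint in joints:
        positions = chim.get(joint.scaffold_id, [])
        is_chimeric = any(
            joint.gap_start - slack <= pos <= joint.gap_end + slack for pos in positions
        )
        joint.set_status("refuted" if is_chimeric else "confirmed")


def _build_at_threshold(cfg: RunConfig, outdir: Path, threshold: int):
    sfs = _load_sfs(outdir)
    pairs = io.read_tsv(outdir / "read_pairs.tsv")
    coverage = pcf_mod.PhysicalCoverageTrack(pairs)
    ref_adj = pcf_mod.AdjacencyOracle.from_sfs(sfs, max_gap=cfg.resolution)
    out_adj = ref_adj  # outgroup emulated as a second colinear genome
    pcfs, joints = pcf_mod.build_pcfs(
        sfs, ref_adj, out_adj, coverage, threshold_c=threshold,
        weights=cfg.weights(), join_min=cfg.join_min, coverage_mode=cfg.coverage_mode,
    )
    blocks = io.read_tsv(outdir / "blocks.tsv")
    joints = pcf_mod.find_split_joints(joints, blocks, resolution=cfg.resolution)
    return sfs, pcfs, joints


def _write_joints(outdir: Path, joints) -> None:
    io.write_tsv(outdir / "split_joints.tsv", pd.DataFrame([
        {"scaffold_id": j.scaffold_id, "gap_start": j.gap_start, "gap_end": j.gap_end,
         "coverage": j.coverage, "status": j.status, "testable": j.testable}
        for j in joints
    ], columns=["scaffold_id", "gap_start", "gap_end", "coverage", "status", "testable"]))


def _load_joints(outdir: Path):
    df = io.read_tsv(outdir / "split_joints.tsv")
    sf0 = synteny.SynFrag("placeholder", "", 0, 1, "", 0, 1, "+")
    out = []
    for r in df.itertuples(index=False):
        j = pcf_mod.SplitJoint(str(r.scaffold_id), int(r.gap_start), int(r.gap_end),
                               int(r.coverage), sf0, sf0, testable=bool(r.testable))
        if str(r.status) != "untested":
            j.set_status(str(r.status))
        out.append(j)
    return out


def _pcf_stats(outdir: Path, pcfs, sfs, joints, threshold) -> dict:
    scaffolds = io.read_scaffolds(outdir / "scaffolds.tsv")
    stats = pcf_mod.assembly_stats(
        pcfs, input_total_bp=sum(s.length for s in scaffolds),
        n_sfs=len(sfs), n_scaffolds=len({sf.target_seq for sf in sfs}),
    )
    stats["threshold_c"] = threshold
    stats["n_split_joints"] = len(joints)
    return stats


def stage_pcf(cfg: RunConfig, outdir: Path) -> dict:
    """Initial PCF build: a conservative threshold splits every
    adjacency lacking comparative support, producing the candidate
    joints that verification will adjudicate."""
    calibrate = cfg.threshold_c == "calibrate"
    c0 = 10**9 if calibrate else int(cfg.threshold_c)
    sfs, pcfs, joints = _build_at_threshold(cfg, outdir, c0)
    io.pcfs_to_agp(outdir / "pcfs.agp", pcfs)
    _write_pcf_members(outdir / "pcf_members.tsv", pcfs)
    _write_joints(outdir, joints)
    stats = _pcf_stats(outdir, pcfs, sfs, joints, c0)
    io.write_json(outdir / "pcf_stats.json", stats)
    return stats


def stage_verify_plan(cfg: RunConfig, outdir: Path) -> dict:
    """Emit the verification plan: the testable (< 6 kb) split joints a
    PCR round would target."""
    joints = _load_joints(outdir)
    plan = [j for j in joints if j.testable]
    io.write_tsv(outdir / "verification_plan.tsv", pd.DataFrame([
        {"scaffold_id": j.scaffold_id, "gap_start": j.gap_start,
         "gap_end": j.gap_end, "coverage": j.coverage}
        for j in plan
    ], columns=["scaffold_id", "gap_start", "gap_end", "coverage"]))
    return {"n_joints": len(joints), "n_testable": len(plan)}


def stage_verify_apply(cfg: RunConfig, outdir: Path) -> dict:
    """Apply verification outcomes: calibrate the coverage threshold,
    rebuild at it, and refine (weld confirmed joints, keep chimeras
    split).  In simulate mode outcomes come from the planted truth; in
    real-input mode from ``verification_results_path`` (a TSV with
    scaffold_id, gap_start, status)."""
    joints = _load_joints(outdir)
    if cfg.mode == "simulate":
        truth = io.read_truth(outdir)
        _verify_joints_in_silico(joints, truth, slack=cfg.resolution)
    elif cfg.verification_results_path:
        statuses = io.read_tsv(cfg.verification_results_path)
        lookup = {(str(r.scaffold_id), int(r.gap_start)): str(r.status)
                  for r in statuses.itertuples(index=False)}
        for j in joints:
            status = lookup.get((j.scaffold_id, j.gap_start))
            if status:
                j.set_status(status)
    else:
        logger.warning("no verification results available; keeping initial build")
        return {"skipped": True}

    calibrate = cfg.threshold_c == "calibrate"
    threshold = pcf_mod.calibrate_threshold(joints) if calibrate else int(cfg.threshold_c)
    sfs, pcfs, final_joints = _build_at_threshold(cfg, outdir, threshold)
    if cfg.mode == "simulate":
        _verify_joints_in_silico(final_joints, truth, slack=cfg.resolution)
    else:
        status_by_pos = {(j.scaffold_id, j.gap_start): j.status for j in joints}
        for j in final_joints:
            status = status_by_pos.get((j.scaffold_id, j.gap_start), "untested")
            if status != "untested":
                j.set_status(status)
    pcfs = pcf_mod.refine_pcfs(pcfs, final_joints)

    io.pcfs_to_agp(outdir / "pcfs.agp", pcfs)
    _write_pcf_members(outdir / "pcf_members.tsv", pcfs)
    _write_joints(outdir, final_joints)
    stats = _pcf_stats(outdir, pcfs, sfs, final_joints, threshold)
    io.write_json(outdir / "pcf_stats.json", stats)
    return stats


def _write_pcf_members(path, pcfs) -> None:
    rows = []
    for p in pcfs:
        offset = 0
        for k, m in enumerate(p.members):
            junction = p.junctions[k - 1] if 0 < k <= len(p.junctions) else None
            rows.append({
                "pcf_id": p.pcf_id, "index": k, "scaffold_id": m.scaffold_id,
                "start": m.start, "end": m.end, "orientation": m.orientation,
                "pcf_offset": offset,
                "sf_ids": ",".join(sf.sf_id for sf in m.sfs),
                "junction_kind": junction.kind if junction else "",
                "junction_coverage": junction.coverage if junction else -1,
            })
            offset += m.length
    io.write_tsv(path, pd.DataFrame(rows, columns=[
        "pcf_id", "index", "scaffold_id", "start", "end", "orientation",
        "pcf_offset", "sf_ids", "junction_kind", "junction_coverage"]))


def _load_pcfs(outdir: Path) -> list[pcf_mod.PCF]:
    members = io.read_tsv(outdir / "pcf_members.tsv")
    sf_index = {sf.sf_id: sf for sf in _load_sfs(outdir)}
    pcfs: dict[str, pcf_mod.PCF] = {}
    for r in members.sort_values(["pcf_id", "index"]).itertuples(index=False):
        p = pcfs.setdefault(str(r.pcf_id), pcf_mod.PCF(str(r.pcf_id), [], []))
        if int(r.index) > 0:
            p.junctions.append(pcf_mod.Junction(
                str(r.junction_kind) or "chain", int(r.junction_coverage)))
        p.members.append(pcf_mod.PCFMember(
            str(r.scaffold_id), int(r.start), int(r.end), str(r.orientation),
            [sf_index[s] for s in str(r.sf_ids).split(",") if s in sf_index],
        ))
    return list(pcfs.values())


def stage_probes(cfg: RunConfig, outdir: Path) -> dict:
    probe_table = io.read_tsv(outdir / "probes.tsv")
    classes = [
        probes_mod.classify_universal({
            "alignable_fraction": r.alignable_fraction,
            "max_ce_len": r.max_ce_len,
            "total_repeat_len": r.total_repeat_len,
            "has_ce_ge_3bp": bool(r.has_ce_ge_3bp),
        })
        for r in probe_table.itertuples(index=False)
    ]
    probe_table = probe_table.assign(probe_class=classes)
    candidates = probe_table[probe_table["probe_class"] == "universal_candidate"]
    cand = candidates.rename(columns={"true_pos": "pos"})[["probe_id", "chrom", "pos"]]
    panel, uncovered = probes_mod.select_spaced_panel(cand, cfg.probe_spacing_bp)
    io.write_tsv(outdir / "probe_classes.tsv", probe_table)
    io.write_tsv(outdir / "probe_panel.tsv", panel)
    io.write_tsv(outdir / "probe_spacing_hist.tsv", probes_mod.spacing_histogram(panel))
    return {
        "n_probes": int(len(probe_table)),
        "n_universal": int(len(candidates)),
        "panel_size": int(len(panel)),
        "uncovered_chromosomes": uncovered,
    }


def _probe_to_pcf(outdir: Path) -> pd.DataFrame:
    """Locate each probe inside a PCF via its descendant coordinate."""
    probe_table = io.read_tsv(outdir / "probes.tsv")
    scaffolds = io.read_scaffolds(outdir / "scaffolds.tsv")
    members = io.read_tsv(outdir / "pcf_members.tsv")

    piece_index = []
    for s in scaffolds:
        offset = 0
        for chrom, start, end, _strand in s.pieces:
            piece_index.append((chrom, start, end, s.scaffold_id, offset))
            offset += end - start
    rows = []
    for r in probe_table.itertuples(index=False):
        hit = next(
            ((sid, off + int(r.true_pos) - start)
             for chrom, start, end, sid, off in piece_index
             if chrom == r.chrom and start <= r.true_pos < end),
            None,
        )
        if hit is None:
            continue
        scaffold_id, scaf_pos = hit
        sub = members[(members["scaffold_id"] == scaffold_id)
                      & (members["start"] <= scaf_pos) & (scaf_pos < members["end"])]
        if sub.empty:
            continue
        m = sub.iloc[0]
        if m["orientation"] == "-":
            pcf_pos = int(m["pcf_offset"]) + (int(m["end"]) - scaf_pos)
        else:
            pcf_pos = int(m["pcf_offset"]) + (scaf_pos - int(m["start"]))
        rows.append({"probe_id": r.probe_id, "pcf_id": m["pcf_id"], "pcf_pos": pcf_pos})
    return pd.DataFrame(rows, columns=["probe_id", "pcf_id", "pcf_pos"])


def stage_anchor(cfg: RunConfig, outdir: Path) -> dict:
    if cfg.mode == "real-input" and cfg.probe_map_path is None:
        logger.warning("no probe map available; anchoring skipped")
        return {"skipped": True}
    cyto = chromassembly.CytogeneticMap(io.read_tsv(outdir / "cyto_map.tsv"))

    # iterate: assign -> split map-conflicting multi-member PCFs at their
    # weakest junction -> re-assign, until conflicts are irreducible
    for _round in range(10):
        probe_to_pcf = _probe_to_pcf(outdir)
        assignment, conflicts = chromassembly.assign_pcfs(probe_to_pcf, cyto)
        pcfs = _load_pcfs(outdir)
        n_members = {p.pcf_id: len(p.members) for p in pcfs}
        splittable = [c["pcf_id"] for c in conflicts if n_members.get(c["pcf_id"], 1) > 1]
        if not splittable:
            break
        logger.info("splitting map-conflicting PCFs: %s", splittable)
        pcfs = pcf_mod.refine_pcfs(pcfs, [], map_conflicts=splittable)
        _write_pcf_members(outdir / "pcf_members.tsv", pcfs)
        io.pcfs_to_agp(outdir / "pcfs.agp", pcfs)

    members = io.read_tsv(outdir / "pcf_members.tsv")
    pcf_lengths = (
        members.assign(length=members["end"] - members["start"])
        .groupby("pcf_id")["length"].sum().to_dict()
    )
    builds = chromassembly.order_and_orient(assignment, pcf_lengths,
                                            on_interleave="drop")
    total_bp = int(sum(pcf_lengths.values()))
    stats = chromassembly.placement_stats(builds, total_bp)

    io.write_tsv(outdir / "pcf_assignment.tsv", assignment)
    io.write_json(outdir / "anchor_conflicts.json", {"conflicts": conflicts})
    io.write_agp(outdir / "chromosomes.agp", [
        (chrom, [(pcf_id, 0, int(pcf_lengths.get(pcf_id, 0)), orient)
                 for pcf_id, orient in b.entries])
        for chrom, b in sorted(builds.items())
    ])
    io.write_tsv(outdir / "placement_per_chrom.tsv", stats["per_chromosome"])
    result = {
        "n_assigned_pcfs": int(assignment["pcf_id"].nunique()) if len(assignment) else 0,
        "n_conflicts": len(conflicts),
        "placed_bp": stats["placed_bp"],
        "placed_fraction": stats["placed_fraction"],
        "oriented_bp": stats["oriented_bp"],
    }
    io.write_json(outdir / "anchor_stats.json", result)
    return result


def _chromosome_blocks(outdir: Path) -> pd.DataFrame:
    """Target-chromosome <-> reference alignment blocks implied by the
    anchored chromosome builds (for EBR detection)."""
    members = io.read_tsv(outdir / "pcf_members.tsv")
    sfs = {sf.sf_id: sf for sf in _load_sfs(outdir)}
    chrom_builds = io.read_agp(outdir / "chromosomes.agp")
    member_rows = {
        (r.pcf_id, int(r.index)): r for r in members.itertuples(index=False)
    }
    by_pcf: dict[str, list] = {}
    for (pcf_id, idx), r in sorted(member_rows.items(), key=lambda kv: kv[0]):
        by_pcf.setdefault(pcf_id, []).append(r)

    rows = []
    for chrom, entries in chrom_builds:
        offset = 0
        for pcf_id, _start, length, orient in [(e[0], e[1], e[2] - e[1], e[3]) for e in entries]:
            mlist = by_pcf.get(pcf_id, [])
            ordered = mlist if orient != "-" else list(reversed(mlist))
            for m in ordered:
                m_len = int(m.end) - int(m.start)
                flip_member = (orient == "-")
                m_orient = m.orientation
                if flip_member:
                    m_orient = "-" if m_orient == "+" else "+"
                for sf_id in str(m.sf_ids).split(","):
                    sf = sfs[sf_id]
                    # position of the SF inside the member, possibly flipped
                    lo = sf.t_start - int(m.start)
                    hi = sf.t_end - int(m.start)
                    if m_orient == "-":
                        lo, hi = m_len - hi, m_len - lo
                        strand = "-" if sf.orientation == "+" else "+"
                    else:
                        strand = sf.orientation
                    rows.append({
                        "target_seq": chrom, "t_start": offset + lo, "t_end": offset + hi,
                        "ref_chrom": sf.ref_chrom, "r_start": sf.r_start,
                        "r_end": sf.r_end, "strand": strand, "identity": 1.0,
                    })
                offset += m_len
    return pd.DataFrame(rows).sort_values(["target_seq", "t_start"]).reset_index(drop=True)


def stage_ebr(cfg: RunConfig, outdir: Path) -> dict:
    blocks = _chromosome_blocks(outdir)
    homeology = synteny.build_homeology_map(blocks, resolution=cfg.resolution)
    detected = ebr_mod.detect_ebrs(homeology)
    typed = ebr_mod.classify_ebrs(detected, homeology)
    counts = ebr_mod.event_counts(typed)

    io.write_tsv(outdir / "ebrs.tsv", pd.DataFrame([
        {"ref_chrom": r.ref_chrom, "start": r.start, "end": r.end,
         "type": r.ebr_type, "target_chrom": r.target_chrom,
         "well_defined": r.well_defined, "excluded": r.excluded,
         "event_group": r.event_group,
         "t_chrom": r.extra.get("target_interval", ("", -1, -1))[0],
         "t_start": r.extra.get("target_interval", ("", -1, -1))[1],
         "t_end": r.extra.get("target_interval", ("", -1, -1))[2]}
        for r in typed
    ], columns=["ref_chrom", "start", "end", "type", "target_chrom", "well_defined",
                "excluded", "event_group", "t_chrom", "t_start", "t_end"]))
    result = {"n_ebr_records": len(typed), "event_counts": counts}
    if cfg.mode == "simulate":
        truth = io.read_truth(outdir)
        result["truth_event_counts"] = truth.ebr_counts()
    io.write_json(outdir / "ebr_stats.json", result)
    return result


def _load_typed_ebrs(outdir: Path) -> list[ebr_mod.EBR]:
    df = io.read_tsv(outdir / "ebrs.tsv")
    out = []
    for r in df.itertuples(index=False):
        rec = ebr_mod.EBR(str(r.ref_chrom), int(r.start), int(r.end), str(r.type),
                          target_chrom=str(r.target_chrom),
                          well_defined=bool(r.well_defined),
                          excluded=bool(r.excluded), event_group=int(r.event_group))
        if pd.notna(r.t_chrom) and str(r.t_chrom) not in ("", "nan"):
            rec.extra["target_interval"] = (str(r.t_chrom), int(r.t_start), int(r.t_end))
        out.append(rec)
    return out


def stage_stats(cfg: RunConfig, outdir: Path) -> dict:
    ancestor_meta = json.loads((outdir / "ancestor.json").read_text())
    chromosomes = {name: int(length) for name, length in ancestor_meta["chromosomes"]}
    mshsb = [(c, int(s), int(e)) for c, s, e in ancestor_meta["mshsb_intervals"]]
    cne = io.read_bed(outdir / "cne.bed", names=("chrom", "start", "end"))
    te = io.read_bed(outdir / "te.bed", names=("chrom", "start", "end", "family"))
    typed = _load_typed_ebrs(outdir)

    track = regionstats.window_scan(
        chromosomes, cne, mshsb, typed, w=cfg.window_bp, te_track=te.iloc[0:0],
    )
    class_means = track.class_means().to_dict()
    distances, excluded = regionstats.zero_window_distances(track)
    samples = {c: d for c, d in distances.items() if len(d) >= 2 and c != "rest"}
    comparison = None
    if len(samples) >= 2:
        comparison = regionstats.compare_groups(samples, alpha=cfg.alpha)

    profiles = []
    for rec in typed:
        if rec.excluded or not rec.well_defined or rec.length == 0:
            continue
        prof = regionstats.flank_density_profile(rec, cne, chromosomes[rec.ref_chrom])
        profiles.append({
            "ref_chrom": rec.ref_chrom, "start": rec.start, "end": rec.end,
            "type": rec.ebr_type,
            **{f"slot_{k}": (d if d is not None else "")
               for k, d in zip(("m2", "m1", "ebr", "p1", "p2"), prof.densities)},
        })
    io.write_tsv(outdir / "ebr_flank_profiles.tsv", pd.DataFrame(profiles, columns=[
        "ref_chrom", "start", "end", "type", "slot_m2", "slot_m1", "slot_ebr",
        "slot_p1", "slot_p2"]))

    descendant = io.read_karyotype(outdir / "truth_karyotype.tsv")
    target_chroms = {c: simdata.karyotype_length(s) for c, s in descendant.items()}
    te_table = regionstats.te_enrichment(
        te, [r for r in typed if "target_interval" in r.extra],
        target_chroms, window_bp=cfg.te_window_bp, alpha=cfg.alpha,
    )
    io.write_tsv(outdir / "te_enrichment.tsv", te_table)
    io.write_tsv(outdir / "window_track.tsv", track.table)

    result = {
        "class_mean_cne_density": {k: round(float(v), 5) for k, v in class_means.items()},
        "zero_window_median_distance_kb": {
            c: float(np.median(d)) for c, d in distances.items() if len(d)
        },
        "zero_windows_excluded": excluded,
        "omnibus_p": comparison.omnibus_p if comparison else None,
        "n_te_families_tested": int(len(te_table)),
    }
    io.write_json(outdir / "region_stats.json", result)
    return result


STAGES = [
    ("simulate", stage_simulate),
    ("sf", stage_sf),
    ("pcf", stage_pcf),
    ("verify-plan", stage_verify_plan),
    ("verify-apply", stage_verify_apply),
    ("probes", stage_probes),
    ("anchor", stage_anchor),
    ("ebr", stage_ebr),
    ("stats", stage_stats),
]


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run all stages in order; on a stage failure the report marks the
    stage and downstream stages are skipped."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "mode": cfg.mode, "stages": {}}
    t0 = time.time()
    failed = False
    for name, fn in STAGES:
        if failed:
            report["stages"][name] = {"skipped": True}
            continue
        if cfg.mode == "real-input" and name == "simulate":
            report["stages"][name] = {"skipped": True}
            continue
        try:
            stage_report = fn(cfg, outdir)
            report["stages"][name] = stage_report
            logger.info("stage %s: %s", name, stage_report)
        except Exception as exc:  # noqa: BLE001 - report and halt downstream
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"failed": str(exc)}
            failed = True
    report["wall_time_s"] = round(time.time() - t0, 2)
    io.write_json(outdir / "run_report.json", report)
    return report
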