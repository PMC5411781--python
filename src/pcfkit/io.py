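"""Readers and writers for the plain-text formats the pipeline exchanges:
AGP v2.1 for assemblies, BED3/BED4 for feature tracks, TSV for block
tables, scaffolds, read pairs, probe maps and truth records."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .pcf import PCF
from .simdata import ChimericJoint, Scaffold, Segment, TruthEBR, TruthSet

AGP_GAP = ("100", "N", "contig", "no", "align_genus")


def write_agp(path, objects: list[tuple[str, list[tuple[str, int, int, str]]]]) -> None:
    """Write AGP v2.1: ``objects`` is a list of (object_id, components),
    each component (component_id, start, end, orientation) in component
    coordinates; a 100-bp contig gap separates consecutive components.
    Orientation '?' is encoded as AGP "na"."""
    lines = ["##agp-version\t2.1"]
    for obj_id, comps in objects:
        pos = 0
        part = 0
        for k, (comp_id, start, end, orient) in enumerate(comps):
            if k > 0:
                part += 1
                gap_len = int(AGP_GAP[0])
                lines.append("\t".join([
                    obj_id, str(pos + 1), str(pos + gap_len), str(part),
                    AGP_GAP[1], AGP_GAP[0], AGP_GAP[2], AGP_GAP[3], AGP_GAP[4],
                ]))
                pos += gap_len
            part += 1
            span = end - start
            agp_orient = {"+": "+", "-": "-", "?": "na"}[orient]
            lines.append("\t".join([
                obj_id, str(pos + 1), str(pos + span), str(part), "W",
                comp_id, str(start + 1), str(end), agp_orient,
            ]))
            pos += span
    Path(path).write_text("\n".join(lines) + "\n")


def read_agp(path) -> list[tuple[str, list[tuple[str, int, int, str]]]]:
    objects: dict[str, list[tuple[str, int, int, str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if f[4] in ("N", "U"):
            continue
        orient = {"+": "+", "-": "-", "na": "?", "?": "?"}.get(f[8], "?")
        objects.setdefault(f[0], []).append((f[5], int(f[6]) - 1, int(f[7]), orient))
    return list(objects.items())


def pcfs_to_agp(path, pcfs: list[PCF]) -> None:
    write_agp(path, [
        (p.pcf_id, [(m.scaffold_id, m.start, m.end, m.orientation) for m in p.members])
        for p in pcfs
    ])


def write_bed(path, track: pd.DataFrame) -> None:
    cols = [c for c in ("chrom", "start", "end", "family", "name") if c in track.columns]
    track[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end", "family")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- simulator state ---------------------------------------------------------


def write_karyotype(path, karyotype: dict[str, list[Segment]]) -> None:
    rows = [
        {"chrom": chrom, "index": k, "anc_chrom": seg.chrom,
         "start": seg.start, "end": seg.end, "strand": seg.strand}
        for chrom, segs in karyotype.items()
        for k, seg in enumerate(segs)
    ]
    write_tsv(path, pd.DataFrame(rows))


def read_karyotype(path) -> dict[str, list[Segment]]:
    df = read_tsv(path)
    karyotype: dict[str, list[Segment]] = {}
    for r in df.sort_values(["chrom", "index"]).itertuples(index=False):
        karyotype.setdefault(str(r.chrom), []).append(
            Segment(str(r.anc_chrom), int(r.start), int(r.end), int(r.strand))
        )
    return karyotype


def write_scaffolds(path, scaffolds: list[Scaffold]) -> None:
    rows = [
        {"scaffold_id": s.scaffold_id, "index": k, "desc_chrom": c,
         "start": a, "end": b, "strand": st}
        for s in scaffolds
        for k, (c, a, b, st) in enumerate(s.pieces)
    ]
    write_tsv(path, pd.DataFrame(rows))


def read_scaffolds(path) -> list[Scaffold]:
    df = read_tsv(path)
    out: dict[str, list] = {}
    for r in df.sort_values(["scaffold_id", "index"]).itertuples(index=False):
        out.setdefault(str(r.scaffold_id), []).append(
            (str(r.desc_chrom), int(r.start), int(r.end), int(r.strand))
        )
    return [Scaffold(sid, pieces) for sid, pieces in out.items()]


def write_truth(outdir: Path, truth: TruthSet) -> None:
    ebr_rows = []
    for rec in truth.ebrs:
        for chrom, pos in rec.anc_positions:
            ebr_rows.append({
                "event_id": rec.event_id, "type": rec.ebr_type,
                "anc_chrom": chrom, "anc_pos": pos,
                "desc_chrom": rec.descendant_pos[0] if rec.descendant_pos else "",
                "desc_pos": rec.descendant_pos[1] if rec.descendant_pos else -1,
                "op_index": rec.op_index,
            })
    ebr_cols = ["event_id", "type", "anc_chrom", "anc_pos", "desc_chrom",
                "desc_pos", "op_index"]
    write_tsv(outdir / "truth_ebrs.tsv", pd.DataFrame(ebr_rows, columns=ebr_cols))
    joint_rows = [
        {"scaffold_id": j.scaffold_id, "position": j.position,
         "left_chrom": j.left_source.chrom, "left_start": j.left_source.start,
         "left_end": j.left_source.end, "right_chrom": j.right_source.chrom,
         "right_start": j.right_source.start, "right_end": j.right_source.end,
         "zero_coverage": j.zero_coverage}
        for j in truth.chimeric_joints
    ]
    joint_cols = ["scaffold_id", "position", "left_chrom", "left_start", "left_end",
                  "right_chrom", "right_start", "right_end", "zero_coverage"]
    write_tsv(outdir / "truth_chimeric_joints.tsv",
              pd.DataFrame(joint_rows, columns=joint_cols))
    write_karyotype(outdir / "truth_karyotype.tsv", truth.karyotype)


def read_truth(outdir: Path) -> TruthSet:
    karyotype = read_karyotype(outdir / "truth_karyotype.tsv")
    truth = TruthSet(karyotype=karyotype)
    ebr_df = read_tsv(outdir / "truth_ebrs.tsv")
    grouped: dict[tuple[int, str, int], TruthEBR] = {}
    for r in ebr_df.itertuples(index=False):
        key = (int(r.event_id), str(r.type), int(r.op_index))
        has_desc = pd.notna(r.desc_chrom) and str(r.desc_chrom) not in ("", "nan")
        desc = (str(r.desc_chrom), int(r.desc_pos)) if has_desc else None
        if key in grouped and str(r.type) == "fusion":
            grouped[key].anc_positions.append((str(r.anc_chrom), int(r.anc_pos)))
        else:
            rec = TruthEBR(int(r.event_id), str(r.type),
                           [(str(r.anc_chrom), int(r.anc_pos))], desc, int(r.op_index))
            if key in grouped:  # second end of an inversion
                truth.ebrs.append(rec)
            else:
                grouped[key] = rec
                truth.ebrs.append(rec)
    joints_df = read_tsv(outdir / "truth_chimeric_joints.tsv")
    for r in joints_df.itertuples(index=False):
        truth.chimeric_joints.append(ChimericJoint(
            str(r.scaffold_id), int(r.position),
            Segment(str(r.left_chrom), int(r.left_start), int(r.left_end)),
            Segment(str(r.right_chrom), int(r.right_start), int(r.right_end)),
            bool(r.zero_coverage),
        ))
    return truth


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
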