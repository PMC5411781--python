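"""Evolutionary breakpoint region (EBR) detection and classification.

EBRs are the reference-genome intervals where target-genome colinearity
breaks between adjacent homologous synteny blocks.  With the reference
treated as the ancestral proxy, a reference chromosome continuing onto
two target chromosomes marks a fission, a target chromosome joining
blocks of two reference chromosomes marks a fusion, and order or
orientation changes within one chromosome pair are intrachromosomal
EBRs.  Records carry an event-group id so that the two ends of one
inversion, or the fission+fusion pair emitted by a single biological
event, are counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .synteny import HomeologyMap

logger = logging.getLogger(__name__)

__all__ = ["EBR", "detect_ebrs", "classify_ebrs", "assign_lineage", "event_counts"]

MAX_EBR_BP = 100_000  # larger regions are excluded from CNE analysis
MIN_EBR_BP = 1_000  # smaller regions are extended by +-1 kb
TERMINAL_FLANK_BP = 10_000  # fusion flank when the junction abuts a chromosome end


@dataclass
class EBR:
    ref_chrom: str
    start: int
    end: int
    ebr_type: str | None = None  # intra | fusion | fission
    lineage: str | None = None
    target_chrom: str | None = None
    partner: tuple[str, int, int] | None = None  # other reference flank of a fusion
    well_defined: bool = True
    excluded: bool = False
    event_group: int = -1
    extra: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EBR", slack: int = 0) -> bool:
        return (
            self.ref_chrom == other.ref_chrom
            and self.start - slack < other.end
            and other.start - slack < self.end
        )


def _continuous(left, right, resolution: int) -> bool:
    """Target-genome continuity of two reference-adjacent HSBs."""
    if left.target_chrom != right.target_chrom:
        return False
    if left.orientation != right.orientation or left.orientation == "?":
        return False
    if left.orientation == "+":
        gap = right.t_start - left.t_end
        ordered = right.t_start >= left.t_start
    else:
        gap = left.t_start - right.t_end
        ordered = left.t_start >= right.t_start
    return ordered and abs(gap) < resolution


def detect_ebrs(homeology: HomeologyMap) -> list[EBR]:
    """One untyped EBR per reference-adjacent HSB pair where target
    continuity breaks.  Intervals below 1 kb are extended by 1 kb on each
    side; intervals above 100 kb are flagged excluded (after extension).
    """
    ebrs: list[EBR] = []
    df = homeology.hsbs
    if df.empty:
        return ebrs
    for ref_chrom, grp in df.groupby("ref_chrom", sort=True):
        grp = grp.sort_values("r_start").reset_index(drop=True)
        for k in range(len(grp) - 1):
            left, right = grp.iloc[k], grp.iloc[k + 1]
            if right.r_start < left.r_end:
                raise ValueError(f"overlapping HSBs on {ref_chrom}")
            if _continuous(left, right, homeology.resolution):
                continue
            start, end = int(left.r_end), int(right.r_start)
            if end - start < MIN_EBR_BP:
                start, end = start - MIN_EBR_BP, end + MIN_EBR_BP
            rec = EBR(str(ref_chrom), start, end,
                      excluded=(end - start) > MAX_EBR_BP)
            rec.extra["left"] = left.to_dict()
            rec.extra["right"] = right.to_dict()
            ebrs.append(rec)
    return ebrs


def _junction_edge(block, side: str) -> tuple[int, str]:
    """Reference coordinate of the block edge facing a target junction.

    ``side`` is which side of the *target* interval faces the junction.
    Returns (edge coordinate, outward direction on the reference:
    'up' = higher coordinates, 'down' = lower).
    """
    facing_high_t = side == "t_end"
    if block["orientation"] == "-":
        facing_high_t = not facing_high_t
    if facing_high_t:
        return int(block["r_end"]), "up"
    return int(block["r_start"]), "down"


def _fusion_flank(df, ref_chrom: str, edge: int, direction: str) -> tuple[int, int]:
    """Reference interval flanking a fusion junction: the gap to the next
    HSB outward, or 10 kb inward when the edge is chromosome-terminal."""
    sub = df[df["ref_chrom"] == ref_chrom]
    if direction == "up":
        beyond = sub[sub["r_start"] >= edge]
        if len(beyond):
            return edge, int(beyond["r_start"].min())
        return max(0, edge - TERMINAL_FLANK_BP), edge
    below = sub[sub["r_end"] <= edge]
    if len(below):
        return int(below["r_end"].max()), edge
    return edge, edge + TERMINAL_FLANK_BP


def classify_ebrs(
    ebrs: list[EBR],
    homeology: HomeologyMap,
    target_karyotype=None,
) -> list[EBR]:
    """Type the reference-side EBRs and emit fusion records from
    target-side junctions.

    Reference-adjacent blocks on the same target chromosome give
    ``intra``; on different target chromosomes, ``fission``.  Each target
    junction joining blocks of two reference chromosomes emits one
    ``fusion`` record per reference flank (sharing an event group), the
    flank being the chromosome-terminal interval adjacent to the
    junction block.  ``well_defined`` requires both flanking blocks
    oriented (not '?').
    """
    df = homeology.hsbs
    typed: list[EBR] = []
    group = 0

    for rec in ebrs:
        left, right = rec.extra["left"], rec.extra["right"]
        rec.ebr_type = "intra" if left["target_chrom"] == right["target_chrom"] else "fission"
        rec.target_chrom = str(left["target_chrom"])
        rec.well_defined = "?" not in (left["orientation"], right["orientation"])
        if rec.ebr_type == "intra":
            t_lo = min(int(left["t_end"]), int(right["t_end"]))
            t_hi = max(int(left["t_start"]), int(right["t_start"]))
            if t_hi - t_lo < MIN_EBR_BP:
                t_lo, t_hi = t_lo - MIN_EBR_BP, t_hi + MIN_EBR_BP
            rec.extra["target_interval"] = (rec.target_chrom, max(0, t_lo), max(0, t_hi))
        typed.append(rec)

    # pair the two intra EBRs flanking one inverted block into one event
    by_ref: dict[str, list[EBR]] = {}
    for rec in typed:
        by_ref.setdefault(rec.ref_chrom, []).append(rec)
    paired: set[int] = set()
    for ref_chrom, recs in by_ref.items():
        recs.sort(key=lambda r: r.start)
        for a, b in zip(recs, recs[1:]):
            if a.ebr_type == b.ebr_type == "intra" and id(a) not in paired and id(b) not in paired:
                between = a.extra["right"]
                outer_left = a.extra["left"]["orientation"]
                outer_right = b.extra["right"]["orientation"]
                # an inversion leaves one block whose orientation differs
                # from its two (mutually concordant) neighbours
                if (b.extra["left"]["hsb_id"] == between["hsb_id"]
                        and outer_left == outer_right != between["orientation"]):
                    a.event_group = b.event_group = group
                    paired.add(id(a))
                    paired.add(id(b))
                    group += 1
    for rec in typed:
        if rec.event_group == -1:
            rec.event_group = group
            group += 1

    # target-side junctions between blocks of different reference chromosomes
    if not df.empty:
        for target_chrom, grp in df.groupby("target_chrom", sort=True):
            grp = grp.sort_values("t_start").reset_index(drop=True)
            for k in range(len(grp) - 1):
                a, b = grp.iloc[k], grp.iloc[k + 1]
                if a.ref_chrom == b.ref_chrom:
                    continue
                edge_a, dir_a = _junction_edge(a, "t_end")
                edge_b, dir_b = _junction_edge(b, "t_start")
                flank_a = _fusion_flank(df, a.ref_chrom, edge_a, dir_a)
                flank_b = _fusion_flank(df, b.ref_chrom, edge_b, dir_b)
                well = "?" not in (a.orientation, b.orientation)
                jt_lo, jt_hi = int(a.t_end), int(b.t_start)
                if jt_hi - jt_lo < MIN_EBR_BP:
                    jt_lo, jt_hi = jt_lo - MIN_EBR_BP, jt_hi + MIN_EBR_BP
                target_interval = (str(target_chrom), max(0, jt_lo), max(0, jt_hi))
                for (chrom, flank, partner) in (
                    (a.ref_chrom, flank_a, (b.ref_chrom, *flank_b)),
                    (b.ref_chrom, flank_b, (a.ref_chrom, *flank_a)),
                ):
                    start, end = flank
                    if end - start < MIN_EBR_BP:
                        start, end = start - MIN_EBR_BP, end + MIN_EBR_BP
                    rec = EBR(str(chrom), int(start), int(end), "fusion",
                              target_chrom=str(target_chrom), partner=partner,
                              well_defined=well, event_group=group,
                              excluded=(end - start) > MAX_EBR_BP)
                    rec.extra["target_interval"] = target_interval
                    typed.append(rec)
                group += 1

    # a fusion flank coinciding with a fission gap is one biological event
    fissions = [r for r in typed if r.ebr_type == "fission"]
    for fus in (r for r in typed if r.ebr_type == "fusion"):
        for fis in fissions:
            if fus.overlaps(fis):
                fis.event_group = fus.event_group
                break
    return typed


def event_counts(typed: list[EBR]) -> dict[str, int]:
    """Number of distinct events per type (event groups counted once;
    a shared fission/fusion group counts toward both types)."""
    counts = {"intra": 0, "fusion": 0, "fission": 0}
    for etype in counts:
        groups = {r.event_group for r in typed if r.ebr_type == etype}
        counts[etype] = len(groups)
    return counts


def assign_lineage(
    ebrs_by_species: dict[str, list[EBR]],
    tree: str | dendropy.Tree,
    slack_bp: int = 150_000,
) -> dict[str, list[EBR]]:
    """Label each species' EBRs as lineage-specific or shared.

    An EBR is specific to species S iff no other species has an EBR
    whose reference interval overlaps it within ``slack_bp``.  Shared
    EBRs are labeled with the smallest clade (MRCA on the given tree)
    containing all disrupted species.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tree.is_rooted = True
    taxa = {t.label: t for t in tree.taxon_namespace}

    for species, recs in ebrs_by_species.items():
        for rec in recs:
            disrupted = {species}
            for other, other_recs in ebrs_by_species.items():
                if other == species:
                    continue
                if any(rec.overlaps(o, slack=slack_bp) for o in other_recs):
                    disrupted.add(other)
            if disrupted == {species}:
                rec.lineage = species
            else:
                labels = [s for s in disrupted if s in taxa]
                if len(labels) < len(disrupted):
                    missing = disrupted - set(labels)
                    logger.warning("species missing from tree: %s", sorted(missing))
                if len(labels) >= 2:
                    mrca = tree.mrca(taxa=[taxa[s] for s in labels])
                    rec.lineage = mrca.label or "+".join(sorted(labels))
                else:
                    rec.lineage = "+".join(sorted(disrupted))
    return ebrs_by_species
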