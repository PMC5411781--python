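"""Anchoring PCFs to chromosomes with a cytogenetic probe map.

A FISH-derived map gives, per chromosome, the relative order of probes.
Each PCF is assigned to the chromosome carrying the majority of its
probes; probes on two or more chromosomes flag the PCF as a candidate
mis-join.  Assigned PCFs are ordered by the mean map position of their
probes and oriented by the sign of the rank correlation between probe
coordinates inside the PCF and their map order — PCFs with a single
probe (or exactly tied ranks) keep unknown ('?') orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CytogeneticMap",
    "ChromosomeBuild",
    "assign_pcfs",
    "order_and_orient",
    "placement_stats",
]


@dataclass
class CytogeneticMap:
    """Per-chromosome ordered probe lists with relative positions."""

    table: pd.DataFrame  # columns: chrom, order_index, probe_id, map_position

    def __post_init__(self):
        required = {"chrom", "order_index", "probe_id", "map_position"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        for chrom, grp in self.table.groupby("chrom"):
            idx = grp.sort_values("order_index")
            if idx["order_index"].duplicated().any():
                raise ValueError(f"duplicate order indices on {chrom}")
            if not idx["map_position"].is_monotonic_increasing:
                raise ValueError(f"map positions not monotone with order on {chrom}")

    def chrom_of(self, probe_id: str) -> str | None:
        hit = self.table[self.table["probe_id"] == probe_id]
        return None if hit.empty else str(hit.iloc[0]["chrom"])

    def lookup(self) -> pd.DataFrame:
        return self.table.set_index("probe_id")


@dataclass
class ChromosomeBuild:
    chrom: str
    entries: list[tuple[str, str]] = field(default_factory=list)  # (pcf_id, orientation)
    placed_bp: int = 0
    oriented_bp: int = 0


def assign_pcfs(
    probe_to_pcf: pd.DataFrame,
    cyto_map: CytogeneticMap,
) -> tuple[pd.DataFrame, list[dict]]:
    """Assign each PCF to the chromosome holding the majority of its probes.

    ``probe_to_pcf`` columns: probe_id, pcf_id, pcf_pos (alignment
    position of the probe inside the PCF).  Probes absent from the map
    are ignored with a log entry.  PCFs whose probes sit on two or more
    chromosomes without a strict majority become conflict records and
    receive no assignment; any PCF touching >= 2 chromosomes is reported
    as an interchromosomal conflict (candidate mis-join).
    """
    lookup = cyto_map.lookup()
    rows = []
    for r in probe_to_pcf.itertuples(index=False):
        if r.probe_id not in lookup.index:
            logger.warning("probe %s absent from cytogenetic map; ignored", r.probe_id)
            continue
        hit = lookup.loc[r.probe_id]
        rows.append({
            "probe_id": r.probe_id, "pcf_id": r.pcf_id, "pcf_pos": r.pcf_pos,
            "chrom": hit["chrom"], "order_index": hit["order_index"],
            "map_position": hit["map_position"],
        })
    placed = pd.DataFrame(rows)
    assignments = []
    conflicts = []
    if placed.empty:
        return placed, conflicts
    for pcf_id, grp in placed.groupby("pcf_id", sort=True):
        counts = grp["chrom"].value_counts()
        if len(counts) > 1:
            conflicts.append({
                "pcf_id": pcf_id,
                "chromosomes": sorted(counts.index.tolist()),
                "probe_counts": counts.to_dict(),
            })
            if counts.iloc[0] == counts.iloc[1]:
                continue  # majority undefined: conflict only, no assignment
        assignments.append(grp.assign(assigned_chrom=counts.index[0]))
    table = pd.concat(assignments, ignore_index=True) if assignments else placed.iloc[0:0]
    return table, conflicts


def order_and_orient(
    assignment_table: pd.DataFrame,
    pcf_lengths: dict[str, int],
    on_interleave: str = "raise",
) -> dict[str, ChromosomeBuild]:
    """Order assigned PCFs along each chromosome and orient them.

    Order: by mean map position of each PCF's probes (ties broken by PCF
    length, longer first, and logged).  Orientation: the sign of the
    Kendall rank correlation between within-PCF probe coordinates and
    map order; '+' when concordant, '-' when reversed, '?' for single
    probes or exact ties.  Interleaved probe ranges of two PCFs raise a
    non-monotonicity error listing the offending probes
    (``on_interleave="raise"``), or drop the PCF with the weaker probe
    support from the build (``"drop"``).
    """
    if on_interleave not in ("raise", "drop"):
        raise ValueError("on_interleave must be 'raise' or 'drop'")
    builds: dict[str, ChromosomeBuild] = {}
    if assignment_table.empty:
        return builds
    for chrom, grp in assignment_table.groupby("assigned_chrom", sort=True):
        per_pcf = []
        for pcf_id, probes in grp.groupby("pcf_id"):
            mean_pos = float(probes["map_position"].mean())
            per_pcf.append((mean_pos, pcf_id, probes))
        by_pos = sorted(per_pcf, key=lambda t: (t[0], -pcf_lengths.get(t[1], 0)))
        seen_means = [t[0] for t in by_pos]
        if len(set(seen_means)) != len(seen_means):
            logger.warning("tied mean map positions on %s broken by PCF length", chrom)

        while by_pos:
            offense = _find_interleave(by_pos)
            if offense is None:
                break
            id_a, id_b, message = offense
            if on_interleave == "raise":
                raise ValueError(f"interleaved probe ranges on {chrom}: {message}")
            support = {t[1]: len(t[2]) for t in by_pos}
            dropped = min((id_a, id_b),
                          key=lambda i: (support[i], pcf_lengths.get(i, 0)))
            logger.warning(
                "dropping %s from %s: probe range interleaves %s",
                dropped, chrom, id_a if dropped == id_b else id_b,
            )
            by_pos = [t for t in by_pos if t[1] != dropped]

        build = ChromosomeBuild(chrom=str(chrom))
        for _mean_pos, pcf_id, probes in by_pos:
            orient = _orientation(probes)
            build.entries.append((pcf_id, orient))
            length = pcf_lengths.get(pcf_id, 0)
            build.placed_bp += length
            if orient != "?":
                build.oriented_bp += length
        builds[str(chrom)] = build
    return builds


def _orientation(probes: pd.DataFrame) -> str:
    if len(probes) < 2:
        return "?"
    x = probes["pcf_pos"].to_numpy(dtype=float)
    y = probes["order_index"].to_numpy(dtype=float)
    if len(set(x)) < 2 or len(set(y)) < 2:
        return "?"
    tau = stats.kendalltau(x, y).statistic
    if tau > 0:
        return "+"
    if tau < 0:
        return "-"
    return "?"


def _find_interleave(by_pos):
    """First pair of consecutive PCFs whose probe order ranges interleave
    (map order A, B, A means the map contradicts the assignment)."""
    spans = []
    for _mean, pcf_id, probes in by_pos:
        spans.append((pcf_id, probes["order_index"].min(), probes["order_index"].max(),
                      probes["probe_id"].tolist()))
    for (id_a, lo_a, hi_a, pr_a), (id_b, lo_b, hi_b, pr_b) in zip(spans, spans[1:]):
        if lo_b <= hi_a and lo_a <= hi_b:
            return id_a, id_b, f"{id_a} ({pr_a}) vs {id_b} ({pr_b})"
    return None


def placement_stats(
    builds: dict[str, ChromosomeBuild],
    total_assembly_bp: int,
) -> dict:
    """Genome-wide placement summary plus a per-chromosome table."""
    placed_bp = sum(b.placed_bp for b in builds.values())
    oriented_bp = sum(b.oriented_bp for b in builds.values())
    table = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "pcfs_placed": len(b.entries),
                "bp_placed": b.placed_bp,
                "bp_oriented": b.oriented_bp,
            }
            for chrom, b in sorted(builds.items())
        ]
    )
    return {
        "placed_bp": int(placed_bp),
        "placed_fraction": placed_bp / total_assembly_bp if total_assembly_bp else 0.0,
        "oriented_bp": int(oriented_bp),
        "per_chromosome": table,
    }
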