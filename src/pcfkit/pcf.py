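"""Predicted chromosome fragment (PCF) construction and refinement.

Scaffolds are cut wherever an internal syntenic-fragment adjacency has
neither sufficient read-pair physical coverage nor joint support from
the reference and outgroup genome order, then the retained runs are
chained across scaffolds into PCFs using a weighted indicator score.
Candidate chimeric junctions become :class:`SplitJoint` records whose
verification outcomes drive threshold calibration and PCF refinement.

This is a deliberately simplified re-implementation of RACA-style
adjacency reasoning: a transparent indicator score replaces the
probabilistic model, because the reusable pieces are the retention
thresholds and the verification loop, not the scoring internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synteny import AlignmentBlock, SynFrag

logger = logging.getLogger(__name__)

__all__ = [
    "PhysicalCoverageTrack",
    "physical_coverage",
    "AdjacencyOracle",
    "PCFMember",
    "Junction",
    "PCF",
    "SplitJoint",
    "build_pcfs",
    "find_split_joints",
    "calibrate_threshold",
    "refine_pcfs",
    "assembly_stats",
]

TESTABLE_GAP_BP = 6_000  # split regions above this cannot be PCR-verified


# ---------------------------------------------------------------------------
# physical coverage


class PhysicalCoverageTrack:
    """Spanning-fragment counts per scaffold.

    A *fragment* is the full molecule interval implied by a read pair,
    ``[min(start1, start2), max(end1, end2))``; only pairs with both
    ends on the same scaffold, in inward orientation and within
    ``max_insert`` contribute.
    """

    def __init__(self, read_pairs: pd.DataFrame, max_insert: int | None = None):
        starts = np.minimum(read_pairs["start1"], read_pairs["start2"]).to_numpy()
        ends = np.maximum(read_pairs["end1"], read_pairs["end2"]).to_numpy()
        keep = np.ones(len(read_pairs), dtype=bool)
        if "orientation" in read_pairs.columns:
            keep &= (read_pairs["orientation"] == "+-").to_numpy()
        if max_insert is not None:
            keep &= (ends - starts) <= max_insert
        self._by_scaffold: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        scafs = read_pairs["scaffold"].to_numpy()
        for scaf in pd.unique(scafs):
            mask = keep & (scafs == scaf)
            self._by_scaffold[scaf] = (
                np.sort(starts[mask]),
                np.sort(ends[mask]),
            )

    def at(self, scaffold: str, positions) -> np.ndarray:
        """Count of fragments containing each position (start <= p < end)."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        if scaffold not in self._by_scaffold:
            return np.zeros(len(positions), dtype=int)
        starts, ends = self._by_scaffold[scaffold]
        n_started = np.searchsorted(starts, positions, side="right")
        n_ended = np.searchsorted(ends, positions, side="right")
        return (n_started - n_ended).astype(int)

    def gap_coverage(self, scaffold: str, gap_start: int, gap_end: int,
                     mode: str = "min") -> int:
        """Coverage attributed to a joint: the minimum over the gap
        (default; a chimeric junction anywhere in the gap shows through)
        or the value at the gap midpoint."""
        if mode == "midpoint":
            return int(self.at(scaffold, [(gap_start + gap_end) // 2])[0])
        if mode == "min":
            positions = np.arange(gap_start, max(gap_end, gap_start + 1))
            return int(self.at(scaffold, positions).min())
        raise ValueError(f"unknown coverage mode {mode!r}")


def physical_coverage(read_pairs: pd.DataFrame, scaffold: str, positions,
                      max_insert: int | None = None) -> np.ndarray:
    """Spanning-fragment count at each position of one scaffold."""
    track = PhysicalCoverageTrack(read_pairs, max_insert=max_insert)
    return track.at(scaffold, positions)


# ---------------------------------------------------------------------------
# adjacency oracles


class AdjacencyOracle:
    """Answers whether two SFs are adjacent in a genome's order.

    Built from each SF's placement on a genome (reference or outgroup):
    two SFs are adjacent iff they are consecutive along a chromosome of
    that genome and the gap between them is below ``max_gap``.
    """

    def __init__(self, placements: dict[str, tuple[str, int, int, str]], max_gap: int):
        # placements: sf_id -> (chrom, start, end, orientation)
        self.placements = placements
        self.max_gap = max_gap
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for sf_id, (chrom, start, end, _o) in placements.items():
            by_chrom.setdefault(chrom, []).append((start, end, sf_id))
        self._neighbors: dict[str, set[str]] = {sf_id: set() for sf_id in placements}
        for entries in by_chrom.values():
            entries.sort()
            for (s1, e1, a), (s2, e2, b) in zip(entries, entries[1:]):
                if 0 <= s2 - e1 < max_gap:
                    self._neighbors[a].add(b)
                    self._neighbors[b].add(a)

    @classmethod
    def from_sfs(cls, sfs: list[SynFrag], max_gap: int) -> "AdjacencyOracle":
        return cls(
            {sf.sf_id: (sf.ref_chrom, sf.r_start, sf.r_end, sf.orientation) for sf in sfs},
            max_gap,
        )

    def adjacent(self, sf_a: str, sf_b: str) -> bool:
        return sf_b in self._neighbors.get(sf_a, ())


# ---------------------------------------------------------------------------
# PCF data structures


@dataclass
class PCFMember:
    scaffold_id: str
    start: int
    end: int
    orientation: str  # '+', '-' (relative to scaffold coordinates)
    sfs: list[SynFrag] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Junction:
    kind: str  # 'weld' (intra-scaffold, retained) or 'chain' (across scaffolds)
    coverage: int = 0
    score: float = 0.0


@dataclass
class PCF:
    pcf_id: str
    members: list[PCFMember]
    junctions: list[Junction] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(m.length for m in self.members)


@dataclass
class SplitJoint:
    """A candidate chimeric junction inside a scaffold."""

    scaffold_id: str
    gap_start: int
    gap_end: int
    coverage: int
    left_sf: SynFrag
    right_sf: SynFrag
    status: str = "untested"  # untested|confirmed|refuted|alternative_confirmed
    testable: bool = False

    @property
    def gap_len(self) -> int:
        return self.gap_end - self.gap_start

    def set_status(self, status: str) -> None:
        if self.status != "untested":
            raise ValueError(f"status already {self.status}; transitions only from untested")
        if status not in ("confirmed", "refuted", "alternative_confirmed"):
            raise ValueError(f"unknown status {status!r}")
        self.status = status


# ---------------------------------------------------------------------------
# PCF construction


def _fragment_orientation(sfs: list[SynFrag]) -> str:
    """Reference-inherited orientation of a retained scaffold run: '+' if
    its SFs' reference coordinates ascend along the scaffold."""
    if len(sfs) == 1:
        return sfs[0].orientation
    r_starts = [sf.r_start for sf in sfs]
    return "+" if r_starts[-1] >= r_starts[0] else "-"


def build_pcfs(
    sfs: list[SynFrag],
    ref_adjacency: AdjacencyOracle,
    outgroup_adjacency: AdjacencyOracle,
    coverage: PhysicalCoverageTrack,
    threshold_c: int,
    weights: dict | None = None,
    join_min: float = 2.0,
    coverage_mode: str = "min",
) -> tuple[list[PCF], list[SplitJoint]]:
    """Cut scaffolds at unsupported SF adjacencies and chain the retained
    runs into PCFs.

    An intra-scaffold adjacency is retained iff its spanning physical
    coverage is at least ``threshold_c`` OR both the reference and the
    outgroup support the adjacency; otherwise the scaffold is cut there
    and a :class:`SplitJoint` is recorded.  Runs are chained across
    scaffolds when the junction score ``w_ref*I_ref + w_out*I_out +
    w_read*cov_norm`` reaches ``join_min`` (read pairs never span two
    scaffolds, so chaining effectively requires both comparative
    supports).  PCFs inherit reference orientation.
    """
    if threshold_c < 0:
        raise ValueError("threshold_c must be >= 0")
    weights = {"w_ref": 1.0, "w_out": 1.0, "w_read": 1.0, **(weights or {})}

    by_scaffold: dict[str, list[SynFrag]] = {}
    for sf in sfs:
        by_scaffold.setdefault(sf.target_seq, []).append(sf)

    fragments: list[list[SynFrag]] = []
    split_joints: list[SplitJoint] = []
    weld_cov: dict[tuple[str, int], int] = {}

    for scaffold in sorted(by_scaffold):
        run: list[SynFrag] = []
        scaffold_sfs = sorted(by_scaffold[scaffold], key=lambda s: s.t_start)
        for sf in scaffold_sfs:
            if not run:
                run.append(sf)
                continue
            prev = run[-1]
            cov = coverage.gap_coverage(scaffold, prev.t_end, max(sf.t_start, prev.t_end),
                                        mode=coverage_mode)
            comparative = ref_adjacency.adjacent(prev.sf_id, sf.sf_id) and \
                outgroup_adjacency.adjacent(prev.sf_id, sf.sf_id)
            if cov >= threshold_c or comparative:
                weld_cov[(scaffold, sf.sf_id)] = cov
                run.append(sf)
            else:
                split_joints.append(
                    SplitJoint(scaffold, prev.t_end, max(sf.t_start, prev.t_end), cov,
                               left_sf=prev, right_sf=sf,
                               testable=(max(sf.t_start, prev.t_end) - prev.t_end)
                               < TESTABLE_GAP_BP)
                )
                fragments.append(run)
                run = [sf]
        if run:
            fragments.append(run)

    pcfs = _chain_fragments(fragments, ref_adjacency, outgroup_adjacency,
                            coverage, weights, join_min, coverage_mode)
    return pcfs, split_joints


def _chain_fragments(
    fragments: list[list[SynFrag]],
    ref_adj: AdjacencyOracle,
    out_adj: AdjacencyOracle,
    coverage: PhysicalCoverageTrack,
    weights: dict,
    join_min: float,
    coverage_mode: str,
) -> list[PCF]:
    """Greedy highest-score chaining of scaffold runs along the reference."""
    n = len(fragments)
    frag_orient = [_fragment_orientation(run) for run in fragments]

    # index terminal SFs: sf_id -> (fragment index, side); side 0 = scaffold
    # left end, side 1 = scaffold right end
    terminal: dict[str, tuple[int, int]] = {}
    for i, run in enumerate(fragments):
        terminal[run[0].sf_id] = (i, 0)
        terminal.setdefault(run[-1].sf_id, (i, 1))
        if len(run) > 1:
            terminal[run[-1].sf_id] = (i, 1)

    # candidate edges: consecutive terminal SFs along each reference chromosome
    placements = []
    for sf_id, (chrom, start, end, orient) in ref_adj.placements.items():
        if sf_id in terminal:
            placements.append((chrom, start, end, sf_id))
    placements.sort()
    edges = []
    for (c1, s1, e1, a), (c2, s2, e2, b) in zip(placements, placements[1:]):
        if c1 != c2:
            continue
        fa, side_a = terminal[a]
        fb, side_b = terminal[b]
        if fa == fb:
            continue
        score = 0.0
        if ref_adj.adjacent(a, b):
            score += weights["w_ref"]
        if out_adj.adjacent(a, b):
            score += weights["w_out"]
        # read pairs map within single scaffolds only: no read term across
        if score >= join_min:
            edges.append((score, a, b, fa, side_a, fb, side_b))
    edges.sort(key=lambda e: -e[0])

    # greedy matching on fragment ends, cycle-safe via union-find
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    end_used = [[False, False] for _ in range(n)]
    links: dict[tuple[int, int], tuple[int, int, float]] = {}
    for score, a, b, fa, side_a, fb, side_b in edges:
        # the junction must use the reference-facing ends: fragment fa
        # contributes its SF `a` side, fb its SF `b` side
        if end_used[fa][side_a] or end_used[fb][side_b]:
            continue
        ra, rb = find(fa), find(fb)
        if ra == rb:
            logger.warning("circular adjacency support broken at %s-%s (score %.1f)", a, b, score)
            continue
        parent[ra] = rb
        end_used[fa][side_a] = True
        end_used[fb][side_b] = True
        links[(fa, side_a)] = (fb, side_b, score)
        links[(fb, side_b)] = (fa, side_a, score)

    # walk chains
    visited = [False] * n
    pcfs: list[PCF] = []

    for i in range(n):
        if visited[i]:
            continue
        # find a chain start: an end not linked
        if not end_used[i][0]:
            start_side = 0
        elif not end_used[i][1]:
            start_side = 1
        else:
            continue  # interior of a chain; reached from its start
        chain: list[tuple[int, int]] = []  # (fragment, entering side)
        frag, entering = i, start_side
        while True:
            visited[frag] = True
            chain.append((frag, entering))
            leaving = 1 - entering
            nxt = links.get((frag, leaving))
            if nxt is None:
                break
            frag, entering, _score = nxt[0], nxt[1], nxt[2]
        members = []
        junctions = []
        for k, (fi, entering) in enumerate(chain):
            run = fragments[fi]
            base = frag_orient[fi]
            # entering side 0 means we traverse the scaffold left->right
            orient = base if entering == 0 else ("-" if base == "+" else "+")
            members.append(
                PCFMember(run[0].target_seq, run[0].t_start, run[-1].t_end, orient, list(run))
            )
            if k > 0:
                prev_fi, prev_entering = chain[k - 1]
                score = links[(prev_fi, 1 - prev_entering)][2]
                junctions.append(Junction("chain", coverage=0, score=score))
        # orient whole chain so reference coordinates ascend
        first_run, last_run = fragments[chain[0][0]], fragments[chain[-1][0]]
        r_first = min(sf.r_start for sf in first_run)
        r_last = min(sf.r_start for sf in last_run)
        if len(chain) > 1 and r_first > r_last:
            members = [
                PCFMember(m.scaffold_id, m.start, m.end,
                          "-" if m.orientation == "+" else "+", m.sfs)
                for m in reversed(members)
            ]
            junctions = list(reversed(junctions))
        # intra-member welded junction coverages
        full_junctions: list[Junction] = junctions
        pcfs.append(PCF(f"pcf_{len(pcfs)}", members, full_junctions))
    return pcfs


# ---------------------------------------------------------------------------
# split-joint narrowing


def find_split_joints(
    joints: list[SplitJoint],
    fine_blocks: list[AlignmentBlock] | pd.DataFrame,
    resolution: int = 150_000,
) -> list[SplitJoint]:
    """Narrow each joint's gap using finer-granularity alignment blocks.

    A fine block narrows the gap from the left when it is colinear with
    the left flanking SF (same reference chromosome and orientation,
    close in reference), and symmetrically from the right.  The testable
    flag is set iff the narrowed gap is under 6 kb.
    """
    from .synteny import blocks_from_dataframe

    if isinstance(fine_blocks, pd.DataFrame):
        fine_blocks = blocks_from_dataframe(fine_blocks)
    by_scaffold: dict[str, list[AlignmentBlock]] = {}
    for blk in fine_blocks:
        by_scaffold.setdefault(blk.target_seq, []).append(blk)

    out = []
    for joint in joints:
        g0, g1 = joint.gap_start, joint.gap_end
        candidates = [
            b for b in by_scaffold.get(joint.scaffold_id, [])
            if b.t_start < g1 and b.t_end > g0
        ]
        new_g0, new_g1 = g0, g1
        for b in candidates:
            if (b.ref_chrom == joint.left_sf.ref_chrom
                    and b.orientation == joint.left_sf.orientation
                    and _ref_gap(joint.left_sf, b) < resolution):
                new_g0 = max(new_g0, min(b.t_end, g1))
            if (b.ref_chrom == joint.right_sf.ref_chrom
                    and b.orientation == joint.right_sf.orientation
                    and _ref_gap(b, joint.right_sf) < resolution):
                new_g1 = min(new_g1, max(b.t_start, g0))
        if new_g1 < new_g0:
            new_g1 = new_g0
        narrowed = SplitJoint(
            joint.scaffold_id, new_g0, new_g1, joint.coverage,
            joint.left_sf, joint.right_sf, status=joint.status,
            testable=(new_g1 - new_g0) < TESTABLE_GAP_BP,
        )
        out.append(narrowed)
    return out


def _ref_gap(left, right) -> int:
    """Reference-side distance between two aligned pieces (orientation-aware)."""
    if left.orientation == "+" if hasattr(left, "orientation") else True:
        gap = right.r_start - left.r_end
    else:
        gap = left.r_start - right.r_end
    return abs(gap)


# ---------------------------------------------------------------------------
# threshold calibration


def calibrate_threshold(joints: list[SplitJoint]) -> int:
    """Smallest integer coverage threshold maximizing agreement with the
    verification outcomes.

    Agreement A(c) = #(confirmed with coverage >= c) + #(refuted with
    coverage < c); ties break toward the smallest c.  With no refuted
    joints the result degenerates to the minimum confirmed coverage
    (keeping every confirmed joint).  Raises ``ValueError`` when nothing
    was tested.
    """
    confirmed = [j.coverage for j in joints if j.status in ("confirmed",)]
    refuted = [j.coverage for j in joints
               if j.status in ("refuted", "alternative_confirmed")]
    if not confirmed and not refuted:
        raise ValueError("cannot calibrate: no tested joints")
    if not refuted:
        return min(confirmed)
    if not confirmed:
        return max(refuted) + 1
    best_c, best_a = 0, -1
    for c in range(0, max(confirmed + refuted) + 2):
        a = sum(cov >= c for cov in confirmed) + sum(cov < c for cov in refuted)
        if a > best_a:
            best_a, best_c = a, c
    return best_c


# ---------------------------------------------------------------------------
# refinement


def refine_pcfs(
    pcfs: list[PCF],
    joints: list[SplitJoint],
    map_conflicts: list[str] | None = None,
) -> list[PCF]:
    """Apply verification outcomes to the PCF set.

    Confirmed joints are welded permanently (the two scaffold sides are
    re-joined in original order), ``alternative_confirmed`` joints are
    welded in the swapped order suggested by the comparative evidence,
    refuted joints stay split, and PCFs named in ``map_conflicts`` are
    split at their lowest-coverage internal junction (cytogenetic
    evidence wins over any other directive).
    """
    map_conflicts = set(map_conflicts or [])
    working = [PCF(p.pcf_id, list(p.members), list(p.junctions)) for p in pcfs]

    conflicted_scaffolds = {
        m.scaffold_id for p in working if p.pcf_id in map_conflicts for m in p.members
    }

    for joint in joints:
        if joint.status not in ("confirmed", "alternative_confirmed"):
            continue
        if joint.scaffold_id in conflicted_scaffolds:
            logger.warning(
                "joint on %s confirmed but its PCF conflicts with the map; map wins",
                joint.scaffold_id,
            )
            continue
        left_loc = _find_member(working, joint.scaffold_id, end=joint.gap_start)
        right_loc = _find_member(working, joint.scaffold_id, start=joint.gap_end)
        if left_loc is None or right_loc is None:
            continue
        swapped = joint.status == "alternative_confirmed"
        working = _weld(working, left_loc, right_loc, joint, swapped=swapped)

    out: list[PCF] = []
    for p in working:
        if p.pcf_id in map_conflicts and len(p.members) > 1:
            cut = int(np.argmin([j.coverage for j in p.junctions]))
            out.append(PCF(f"{p.pcf_id}.a", p.members[: cut + 1], p.junctions[:cut]))
            out.append(PCF(f"{p.pcf_id}.b", p.members[cut + 1:], p.junctions[cut + 1:]))
        else:
            out.append(p)
    return out


def _find_member(pcfs: list[PCF], scaffold_id: str, start: int | None = None,
                 end: int | None = None):
    for pi, p in enumerate(pcfs):
        for mi, m in enumerate(p.members):
            if m.scaffold_id != scaffold_id:
                continue
            if start is not None and m.start == start:
                return pi, mi
            if end is not None and m.end == end:
                return pi, mi
    return None


def _weld(pcfs: list[PCF], left_loc, right_loc, joint: SplitJoint,
          swapped: bool) -> list[PCF]:
    """Re-join two PCF members split at a (now verified) joint."""
    (pl, ml), (pr, mr) = left_loc, right_loc
    if pl == pr:
        return pcfs  # already in one PCF
    left_p, right_p = pcfs[pl], pcfs[pr]
    # only weld when the members sit at joinable ends of their PCFs
    if ml != len(left_p.members) - 1 or mr != 0:
        return pcfs
    if swapped:
        members = right_p.members + left_p.members
        junctions = right_p.junctions + [Junction("weld", joint.coverage)] + left_p.junctions
    else:
        members = left_p.members + [*right_p.members]
        junctions = left_p.junctions + [Junction("weld", joint.coverage)] + right_p.junctions
    merged = PCF(left_p.pcf_id, members, junctions)
    return [p for i, p in enumerate(pcfs) if i not in (pl, pr)] + [merged]


# ---------------------------------------------------------------------------
# statistics


def assembly_stats(
    items,
    input_total_bp: int | None = None,
    n_sfs: int | None = None,
    n_scaffolds: int | None = None,
) -> dict:
    """Count, N50, total bp, fraction of the input assembly represented,
    and the scaffold:SF accuracy ratio.

    ``items`` may be PCFs, scaffolds, or raw lengths.  N50 is the length
    L such that members of length >= L sum to at least half the total.
    """
    lengths = sorted(
        (item if isinstance(item, (int, np.integer)) else item.length for item in items),
        reverse=True,
    )
    total = int(sum(lengths))
    stats = {"count": len(lengths), "n50": 0, "total_bp": total,
             "pct_of_input": 0.0, "sf_scaffold_ratio": None}
    if lengths:
        acc = 0
        for length in lengths:
            acc += length
            if acc * 2 >= total:
                stats["n50"] = int(length)
                break
    if input_total_bp:
        stats["pct_of_input"] = 100.0 * total / input_total_bp
    if n_sfs and n_scaffolds:
        stats["sf_scaffold_ratio"] = n_scaffolds / n_sfs
    return stats
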