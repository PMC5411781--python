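"""Karyotype rearrangement simulator with complete ground truth.

Generates an ancestor genome (a proxy for the reference species used in
comparative scaffolding), applies a replayable plan of inversions,
fissions, fusions and translocations, shreds the descendant into
scaffolds with optional chimeric mis-joins, simulates mate-pair physical
coverage, and emits CNE / conserved-element / transposable-element
tracks and probe maps.  Every stochastic step records its truth so that
downstream recovery can be scored exactly.

All coordinates are 0-based half-open.  All randomness flows through a
single :class:`numpy.random.Generator` passed explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AncestorGenome",
    "Segment",
    "RearrangementPlan",
    "TruthEBR",
    "TruthSet",
    "Scaffold",
    "apply_rearrangements",
    "random_plan",
    "shred_to_scaffolds",
    "simulate_feature_tracks",
    "plant_probes",
    "alignment_blocks_from_scaffolds",
    "alignment_blocks_from_karyotype",
    "default_ancestor",
]

CNE_ELEMENT_BP = 200
CNE_CELL_BP = 1_000


# ---------------------------------------------------------------------------
# core genome representations


@dataclass(frozen=True)
class Segment:
    """A contiguous slice of one ancestor chromosome, possibly reversed."""

    chrom: str
    start: int
    end: int
    strand: int = 1  # +1 forward, -1 reversed

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad segment interval {self.start}-{self.end}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def reverse(self) -> "Segment":
        return replace(self, strand=-self.strand)


@dataclass
class AncestorGenome:
    """The ancestor/reference proxy: chromosome sizes plus designated
    multispecies homologous synteny block (msHSB) intervals where CNE
    density is high."""

    chromosomes: list[tuple[str, int]]
    mshsb_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        sizes = dict(self.chromosomes)
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.mshsb_intervals:
            if chrom not in sizes:
                raise ValueError(f"msHSB on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= sizes[chrom]):
                raise ValueError(f"msHSB {chrom}:{start}-{end} out of bounds")
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivals in by_chrom.values():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError("msHSB intervals overlap")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)


Karyotype = dict[str, list[Segment]]
"""A descendant genome: ordered segments of ancestor material per chromosome."""


def karyotype_length(segments: list[Segment]) -> int:
    return sum(seg.length for seg in segments)


@dataclass(frozen=True)
class Op:
    kind: str  # inversion | fission | fusion | translocation
    args: tuple

    def __repr__(self):
        return f"{self.kind}{self.args}"


@dataclass
class RearrangementPlan:
    """An ordered, replayable list of rearrangement operations.

    Coordinates refer to the descendant karyotype as it exists when the
    operation is applied.
    """

    ops: list[Op] = field(default_factory=list)

    def inversion(self, chrom: str, start: int, end: int) -> "RearrangementPlan":
        self.ops.append(Op("inversion", (chrom, start, end)))
        return self

    def fission(self, chrom: str, pos: int) -> "RearrangementPlan":
        self.ops.append(Op("fission", (chrom, pos)))
        return self

    def fusion(self, chrom_a: str, end_a: str, chrom_b: str, end_b: str) -> "RearrangementPlan":
        if end_a not in ("start", "end") or end_b not in ("start", "end"):
            raise ValueError("fusion ends must be 'start' or 'end'")
        self.ops.append(Op("fusion", (chrom_a, end_a, chrom_b, end_b)))
        return self

    def translocation(self, chrom_a: str, pos_a: int, chrom_b: str, pos_b: int) -> "RearrangementPlan":
        self.ops.append(Op("translocation", (chrom_a, pos_a, chrom_b, pos_b)))
        return self

    def __len__(self):
        return len(self.ops)


@dataclass
class TruthEBR:
    """One planted breakpoint record.

    ``anc_pos`` entries are (ancestor chromosome, position) breakpoints;
    an inversion contributes two records sharing an ``event_id``,
    fission one, fusion one (with both flanking ancestor ends recorded).
    """

    event_id: int
    ebr_type: str  # intra | fusion | fission
    anc_positions: list[tuple[str, int]]
    descendant_pos: tuple[str, int] | None = None
    op_index: int = -1


@dataclass
class ChimericJoint:
    scaffold_id: str
    position: int  # scaffold coordinate of the junction
    left_source: Segment
    right_source: Segment
    zero_coverage: bool = False


@dataclass
class Scaffold:
    """A sequenced scaffold: one (intact) or more (chimeric) descendant
    intervals concatenated."""

    scaffold_id: str
    pieces: list[tuple[str, int, int, int]]  # (desc_chrom, start, end, strand)

    @property
    def length(self) -> int:
        return sum(end - start for _, start, end, _ in self.pieces)

    @property
    def is_chimeric(self) -> bool:
        return len(self.pieces) > 1


@dataclass
class TruthSet:
    karyotype: Karyotype
    ebrs: list[TruthEBR] = field(default_factory=list)
    chimeric_joints: list[ChimericJoint] = field(default_factory=list)
    probe_truth: pd.DataFrame | None = None

    def ebr_counts(self) -> dict[str, int]:
        counts = {"intra": 0, "fusion": 0, "fission": 0}
        seen: set[tuple[int, str]] = set()
        for rec in self.ebrs:
            key = (rec.event_id, rec.ebr_type)
            if key not in seen:
                seen.add(key)
                counts[rec.ebr_type] += 1
        return counts


# ---------------------------------------------------------------------------
# rearrangement engine


def _split_segments(segments: list[Segment], pos: int) -> tuple[list[Segment], list[Segment]]:
    """Cut a segment list at karyotype coordinate ``pos``."""
    total = karyotype_length(segments)
    if not (0 <= pos <= total):
        raise ValueError(f"cut position {pos} outside chromosome of length {total}")
    left: list[Segment] = []
    right: list[Segment] = []
    offset = 0
    for seg in segments:
        if pos <= offset:
            right.append(seg)
        elif pos >= offset + seg.length:
            left.append(seg)
        else:
            cut = pos - offset
            if seg.strand == 1:
                left.append(replace(seg, end=seg.start + cut))
                right.append(replace(seg, start=seg.start + cut))
            else:
                left.append(replace(seg, start=seg.end - cut))
                right.append(replace(seg, end=seg.end - cut))
        offset += seg.length
    return left, right


def _anc_position(segments: list[Segment], pos: int) -> tuple[str, int]:
    """Map a karyotype coordinate to its ancestor (chrom, position)."""
    offset = 0
    for seg in segments:
        if offset <= pos <= offset + seg.length:
            if pos < offset + seg.length or seg is segments[-1]:
                inner = pos - offset
                if seg.strand == 1:
                    return seg.chrom, seg.start + inner
                return seg.chrom, seg.end - inner
        offset += seg.length
    raise ValueError(f"position {pos} outside chromosome")


def apply_rearrangements(
    ancestor: AncestorGenome, plan: RearrangementPlan
) -> tuple[Karyotype, TruthSet]:
    """Replay ``plan`` on the ancestor and record the planted truth.

    Fusion junctions are recorded in descendant coordinates, fission
    breaks (and inversion ends) in ancestor coordinates.  Raises
    ``ValueError`` naming the offending op index on invalid coordinates.
    """
    karyotype: Karyotype = {
        name: [Segment(name, 0, length)] for name, length in ancestor.chromosomes
    }
    order = [name for name, _ in ancestor.chromosomes]
    truth = TruthSet(karyotype={})
    fission_counter = 0
    fusion_counter = 0

    for i, op in enumerate(plan.ops):
        try:
            if op.kind == "inversion":
                chrom, start, end = op.args
                segs = karyotype[chrom]
                if not (0 <= start < end <= karyotype_length(segs)):
                    raise ValueError(f"inversion interval {start}-{end} invalid")
                anc_a = _anc_position(segs, start)
                anc_b = _anc_position(segs, end)
                left, rest = _split_segments(segs, start)
                mid, right = _split_segments(rest, end - start)
                karyotype[chrom] = left + [s.reverse() for s in reversed(mid)] + right
                truth.ebrs.append(TruthEBR(i, "intra", [anc_a], (chrom, start), i))
                truth.ebrs.append(TruthEBR(i, "intra", [anc_b], (chrom, end), i))
            elif op.kind == "fission":
                chrom, pos = op.args
                segs = karyotype[chrom]
                if not (0 < pos < karyotype_length(segs)):
                    raise ValueError(f"fission position {pos} invalid")
                anc = _anc_position(segs, pos)
                left, right = _split_segments(segs, pos)
                fission_counter += 1
                name_a, name_b = f"{chrom}.a", f"{chrom}.b"
                idx = order.index(chrom)
                del karyotype[chrom]
                karyotype[name_a] = left
                karyotype[name_b] = right
                order[idx : idx + 1] = [name_a, name_b]
                truth.ebrs.append(TruthEBR(i, "fission", [anc], None, i))
            elif op.kind == "fusion":
                chrom_a, end_a, chrom_b, end_b = op.args
                if chrom_a == chrom_b:
                    raise ValueError("cannot fuse a chromosome to itself")
                segs_a = karyotype[chrom_a]
                segs_b = karyotype[chrom_b]
                # orient A so the chosen end is rightmost, B so its end is leftmost
                if end_a == "start":
                    segs_a = [s.reverse() for s in reversed(segs_a)]
                if end_b == "end":
                    segs_b = [s.reverse() for s in reversed(segs_b)]
                junction = karyotype_length(segs_a)
                anc_left = _anc_position(segs_a, junction)
                anc_right = _anc_position(segs_b, 0)
                fusion_counter += 1
                name = f"{chrom_a}+{chrom_b}"
                del karyotype[chrom_a]
                del karyotype[chrom_b]
                order.remove(chrom_b)
                idx = order.index(chrom_a)
                karyotype[name] = segs_a + segs_b
                order[idx] = name
                truth.ebrs.append(
                    TruthEBR(i, "fusion", [anc_left, anc_right], (name, junction), i)
                )
            elif op.kind == "translocation":
                chrom_a, pos_a, chrom_b, pos_b = op.args
                if chrom_a == chrom_b:
                    raise ValueError("translocation needs two chromosomes")
                left_a, right_a = _split_segments(karyotype[chrom_a], pos_a)
                left_b, right_b = _split_segments(karyotype[chrom_b], pos_b)
                anc_a = _anc_position(karyotype[chrom_a], pos_a)
                anc_b = _anc_position(karyotype[chrom_b], pos_b)
                karyotype[chrom_a] = left_a + right_b
                karyotype[chrom_b] = left_b + right_a
                truth.ebrs.append(TruthEBR(i, "fission", [anc_a], None, i))
                truth.ebrs.append(TruthEBR(i, "fission", [anc_b], None, i))
                truth.ebrs.append(TruthEBR(i, "fusion", [anc_a, anc_b], (chrom_a, pos_a), i))
                truth.ebrs.append(TruthEBR(i, "fusion", [anc_b, anc_a], (chrom_b, pos_b), i))
            else:
                raise ValueError(f"unknown op kind {op.kind!r}")
        except (KeyError, ValueError) as exc:
            raise ValueError(f"op {i} ({op}) rejected: {exc}") from exc

    karyotype = {name: karyotype[name] for name in order}
    truth.karyotype = karyotype

    if sum(karyotype_length(s) for s in karyotype.values()) != ancestor.total_bp:
        raise AssertionError("rearrangement lost or duplicated bases")
    return karyotype, truth


def _boundaries(segments: list[Segment]) -> list[int]:
    out = [0]
    offset = 0
    for seg in segments:
        offset += seg.length
        out.append(offset)
    return out


def random_plan(
    ancestor: AncestorGenome,
    n_inversions: int,
    n_fusions: int,
    n_fissions: int,
    rng: np.random.Generator,
    min_event_bp: int = 200_000,
    max_event_bp: int = 1_500_000,
    margin_bp: int = 300_000,
    min_separation_bp: int = 300_000,
    avoid_anc_intervals: list[tuple[str, int, int]] | None = None,
    avoid_pad_bp: int = 50_000,
) -> RearrangementPlan:
    """Sample a valid plan: fusions first (joining whole chromosomes at
    their termini), then fissions, then inversions confined to single
    ancestor segments.  Breakpoints keep ``min_separation_bp`` from each
    other and from chromosome ends so every planted event leaves an
    unambiguous, resolvable signature.  ``avoid_anc_intervals`` keeps
    fission and inversion breakpoints out of the given ancestor regions
    (padded by ``avoid_pad_bp``), e.g. out of msHSBs, mirroring the
    observation that breakpoints avoid conserved synteny blocks.
    """
    plan = RearrangementPlan()
    karyotype: Karyotype = {
        name: [Segment(name, 0, length)] for name, length in ancestor.chromosomes
    }
    avoid = avoid_anc_intervals or []

    def anc_ok(chrom: str, pos: int) -> bool:
        anc_chrom, anc_pos = _anc_position(karyotype[chrom], pos)
        return not any(
            c == anc_chrom and s - avoid_pad_bp <= anc_pos < e + avoid_pad_bp
            for c, s, e in avoid
        )

    def chrom_names():
        return list(karyotype.keys())

    n_chrom_final = len(karyotype) - n_fusions + n_fissions
    if n_chrom_final < 1 or n_fusions > len(karyotype) - 1:
        raise ValueError("more fusions than chromosome ends available")

    for _ in range(n_fusions):
        a, b = rng.choice(chrom_names(), size=2, replace=False)
        end_a = rng.choice(["start", "end"])
        end_b = rng.choice(["start", "end"])
        plan.fusion(a, end_a, b, end_b)
        _replay_last(karyotype, plan)

    def far_from_boundaries(chrom: str, pos: int) -> bool:
        bounds = _boundaries(karyotype[chrom])
        return all(abs(pos - b) >= min_separation_bp for b in bounds)

    for _ in range(n_fissions):
        for _attempt in range(200):
            candidates = [c for c in chrom_names() if karyotype_length(karyotype[c]) >= 2 * margin_bp]
            chrom = rng.choice(candidates)
            length = karyotype_length(karyotype[chrom])
            pos = int(rng.integers(margin_bp, length - margin_bp))
            if far_from_boundaries(chrom, pos) and anc_ok(chrom, pos):
                plan.fission(chrom, pos)
                _replay_last(karyotype, plan)
                break
        else:
            raise RuntimeError("could not place fission with required separation")

    for _ in range(n_inversions):
        for _attempt in range(500):
            chrom = rng.choice(chrom_names())
            segs = karyotype[chrom]
            # pick a segment long enough to host an interior inversion
            offsets = _boundaries(segs)
            seg_idx = [
                k
                for k, seg in enumerate(segs)
                if seg.length >= min_event_bp + 2 * min_separation_bp
            ]
            if not seg_idx:
                continue
            k = int(rng.choice(seg_idx))
            lo = offsets[k] + min_separation_bp
            hi = offsets[k + 1] - min_separation_bp
            size = int(rng.integers(min_event_bp, min(max_event_bp, hi - lo) + 1))
            if hi - lo <= size:
                continue
            start = int(rng.integers(lo, hi - size))
            end = start + size
            if (far_from_boundaries(chrom, start) and far_from_boundaries(chrom, end)
                    and anc_ok(chrom, start) and anc_ok(chrom, end)):
                plan.inversion(chrom, start, end)
                _replay_last(karyotype, plan)
                break
        else:
            raise RuntimeError("could not place inversion with required separation")
    return plan


def _replay_last(karyotype: Karyotype, plan: RearrangementPlan) -> None:
    """Apply the most recently appended op to a working karyotype."""
    op = plan.ops[-1]
    tmp_plan = RearrangementPlan([op])
    # reuse the full engine on a throwaway ancestor-like view
    names = list(karyotype.keys())
    fake_anc = AncestorGenome([(n, karyotype_length(karyotype[n])) for n in names])
    flat = {n: list(karyotype[n]) for n in names}
    # inline application, mirroring apply_rearrangements without truth
    if op.kind == "inversion":
        chrom, start, end = op.args
        left, rest = _split_segments(flat[chrom], start)
        mid, right = _split_segments(rest, end - start)
        flat[chrom] = left + [s.reverse() for s in reversed(mid)] + right
    elif op.kind == "fission":
        chrom, pos = op.args
        left, right = _split_segments(flat[chrom], pos)
        del flat[chrom]
        flat[f"{chrom}.a"] = left
        flat[f"{chrom}.b"] = right
    elif op.kind == "fusion":
        a, end_a, b, end_b = op.args
        segs_a = flat.pop(a)
        segs_b = flat.pop(b)
        if end_a == "start":
            segs_a = [s.reverse() for s in reversed(segs_a)]
        if end_b == "end":
            segs_b = [s.reverse() for s in reversed(segs_b)]
        flat[f"{a}+{b}"] = segs_a + segs_b
    karyotype.clear()
    karyotype.update(flat)
    del fake_anc, tmp_plan


# ---------------------------------------------------------------------------
# scaffolding / shredding


def shred_to_scaffolds(
    karyotype: Karyotype,
    truth: TruthSet,
    rng: np.random.Generator,
    mean_scaffold_bp: int = 1_000_000,
    chimera_rate: float = 0.0,
    n_pairs: int = 50_000,
    insert_mean: float = 3_000.0,
    insert_sd: float = 300.0,
    read_len: int = 100,
    p_chim_zero: float = 0.9,
) -> tuple[list[Scaffold], pd.DataFrame]:
    """Shred the descendant into scaffolds and simulate mate pairs.

    With probability ``chimera_rate`` a scaffold is assembled from two
    fragments originating from different genomic locations; the joint is
    registered in ``truth.chimeric_joints``.  A chimeric joint receives
    zero spanning pairs with probability ``p_chim_zero``, otherwise its
    spanning pairs are thinned to half rate.

    Returns the scaffold list and a read-pair table with columns
    scaffold, start1, end1, start2, end2, orientation.
    """
    if not 0.0 <= chimera_rate <= 1.0:
        raise ValueError("chimera_rate must be in [0, 1]")
    if insert_mean <= 0:
        raise ValueError("insert_mean must be positive")
    if mean_scaffold_bp < insert_mean:
        warnings.warn(
            "mean scaffold length below insert size: coverage calibration unreliable",
            stacklevel=2,
        )

    # cut each descendant chromosome into fragments (Poisson process)
    fragments: list[tuple[str, int, int]] = []
    for chrom, segs in karyotype.items():
        length = karyotype_length(segs)
        pos = 0
        while pos < length:
            frag = max(int(rng.exponential(mean_scaffold_bp)), int(insert_mean) + 1)
            end = min(pos + frag, length)
            fragments.append((chrom, pos, end))
            pos = end

    order = rng.permutation(len(fragments))
    scaffolds: list[Scaffold] = []
    i = 0
    sid = 0
    while i < len(order):
        frag = fragments[order[i]]
        pieces = [(frag[0], frag[1], frag[2], 1)]
        i += 1
        if i < len(order) and rng.random() < chimera_rate:
            other = fragments[order[i]]
            pieces.append((other[0], other[1], other[2], 1))
            i += 1
        # a randomly paired fragment that is the true genomic continuation
        # is not a mis-join; keep it as a single piece
        if len(pieces) == 2 and pieces[0][0] == pieces[1][0] and pieces[0][2] == pieces[1][1]:
            pieces = [(pieces[0][0], pieces[0][1], pieces[1][2], 1)]
        scaf = Scaffold(f"scaffold_{sid}", pieces)
        sid += 1
        scaffolds.append(scaf)
        if len(pieces) == 2:
            joint_pos = pieces[0][2] - pieces[0][1]
            truth.chimeric_joints.append(
                ChimericJoint(
                    scaf.scaffold_id,
                    joint_pos,
                    Segment(pieces[0][0], pieces[0][1], pieces[0][2]),
                    Segment(pieces[1][0], pieces[1][1], pieces[1][2]),
                )
            )

    # mate pairs: scaffold chosen proportional to length
    lengths = np.array([s.length for s in scaffolds], dtype=float)
    eligible = lengths > insert_mean + 4 * insert_sd
    probs = np.where(eligible, lengths, 0.0)
    probs /= probs.sum()
    choice = rng.choice(len(scaffolds), size=n_pairs, p=probs)
    inserts = np.maximum(
        rng.normal(insert_mean, insert_sd, size=n_pairs), 2 * read_len + 1
    ).astype(int)
    starts = np.empty(n_pairs, dtype=int)
    for k in range(n_pairs):
        starts[k] = rng.integers(0, scaffolds[choice[k]].length - inserts[k])
    pairs = pd.DataFrame(
        {
            "scaffold": [scaffolds[c].scaffold_id for c in choice],
            "start1": starts,
            "end1": starts + read_len,
            "start2": starts + inserts - read_len,
            "end2": starts + inserts,
            "orientation": "+-",
        }
    )

    # chimeric joints: zero out or thin spanning pairs
    drop = np.zeros(len(pairs), dtype=bool)
    for joint in truth.chimeric_joints:
        mask = (
            (pairs["scaffold"] == joint.scaffold_id)
            & (pairs["start1"] <= joint.position)
            & (pairs["end2"] > joint.position)
        ).to_numpy()
        if rng.random() < p_chim_zero:
            joint.zero_coverage = True
            drop |= mask
        else:
            drop |= mask & (rng.random(len(pairs)) < 0.5)
    pairs = pairs.loc[~drop].reset_index(drop=True)
    return scaffolds, pairs


# ---------------------------------------------------------------------------
# feature tracks


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        ivals = grp[["start", "end"]].sort_values("start").to_numpy()
        cur_s, cur_e = None, None
        for s, e in ivals:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _subtract_intervals(track: pd.DataFrame, holes: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Remove every element overlapping any hole (elements are short, so
    whole-element deletion keeps deserts exactly empty)."""
    if track.empty or not holes:
        return track
    keep = np.ones(len(track), dtype=bool)
    for chrom, h_start, h_end in holes:
        mask = (
            (track["chrom"] == chrom)
            & (track["start"] < h_end)
            & (track["end"] > h_start)
        ).to_numpy()
        keep &= ~mask
    return track.loc[keep].reset_index(drop=True)


def simulate_feature_tracks(
    ancestor: AncestorGenome,
    karyotype: Karyotype,
    truth: TruthSet,
    rng: np.random.Generator,
    cne_density_mshsb: float = 0.11,
    cne_density_background: float = 0.02,
    desert_halfwidth_bp: int = 50_000,
    fusion_poor_halfwidth_bp: int = 50_000,
    fusion_density_factor: float = 1.0 / 12.0,
    te_params: dict | None = None,
    ce_density: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Emit CNE / conserved-element tracks in ancestor (reference)
    coordinates and a TE track in descendant coordinates.

    CNE elements (fixed 200 bp) are dropped one-per-1-kb cell with a
    Bernoulli probability chosen so the expected base fraction equals the
    configured density per region class.  Intervals of ±``desert_halfwidth_bp``
    around every planted fission site are cleared of CNE bases entirely;
    regions of ±``fusion_poor_halfwidth_bp`` around fusion flanks carry
    ``fusion_density_factor`` times the background density (emulating the
    observation that interchromosomal breakpoints sit in regions roughly
    an order of magnitude poorer in CNEs than intrachromosomal ones,
    with fission sites restricted to outright deserts).
    """
    for name, dens in (("cne_density_mshsb", cne_density_mshsb),
                       ("cne_density_background", cne_density_background)):
        if not 0.0 <= dens <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if desert_halfwidth_bp < 0:
        raise ValueError("desert_halfwidth_bp must be >= 0")

    mshsb = {}
    for chrom, start, end in ancestor.mshsb_intervals:
        mshsb.setdefault(chrom, []).append((start, end))
    fusion_flanks = [
        (chrom, pos)
        for rec in truth.ebrs
        if rec.ebr_type == "fusion"
        for chrom, pos in rec.anc_positions
    ]

    def cell_density(chrom: str, cell_start: int) -> float:
        for s, e in mshsb.get(chrom, []):
            if s <= cell_start and cell_start + CNE_CELL_BP <= e:
                return cne_density_mshsb
        dens = cne_density_background
        mid = cell_start + CNE_CELL_BP // 2
        for c, pos in fusion_flanks:
            if c == chrom and abs(mid - pos) <= fusion_poor_halfwidth_bp:
                return dens * fusion_density_factor
        return dens

    cne_rows = []
    for chrom, length in ancestor.chromosomes:
        n_cells = length // CNE_CELL_BP
        cell_starts = np.arange(n_cells) * CNE_CELL_BP
        dens = np.array([cell_density(chrom, cs) for cs in cell_starts])
        q = dens * CNE_CELL_BP / CNE_ELEMENT_BP
        hit = rng.random(n_cells) < q
        offsets = rng.integers(0, CNE_CELL_BP - CNE_ELEMENT_BP + 1, size=n_cells)
        for cs, off in zip(cell_starts[hit], offsets[hit]):
            cne_rows.append((chrom, int(cs + off), int(cs + off + CNE_ELEMENT_BP)))
    cne = pd.DataFrame(cne_rows, columns=["chrom", "start", "end"])

    deserts = [
        (chrom, max(0, pos - desert_halfwidth_bp), pos + desert_halfwidth_bp)
        for rec in truth.ebrs
        if rec.ebr_type == "fission"
        for chrom, pos in rec.anc_positions
    ]
    cne = _subtract_intervals(cne, deserts)
    cne = _merge_intervals(cne) if not cne.empty else cne

    # conserved elements (inputs to probe feature extraction): mixed lengths
    ce_rows = []
    for chrom, length in ancestor.chromosomes:
        n = int(length * ce_density / 400)  # mean element 400 bp
        starts = np.sort(rng.integers(0, max(1, length - 2000), size=n))
        sizes = rng.integers(3, 800, size=n)
        for s, sz in zip(starts, sizes):
            ce_rows.append((chrom, int(s), int(min(s + sz, length))))
    ce = _merge_intervals(pd.DataFrame(ce_rows, columns=["chrom", "start", "end"]))

    te_params = te_params or {
        "families": {
            "LTR-ERV1": {"density": 0.01, "length": 500, "intra_ebr_multiplier": 2.5},
            "LINE-CR1": {"density": 0.03, "length": 600, "intra_ebr_multiplier": 1.0},
        },
        "enrich_halfwidth_bp": 20_000,
    }
    intra_sites = [
        rec.descendant_pos
        for rec in truth.ebrs
        if rec.ebr_type == "intra" and rec.descendant_pos is not None
    ]
    halfw = te_params.get("enrich_halfwidth_bp", 20_000)
    te_rows = []
    for family, p in te_params["families"].items():
        length_el = p["length"]
        mult = p.get("intra_ebr_multiplier", 1.0)
        for chrom, segs in karyotype.items():
            clen = karyotype_length(segs)
            n_cells = clen // CNE_CELL_BP
            cell_starts = np.arange(n_cells) * CNE_CELL_BP
            q = np.full(n_cells, p["density"] * CNE_CELL_BP / length_el)
            for site_chrom, site_pos in intra_sites:
                if site_chrom == chrom:
                    near = np.abs(cell_starts + CNE_CELL_BP // 2 - site_pos) <= halfw
                    q[near] *= mult
            hit = rng.random(n_cells) < np.minimum(q, 1.0)
            offsets = rng.integers(0, max(1, CNE_CELL_BP - min(length_el, CNE_CELL_BP) + 1), size=n_cells)
            for cs, off in zip(cell_starts[hit], offsets[hit]):
                te_rows.append((chrom, int(cs + off), int(min(cs + off + length_el, clen)), family))
    te = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "family"])
    te = te.sort_values(["chrom", "start"]).reset_index(drop=True)

    return {"cne": cne, "ce": ce, "te": te}


# ---------------------------------------------------------------------------
# probes


_DEFAULT_FEATURE_DISTS = {
    "alignable_fraction": ("uniform", 0.86, 1.0),
    "max_ce_len": ("choice", [0, 100, 250, 350, 500], [0.2, 0.2, 0.2, 0.2, 0.2]),
    "total_repeat_len": ("uniform", 0, 2600),
    "has_ce_ge_3bp": ("bernoulli", 0.9),
    "gene_count": ("poisson", 3.0),
    "mean_conservation_score": ("uniform", 0.0, 1.0),
}


def _draw_feature(spec, rng: np.random.Generator):
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    if kind == "choice":
        return rng.choice(spec[1], p=spec[2]).item()
    if kind == "bernoulli":
        return bool(rng.random() < spec[1])
    if kind == "poisson":
        return int(rng.poisson(spec[1]))
    if kind == "constant":
        return spec[1]
    raise ValueError(f"unknown distribution {kind!r}")


def plant_probes(
    karyotype: Karyotype,
    rng: np.random.Generator,
    spacing_bp: int = 1_000_000,
    position_noise_sd: float = 0.0,
    feature_distributions: dict | None = None,
    probe_len: int = 150_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place one probe at each ``spacing_bp`` window midpoint and build a
    cytogenetic map whose per-chromosome order reflects true positions
    perturbed by Gaussian noise of ``position_noise_sd`` bp.

    Returns (probe table, cytogenetic map).  The probe table carries the
    true descendant coordinates and features drawn from
    ``feature_distributions``; the map has columns chrom, order_index,
    probe_id, map_position (relative, in [0, 1]).
    """
    if spacing_bp <= 0:
        raise ValueError("spacing_bp must be positive")
    dists = feature_distributions or _DEFAULT_FEATURE_DISTS
    probe_rows = []
    map_rows = []
    pid = 0
    for chrom, segs in karyotype.items():
        clen = karyotype_length(segs)
        n = clen // spacing_bp
        mids = [w * spacing_bp + spacing_bp // 2 for w in range(n)]
        noisy = [m + rng.normal(0.0, position_noise_sd) for m in mids] if position_noise_sd else list(mids)
        entries = []
        for m, nm in zip(mids, noisy):
            name = f"probe_{pid}"
            pid += 1
            feats = {key: _draw_feature(spec, rng) for key, spec in dists.items()}
            start = max(0, m - probe_len // 2)
            probe_rows.append(
                {"probe_id": name, "chrom": chrom, "start": start,
                 "end": min(clen, start + probe_len), "true_pos": m, **feats}
            )
            entries.append((nm, name))
        entries.sort()
        for order_index, (nm, name) in enumerate(entries):
            map_rows.append(
                {"chrom": chrom, "order_index": order_index, "probe_id": name,
                 "map_position": min(max(nm / clen, 0.0), 1.0)}
            )
    probes = pd.DataFrame(probe_rows)
    cyto_map = pd.DataFrame(map_rows)
    return probes, cyto_map


# ---------------------------------------------------------------------------
# alignment-block emission (the comparative evidence downstream consumes)


def _scaffold_to_ancestor(scaffold: Scaffold, karyotype: Karyotype) -> list[tuple[int, int, str, int, int, int]]:
    """Project scaffold coordinates onto the ancestor: list of
    (t_start, t_end, anc_chrom, a_start, a_end, strand)."""
    out = []
    offset = 0
    for dchrom, p_start, p_end, p_strand in scaffold.pieces:
        segs = karyotype[dchrom]
        walked = 0
        for seg in segs:
            seg_lo, seg_hi = walked, walked + seg.length
            lo = max(p_start, seg_lo)
            hi = min(p_end, seg_hi)
            if lo < hi:
                t_start = offset + (lo - p_start)
                t_end = offset + (hi - p_start)
                if seg.strand == 1:
                    a_start = seg.start + (lo - seg_lo)
                    a_end = seg.start + (hi - seg_lo)
                else:
                    a_end = seg.end - (lo - seg_lo)
                    a_start = seg.end - (hi - seg_lo)
                out.append((t_start, t_end, seg.chrom, a_start, a_end, seg.strand * p_strand))
            walked += seg.length
        offset += p_end - p_start
    return out


def _emit_blocks(
    runs: list[tuple[str, int, int, str, int, int, int]],
    rng: np.random.Generator,
    block_bp: int,
    gap_bp: int,
    edge_erosion_bp: int,
) -> list[dict]:
    """Erode run ends, then split each run into sub-blocks separated by
    small gaps, mimicking raw pairwise alignment output."""
    rows = []
    for tname, t_start, t_end, achrom, a_start, a_end, strand in runs:
        erode_l = int(rng.integers(0, edge_erosion_bp + 1)) if edge_erosion_bp else 0
        erode_r = int(rng.integers(0, edge_erosion_bp + 1)) if edge_erosion_bp else 0
        if (t_end - t_start) - (erode_l + erode_r) < 2_000:
            erode_l = erode_r = 0
        ts, te = t_start + erode_l, t_end - erode_r
        if strand == 1:
            as_, ae = a_start + erode_l, a_end - erode_r
        else:
            as_, ae = a_start + erode_r, a_end - erode_l
        pos = ts
        a_pos = as_ if strand == 1 else ae
        while pos < te:
            size = min(block_bp, te - pos)
            if te - (pos + size) < gap_bp + 1_000:  # absorb the tail
                size = te - pos
            if strand == 1:
                rows.append(dict(target_seq=tname, t_start=pos, t_end=pos + size,
                                 ref_chrom=achrom, r_start=a_pos, r_end=a_pos + size,
                                 strand="+", identity=1.0))
                a_pos += size + gap_bp
            else:
                rows.append(dict(target_seq=tname, t_start=pos, t_end=pos + size,
                                 ref_chrom=achrom, r_start=a_pos - size, r_end=a_pos,
                                 strand="-", identity=1.0))
                a_pos -= size + gap_bp
            pos += size + gap_bp
    return rows


def alignment_blocks_from_scaffolds(
    scaffolds: list[Scaffold],
    karyotype: Karyotype,
    rng: np.random.Generator,
    block_bp: int = 40_000,
    gap_bp: int = 200,
    edge_erosion_bp: int = 5_000,
) -> pd.DataFrame:
    """Pairwise alignment blocks scaffold↔ancestor, with block-end
    erosion near breakpoints and scaffold ends.

    Raw pairwise alignments localize break-adjacent edges to a few kb,
    so the default erosion here is much smaller than for the
    chromosome-level synteny blocks of
    :func:`alignment_blocks_from_karyotype`."""
    runs = []
    for scaf in scaffolds:
        for t_start, t_end, achrom, a_start, a_end, strand in _scaffold_to_ancestor(scaf, karyotype):
            runs.append((scaf.scaffold_id, t_start, t_end, achrom, a_start, a_end, strand))
    rows = _emit_blocks(runs, rng, block_bp, gap_bp, edge_erosion_bp)
    return pd.DataFrame(rows).sort_values(["target_seq", "t_start"]).reset_index(drop=True)


def alignment_blocks_from_karyotype(
    karyotype: Karyotype,
    rng: np.random.Generator,
    block_bp: int = 40_000,
    gap_bp: int = 200,
    edge_erosion_bp: int = 25_000,
) -> pd.DataFrame:
    """Chromosome-level target↔ancestor alignment blocks (as if the
    descendant were already assembled to chromosomes)."""
    runs = []
    for chrom, segs in karyotype.items():
        offset = 0
        for seg in segs:
            if seg.strand == 1:
                runs.append((chrom, offset, offset + seg.length, seg.chrom, seg.start, seg.end, 1))
            else:
                runs.append((chrom, offset, offset + seg.length, seg.chrom, seg.start, seg.end, -1))
            offset += seg.length
    rows = _emit_blocks(runs, rng, block_bp, gap_bp, edge_erosion_bp)
    return pd.DataFrame(rows).sort_values(["target_seq", "t_start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# convenience ancestors


def default_ancestor(
    n_chromosomes: int = 5,
    chrom_bp: int = 4_000_000,
    mshsb_per_chrom: int = 1,
    mshsb_bp: int = 1_800_000,
    seed: int = 0,
) -> AncestorGenome:
    """A small avian-like ancestor: equal-size chromosomes, one interior
    msHSB each (placed centrally, away from termini)."""
    chroms = [(f"anc{i + 1}", chrom_bp) for i in range(n_chromosomes)]
    mshsb = []
    for name, length in chroms:
        gap = (length - mshsb_per_chrom * mshsb_bp) // (mshsb_per_chrom + 1)
        pos = gap
        for _ in range(mshsb_per_chrom):
            mshsb.append((name, pos, pos + mshsb_bp))
            pos += mshsb_bp + gap
    return AncestorGenome(chroms, mshsb, seed=seed)
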