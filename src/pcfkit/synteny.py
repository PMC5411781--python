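"""Syntenic fragment (SF) detection and homeology maps.

Consumes pairwise alignment blocks (target scaffold or chromosome vs.
one reference genome) and chains colinear runs into SFs at a stated
resolution, the same way synteny-block tools condense raw alignments.
Chaining is dual-gap: both the target-side and the reference-side
inter-block gap must be below the resolution, so insertions on either
genome cannot induce spurious merges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentBlock",
    "SynFrag",
    "HomeologyMap",
    "detect_sfs",
    "build_homeology_map",
    "blocks_from_dataframe",
    "sfs_to_dataframe",
]


@dataclass(frozen=True)
class AlignmentBlock:
    """One raw pairwise alignment block, 0-based half-open on both genomes."""

    target_seq: str
    t_start: int
    t_end: int
    ref_chrom: str
    r_start: int
    r_end: int
    orientation: str  # '+' or '-'
    identity: float | None = None

    def __post_init__(self):
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(f"bad target interval {self.t_start}-{self.t_end}")
        if not (0 <= self.r_start < self.r_end):
            raise ValueError(f"bad reference interval {self.r_start}-{self.r_end}")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")

    @property
    def t_len(self) -> int:
        return self.t_end - self.t_start


@dataclass
class SynFrag:
    """A maximal colinear chain of alignment blocks: the unit RACA-style
    scaffolding reasons about."""

    sf_id: str
    target_seq: str
    t_start: int
    t_end: int
    ref_chrom: str
    r_start: int
    r_end: int
    orientation: str
    n_blocks: int = 1

    @property
    def t_len(self) -> int:
        return self.t_end - self.t_start


def blocks_from_dataframe(df: pd.DataFrame) -> list[AlignmentBlock]:
    """Build blocks from a table with columns target_seq, t_start, t_end,
    ref_chrom, r_start, r_end, strand[, identity]."""
    has_id = "identity" in df.columns
    return [
        AlignmentBlock(
            str(r.target_seq), int(r.t_start), int(r.t_end),
            str(r.ref_chrom), int(r.r_start), int(r.r_end),
            str(r.strand), float(r.identity) if has_id else None,
        )
        for r in df.itertuples(index=False)
    ]


def sfs_to_dataframe(sfs: list[SynFrag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sf_id": sf.sf_id, "target_seq": sf.target_seq,
                "t_start": sf.t_start, "t_end": sf.t_end,
                "ref_chrom": sf.ref_chrom, "r_start": sf.r_start,
                "r_end": sf.r_end, "orientation": sf.orientation,
                "n_blocks": sf.n_blocks,
            }
            for sf in sfs
        ]
    )


def _resolve_target_overlaps(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Overlapping blocks on the target: keep the longer, log the loser."""
    out: list[AlignmentBlock] = []
    for blk in sorted(blocks, key=lambda b: (b.target_seq, b.t_start, -b.t_len)):
        if out and out[-1].target_seq == blk.target_seq and blk.t_start < out[-1].t_end:
            keep, drop = (out[-1], blk) if out[-1].t_len >= blk.t_len else (blk, out[-1])
            logger.warning(
                "overlapping blocks on %s: kept %d-%d, dropped %d-%d",
                blk.target_seq, keep.t_start, keep.t_end, drop.t_start, drop.t_end,
            )
            out[-1] = keep
        else:
            out.append(blk)
    return out


def _chainable(a: AlignmentBlock, b: AlignmentBlock, resolution: int) -> bool:
    """Can block ``b`` (following ``a`` on the target) extend a's chain?"""
    if a.target_seq != b.target_seq or a.ref_chrom != b.ref_chrom:
        return False
    if a.orientation != b.orientation:
        return False
    t_gap = b.t_start - a.t_end
    if t_gap < 0 or t_gap >= resolution:
        return False
    if a.orientation == "+":
        r_gap = b.r_start - a.r_end
    else:
        r_gap = a.r_start - b.r_end
    return 0 <= r_gap < resolution


def detect_sfs(
    blocks: list[AlignmentBlock] | pd.DataFrame,
    resolution: int,
    min_block_bp: int = 5_000,
) -> list[SynFrag]:
    """Chain alignment blocks into syntenic fragments.

    Two consecutive blocks merge iff they share target sequence,
    reference chromosome and orientation, are colinear in both genomes,
    and both inter-block gaps are below ``resolution``.  Blocks shorter
    than ``min_block_bp`` are discarded before chaining.  Output is
    sorted by target coordinate.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if isinstance(blocks, pd.DataFrame):
        blocks = blocks_from_dataframe(blocks)
    blocks = [b for b in blocks if b.t_len >= min_block_bp]
    blocks = _resolve_target_overlaps(blocks)

    sfs: list[SynFrag] = []
    current: list[AlignmentBlock] = []

    def flush():
        if not current:
            return
        first, last = current[0], current[-1]
        r_lo = min(b.r_start for b in current)
        r_hi = max(b.r_end for b in current)
        sfs.append(
            SynFrag(
                sf_id=f"sf_{len(sfs)}",
                target_seq=first.target_seq,
                t_start=first.t_start,
                t_end=last.t_end,
                ref_chrom=first.ref_chrom,
                r_start=r_lo,
                r_end=r_hi,
                orientation=first.orientation,
                n_blocks=len(current),
            )
        )
        current.clear()

    for blk in blocks:
        if current and _chainable(current[-1], blk, resolution):
            current.append(blk)
        else:
            flush()
            current.append(blk)
    flush()
    return sfs


@dataclass
class HomeologyMap:
    """Chromosome-scale synteny: per (target chromosome, reference
    chromosome) the ordered homologous synteny blocks (HSBs)."""

    resolution: int
    hsbs: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: hsb_id, target_chrom, t_start, t_end, ref_chrom, r_start,
    #          r_end, orientation

    def per_pair(self) -> dict[tuple[str, str], pd.DataFrame]:
        return {
            (t, r): grp.sort_values("r_start").reset_index(drop=True)
            for (t, r), grp in self.hsbs.groupby(["target_chrom", "ref_chrom"], sort=True)
        }

    def reference_chromosomes(self) -> list[str]:
        return sorted(self.hsbs["ref_chrom"].unique())


def build_homeology_map(
    blocks: list[AlignmentBlock] | pd.DataFrame,
    resolution: int,
    min_block_bp: int = 5_000,
) -> HomeologyMap:
    """Chain chromosome-level alignment blocks into an HSB map at the
    given resolution.  Each target base inside a block maps to exactly
    one reference block (blocks never overlap on the target after
    conflict resolution in :func:`detect_sfs`)."""
    sfs = detect_sfs(blocks, resolution=resolution, min_block_bp=min_block_bp)
    df = sfs_to_dataframe(sfs)
    if df.empty:
        return HomeologyMap(resolution=resolution, hsbs=df)
    df = df.rename(columns={"sf_id": "hsb_id", "target_seq": "target_chrom"})
    df = df.sort_values(["ref_chrom", "r_start"]).reset_index(drop=True)
    df = _resolve_reference_overlaps(df)
    return HomeologyMap(resolution=resolution, hsbs=df)


def _resolve_reference_overlaps(df: pd.DataFrame) -> pd.DataFrame:
    """Reference-side overlaps between HSBs (possible when the target is
    an imperfect assembly duplicating reference context): drop contained
    blocks, trim partial overlaps to the previous block's end."""
    keep = []
    prev_end: dict[str, int] = {}
    for row in df.to_dict("records"):
        chrom = row["ref_chrom"]
        end = prev_end.get(chrom, 0)
        if row["r_start"] < end:
            if row["r_end"] <= end:
                logger.warning(
                    "dropping HSB %s contained within another on %s",
                    row["hsb_id"], chrom,
                )
                continue
            logger.warning(
                "trimming HSB %s reference overlap on %s (%d -> %d)",
                row["hsb_id"], chrom, row["r_start"], end,
            )
            row = {**row, "r_start": end}
        prev_end[chrom] = row["r_end"]
        keep.append(row)
    return pd.DataFrame(keep).reset_index(drop=True)
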