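"""Universal-probe (BAC clone) scoring, filtering and panel selection.

Implements the cross-species hybridization decision rule: a probe is a
universal candidate when at least 93% of its sequence is alignable with
the other genomes and it either contains a conserved element (CE) of at
least 300 bp, or carries only short repetitive content (< 1290 bp total)
together with at least one CE of >= 3 bp.  Placement concordance follows
the standard clone-placement definition: insert length within the
library mean +- 3 SD and end sequences on opposite strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProbePlacement",
    "ProbeFeatures",
    "filter_concordant",
    "extract_features",
    "classify_universal",
    "select_spaced_panel",
]

ALIGNABLE_MIN = 0.93
CE_LONG_BP = 300
REPEAT_MAX_BP = 1_290


@dataclass(frozen=True)
class ProbePlacement:
    probe_id: str
    library_id: str
    ref_chrom: str
    start: int
    end: int
    strand1: str
    strand2: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("placement start must precede end")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError("strands must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProbeFeatures:
    probe_id: str
    alignable_fraction: float
    max_ce_len: int
    has_ce_ge_3bp: bool
    total_repeat_len: int
    gene_count: int = 0
    mean_conservation_score: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.alignable_fraction <= 1.0:
            raise ValueError("alignable_fraction must be in [0, 1]")
        if self.max_ce_len < 0 or self.total_repeat_len < 0:
            raise ValueError("lengths must be >= 0")


def filter_concordant(
    placements: list[ProbePlacement],
    library_mean_bp: float,
    library_sd_bp: float,
) -> list[ProbePlacement]:
    """Keep placements whose implied insert length lies within
    mean +- 3 SD and whose end sequences map to opposite strands."""
    if library_mean_bp <= 0 or library_sd_bp <= 0:
        raise ValueError("library statistics must be positive")
    lo = library_mean_bp - 3 * library_sd_bp
    hi = library_mean_bp + 3 * library_sd_bp
    return [
        p for p in placements
        if lo <= p.length <= hi and p.strand1 != p.strand2
    ]


def _clipped_overlap(track: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    if track is None or track.empty:
        return pd.DataFrame(columns=["start", "end"])
    sub = track[(track["chrom"] == chrom) & (track["start"] < end) & (track["end"] > start)]
    if sub.empty:
        return pd.DataFrame(columns=["start", "end"])
    clipped = sub[["start", "end"]].copy()
    clipped["start"] = clipped["start"].clip(lower=start)
    clipped["end"] = clipped["end"].clip(upper=end)
    return clipped


def extract_features(
    probe_id: str,
    chrom: str,
    start: int,
    end: int,
    alignable_track: pd.DataFrame | None = None,
    ce_track: pd.DataFrame | None = None,
    repeat_track: pd.DataFrame | None = None,
    gene_track: pd.DataFrame | None = None,
    conservation_track: pd.DataFrame | None = None,
) -> ProbeFeatures:
    """Measure the decision-rule inputs for one probe interval.

    Tracks are BED-like frames (chrom, start, end[, score]) with sorted,
    non-overlapping intervals.  Overlaps are clipped to the probe.
    """
    if end <= start:
        raise ValueError("zero-length probe")
    length = end - start

    aln = _clipped_overlap(alignable_track, chrom, start, end)
    alignable_fraction = float((aln["end"] - aln["start"]).sum()) / length if len(aln) else 0.0

    ce = _clipped_overlap(ce_track, chrom, start, end)
    ce_lens = (ce["end"] - ce["start"]).to_numpy() if len(ce) else np.array([], dtype=int)
    max_ce_len = int(ce_lens.max()) if ce_lens.size else 0
    has_ce_ge_3bp = bool((ce_lens >= 3).any())

    rep = _clipped_overlap(repeat_track, chrom, start, end)
    total_repeat_len = int((rep["end"] - rep["start"]).sum()) if len(rep) else 0

    gene_count = 0
    if gene_track is not None and not gene_track.empty:
        gene_count = int(len(_clipped_overlap(gene_track, chrom, start, end)))

    mean_cons = 0.0
    if conservation_track is not None and not conservation_track.empty:
        sub = conservation_track[
            (conservation_track["chrom"] == chrom)
            & (conservation_track["start"] < end)
            & (conservation_track["end"] > start)
        ]
        if len(sub):
            widths = np.minimum(sub["end"], end) - np.maximum(sub["start"], start)
            mean_cons = float(np.average(sub["score"], weights=widths))

    return ProbeFeatures(
        probe_id=probe_id,
        alignable_fraction=min(alignable_fraction, 1.0),
        max_ce_len=max_ce_len,
        has_ce_ge_3bp=has_ce_ge_3bp,
        total_repeat_len=total_repeat_len,
        gene_count=gene_count,
        mean_conservation_score=mean_cons,
    )


def classify_universal(features: ProbeFeatures | dict) -> str:
    """Apply the universality decision rule.

    Returns ``"universal_candidate"`` iff alignable_fraction >= 0.93 AND
    (max_ce_len >= 300 OR (total_repeat_len < 1290 AND a CE >= 3 bp is
    present)); otherwise ``"restricted"``.
    """
    if isinstance(features, dict):
        f = features
        alignable = f["alignable_fraction"]
        max_ce = f["max_ce_len"]
        repeats = f["total_repeat_len"]
        has_ce3 = f["has_ce_ge_3bp"]
    else:
        alignable = features.alignable_fraction
        max_ce = features.max_ce_len
        repeats = features.total_repeat_len
        has_ce3 = features.has_ce_ge_3bp
    ok = alignable >= ALIGNABLE_MIN and (
        max_ce >= CE_LONG_BP or (repeats < REPEAT_MAX_BP and has_ce3)
    )
    return "universal_candidate" if ok else "restricted"


def select_spaced_panel(
    candidates: pd.DataFrame,
    target_spacing_bp: int,
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy sweep selecting an evenly spaced probe panel per chromosome.

    ``candidates`` needs columns probe_id, chrom, pos (sorted or not).
    The first candidate of each chromosome is always accepted; each
    subsequent candidate is accepted iff it lies >= ``target_spacing_bp``
    beyond the last accepted one.  Returns (panel, uncovered chromosomes)
    where uncovered lists chromosomes present in the index but with no
    candidates (callers pass them via a 'chromosomes' attr or an empty
    group).
    """
    if target_spacing_bp <= 0:
        raise ValueError("target_spacing_bp must be positive")
    rows = []
    uncovered = []
    for chrom, grp in candidates.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        if grp.empty:
            uncovered.append(chrom)
            continue
        last = None
        for r in grp.itertuples(index=False):
            if last is None or r.pos - last >= target_spacing_bp:
                rows.append(r._asdict())
                last = r.pos
    panel = pd.DataFrame(rows, columns=list(candidates.columns))
    return panel, uncovered


def spacing_histogram(panel: pd.DataFrame, bin_bp: int = 500_000) -> pd.DataFrame:
    """Distribution of gaps between consecutive panel probes per chromosome."""
    gaps = []
    for _, grp in panel.groupby("chrom", sort=True):
        pos = grp["pos"].sort_values().to_numpy()
        gaps.extend(np.diff(pos).tolist())
    if not gaps:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    gaps = np.asarray(gaps)
    n_bins = int(gaps.max() // bin_bp) + 1
    counts, edges = np.histogram(gaps, bins=np.arange(0, (n_bins + 1) * bin_bp, bin_bp))
    return pd.DataFrame({
        "bin_start": edges[:-1].astype(int),
        "bin_end": edges[1:].astype(int),
        "count": counts,
    })
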