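"""CNE / TE density statistics around breakpoints and synteny blocks.

The genome is scanned in fixed 1-kb windows, each labeled msHSB,
intra-/fusion-/fission-EBR, or rest (EBR labels win on overlap).  The
headline statistics are per-class CNE densities, the distance from every
zero-CNE window to the nearest window at or above the mean msHSB
density, per-EBR five-slot flanking density profiles, and per-family TE
enrichment of EBR-containing 10-kb windows.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ebr import EBR

__all__ = [
    "WindowTrack",
    "DensityProfile",
    "GroupComparison",
    "flank_density_profile",
    "window_scan",
    "zero_window_distances",
    "mannwhitney_exact_p",
    "compare_groups",
    "te_enrichment",
]

WINDOW_BP = 1_000
MSHSB_MIN_BP = 1_500_000
COVERED_MIN_FRACTION = 0.5
EXACT_MAX_N = 8

CLASS_ORDER = ["msHSB", "intra_EBR", "fusion_EBR", "fission_EBR", "rest"]


# ---------------------------------------------------------------------------
# interval coverage helper


def _interval_bases_per_window(track: pd.DataFrame, chrom: str, n_windows: int,
                               w: int) -> np.ndarray:
    """Base count of track intervals falling in each w-bp window, via a
    difference array over clipped interval projections."""
    out = np.zeros(n_windows, dtype=np.int64)
    if track is None or track.empty:
        return out
    sub = track[track["chrom"] == chrom]
    limit = n_windows * w
    for s, e in sub[["start", "end"]].itertuples(index=False):
        s, e = max(0, int(s)), min(limit, int(e))
        if s >= e:
            continue
        w0, w1 = s // w, (e - 1) // w
        if w0 == w1:
            out[w0] += e - s
        else:
            out[w0] += (w0 + 1) * w - s
            out[w1] += e - w1 * w
            if w1 > w0 + 1:
                out[w0 + 1: w1] += w
    return out


def interval_bases(track: pd.DataFrame, chrom: str, start: int, end: int) -> int:
    """Bases of a sorted non-overlapping track inside [start, end)."""
    if track is None or track.empty:
        return 0
    sub = track[(track["chrom"] == chrom) & (track["start"] < end) & (track["end"] > start)]
    if sub.empty:
        return 0
    return int((np.minimum(sub["end"], end) - np.maximum(sub["start"], start)).sum())


# ---------------------------------------------------------------------------
# flank profiles


@dataclass
class DensityProfile:
    """Densities for (-2, -1, EBR, +1, +2) windows, each the EBR's size;
    flanks beyond the chromosome are None.  Window sign follows genomic
    coordinate: '-' slots lie at lower coordinates."""

    ebr: EBR
    densities: list[float | None]  # exactly 5 slots


def flank_density_profile(ebr: EBR, cne_track: pd.DataFrame, chrom_length: int) -> DensityProfile:
    """CNE base fraction in the EBR and two same-size windows on each side."""
    size = ebr.length
    if size == 0:
        raise ValueError("zero-length EBR; extend before profiling")
    slots = []
    for k in (-2, -1, 0, 1, 2):
        start = ebr.start + k * size
        end = start + size
        if start < 0 or end > chrom_length:
            slots.append(None)
            continue
        slots.append(interval_bases(cne_track, ebr.ref_chrom, start, end) / size)
    return DensityProfile(ebr=ebr, densities=slots)


# ---------------------------------------------------------------------------
# window scan


@dataclass
class WindowTrack:
    """Fixed-width window table: chrom, start, end, covered_bases,
    cne_bases, te_bases, class, usable."""

    width: int
    table: pd.DataFrame

    def usable(self) -> pd.DataFrame:
        return self.table[self.table["usable"]]

    def class_means(self) -> pd.Series:
        usable = self.usable()
        return usable.groupby("class")["cne_density"].mean()


def window_scan(
    chromosomes: dict[str, int],
    cne_track: pd.DataFrame,
    mshsb_intervals: list[tuple[str, int, int]],
    typed_ebrs: list[EBR],
    w: int = WINDOW_BP,
    te_track: pd.DataFrame | None = None,
    coverage_track: pd.DataFrame | None = None,
) -> WindowTrack:
    """Label every w-bp window and count CNE/TE bases in it.

    msHSB intervals shorter than 1.5 Mb are dropped before labeling; an
    EBR label always wins over msHSB on overlap; EBRs flagged excluded
    (> 100 kb) or not well-defined do not label windows.  Windows with
    more than half their bases uncovered are unusable; the terminal
    short window of each chromosome is dropped.
    """
    mshsb_intervals = [iv for iv in mshsb_intervals if iv[2] - iv[1] > MSHSB_MIN_BP]
    frames = []
    for chrom, length in sorted(chromosomes.items()):
        n_windows = length // w
        if n_windows == 0:
            continue
        starts = np.arange(n_windows, dtype=np.int64) * w
        cne = _interval_bases_per_window(cne_track, chrom, n_windows, w)
        te = _interval_bases_per_window(te_track, chrom, n_windows, w)
        if coverage_track is not None:
            covered = _interval_bases_per_window(coverage_track, chrom, n_windows, w)
        else:
            covered = np.full(n_windows, w, dtype=np.int64)

        label = np.full(n_windows, "rest", dtype=object)
        for c, s, e in mshsb_intervals:
            if c == chrom:
                label[_window_slice(s, e, w, n_windows)] = "msHSB"
        for rec in typed_ebrs:
            if rec.ref_chrom != chrom or rec.excluded or not rec.well_defined:
                continue
            label[_window_slice(rec.start, rec.end, w, n_windows)] = f"{rec.ebr_type}_EBR"

        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + w,
            "covered_bases": covered, "cne_bases": cne, "te_bases": te,
            "class": label, "usable": covered > w * COVERED_MIN_FRACTION,
        }))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "covered_bases", "cne_bases",
                 "te_bases", "class", "usable"])
    table["cne_density"] = table["cne_bases"] / w
    return WindowTrack(width=w, table=table)


def _window_slice(start: int, end: int, w: int, n_windows: int) -> slice:
    """Windows overlapping [start, end) by any amount."""
    lo = max(0, start // w)
    hi = min(n_windows, (end + w - 1) // w)
    return slice(lo, hi)


# ---------------------------------------------------------------------------
# zero-window distances


def zero_window_distances(
    track: WindowTrack,
    mshsb_mean_density: float | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Distance (in windows, bidirectional minimum within the chromosome)
    from each usable zero-CNE window to the nearest usable window whose
    density reaches the mean msHSB density.

    Returns (per-class distance arrays, per-class counts of zero windows
    excluded because their chromosome has no qualifying window).
    """
    usable = track.usable()
    if mshsb_mean_density is None:
        ms = usable[usable["class"] == "msHSB"]
        if ms.empty:
            raise ValueError("no msHSB windows to compute the threshold density from")
        mshsb_mean_density = float(ms["cne_density"].mean())

    distances: dict[str, list[int]] = {c: [] for c in CLASS_ORDER}
    excluded: dict[str, int] = {c: 0 for c in CLASS_ORDER}
    for chrom, grp in usable.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        idx = (grp["start"].to_numpy() // track.width).astype(np.int64)
        dens = grp["cne_density"].to_numpy()
        classes = grp["class"].to_numpy()
        qualify = idx[dens >= mshsb_mean_density]
        zero_mask = grp["cne_bases"].to_numpy() == 0
        for wi, cls in zip(idx[zero_mask], classes[zero_mask]):
            if qualify.size == 0:
                excluded[cls] += 1
                continue
            pos = np.searchsorted(qualify, wi)
            best = math.inf
            if pos < qualify.size:
                best = min(best, qualify[pos] - wi)
            if pos > 0:
                best = min(best, wi - qualify[pos - 1])
            distances[cls].append(int(best))
    return ({c: np.asarray(v, dtype=int) for c, v in distances.items()}, excluded)


# ---------------------------------------------------------------------------
# group comparisons


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by complete enumeration of all
    label assignments (valid with ties; feasible for small groups).

    The two-sided p is the probability, over all C(n+m, n) assignments,
    of a U deviating from its mean nm/2 at least as much as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)
    obs_u = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    obs_dev = abs(obs_u - center)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        if abs(u - center) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return count / total


@dataclass
class GroupComparison:
    groups: dict[str, dict]
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05


def compare_groups(
    samples: dict[str, np.ndarray],
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
) -> GroupComparison:
    """Kruskal-Wallis omnibus test followed by all pairwise two-sided
    Mann-Whitney tests (exact by enumeration for groups of <= 8, normal
    approximation with tie correction otherwise), with raw and
    Benjamini-Hochberg-adjusted p values.

    Pairwise tests are only run when the omnibus p is below ``alpha``.
    Groups with fewer than 2 observations are excluded with a warning.
    """
    kept = {}
    for name, vals in samples.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has n < 2; excluded", stacklevel=2)
            continue
        kept[name] = vals
    if len(kept) < 2:
        raise ValueError("need at least two non-empty groups")

    groups = {
        name: {"n": len(v), "median": float(np.median(v)), "mean": float(v.mean())}
        for name, v in kept.items()
    }
    pooled = np.concatenate(list(kept.values()))
    if np.ptp(pooled) == 0:  # constant data: no evidence of any difference
        omnibus_stat, omnibus_p = 0.0, 1.0
    else:
        omnibus_stat, omnibus_p = stats.kruskal(*kept.values())

    pairwise_rows = []
    if omnibus_p < alpha:
        for a, b in itertools.combinations(sorted(kept), 2):
            x, y = kept[a], kept[b]
            if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
                p = mannwhitney_exact_p(x, y)
                u = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                             method="asymptotic").statistic)
            else:
                res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
                u, p = float(res.statistic), float(res.pvalue)
            pairwise_rows.append({"group_a": a, "group_b": b, "U": u, "p_raw": p})
    pairwise = pd.DataFrame(pairwise_rows)
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p_raw"], method=adjust)[1]
    return GroupComparison(groups, float(omnibus_stat), float(omnibus_p), pairwise, alpha)


# ---------------------------------------------------------------------------
# TE enrichment


def te_enrichment(
    te_track: pd.DataFrame,
    typed_ebrs: list[EBR],
    chromosomes: dict[str, int],
    window_bp: int = 10_000,
    min_te_bp: int = 100,
    alpha: float = 0.05,
    ebr_coords: str = "target",
) -> pd.DataFrame:
    """Per-family Welch t-test of TE density in EBR-containing vs other
    10-kb windows.

    ``te_track`` columns: chrom, start, end, family (in the coordinates
    named by ``ebr_coords``; EBR intervals are taken from
    ``rec.extra['target_interval']`` when 'target', else the reference
    interval).  Families whose elements average <= ``min_te_bp`` are
    skipped; the terminal short window of each chromosome is dropped.
    """
    ebr_intervals = []
    for rec in typed_ebrs:
        if ebr_coords == "target" and "target_interval" in rec.extra:
            ebr_intervals.append(rec.extra["target_interval"])
        else:
            ebr_intervals.append((rec.ref_chrom, rec.start, rec.end))

    rows = []
    families = sorted(te_track["family"].unique()) if len(te_track) else []
    for family in families:
        fam = te_track[te_track["family"] == family]
        if (fam["end"] - fam["start"]).mean() <= min_te_bp:
            continue
        dens_in, dens_out = [], []
        for chrom, length in sorted(chromosomes.items()):
            n_windows = length // window_bp
            if n_windows == 0:
                continue
            dens = _interval_bases_per_window(fam, chrom, n_windows, window_bp) / window_bp
            has_ebr = np.zeros(n_windows, dtype=bool)
            for c, s, e in ebr_intervals:
                if c == chrom:
                    has_ebr[_window_slice(s, e, window_bp, n_windows)] = True
            dens_in.extend(dens[has_ebr].tolist())
            dens_out.extend(dens[~has_ebr].tolist())
        if len(dens_in) < 2 or len(dens_out) < 2:
            continue
        t, p = stats.ttest_ind(dens_in, dens_out, equal_var=False)
        rows.append({
            "family": family, "n_ebr_windows": len(dens_in),
            "n_other_windows": len(dens_out),
            "mean_density_ebr": float(np.mean(dens_in)),
            "mean_density_other": float(np.mean(dens_out)),
            "t": float(t), "p_raw": float(p),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    return out
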