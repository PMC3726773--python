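"""Copy-number detection from binned tumor:normal depth ratios.

Read depth is summed in fixed windows tiling each chromosome; windows with
insufficient normal coverage are masked.  Log2 tumor:normal ratios are
library-size normalized and median-centered, change points are proposed
where the difference between flanking window means is large relative to the
pooled standard deviation (a local z statistic), adjacent proposals collapse
to the local maximum, and the resulting segments are merged greedily and
called gain / neutral / loss against symmetric log2 thresholds.  The design
follows depth-ratio change-point segmentation; with the pileup-level
substrate, window count ratios are the natural sufficient statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class DepthWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    count_tumor: int
    count_normal: int
    log2_ratio: float = math.nan
    masked: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if self.count_tumor < 0 or self.count_normal < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class CNASegment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    mean_log2: float
    n_windows: int
    state: str  # loss | neutral | gain

    @property
    def length(self) -> int:
        return self.end - self.start


def bin_depth(
    depth_track: Mapping[str, tuple[np.ndarray, np.ndarray]] | pd.DataFrame,
    window_size: int = 1000,
    min_normal_count: int = 10,
) -> list[DepthWindow]:
    """Tile each chromosome with fixed windows of summed depth.

    ``depth_track`` is either a mapping chrom -> (tumor depth array, normal
    depth array) of per-base depths, or a DataFrame already carrying columns
    chrom, start, end, count_tumor, count_normal (window_size then ignored).
    Windows whose normal count falls below ``min_normal_count`` are masked
    and excluded from segmentation.
    """
    windows: list[DepthWindow] = []
    if isinstance(depth_track, pd.DataFrame):
        for row in depth_track.itertuples(index=False):
            w = DepthWindow(
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                count_tumor=int(row.count_tumor), count_normal=int(row.count_normal),
            )
            w.masked = w.count_normal < min_normal_count
            windows.append(w)
        return windows

    if window_size < 100:
        raise ValueError("window_size must be >= 100")
    for chrom in sorted(depth_track):
        tumor, normal = depth_track[chrom]
        tumor = np.asarray(tumor)
        normal = np.asarray(normal)
        if tumor.shape != normal.shape:
            raise ValueError(f"depth arrays differ in length on {chrom}")
        n_win = tumor.size // window_size
        for i in range(n_win):
            lo, hi = i * window_size, (i + 1) * window_size
            w = DepthWindow(
                chrom=chrom, start=lo, end=hi,
                count_tumor=int(tumor[lo:hi].sum()),
                count_normal=int(normal[lo:hi].sum()),
            )
            w.masked = w.count_normal < min_normal_count
            windows.append(w)
    return windows


def normalize_ratios(windows: Sequence[DepthWindow]) -> list[DepthWindow]:
    """Set library-size-normalized, median-centered log2 ratios in place.

    log2((t/T)/(n/N)) over unmasked windows, then centered so the genome-wide
    median is 0 (assumes a predominantly copy-neutral genome).
    """
    live = [w for w in windows if not w.masked]
    if not live:
        raise ValueError("no unmasked windows to normalize")
    total_t = sum(w.count_tumor for w in live)
    total_n = sum(w.count_normal for w in live)
    if total_t == 0:
        raise ValueError("zero total tumor count")
    ratios = []
    for w in live:
        if w.count_tumor == 0:
            w.masked = True
            continue
        w.log2_ratio = math.log2((w.count_tumor / total_t) / (w.count_normal / total_n))
        ratios.append(w.log2_ratio)
    med = float(np.median(ratios))
    for w in live:
        if not w.masked:
            w.log2_ratio -= med
    return list(windows)


def segment(
    windows: Sequence[DepthWindow],
    flank_w: int = 10,
    z_threshold: float = 5.0,
) -> list[tuple[str, int]]:
    """Propose change points between adjacent retained windows.

    A breakpoint is proposed at boundary i (between retained windows i-1 and
    i of one chromosome) when |mean(left flank) - mean(right flank)| /
    (pooled sd * sqrt(2/flank_w)) >= z_threshold; runs of adjacent proposals
    collapse to their local |z| maximum.  Returns (chrom, boundary index into
    that chromosome's retained windows).
    """
    breakpoints: list[tuple[str, int]] = []
    by_chrom: dict[str, list[DepthWindow]] = {}
    for w in windows:
        if not w.masked:
            by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        vals = np.array([w.log2_ratio for w in ws])
        n = vals.size
        if n < 2 * flank_w:
            continue
        zs = np.zeros(n + 1)
        for i in range(flank_w, n - flank_w + 1):
            left = vals[i - flank_w : i]
            right = vals[i : i + flank_w]
            pooled_var = (left.var(ddof=1) + right.var(ddof=1)) / 2.0
            if pooled_var <= 0:
                pooled_var = 1e-12
            z = abs(left.mean() - right.mean()) / (math.sqrt(pooled_var) * math.sqrt(2.0 / flank_w))
            zs[i] = z
        above = zs >= z_threshold
        i = 0
        while i <= n:
            if above[i]:
                j = i
                while j + 1 <= n and above[j + 1]:
                    j += 1
                best = i + int(np.argmax(zs[i : j + 1]))
                breakpoints.append((chrom, best))
                i = j + 1
            else:
                i += 1
    return sorted(breakpoints)


def merge_and_call(
    windows: Sequence[DepthWindow],
    breakpoints: Sequence[tuple[str, int]],
    gain_threshold: float = 0.25,
    loss_threshold: float = -0.25,
    merge_delta: float = 0.1,
) -> list[CNASegment]:
    """Cut retained windows at the breakpoints, merge near-equal neighbors,
    and call each segment's state from its mean log2 ratio."""
    by_chrom: dict[str, list[DepthWindow]] = {}
    for w in windows:
        if not w.masked:
            by_chrom.setdefault(w.chrom, []).append(w)
    bp_by_chrom: dict[str, list[int]] = {}
    for chrom, idx in breakpoints:
        bp_by_chrom.setdefault(chrom, []).append(idx)

    segments: list[CNASegment] = []
    for chrom, ws in sorted(by_chrom.items()):
        cuts = sorted(set(bp_by_chrom.get(chrom, [])))
        bounds = [0] + [c for c in cuts if 0 < c < len(ws)] + [len(ws)]
        pieces = []
        for lo, hi in zip(bounds, bounds[1:]):
            chunk = ws[lo:hi]
            mean = float(np.mean([w.log2_ratio for w in chunk]))
            pieces.append([chunk[0].start, chunk[-1].end, mean, len(chunk)])
        # greedy merge of adjacent near-equal segments
        merged = [pieces[0]]
        for piece in pieces[1:]:
            prev = merged[-1]
            if abs(piece[2] - prev[2]) < merge_delta:
                total = prev[3] + piece[3]
                prev[2] = (prev[2] * prev[3] + piece[2] * piece[3]) / total
                prev[1] = piece[1]
                prev[3] = total
            else:
                merged.append(piece)
        for start, end, mean, n_win in merged:
            if mean >= gain_threshold:
                state = "gain"
            elif mean <= loss_threshold:
                state = "loss"
            else:
                state = "neutral"
            segments.append(CNASegment(chrom, start, end, mean, n_win, state))
    return segments


def _reciprocal_overlap(a: CNASegment, b: CNASegment) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def compare_segment_sets(
    pre: Sequence[CNASegment],
    post: Sequence[CNASegment],
    reciprocal_overlap: float = 0.5,
) -> dict:
    """Pair non-neutral segments across the two tumors.

    Segments pair when they share chromosome and state and overlap by at
    least ``reciprocal_overlap`` of each segment's length.  Returns shared /
    pre-only / post-only counts and the Jaccard index of gained+lost base
    pairs (state-aware).
    """
    pre_alt = [s for s in pre if s.state != "neutral"]
    post_alt = [s for s in post if s.state != "neutral"]
    used_post: set[int] = set()
    shared = 0
    for a in pre_alt:
        best_j, best_ov = None, 0.0
        for j, b in enumerate(post_alt):
            if j in used_post or b.chrom != a.chrom or b.state != a.state:
                continue
            ov = _reciprocal_overlap(a, b)
            if ov >= reciprocal_overlap and ov > best_ov:
                best_j, best_ov = j, ov
        if best_j is not None:
            used_post.add(best_j)
            shared += 1

    def _bp_set(segs: Iterable[CNASegment]) -> set[tuple[str, str, int]]:
        out = set()
        for s in segs:
            for p in range(s.start, s.end):
                out.add((s.chrom, s.state, p))
        return out

    bp_pre = _bp_set(pre_alt)
    bp_post = _bp_set(post_alt)
    union = len(bp_pre | bp_post)
    jaccard = (len(bp_pre & bp_post) / union) if union else 1.0
    return {
        "shared": shared,
        "pre_only": len(pre_alt) - shared,
        "post_only": len(post_alt) - shared,
        "jaccard_altered_bp": jaccard,
    }


def segments_to_bed(segments: Sequence[CNASegment]) -> str:
    """BED text (0-based half-open): chrom, start, end, mean_log2, state."""
    lines = ["#chrom\tstart\tend\tmean_log2\tstate"]
    for s in segments:
        lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{s.mean_log2:.4f}\t{s.state}")
    return "\n".join(lines) + "\n"
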