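"""Interval arithmetic on half-open [start, end) coordinates.

All functions treat intervals per chromosome independently and use the
half-open overlap rule: [a, b) overlaps [c, d) iff a < d and c < b.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from methyloscope.io_formats import GenomicInterval


def _by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        out[iv.chrom].append(iv)
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or abutting intervals are coalesced."""
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(_by_chrom(intervals).items()):
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def complement_intervals(
    intervals: Iterable[GenomicInterval], chrom_sizes: dict[str, int]
) -> list[GenomicInterval]:
    """Genome minus the union of ``intervals`` over the given chromosomes."""
    merged = _by_chrom(merge_intervals(intervals))
    out: list[GenomicInterval] = []
    for chrom, size in sorted(chrom_sizes.items()):
        pos = 0
        for iv in merged.get(chrom, []):
            start = max(0, min(iv.start, size))
            end = max(0, min(iv.end, size))
            if start > pos:
                out.append(GenomicInterval(chrom, pos, start))
            pos = max(pos, end)
        if pos < size:
            out.append(GenomicInterval(chrom, pos, size))
    return out


def interval_overlap(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query_index, subject_index) pairs that overlap, by sorted sweep.

    Pairs are returned sorted by (query_index, subject_index).
    """
    pairs: list[tuple[int, int]] = []
    q_by = defaultdict(list)
    s_by = defaultdict(list)
    for i, iv in enumerate(queries):
        q_by[iv.chrom].append((iv.start, iv.end, i))
    for j, iv in enumerate(subjects):
        s_by[iv.chrom].append((iv.start, iv.end, j))
    for chrom in set(q_by) & set(s_by):
        ss = sorted(s_by[chrom])
        starts = np.array([s for s, _, _ in ss])
        ends = np.array([e for _, e, _ in ss])
        idxs = np.array([k for _, _, k in ss])
        for q_start, q_end, qi in sorted(q_by[chrom]):
            hi = np.searchsorted(starts, q_end, side="left")
            cand = np.flatnonzero(ends[:hi] > q_start)
            pairs.extend((qi, int(j)) for j in idxs[cand])
    pairs.sort()
    return pairs


def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per query: does it overlap at least one subject interval."""
    hit = np.zeros(len(queries), dtype=bool)
    merged = _by_chrom(merge_intervals(subjects)) if subjects else {}
    for chrom, ivs in merged.items():
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        for qi, q in enumerate(queries):
            if q.chrom != chrom:
                continue
            k = np.searchsorted(ends, q.start, side="right")
            if k < len(starts) and starts[k] < q.end:
                hit[qi] = True
    return hit


def points_in_intervals(
    chroms: Sequence[str], positions: np.ndarray, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per point: does (chrom, pos) fall inside any interval."""
    positions = np.asarray(positions)
    inside = np.zeros(len(positions), dtype=bool)
    merged = _by_chrom(merge_intervals(intervals)) if intervals else {}
    chroms_arr = np.asarray(chroms, dtype=object)
    for chrom, ivs in merged.items():
        mask = chroms_arr == chrom
        if not mask.any():
            continue
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        pos = positions[mask]
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
        inside[np.flatnonzero(mask)] = ok
    return inside
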