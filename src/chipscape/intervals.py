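"""Interval arithmetic on 0-based half-open regions.

Two half-open intervals overlap iff they share at least 1 bp:
``a.start < b.end and b.start < a.end`` on the same chromosome.  This 1-bp
threshold is used uniformly (consensus building, promoter exclusion,
blacklist filtering, read counting).

Scalable operations are backed by sorted numpy arrays (searchsorted /
sweep-line); convenience wrappers accept lists of :class:`GenomicInterval`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .types import GenomicInterval, TssRecord


def _coords(intervals: Sequence) -> tuple[list[str], np.ndarray, np.ndarray]:
    chroms = [iv.chrom for iv in intervals]
    starts = np.fromiter((iv.start for iv in intervals), dtype=np.int64, count=len(intervals))
    ends = np.fromiter((iv.end for iv in intervals), dtype=np.int64, count=len(intervals))
    return chroms, starts, ends


def _group_by_chrom(intervals: Sequence) -> dict[str, np.ndarray]:
    """chrom -> array of original indices."""
    groups: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        groups.setdefault(iv.chrom, []).append(i)
    return {c: np.asarray(ix, dtype=np.int64) for c, ix in groups.items()}


def overlap_pairs(a: Sequence, b: Sequence) -> list[tuple[int, int]]:
    """All index pairs (i, j) with ``a[i]`` overlapping ``b[j]`` by >= 1 bp.

    Symmetric in the sense that swapping the arguments transposes the pair
    set.  Pairs are returned sorted by (i, j).  Sweep-line per chromosome,
    O((n+m) log(n+m) + k) for k output pairs.
    """
    pairs: list[tuple[int, int]] = []
    a_groups = _group_by_chrom(a)
    b_groups = _group_by_chrom(b)
    for chrom in set(a_groups) & set(b_groups):
        ai = a_groups[chrom]
        bi = b_groups[chrom]
        b_starts = np.asarray([b[j].start for j in bi])
        b_ends = np.asarray([b[j].end for j in bi])
        order = np.argsort(b_starts, kind="stable")
        b_starts, b_ends, bi = b_starts[order], b_ends[order], bi[order]
        for i in ai:
            lo = np.searchsorted(b_starts, a[i].end, side="left")
            hit = np.nonzero(b_ends[:lo] > a[i].start)[0]
            pairs.extend((int(i), int(bi[h])) for h in hit)
    pairs.sort()
    return pairs


def overlaps_any(queries: Sequence, subjects: Sequence) -> np.ndarray:
    """Boolean array: query i overlaps >= 1 subject by >= 1 bp."""
    out = np.zeros(len(queries), dtype=bool)
    if not queries or not subjects:
        return out
    s_groups = _group_by_chrom(subjects)
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, si in s_groups.items():
        ivs = merge_coords(
            np.asarray([subjects[j].start for j in si]),
            np.asarray([subjects[j].end for j in si]),
        )
        merged[chrom] = ivs
    for i, q in enumerate(queries):
        if q.chrom not in merged:
            continue
        m_starts, m_ends = merged[q.chrom]
        # merged intervals are disjoint & sorted: candidate is the one whose
        # start is the rightmost <= q.end-1
        k = np.searchsorted(m_starts, q.end, side="left") - 1
        if k >= 0 and m_ends[k] > q.start:
            out[i] = True
    return out


def merge_coords(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Overlap-merge intervals given as coordinate arrays (single chromosome).

    Abutting intervals ([0,10) and [10,20)) are NOT merged: merging is by
    >= 1 bp overlap, consistent with the global overlap convention.
    """
    if len(starts) == 0:
        return starts.copy(), ends.copy()
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for i in range(1, len(s)):
        if s[i] < out_e[-1]:  # strict: >=1 bp overlap
            out_e[-1] = max(out_e[-1], int(e[i]))
        else:
            out_s.append(int(s[i]))
            out_e.append(int(e[i]))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Overlap-merge; output sorted by (chrom, start), pairwise non-overlapping."""
    groups = _group_by_chrom(intervals)
    out: list[GenomicInterval] = []
    for chrom in sorted(groups):
        ix = groups[chrom]
        starts = np.asarray([intervals[i].start for i in ix])
        ends = np.asarray([intervals[i].end for i in ix])
        ms, me = merge_coords(starts, ends)
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(ms, me))
    return out


def count_overlaps_sorted(
    region_starts: np.ndarray,
    region_ends: np.ndarray,
    sorted_read_starts: np.ndarray,
    sorted_read_ends: np.ndarray,
) -> np.ndarray:
    """Per-region count of reads overlapping by >= 1 bp (single chromosome).

    ``sorted_read_starts`` and ``sorted_read_ends`` are the read start/end
    coordinates each sorted ascending (independently).  Count = total −
    #(read.end <= region.start) − #(read.start >= region.end), which is exact
    for half-open overlap.
    """
    n = len(sorted_read_starts)
    before = np.searchsorted(sorted_read_ends, region_starts, side="right")
    after = n - np.searchsorted(sorted_read_starts, region_ends, side="left")
    return n - before - after


def nearest_feature(
    query: GenomicInterval, features: Sequence[TssRecord]
) -> tuple[str, int]:
    """Nearest TSS to a region, with a deterministic tie rule.

    Distance is 0 if the TSS lies within the (half-open) query; otherwise the
    gap from the nearest query edge to the TSS, signed negative for features
    upstream (left) of the query.  Ties on |distance| are broken in favour of
    the upstream feature, then lexicographically smallest gene_id.

    Only features on the query's chromosome are considered; raises if the
    feature list is empty or has no feature on that chromosome.
    """
    if not features:
        raise ValueError("nearest_feature: empty feature list")
    best: tuple[int, int, str] | None = None  # (|d|, upstream_rank, gene_id)
    best_signed = 0
    for f in features:
        if f.chrom != query.chrom:
            continue
        if query.start <= f.tss < query.end:
            signed = 0
        elif f.tss < query.start:
            signed = -(query.start - f.tss)
        else:
            signed = f.tss - query.end
        # upstream (negative) preferred on ties; rank 0 beats 1
        key = (abs(signed), 0 if signed < 0 else 1, f.gene_id)
        if best is None or key < best:
            best = key
            best_signed = signed
    if best is None:
        raise ValueError(f"no feature on chromosome {query.chrom!r}")
    return best[2], best_signed
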