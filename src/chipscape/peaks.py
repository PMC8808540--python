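"""Peak calling (a Poisson stand-in caller), replicate QC, blacklist
filtering, majority-rules consensus and the master set.

The caller is an explicitly documented stand-in for an external
MACS2-style caller: a per-bin Poisson upper-tail test against the larger of
the genome-wide and a 10-kb local input rate, depth-scaled, with
Benjamini-Hochberg correction across bins.  Externally called narrowPeak
files can be supplied instead and bypass it entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .intervals import merge_coords
from .stats import bh_fdr
from .types import GenomicInterval, Peak, SampleMeta


@dataclass
class PeakSet:
    """Peaks of one sample; sorted and non-overlapping after ``normalize``."""

    meta: SampleMeta
    peaks: list[Peak]
    provenance: str = "internal_caller"  # or "external_narrowPeak"

    def __len__(self) -> int:
        return len(self.peaks)

    def normalize(self) -> "PeakSet":
        return PeakSet(self.meta, merge_peaks(self.peaks), self.provenance)


@dataclass
class ConsensusSet:
    """Majority-supported regions of one experimental group."""

    group_key: tuple[str, str, str]  # (cell_type, condition, mark)
    peaks: list[Peak]
    support: list[int]
    n_replicates: int

    def __len__(self) -> int:
        return len(self.peaks)


def merge_peaks(peaks: Sequence[Peak]) -> list[Peak]:
    """Single-linkage overlap merge; the merged region is the union span and
    inherits summit/score/q-value from the highest-scoring member."""
    groups: dict[str, list[Peak]] = {}
    for p in peaks:
        groups.setdefault(p.chrom, []).append(p)
    out: list[Peak] = []
    for chrom in sorted(groups):
        ps = sorted(groups[chrom], key=lambda p: (p.start, p.end))
        run: list[Peak] = []
        run_end = -1
        for p in ps + [None]:  # sentinel flushes the last run
            if p is not None and (not run or p.start < run_end):
                run.append(p)
                run_end = max(run_end, p.end)
                continue
            if run:
                best = max(run, key=lambda q: (q.score, -q.start))
                start = min(q.start for q in run)
                end = max(q.end for q in run)
                out.append(
                    Peak(
                        interval=GenomicInterval(chrom, start, end),
                        summit_offset=best.summit - start,
                        score=best.score,
                        qvalue=min(q.qvalue for q in run),
                        name=best.name,
                    )
                )
            if p is not None:
                run = [p]
                run_end = p.end
    return out


def call_peaks_poisson(
    chip: CoverageTrack,
    control: CoverageTrack,
    q_threshold: float = 0.05,
    local_window: int = 10_000,
    min_width: int = 200,
    meta: SampleMeta | None = None,
) -> PeakSet:
    """Per-bin Poisson enrichment test against a local/global input rate.

    lambda for a bin is ``max(genome-wide input mean, local input mean over
    ``local_window``)`` scaled by the depth ratio N_chip / N_input.
    Significant (BH q < ``q_threshold``) adjacent bins are merged; runs
    shorter than ``min_width`` bp are discarded.  The summit is the centre
    of the bin with the highest ChIP count (leftmost on ties).
    """
    if chip.bin_size != control.bin_size:
        raise ValueError("chip and input tracks have different bin sizes")
    bin_size = chip.bin_size
    chroms = list(chip.data)

    if control.n_reads == 0 or sum(int(v.sum()) for v in control.data.values()) == 0:
        warnings.warn(
            "input track is empty; falling back to genome-wide ChIP mean as lambda"
        )
        total_bins = sum(len(v) for v in chip.data.values())
        lam_global = sum(float(v.sum()) for v in chip.data.values()) / total_bins
        lam = {c: np.full(len(chip.data[c]), lam_global) for c in chroms}
        scale = 1.0
    else:
        total_bins = sum(len(v) for v in control.data.values())
        global_rate = sum(float(v.sum()) for v in control.data.values()) / total_bins
        half = max(1, local_window // (2 * bin_size))
        scale = chip.n_reads / control.n_reads
        lam = {}
        for c in chroms:
            v = control.data[c].astype(float)
            # centred rolling mean over ~local_window bp, edge-truncated
            cums = np.concatenate(([0.0], np.cumsum(v)))
            idx = np.arange(len(v))
            lo = np.maximum(0, idx - half)
            hi = np.minimum(len(v), idx + half + 1)
            local = (cums[hi] - cums[lo]) / (hi - lo)
            lam[c] = np.maximum(global_rate, local)

    pvals = []
    for c in chroms:
        lam_c = lam[c] * scale
        pvals.append(stats.poisson.sf(chip.data[c] - 1, np.maximum(lam_c, 1e-12)))
    flat_p = np.concatenate(pvals)
    flat_q = bh_fdr(flat_p)

    peaks: list[Peak] = []
    offset = 0
    for ci, c in enumerate(chroms):
        nb = len(chip.data[c])
        q_c = flat_q[offset : offset + nb]
        offset += nb
        sig = q_c < q_threshold
        if not sig.any():
            continue
        # runs of consecutive significant bins
        boundaries = np.flatnonzero(np.diff(np.concatenate(([0], sig.view(np.int8), [0]))))
        for lo, hi in zip(boundaries[::2], boundaries[1::2]):
            start = int(lo) * bin_size
            end = min(int(hi) * bin_size, int(nb * bin_size))
            if end - start < min_width:
                continue
            counts = chip.data[c][lo:hi]
            k = int(np.argmax(counts))  # leftmost max
            summit = min((int(lo) + k) * bin_size + bin_size // 2, end - 1)
            qmin = float(q_c[lo:hi].min())
            peaks.append(
                Peak(
                    interval=GenomicInterval(c, start, end),
                    summit_offset=summit - start,
                    score=float(counts.max()),
                    qvalue=qmin,
                    name=f"peak_{len(peaks) + 1}",
                )
            )
    if meta is None:
        meta = SampleMeta("unknown", "BC", "NC", "H3K27ac", 1, "chip")
    return PeakSet(meta=meta, peaks=peaks, provenance="internal_caller")


def qc_filter(
    peaksets: Sequence[PeakSet], min_peaks: int = 10_000
) -> tuple[list[PeakSet], pd.DataFrame]:
    """Drop replicates with fewer than ``min_peaks`` called peaks.

    Returns the retained sets and a per-replicate report.  Raises if every
    replicate of an experimental group is dropped.
    """
    rows = []
    kept: list[PeakSet] = []
    group_total: dict[tuple, int] = {}
    group_kept: dict[tuple, int] = {}
    for ps in peaksets:
        ok = len(ps.peaks) >= min_peaks
        rows.append(
            {
                "sample_id": ps.meta.sample_id,
                "cell_type": ps.meta.cell_type,
                "condition": ps.meta.condition,
                "mark": ps.meta.mark,
                "replicate": ps.meta.replicate,
                "n_peaks": len(ps.peaks),
                "retained": ok,
            }
        )
        key = ps.meta.group_key
        group_total[key] = group_total.get(key, 0) + 1
        if ok:
            kept.append(ps)
            group_kept[key] = group_kept.get(key, 0) + 1
    for key, total in group_total.items():
        if group_kept.get(key, 0) == 0:
            raise ValueError(
                f"all {total} replicate(s) of group {key} dropped by the "
                f"min_peaks={min_peaks} QC rule"
            )
    return kept, pd.DataFrame(rows)


def pool_replicates(peaksets: Sequence[PeakSet], meta: SampleMeta) -> PeakSet:
    """Pool technical replicates of one cell sample into a single peak set
    (union, overlap-merged)."""
    allpeaks = [p for ps in peaksets for p in ps.peaks]
    return PeakSet(meta=meta, peaks=merge_peaks(allpeaks), provenance="pooled")


def remove_blacklist(
    peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]
) -> list[Peak]:
    """Remove any peak overlapping a blacklist region by >= 1 bp, whole."""
    from .intervals import overlaps_any

    if not blacklist or not peaks:
        return list(peaks)
    hit = overlaps_any(list(peaks), list(blacklist))
    return [p for p, h in zip(peaks, hit) if not h]


def consensus_majority(replicate_sets: Sequence[PeakSet]) -> ConsensusSet:
    """Majority-rules consensus across biological replicates.

    Overlap-connected components (single linkage, >= 1 bp) are formed over
    the union of all replicates' peaks; a component is valid iff peaks from
    at least ``floor(n/2) + 1`` distinct replicates contribute.  The region
    is the component's union span; the summit comes from the
    highest-scoring contributing peak.  Output is independent of replicate
    input order.
    """
    if not replicate_sets:
        raise ValueError("consensus requires >= 1 replicate peak set")
    keys = {ps.meta.group_key for ps in replicate_sets}
    if len(keys) > 1:
        raise ValueError(f"replicates span multiple groups: {sorted(keys)}")
    n = len(replicate_sets)
    need = n // 2 + 1

    tagged: dict[str, list[tuple[Peak, int]]] = {}
    for ps in sorted(replicate_sets, key=lambda ps: ps.meta.sample_id):
        for ri, p in enumerate([p for p in ps.peaks]):
            tagged.setdefault(p.chrom, []).append((p, ps.meta.replicate))

    out_peaks: list[Peak] = []
    out_support: list[int] = []
    for chrom in sorted(tagged):
        items = sorted(tagged[chrom], key=lambda t: (t[0].start, t[0].end))
        run: list[tuple[Peak, int]] = []
        run_end = -1
        for item in items + [None]:
            if item is not None and (not run or item[0].start < run_end):
                run.append(item)
                run_end = max(run_end, item[0].end)
                continue
            if run:
                reps = {r for _, r in run}
                if len(reps) >= need:
                    best = max(run, key=lambda t: (t[0].score, -t[0].start))[0]
                    start = min(p.start for p, _ in run)
                    end = max(p.end for p, _ in run)
                    out_peaks.append(
                        Peak(
                            interval=GenomicInterval(chrom, start, end),
                            summit_offset=best.summit - start,
                            score=best.score,
                            qvalue=min(p.qvalue for p, _ in run),
                            name=best.name,
                        )
                    )
                    out_support.append(len(reps))
            if item is not None:
                run = [item]
                run_end = item[0].end
    key = replicate_sets[0].meta.group_key
    return ConsensusSet(group_key=key, peaks=out_peaks, support=out_support, n_replicates=n)


def master_set(consensus_sets: Sequence[ConsensusSet]) -> list[Peak]:
    """Overlap-merge of all groups' consensus regions; sorted, disjoint."""
    if not consensus_sets:
        raise ValueError("master set requires >= 1 consensus set")
    allpeaks = [p for cs in consensus_sets for p in cs.peaks]
    return merge_peaks(allpeaks)
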