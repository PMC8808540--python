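"""Binned coverage, depth-normalized input-subtracted signal, FrIP and
promoter-signal correlation structure.

The signal definition is the per-bin, depth-normalized difference between
ChIP and input coverage::

    normalized signal = (chip_count / N_chip - input_count / N_input) * 1e6

computed in fixed-width genome windows (100 bp by default).  A bin's count
is the number of (extended) reads overlapping it by >= 1 bp.  Sample
similarity is summarized by Pearson correlation of per-promoter (TSS +/- 2
kb) summed signal.

Reads are carried as ``{chrom: (n, 2) int64 array}`` of half-open
[start, end) coordinates, the in-memory form of a post-alignment BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import Genome, TssRecord

ReadSet = dict[str, np.ndarray]  # chrom -> (n, 2) array of [start, end)


def reads_from_lists(raw: Mapping[str, Sequence[tuple[int, int]]]) -> ReadSet:
    return {
        chrom: np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        for chrom, pairs in raw.items()
    }


def total_reads(reads: ReadSet) -> int:
    return sum(arr.shape[0] for arr in reads.values())


def extend_reads(reads: ReadSet, genome: Genome, flank: int = 100) -> ReadSet:
    """Extend each read by ``flank`` bp on either side, clipped to the
    chromosome; a 50-bp read with the default flank becomes 250 bp."""
    out: ReadSet = {}
    for chrom, arr in reads.items():
        length = genome.chrom_sizes[chrom]
        ext = np.empty_like(arr)
        np.maximum(arr[:, 0] - flank, 0, out=ext[:, 0])
        np.minimum(arr[:, 1] + flank, length, out=ext[:, 1])
        out[chrom] = ext
    return out


@dataclass
class CoverageTrack:
    """Read-overlap counts per fixed-width bin, plus the library size N."""

    bin_size: int
    data: dict[str, np.ndarray]
    n_reads: int

    def chroms(self) -> list[str]:
        return list(self.data)


@dataclass
class SignalTrack:
    """Real-valued per-bin signal; negative where input exceeds ChIP."""

    bin_size: int
    data: dict[str, np.ndarray]

    def write_bedgraph(self, path, genome: Genome) -> None:
        with open(path, "w") as fh:
            for chrom, vec in self.data.items():
                length = genome.chrom_sizes[chrom]
                for i, v in enumerate(vec):
                    start = i * self.bin_size
                    end = min(length, start + self.bin_size)
                    fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def n_bins(length: int, bin_size: int) -> int:
    return -(-length // bin_size)  # ceil


def make_coverage(reads: ReadSet, genome: Genome, bin_size: int = 100) -> CoverageTrack:
    """Bin count = number of reads overlapping the bin by >= 1 bp.

    A read spanning [s, e) overlaps exactly the bins s//B .. (e-1)//B, so a
    +1/-1 difference array followed by a cumulative sum gives every bin's
    overlap count in O(reads + bins).
    """
    data: dict[str, np.ndarray] = {}
    total = 0
    for chrom, length in genome.chrom_sizes.items():
        nb = n_bins(length, bin_size)
        diff = np.zeros(nb + 1, dtype=np.int64)
        arr = reads.get(chrom)
        if arr is not None and arr.shape[0] > 0:
            total += arr.shape[0]
            first = arr[:, 0] // bin_size
            last = (arr[:, 1] - 1) // bin_size
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
        data[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(bin_size=bin_size, data=data, n_reads=total)


def normalized_signal(chip: CoverageTrack, control: CoverageTrack) -> SignalTrack:
    """Depth-normalized input subtraction, scaled to reads-per-million."""
    if chip.bin_size != control.bin_size:
        raise ValueError("chip and input tracks have different bin sizes")
    if chip.n_reads == 0 or control.n_reads == 0:
        raise ValueError("normalized signal undefined for an empty track (N = 0)")
    if set(chip.data) != set(control.data):
        raise ValueError("chip and input tracks cover different chromosomes")
    data = {
        chrom: (chip.data[chrom] / chip.n_reads - control.data[chrom] / control.n_reads)
        * 1e6
        for chrom in chip.data
    }
    return SignalTrack(bin_size=chip.bin_size, data=data)


def frip(reads: ReadSet, peaks: Sequence) -> float:
    """Fraction of reads overlapping any peak by >= 1 bp."""
    from .intervals import merge_coords

    total = total_reads(reads)
    if total == 0:
        raise ValueError("FrIP undefined with zero reads")
    if not peaks:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    in_peaks = 0
    for chrom, coords in by_chrom.items():
        arr = reads.get(chrom)
        if arr is None or arr.shape[0] == 0:
            continue
        c = np.asarray(coords, dtype=np.int64)
        m_starts, m_ends = merge_coords(c[:, 0], c[:, 1])
        # rightmost merged interval starting before the read ends
        k = np.searchsorted(m_starts, arr[:, 1], side="left") - 1
        valid = k >= 0
        hit = np.zeros(arr.shape[0], dtype=bool)
        hit[valid] = m_ends[k[valid]] > arr[valid, 0]
        in_peaks += int(hit.sum())
    return in_peaks / total


def promoter_matrix(
    signals: Mapping[str, SignalTrack],
    tss: Sequence[TssRecord],
    genome: Genome,
    flank: int = 2000,
) -> pd.DataFrame:
    """Genes x samples matrix of summed signal over bins overlapping
    TSS +/- ``flank``; windows truncated at chromosome edges."""
    if not signals:
        raise ValueError("no signal tracks given")
    bin_sizes = {t.bin_size for t in signals.values()}
    if len(bin_sizes) != 1:
        raise ValueError("all samples must share a bin size")
    bin_size = bin_sizes.pop()
    cols = {}
    for sample_id, track in signals.items():
        cums = {c: np.concatenate(([0.0], np.cumsum(v))) for c, v in track.data.items()}
        vals = np.empty(len(tss))
        for i, t in enumerate(tss):
            vec_cum = cums[t.chrom]
            nb = len(vec_cum) - 1
            lo = max(0, t.tss - flank)
            hi = min(genome.chrom_sizes[t.chrom], t.tss + flank)
            first = lo // bin_size
            last = min(nb - 1, (hi - 1) // bin_size)
            vals[i] = vec_cum[last + 1] - vec_cum[first]
        cols[sample_id] = vals
    return pd.DataFrame(cols, index=[t.gene_id for t in tss])


def region_signal_matrix(
    signals: Mapping[str, SignalTrack], regions: Sequence
) -> pd.DataFrame:
    """Regions x samples matrix of mean signal over the bins each region
    overlaps (used for the all-peak condition comparison and heatmaps)."""
    if not signals:
        raise ValueError("no signal tracks given")
    bin_size = next(iter(signals.values())).bin_size
    cols = {}
    for sample_id, track in signals.items():
        cums = {c: np.concatenate(([0.0], np.cumsum(v))) for c, v in track.data.items()}
        vals = np.empty(len(regions))
        for i, r in enumerate(regions):
            vec_cum = cums[r.chrom]
            nb = len(vec_cum) - 1
            first = r.start // bin_size
            last = min(nb - 1, (r.end - 1) // bin_size)
            vals[i] = (vec_cum[last + 1] - vec_cum[first]) / (last - first + 1)
        cols[sample_id] = vals
    idx = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    return pd.DataFrame(cols, index=idx)


def pearson_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of the promoter-signal matrix."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples for a correlation matrix")
    stds = matrix.std(axis=0)
    dead = stds[stds == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance sample(s): {dead}")
    return matrix.corr(method="pearson")


def correlation_band(r: float) -> str:
    """Verbal quality band for a correlation coefficient."""
    if r > 0.95:
        return "high"
    if r > 0.9:
        return "good"
    if r > 0.75:
        return "fair"
    if r > 0.6:
        return "low"
    return "poor"
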