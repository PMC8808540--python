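"""Enhancer calling and enhancer-level comparative analyses.

An enhancer is a 1-kb region centred on the summit of a H3K27ac consensus
peak (summit +/- 500 bp) that does not intersect any promoter window
(TSS +/- 500 bp).  Cross-condition identity is by >= 1 bp overlap of the
1-kb regions: overlapping NC and MUT enhancers are merged into a single
enhancer entity present in both conditions, which makes the NC-only /
shared / MUT-only Venn classes a genuine partition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import nearest_feature, overlaps_any
from .peaks import ConsensusSet
from .types import Genome, GenomicInterval, Peak, SnpRecord, TssRecord


@dataclass
class Enhancer:
    """A merged enhancer entity for one cell type."""

    interval: GenomicInterval
    cell_type: str
    present_in: frozenset[str]  # subset of {"NC", "MUT"}
    category: str | None = None
    snp_proximal: bool = False


@dataclass
class EnhancerSet:
    """All enhancers of one cell type plus the per-condition 1-kb regions."""

    cell_type: str
    enhancers: list[Enhancer]
    condition_regions: dict[str, list[GenomicInterval]]  # promoter-excluded 1-kb regions

    @property
    def venn(self) -> dict[str, int]:
        c = Counter(
            "shared" if e.present_in == {"NC", "MUT"} else f"{next(iter(e.present_in))}_only"
            for e in self.enhancers
        )
        return {
            "NC_only": c.get("NC_only", 0),
            "shared": c.get("shared", 0),
            "MUT_only": c.get("MUT_only", 0),
        }


def _summit_windows(
    consensus: ConsensusSet, genome: Genome, half_width: int = 500
) -> list[GenomicInterval]:
    out = []
    for p in consensus.peaks:
        iv = GenomicInterval(p.chrom, max(0, p.summit - half_width), p.summit + half_width)
        out.append(genome.clip(iv))
    return out


def call_enhancers(
    consensus_by_condition: Mapping[str, ConsensusSet],
    tss: Sequence[TssRecord],
    genome: Genome,
    cell_type: str,
    promoter_flank: int = 500,
    half_width: int = 500,
) -> EnhancerSet:
    """Call enhancers for one cell type from per-condition H3K27ac consensus.

    Each consensus peak is reduced to its summit +/- ``half_width`` window
    (clipped at chromosome edges); windows overlapping any TSS +/-
    ``promoter_flank`` promoter by >= 1 bp are removed.  Remaining NC and
    MUT windows are merged by >= 1 bp overlap into enhancer entities whose
    ``present_in`` records the contributing conditions.

    Postcondition (asserted): no emitted enhancer overlaps any promoter.
    """
    promoters = [t.promoter(promoter_flank) for t in tss]
    cond_regions: dict[str, list[GenomicInterval]] = {}
    tagged: list[tuple[GenomicInterval, str]] = []
    for cond, cons in consensus_by_condition.items():
        windows = _summit_windows(cons, genome, half_width)
        if windows and promoters:
            keep = ~overlaps_any(windows, promoters)
        else:
            keep = np.ones(len(windows), dtype=bool)
        kept = [w for w, k in zip(windows, keep) if k]
        cond_regions[cond] = kept
        tagged.extend((w, cond) for w in kept)

    # single-linkage merge across conditions
    enhancers: list[Enhancer] = []
    by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for iv, cond in tagged:
        by_chrom.setdefault(iv.chrom, []).append((iv, cond))
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end))
        run: list[tuple[GenomicInterval, str]] = []
        run_end = -1
        for item in items + [None]:
            if item is not None and (not run or item[0].start < run_end):
                run.append(item)
                run_end = max(run_end, item[0].end)
                continue
            if run:
                start = min(iv.start for iv, _ in run)
                end = max(iv.end for iv, _ in run)
                conds = frozenset(c for _, c in run)
                enhancers.append(
                    Enhancer(
                        interval=GenomicInterval(chrom, start, end),
                        cell_type=cell_type,
                        present_in=conds,
                    )
                )
            if item is not None:
                run = [item]
                run_end = item[0].end
    if enhancers and promoters:
        bad = overlaps_any([e.interval for e in enhancers], promoters)
        assert not bad.any(), "enhancer overlapping a promoter window emitted"
    return EnhancerSet(cell_type=cell_type, enhancers=enhancers, condition_regions=cond_regions)


def coverage_fraction(
    nc_regions: Sequence[GenomicInterval], mut_regions: Sequence[GenomicInterval]
) -> dict[str, float]:
    """Fraction of NC enhancers overlapped (>= 1 bp) by a MUT enhancer,
    plus the fraction of MUT enhancers unique to MUT."""
    if not nc_regions:
        raise ValueError("empty NC enhancer set")
    nc_hit = overlaps_any(list(nc_regions), list(mut_regions)) if mut_regions else np.zeros(
        len(nc_regions), dtype=bool
    )
    out = {"nc_covered_by_mut": float(nc_hit.mean())}
    if mut_regions:
        mut_hit = overlaps_any(list(mut_regions), list(nc_regions))
        out["mut_unique_fraction"] = float(1.0 - mut_hit.mean())
    else:
        out["mut_unique_fraction"] = float("nan")
    return out


def _edge_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two intervals on one chromosome; 0 if they touch
    or overlap."""
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def annotate_locations(
    enhancers: Sequence[GenomicInterval],
    tss: Sequence[TssRecord],
    gene_spans: Sequence[GenomicInterval],
    promoter_flank: int = 500,
    vicinity: int = 2000,
) -> tuple[list[str], dict[str, float]]:
    """Genomic-location category per enhancer, by priority:

    ``promoter_vicinity`` (< ``vicinity`` bp from the nearest promoter-window
    edge) > ``genic`` (overlaps a gene span) > ``distal_intergenic``.
    Returns (per-enhancer categories, category distribution summing to 1).
    """
    promoters = [t.promoter(promoter_flank) for t in tss]
    prom_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in promoters:
        prom_by_chrom.setdefault(p.chrom, []).append(p)
    genic = (
        overlaps_any(list(enhancers), list(gene_spans))
        if enhancers and gene_spans
        else np.zeros(len(enhancers), dtype=bool)
    )
    cats: list[str] = []
    for i, e in enumerate(enhancers):
        near = False
        for p in prom_by_chrom.get(e.chrom, []):
            if _edge_distance(e, p) < vicinity:
                near = True
                break
        if near:
            cats.append("promoter_vicinity")
        elif genic[i]:
            cats.append("genic")
        else:
            cats.append("distal_intergenic")
    n = max(1, len(cats))
    counts = Counter(cats)
    dist = {
        k: counts.get(k, 0) / n
        for k in ("promoter_vicinity", "genic", "distal_intergenic")
    }
    return cats, dist


def snp_fraction(
    enhancers: Sequence[GenomicInterval],
    snps: Sequence[SnpRecord],
    window: int = 150_000,
) -> tuple[float, list[bool]]:
    """Fraction of enhancers with a SNP within ``window`` bp up- or
    downstream: SNP position in ``[start - window, end + window)``."""
    if not snps:
        raise ValueError("empty SNP list")
    pos_by_chrom: dict[str, np.ndarray] = {}
    for s in snps:
        pos_by_chrom.setdefault(s.chrom, []).append(s.pos)  # type: ignore[arg-type]
    pos_by_chrom = {c: np.sort(np.asarray(v)) for c, v in pos_by_chrom.items()}
    flags: list[bool] = []
    for e in enhancers:
        pos = pos_by_chrom.get(e.chrom)
        if pos is None:
            flags.append(False)
            continue
        lo = np.searchsorted(pos, e.start - window, side="left")
        hi = np.searchsorted(pos, e.end + window, side="left")
        flags.append(hi > lo)
    frac = float(np.mean(flags)) if flags else 0.0
    return frac, flags


def gene_change_fraction(
    up_regions: Sequence[Peak | GenomicInterval],
    down_regions: Sequence[Peak | GenomicInterval],
    celltype_genes: Sequence[str],
    tss: Sequence[TssRecord],
) -> dict:
    """Fraction of a cell-type-specific gene list whose nearest differential
    region makes them 'changed', and the fraction of changed genes whose
    associated regions are majority down in MUT (ties count as down).
    """
    if not celltype_genes:
        raise ValueError("empty cell-type gene list")
    per_gene: dict[str, list[str]] = {}
    for regions, direction in ((up_regions, "up"), (down_regions, "down")):
        for r in regions:
            iv = r.interval if isinstance(r, Peak) else r
            gene, _dist = nearest_feature(iv, tss)
            per_gene.setdefault(gene, []).append(direction)
    gene_set = set(celltype_genes)
    changed = sorted(g for g in per_gene if g in gene_set)
    n_changed, n_total = len(changed), len(celltype_genes)
    if n_changed:
        n_down = sum(
            1
            for g in changed
            if per_gene[g].count("down") >= per_gene[g].count("up")
        )
        fraction_down = n_down / n_changed
    else:
        fraction_down = 0.0
    return {
        "n_changed": n_changed,
        "n_total": n_total,
        "fraction": n_changed / n_total,
        "fraction_down": fraction_down,
        "changed_genes": changed,
    }
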