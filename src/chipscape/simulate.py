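"""Synthetic four-cell-type x two-condition ChIP-seq study with known truth.

The generator emulates the post-alignment inputs of a cell-type-resolved
histone-modification study: a small random genome with annotated genes, a
planted peak landscape (shared, cell-type-specific, condition-specific and
condition-differential regions), per-sample ChIP and input read BEDs with a
target fraction of reads in peaks, enhancer sequences carrying planted
transcription-factor motifs, a decoy blacklist, and a SNP catalogue with a
planted enrichment near MUT-BC-specific enhancers.  Everything is
deterministic given the seed.

The read model is deliberately simple — reads are placed directly (no
sequencing errors, duplicates, GC or mappability bias), since the pipeline
under test starts at aligned reads.  Replicates share per-peak activity
weights (Gamma-distributed, creating realistic rank variation) and differ
by a small lognormal per-replicate jitter plus sampling noise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as cio
from .coverage import ReadSet
from .intervals import nearest_feature
from .motifs import PWM, write_jaspar
from .types import (
    CELL_TYPES,
    CONDITIONS,
    Genome,
    GenomicInterval,
    SampleMeta,
    SnpRecord,
    TssRecord,
)

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Study-design knobs of the synthetic landscape.

    Defaults describe a desk-scale study: a 2 x 5 Mb genome, 300 genes, 400
    peaks shared by all cell types, 120 cell-type-specific peaks per cell
    type (of which 30 are NC-only and 30 MUT-only), 60 condition-
    differential peaks per cell type at 4-fold effect, three ChIP
    replicates per group at 200k reads with a target FrIP of 0.3, and 123
    SNPs of which half are planted near MUT-BC-specific enhancers.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    gc: float = 0.41
    n_genes: int = 300
    min_gene_spacing: int = 10_000

    n_shared: int = 400
    n_promoter_peaks: int = 150    # TSS-centred peaks (H3K27ac marks active promoters)
    promoter_ct_sd: float = 0.4    # lognormal sd of per-cell-type promoter strength
    n_celltype: int = 120          # per cell type; see condition split below
    n_celltype_nc_only: int = 30
    n_celltype_mut_only: int = 30
    n_differential: int = 60       # per cell type, half up / half down in MUT
    differential_fold: float = 4.0
    peak_width_min: int = 600
    peak_width_max: int = 2000
    peak_margin: int = 400         # clearance around peaks and promoters

    n_replicates: int = 3
    reads_per_chip: int = 200_000
    reads_per_input: int = 200_000
    target_frip: float = 0.3
    read_length: int = 50
    position_sd: float = 75.0
    replicate_log_sd: float = 0.1  # lognormal per-replicate weight jitter
    weight_shape: float = 4.0      # Gamma shape of per-peak weights

    n_snps: int = 123
    snp_planted_fraction: float = 0.5
    snp_window: int = 5_000        # analysis window scaled to the genome

    n_blacklist: int = 5
    blacklist_width: int = 5_000
    blacklist_weight: float = 4.0

    motif_length: int = 10
    n_decoy_motifs: int = 16
    plant_shift: bool = True       # plant the LP motif into MUT-BC-only enhancers

    min_peaks_qc: int = 300        # "min called peaks" QC gate scaled to genome
    seed: int = 17

    def __post_init__(self) -> None:
        if not (0.0 < self.target_frip < 1.0):
            raise ValueError("target_frip must be in (0,1)")
        for name in (
            "n_chroms", "chrom_length", "n_genes", "n_shared", "n_celltype",
            "n_differential", "n_replicates", "reads_per_chip", "reads_per_input",
            "n_snps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_celltype_nc_only + self.n_celltype_mut_only > self.n_celltype:
            raise ValueError("condition-specific split exceeds n_celltype")


@dataclass
class PlantedPeak:
    interval: GenomicInterval
    kind: str  # shared | promoter | celltype | differential | blacklist_decoy
    weight: float
    cell_type: str | None = None
    conditions: frozenset = frozenset(CONDITIONS)
    direction: str | None = None   # up_in_MUT | down_in_MUT
    fold: float = 1.0
    motif_ids: tuple[str, ...] = ()
    ct_factors: dict[str, float] | None = None  # per-cell-type strength (promoter kind)

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2

    def enhancer_window(self, genome: Genome, half_width: int = 500) -> GenomicInterval:
        return genome.clip(
            GenomicInterval(self.interval.chrom, max(0, self.center - half_width),
                            self.center + half_width)
        )


@dataclass
class LandscapeTruth:
    """Everything needed to score downstream recovery."""

    peaks: list[PlantedPeak]
    snps: list[SnpRecord]
    blacklist: list[GenomicInterval]
    pwms: list[PWM]
    motif_assignment: dict[str, str]
    celltype_genes: dict[str, list[str]]

    def active_peaks(self, cell_type: str, condition: str) -> list[tuple[PlantedPeak, float]]:
        """Planted peaks contributing reads for a (cell type, condition)
        group, with their condition-adjusted weights."""
        out = []
        for p in self.peaks:
            if p.kind in ("shared", "blacklist_decoy"):
                out.append((p, p.weight))
            elif p.kind == "promoter":
                factor = p.ct_factors.get(cell_type, 1.0) if p.ct_factors else 1.0
                out.append((p, p.weight * factor))
            elif p.cell_type != cell_type:
                continue
            elif p.kind == "celltype":
                if condition in p.conditions:
                    out.append((p, p.weight))
            elif p.kind == "differential":
                if condition == "NC":
                    out.append((p, p.weight))
                else:
                    factor = p.fold if p.direction == "up_in_MUT" else 1.0 / p.fold
                    out.append((p, p.weight * factor))
        return out

    def signal_peaks(self, cell_type: str, condition: str) -> list[PlantedPeak]:
        """Active peaks excluding blacklist decoys (the 'real' landscape)."""
        return [
            p for p, _w in self.active_peaks(cell_type, condition)
            if p.kind != "blacklist_decoy"
        ]

    def enhancer_truth(self, genome: Genome, cell_type: str,
                       condition: str | None = None, half_width: int = 500
                       ) -> list[GenomicInterval]:
        """Planted 1-kb enhancer windows active for a cell type (union over
        conditions when ``condition`` is None)."""
        conds = CONDITIONS if condition is None else (condition,)
        seen: dict[tuple, GenomicInterval] = {}
        for c in conds:
            for p in self.signal_peaks(cell_type, c):
                if p.kind == "promoter":  # excluded by the promoter filter
                    continue
                w = p.enhancer_window(genome, half_width)
                seen[(w.chrom, w.start, w.end)] = w
        return sorted(seen.values(), key=lambda iv: (iv.chrom, iv.start))

    def differential(self, cell_type: str) -> list[tuple[GenomicInterval, str, float]]:
        return [
            (p.interval, p.direction, p.fold)
            for p in self.peaks
            if p.kind == "differential" and p.cell_type == cell_type
        ]

    def all_condition_truth(self, cell_type: str) -> list[tuple[GenomicInterval, str, float]]:
        """Every region truly different between conditions for a cell type:
        the planted fold-change regions plus the condition-specific peaks
        (present in only one condition, an unbounded effect)."""
        out = self.differential(cell_type)
        for p in self.peaks:
            if p.kind == "celltype" and p.cell_type == cell_type and len(p.conditions) == 1:
                direction = "up_in_MUT" if "MUT" in p.conditions else "down_in_MUT"
                out.append((p.interval, direction, float("inf")))
        return out


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(sample_id.encode())])
    )


def generate_genome_and_annotation(
    params: SimParams, rng: np.random.Generator
) -> tuple[Genome, dict[str, bytearray], list[TssRecord], list[GenomicInterval]]:
    """Random genome (i.i.d. bases at the stated GC) plus a gene annotation
    with minimum TSS spacing."""
    at = (1.0 - params.gc) / 2.0
    gc = params.gc / 2.0
    probs = np.array([at, gc, gc, at])
    sizes = {f"chr{i + 1}": params.chrom_length for i in range(params.n_chroms)}
    genome = Genome(chrom_sizes=sizes)
    sequences: dict[str, bytearray] = {}
    for chrom, length in sizes.items():
        codes = rng.choice(_BASE_ARR, size=length, p=probs)
        sequences[chrom] = bytearray(codes.tobytes())

    total = genome.total_length
    spacing = params.min_gene_spacing
    if params.n_genes * spacing >= total:
        raise ValueError(
            f"cannot place {params.n_genes} genes with {spacing} bp spacing "
            f"in a {total} bp genome"
        )
    # proportional allocation per chromosome, sorted-uniform + spacing trick
    tss_records: list[TssRecord] = []
    spans: list[GenomicInterval] = []
    chroms = list(sizes)
    per_chrom = [params.n_genes // len(chroms)] * len(chroms)
    per_chrom[0] += params.n_genes - sum(per_chrom)
    gi = 0
    for chrom, n in zip(chroms, per_chrom):
        length = sizes[chrom]
        slack = length - n * spacing - 2 * spacing
        if slack <= n:
            raise ValueError(f"gene spacing infeasible on {chrom}")
        offsets = np.sort(rng.integers(0, slack, size=n))
        positions = offsets + spacing * np.arange(n) + spacing
        for pos in positions:
            gi += 1
            strand = "+" if rng.integers(2) == 0 else "-"
            glen = int(rng.integers(5_000, 15_001))
            tss = int(pos)
            if strand == "+":
                span = GenomicInterval(chrom, tss, min(length, tss + glen))
            else:
                span = GenomicInterval(chrom, max(0, tss - glen + 1), tss + 1)
            tss_records.append(
                TssRecord(gene_id=f"gene{gi:04d}", chrom=chrom, tss=tss, strand=strand)
            )
            spans.append(span)
    return genome, sequences, tss_records, spans


def make_pwm_panel(params: SimParams, rng: np.random.Generator) -> tuple[list[PWM], dict[str, str]]:
    """Sharp synthetic PWMs: one per cell type plus random decoys."""
    L = params.motif_length
    ids = [f"M_{ct}" for ct in CELL_TYPES] + [
        f"D{i + 1:02d}" for i in range(params.n_decoy_motifs)
    ]
    consensi: set[str] = set()
    pwms = []
    for motif_id in ids:
        while True:
            cons = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
            from .motifs import reverse_complement

            if cons not in consensi and reverse_complement(cons) not in consensi:
                consensi.add(cons)
                break
        mat = np.full((4, L), 0.05)
        for j, b in enumerate(cons):
            mat["ACGT".index(b), j] = 0.85
        pwms.append(PWM(motif_id=motif_id, matrix=mat))
    assignment = {f"celltype:{ct}": f"M_{ct}" for ct in CELL_TYPES}
    if params.plant_shift:
        assignment["shift:BC<-LP"] = "M_LP"
    return pwms, assignment


class _Occupancy:
    """Per-chromosome sorted occupied intervals for rejection placement."""

    def __init__(self, chroms: Sequence[str]):
        self._starts: dict[str, list[int]] = {c: [] for c in chroms}
        self._ends: dict[str, list[int]] = {c: [] for c in chroms}

    def add(self, iv: GenomicInterval) -> None:
        import bisect

        i = bisect.bisect_left(self._starts[iv.chrom], iv.start)
        self._starts[iv.chrom].insert(i, iv.start)
        self._ends[iv.chrom].insert(i, iv.end)

    def clashes(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        starts, ends = self._starts[chrom], self._ends[chrom]
        i = bisect.bisect_left(starts, end)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end


def plant_landscape(
    genome: Genome,
    sequences: dict[str, bytearray],
    tss: Sequence[TssRecord],
    params: SimParams,
    rng: np.random.Generator,
) -> LandscapeTruth:
    """Place the peak landscape, embed motif consensus strings into
    enhancer-class sequences, plant the blacklist decoys and the SNP
    catalogue."""
    pwms, assignment = make_pwm_panel(params, rng)
    pwm_by_id = {p.motif_id: p for p in pwms}

    occ = _Occupancy(genome.chroms)
    for t in tss:
        p = t.promoter(500)
        occ.add(GenomicInterval(p.chrom, max(0, p.start - params.peak_margin),
                                p.end + params.peak_margin))

    chroms = genome.chroms
    chrom_lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()

    def place(width: int, max_tries: int = 300) -> GenomicInterval:
        for _ in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
            length = genome.chrom_sizes[chrom]
            start = int(rng.integers(1000, length - width - 1000))
            center = start + width // 2
            lo = min(start, center - 500) - params.peak_margin
            hi = max(start + width, center + 500) + params.peak_margin
            if not occ.clashes(chrom, lo, hi):
                occ.add(GenomicInterval(chrom, lo, hi))
                return GenomicInterval(chrom, start, start + width)
        raise RuntimeError(f"could not place a {width} bp region after {max_tries} tries")

    def draw_width() -> int:
        return int(rng.integers(params.peak_width_min, params.peak_width_max + 1))

    peaks: list[PlantedPeak] = []

    def weight() -> float:
        return float(rng.gamma(params.weight_shape, 1.0))

    # promoter peaks first: centred on a random subset of TSSs, active in
    # every group with a cell-type-dependent strength
    n_prom = min(params.n_promoter_peaks, len(tss))
    prom_idx = rng.choice(len(tss), size=n_prom, replace=False)
    for ti in sorted(prom_idx):
        t = tss[int(ti)]
        w = draw_width()
        length = genome.chrom_sizes[t.chrom]
        start = max(0, min(t.tss - w // 2, length - w))
        iv = GenomicInterval(t.chrom, start, start + w)
        occ.add(GenomicInterval(t.chrom, max(0, start - params.peak_margin),
                                start + w + params.peak_margin))
        factors = {
            ct: float(np.exp(rng.normal(0.0, params.promoter_ct_sd)))
            for ct in CELL_TYPES
        }
        peaks.append(
            PlantedPeak(interval=iv, kind="promoter", weight=weight(), ct_factors=factors)
        )

    for _ in range(params.n_shared):
        peaks.append(PlantedPeak(interval=place(draw_width()), kind="shared", weight=weight()))

    n_both = params.n_celltype - params.n_celltype_nc_only - params.n_celltype_mut_only
    for ct in CELL_TYPES:
        subtypes = (
            [frozenset(CONDITIONS)] * n_both
            + [frozenset({"NC"})] * params.n_celltype_nc_only
            + [frozenset({"MUT"})] * params.n_celltype_mut_only
        )
        for conds in subtypes:
            peaks.append(
                PlantedPeak(
                    interval=place(draw_width()),
                    kind="celltype",
                    weight=weight(),
                    cell_type=ct,
                    conditions=conds,
                )
            )
        n_up = params.n_differential // 2
        for k in range(params.n_differential):
            direction = "up_in_MUT" if k < n_up else "down_in_MUT"
            peaks.append(
                PlantedPeak(
                    interval=place(draw_width()),
                    kind="differential",
                    weight=weight(),
                    cell_type=ct,
                    direction=direction,
                    fold=params.differential_fold,
                )
            )

    blacklist: list[GenomicInterval] = []
    for _ in range(params.n_blacklist):
        iv = place(params.blacklist_width)
        blacklist.append(iv)
        peaks.append(
            PlantedPeak(interval=iv, kind="blacklist_decoy", weight=params.blacklist_weight)
        )

    # embed motif consensus strings at enhancer-class region centres
    def write_motif(seq_id: str, peak: PlantedPeak, offset: int) -> None:
        pwm = pwm_by_id[seq_id]
        cons = pwm.consensus()
        if rng.integers(2) == 1:
            from .motifs import reverse_complement

            cons = reverse_complement(cons)
        pos = peak.center + offset
        sequences[peak.interval.chrom][pos : pos + len(cons)] = cons.encode()

    for p in peaks:
        if p.kind != "celltype":
            continue
        motifs = [f"M_{p.cell_type}"]
        if (
            params.plant_shift
            and p.cell_type == "BC"
            and p.conditions == frozenset({"MUT"})
        ):
            motifs.append("M_LP")
        for k, mid in enumerate(motifs):
            write_motif(mid, p, k * (params.motif_length + 5))
        p.motif_ids = tuple(motifs)

    # SNP catalogue: a planted fraction near MUT-BC-specific enhancers
    mut_bc_only = [
        p for p in peaks
        if p.kind == "celltype" and p.cell_type == "BC" and p.conditions == frozenset({"MUT"})
    ]
    snps: list[SnpRecord] = []
    n_planted = int(round(params.n_snps * params.snp_planted_fraction))
    for i in range(params.n_snps):
        if i < n_planted and mut_bc_only:
            target = mut_bc_only[int(rng.integers(len(mut_bc_only)))]
            offset = int(rng.integers(-(params.snp_window - 600), params.snp_window - 600))
            pos = min(
                genome.chrom_sizes[target.interval.chrom] - 1,
                max(0, target.center + offset),
            )
            chrom = target.interval.chrom
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
            pos = int(rng.integers(0, genome.chrom_sizes[chrom]))
        snps.append(SnpRecord(snp_id=f"rs{i + 1:04d}", chrom=chrom, pos=pos))

    # cell-type gene lists: the genes nearest to each cell type's
    # differential regions, padded with unrelated genes
    celltype_genes: dict[str, list[str]] = {}
    for ct in CELL_TYPES:
        hits: list[str] = []
        for p in peaks:
            if p.kind == "differential" and p.cell_type == ct:
                gene, _ = nearest_feature(p.interval, list(tss))
                hits.append(gene)
        hit_set = sorted(set(hits))
        others = [t.gene_id for t in tss if t.gene_id not in hit_set]
        extras = [others[int(i)] for i in rng.choice(len(others), size=min(120, len(others)), replace=False)]
        celltype_genes[ct] = sorted(set(hit_set + extras))

    return LandscapeTruth(
        peaks=peaks,
        snps=snps,
        blacklist=blacklist,
        pwms=pwms,
        motif_assignment=assignment,
        celltype_genes=celltype_genes,
    )


def simulate_sample(
    truth: LandscapeTruth,
    meta: SampleMeta,
    params: SimParams,
    genome: Genome,
    n_reads: int | None = None,
) -> ReadSet:
    """Sample one library, deterministically from (seed, sample_id).

    ChIP: a depth-corrected fraction of reads is multinomially assigned to
    the peaks active for the sample's (cell type, condition), with weights
    jittered per replicate; positions are Normal(peak centre, 75 bp).  The
    assigned fraction is chosen so that (with uniform background reads
    falling into peaks by chance) the realized fraction of reads in planted
    peaks matches ``target_frip``.  Input: all reads uniform.
    """
    rng = _sample_rng(params.seed, meta.sample_id)
    if n_reads is None:
        n_reads = params.reads_per_chip if meta.role == "chip" else params.reads_per_input
    rl = params.read_length
    chroms = genome.chroms
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)
    total_len = int(lengths.sum())

    def uniform_reads(n: int) -> dict[str, list[np.ndarray]]:
        pos = rng.integers(0, total_len - rl, size=n)
        bounds = np.cumsum(lengths)
        chrom_idx = np.searchsorted(bounds, pos, side="right")
        local = pos - np.concatenate(([0], bounds[:-1]))[chrom_idx]
        out: dict[str, list[np.ndarray]] = {}
        for ci, c in enumerate(chroms):
            sel = np.minimum(local[chrom_idx == ci], lengths[ci] - rl)
            out.setdefault(c, []).append(np.column_stack((sel, sel + rl)))
        return out

    parts: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    if meta.role == "input":
        for c, arrs in uniform_reads(n_reads).items():
            parts[c].extend(arrs)
    else:
        active = truth.active_peaks(meta.cell_type, meta.condition)
        widths = np.array([p.interval.width for p, _ in active], dtype=float)
        rho = float(widths.sum()) / total_len
        f0 = max(0.0, (params.target_frip - rho) / (1.0 - rho))
        n_peak = int(round(f0 * n_reads))
        w = np.array([wt for _, wt in active])
        jitter = np.exp(rng.normal(0.0, params.replicate_log_sd, size=len(w)))
        probs = w * jitter
        probs = probs / probs.sum()
        alloc = rng.multinomial(n_peak, probs)
        for (p, _wt), k in zip(active, alloc):
            if k == 0:
                continue
            centers = p.center + rng.normal(0.0, params.position_sd, size=k)
            starts = np.rint(centers - rl / 2).astype(np.int64)
            length = genome.chrom_sizes[p.interval.chrom]
            starts = np.clip(starts, 0, length - rl)
            parts[p.interval.chrom].append(np.column_stack((starts, starts + rl)))
        for c, arrs in uniform_reads(n_reads - n_peak).items():
            parts[c].extend(arrs)

    return {
        c: (np.concatenate(arrs) if arrs else np.empty((0, 2), dtype=np.int64)).astype(np.int64)
        for c, arrs in parts.items()
    }


@dataclass
class Study:
    """A fully simulated study held in memory."""

    params: SimParams
    genome: Genome
    sequences: dict[str, bytearray]
    tss: list[TssRecord]
    gene_spans: list[GenomicInterval]
    truth: LandscapeTruth
    samples: list[SampleMeta]
    reads: dict[str, ReadSet]

    def chip_samples(self, cell_type: str | None = None, condition: str | None = None
                     ) -> list[SampleMeta]:
        return [
            s for s in self.samples
            if s.role == "chip"
            and (cell_type is None or s.cell_type == cell_type)
            and (condition is None or s.condition == condition)
        ]

    def input_for(self, meta: SampleMeta) -> SampleMeta:
        for s in self.samples:
            if s.role == "input" and s.cell_type == meta.cell_type and s.condition == meta.condition:
                return s
        raise KeyError(f"no input sample for {meta.sample_id}")

    def sequence(self, iv: GenomicInterval) -> str:
        return bytes(self.sequences[iv.chrom][iv.start : iv.end]).decode()


def simulate_study(params: SimParams | None = None) -> Study:
    """Generate the full study (genome, annotation, truth, all read sets)."""
    params = params or SimParams()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    genome, sequences, tss, spans = generate_genome_and_annotation(params, rng)
    truth = plant_landscape(genome, sequences, tss, params, rng)

    samples: list[SampleMeta] = []
    for ct in CELL_TYPES:
        for cond in CONDITIONS:
            for r in range(1, params.n_replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{ct}_{cond}_rep{r}",
                        cell_type=ct,
                        condition=cond,
                        mark="H3K27ac",
                        replicate=r,
                        role="chip",
                    )
                )
            samples.append(
                SampleMeta(
                    sample_id=f"{ct}_{cond}_input",
                    cell_type=ct,
                    condition=cond,
                    mark="H3K27ac",
                    replicate=1,
                    role="input",
                )
            )
    reads = {s.sample_id: simulate_sample(truth, s, params, genome) for s in samples}
    return Study(
        params=params,
        genome=genome,
        sequences=sequences,
        tss=tss,
        gene_spans=spans,
        truth=truth,
        samples=samples,
        reads=reads,
    )


def write_fasta(path, sequences: Mapping[str, bytearray], width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            data = bytes(seq).decode()
            for i in range(0, len(data), width):
                fh.write(data[i : i + width] + "\n")


def write_dataset(study: Study, outdir) -> dict:
    """Write the study to disk (FASTA, BEDs, sample sheet, truth files).

    Returns a manifest of written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    reads_dir = out / "reads"
    truth_dir.mkdir(exist_ok=True)
    reads_dir.mkdir(exist_ok=True)

    manifest: dict[str, str] = {}

    write_fasta(out / "genome.fa", study.sequences)
    manifest["genome"] = str(out / "genome.fa")
    cio.write_chrom_sizes(out / "chrom.sizes", study.genome.chrom_sizes)
    manifest["chrom_sizes"] = str(out / "chrom.sizes")
    cio.write_gene_table(out / "genes.bed", study.tss, study.gene_spans)
    manifest["genes"] = str(out / "genes.bed")
    cio.write_snps(out / "snps.bed", study.truth.snps)
    manifest["snps"] = str(out / "snps.bed")
    cio.write_regions(out / "blacklist.bed", study.truth.blacklist, dialect="bed")
    manifest["blacklist"] = str(out / "blacklist.bed")
    write_jaspar(out / "motifs.jaspar", study.truth.pwms)
    manifest["pwms"] = str(out / "motifs.jaspar")

    paths: dict[str, str] = {}
    for s in study.samples:
        p = reads_dir / f"{s.sample_id}.bed"
        cio.write_reads_bed(p, {c: arr.tolist() for c, arr in study.reads[s.sample_id].items()})
        paths[s.sample_id] = str(p)
    cio.write_sample_sheet(out / "sample_sheet.csv", study.samples, paths)
    manifest["sample_sheet"] = str(out / "sample_sheet.csv")

    # truth files: peak classes as BED (name = class), per-group enhancer
    # windows, and a JSON with everything needed for scoring
    with open(truth_dir / "peaks.bed", "w") as fh:
        for p in study.truth.peaks:
            tag = p.kind
            if p.cell_type:
                tag += f"|{p.cell_type}|{'+'.join(sorted(p.conditions))}"
            if p.direction:
                tag += f"|{p.direction}|fold={p.fold:g}"
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{tag}\t{p.weight:.3f}\t.\n")
    manifest["truth_peaks"] = str(truth_dir / "peaks.bed")
    for ct in CELL_TYPES:
        for cond in CONDITIONS:
            ivs = study.truth.enhancer_truth(study.genome, ct, cond)
            cio.write_regions(truth_dir / f"enhancers_{ct}_{cond}.bed", ivs, dialect="bed")
    truth_json = {
        "motif_assignment": study.truth.motif_assignment,
        "celltype_genes": study.truth.celltype_genes,
        "n_snps": len(study.truth.snps),
        "snp_planted_fraction": study.params.snp_planted_fraction,
        "differential": {
            ct: [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                 "direction": d, "fold": f}
                for iv, d, f in study.truth.differential(ct)
            ]
            for ct in CELL_TYPES
        },
    }
    with open(truth_dir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    manifest["truth_json"] = str(truth_dir / "truth.json")

    import yaml

    cfg = {
        "seed": study.params.seed,
        "bin_size": 100,
        "read_flank": 100,
        "q_peak": 0.05,
        "min_peaks": study.params.min_peaks_qc,
        "fc": 2.0,
        "fdr": 0.05,
        "motif_alpha": 1e-4,
        "snp_window": study.params.snp_window,
        "promoter_flank": 500,
        "enhancer_half_width": 500,
        "correlation_flank": 2000,
        "paths": {k: str(v) for k, v in manifest.items()},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    manifest["config"] = str(out / "config.yaml")
    return manifest


def simulate_nb_counts(
    n_regions: int,
    n_per_group: int,
    rng: np.random.Generator,
    base_mean_range: tuple[float, float] = (50.0, 500.0),
    dispersion: float = 0.05,
    fold_changes: np.ndarray | None = None,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Negative-binomial count matrix for calibration/power studies.

    Returns (counts with NC columns first, design labels, true log2 fold
    changes).  ``fold_changes`` is the per-region MUT/NC ratio (1 = null).
    """
    mu = np.exp(rng.uniform(np.log(base_mean_range[0]), np.log(base_mean_range[1]), n_regions))
    if fold_changes is None:
        fold_changes = np.ones(n_regions)
    s = rng.uniform(*size_factor_range, size=2 * n_per_group)
    design = ["NC"] * n_per_group + ["MUT"] * n_per_group
    counts = np.zeros((n_regions, 2 * n_per_group), dtype=np.int64)
    r_nb = 1.0 / dispersion
    for j in range(2 * n_per_group):
        mu_j = mu * s[j] * (fold_changes if design[j] == "MUT" else 1.0)
        p_nb = r_nb / (r_nb + mu_j)
        counts[:, j] = rng.negative_binomial(r_nb, p_nb)
    return counts, design, np.log2(fold_changes)
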