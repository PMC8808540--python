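"""End-to-end orchestration: signal -> peaks -> differential -> enhancers
-> motifs, on an in-memory :class:`~chipscape.simulate.Study` or on a
dataset loaded from disk.

All stages are plain functions over the module APIs; :func:`analyze_study`
runs them in dependency order and returns a :class:`StudyResults` bundle
with a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .coverage import (
    CoverageTrack,
    ReadSet,
    SignalTrack,
    extend_reads,
    make_coverage,
    normalized_signal,
    pearson_matrix,
    promoter_matrix,
    region_signal_matrix,
)
from .differential import (
    CountMatrix,
    DifferentialResult,
    NBDifferentialModel,
    allpeak_signal_comparison,
    count_reads,
)
from .enhancers import (
    EnhancerSet,
    annotate_locations,
    call_enhancers,
    coverage_fraction,
    gene_change_fraction,
    snp_fraction,
)
from .motifs import (
    MotifEnrichmentTable,
    PWM,
    celltype_specific_tfs,
    condition_differential_motifs,
    mut_preservation,
)
from .peaks import (
    ConsensusSet,
    PeakSet,
    call_peaks_poisson,
    consensus_majority,
    master_set,
    qc_filter,
    remove_blacklist,
)
from .types import (
    CELL_TYPES,
    CONDITIONS,
    Genome,
    GenomicInterval,
    Peak,
    SampleMeta,
    SnpRecord,
    TssRecord,
)


@dataclass
class AnalysisConfig:
    """All thresholds of the pipeline, with the study's published defaults.

    ``min_peaks`` (the replicate QC gate) and ``snp_window`` are stated at
    human-genome scale; desk-scale synthetic runs pass scaled values via
    the dataset's config file.
    """

    bin_size: int = 100
    read_flank: int = 100
    q_peak: float = 0.05
    min_peak_width: int = 200
    min_peaks: int = 10_000
    fc: float = 2.0
    fdr: float = 0.05
    motif_alpha: float = 1e-4
    snp_window: int = 150_000
    promoter_flank: int = 500
    enhancer_half_width: int = 500
    correlation_flank: int = 2000
    bg_times: int = 2
    seed: int = 17

    def __post_init__(self) -> None:
        for name in (
            "bin_size", "read_flank", "q_peak", "fc", "fdr", "motif_alpha",
            "snp_window", "promoter_flank", "enhancer_half_width",
            "correlation_flank",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class StudyResults:
    config: AnalysisConfig
    qc_report: pd.DataFrame
    retained: list[SampleMeta]
    peaksets: list[PeakSet]  # retained, blacklist-filtered, per ChIP sample
    pearson: pd.DataFrame
    consensus: dict[tuple[str, str], ConsensusSet]
    master: list[Peak]
    counts: CountMatrix
    differential: dict[str, DifferentialResult]
    significant: dict[str, tuple[list[Peak], list[Peak]]]
    allpeak: dict[str, dict]
    enhancer_sets: dict[str, EnhancerSet]
    enhancer_stats: dict[str, dict]
    motif_table: MotifEnrichmentTable
    condition_motifs: dict[str, dict[str, set[str]]]
    specific_tfs: dict[str, set[str]]
    preservation: pd.DataFrame
    gene_change: dict[str, dict]

    def summary(self) -> str:
        lines = ["chipscape run summary", "=" * 21]
        lines.append(
            f"samples retained after QC: {len(self.retained)} "
            f"(dropped {int((~self.qc_report.retained).sum())})"
        )
        lines.append(f"master set regions: {len(self.master)}")
        for ct in sorted(self.significant):
            up, down = self.significant[ct]
            lines.append(
                f"{ct}: differential regions (FC >= {self.config.fc:g}, "
                f"FDR < {self.config.fdr:g}): {len(up) + len(down)} "
                f"(up {len(up)}, down {len(down)})"
            )
        for ct in sorted(self.enhancer_sets):
            v = self.enhancer_sets[ct].venn
            st = self.enhancer_stats[ct]
            lines.append(
                f"{ct}: enhancers NC-only {v['NC_only']}, shared {v['shared']}, "
                f"MUT-only {v['MUT_only']}; MUT covers "
                f"{100 * st['coverage']['nc_covered_by_mut']:.1f}% of NC; "
                f"SNP-proximal NC {100 * st['snp_fraction']['NC']:.1f}% / "
                f"MUT {100 * st['snp_fraction']['MUT']:.1f}%"
            )
        for ct in sorted(self.specific_tfs):
            lines.append(
                f"{ct}: {len(self.specific_tfs[ct])} cell-type-specific TF(s), "
                f"{int(self.preservation.loc[ct, ct])} preserved in MUT"
            )
        return "\n".join(lines)


def sample_signals(
    reads: Mapping[str, ReadSet],
    samples: Sequence[SampleMeta],
    genome: Genome,
    config: AnalysisConfig,
    input_for: Callable[[SampleMeta], SampleMeta],
) -> tuple[dict[str, CoverageTrack], dict[str, SignalTrack]]:
    """Extended-read coverage for every sample and normalized (ChIP - input)
    signal for every ChIP sample."""
    coverage: dict[str, CoverageTrack] = {}
    for s in samples:
        ext = extend_reads(reads[s.sample_id], genome, config.read_flank)
        coverage[s.sample_id] = make_coverage(ext, genome, config.bin_size)
    signals: dict[str, SignalTrack] = {}
    for s in samples:
        if s.role != "chip":
            continue
        ctrl = input_for(s)
        signals[s.sample_id] = normalized_signal(
            coverage[s.sample_id], coverage[ctrl.sample_id]
        )
    return coverage, signals


def analyze_study(
    study,
    config: AnalysisConfig | None = None,
    celltype_genes: Mapping[str, Sequence[str]] | None = None,
    pwms: Sequence[PWM] | None = None,
    blacklist: Sequence[GenomicInterval] | None = None,
    snps: Sequence[SnpRecord] | None = None,
    external_peaks: Mapping[str, PeakSet] | None = None,
) -> StudyResults:
    """Run the full comparative analysis on a study.

    ``study`` provides genome, tss, gene_spans, samples, reads and a
    ``sequence(interval)`` accessor (a :class:`~chipscape.simulate.Study`
    or a :class:`LoadedStudy`).  Ground-truth-derived defaults (cell-type
    gene lists, PWM panel, blacklist, SNPs) are taken from the study's
    truth when not supplied.  ``external_peaks`` maps sample ids to called
    peak sets and bypasses the internal Poisson caller for those samples.
    """
    config = config or AnalysisConfig()
    genome: Genome = study.genome
    tss: list[TssRecord] = study.tss
    if blacklist is None:
        blacklist = study.truth.blacklist if hasattr(study, "truth") else []
    if snps is None:
        snps = study.truth.snps if hasattr(study, "truth") else []
    if pwms is None:
        pwms = study.truth.pwms if hasattr(study, "truth") else []
    if celltype_genes is None and hasattr(study, "truth"):
        celltype_genes = study.truth.celltype_genes

    chip_samples = [s for s in study.samples if s.role == "chip"]
    coverage, signals = sample_signals(
        study.reads, study.samples, genome, config, study.input_for
    )

    # --- peak calling + QC + blacklist ---
    peaksets: list[PeakSet] = []
    for s in chip_samples:
        if external_peaks and s.sample_id in external_peaks:
            ps = external_peaks[s.sample_id]
        else:
            ps = call_peaks_poisson(
                coverage[s.sample_id],
                coverage[study.input_for(s).sample_id],
                q_threshold=config.q_peak,
                min_width=config.min_peak_width,
                meta=s,
            )
        peaksets.append(ps)
    retained_sets, qc_report = qc_filter(peaksets, min_peaks=config.min_peaks)
    retained_sets = [
        PeakSet(ps.meta, remove_blacklist(ps.peaks, list(blacklist)), ps.provenance)
        for ps in retained_sets
    ]
    retained = [ps.meta for ps in retained_sets]

    # --- correlation QC on retained ChIP samples ---
    retained_signals = {m.sample_id: signals[m.sample_id] for m in retained}
    pmat = promoter_matrix(retained_signals, tss, genome, flank=config.correlation_flank)
    pearson = pearson_matrix(pmat)

    # --- consensus per group, master set ---
    consensus: dict[tuple[str, str], ConsensusSet] = {}
    for ct in CELL_TYPES:
        for cond in CONDITIONS:
            reps = [
                ps for ps in retained_sets
                if ps.meta.cell_type == ct and ps.meta.condition == cond
            ]
            if reps:
                consensus[(ct, cond)] = consensus_majority(reps)
    master = master_set(list(consensus.values()))

    # --- counting + differential per cell type ---
    ext_reads = {
        m.sample_id: extend_reads(study.reads[m.sample_id], genome, config.read_flank)
        for m in retained
    }
    counts_all = count_reads(master, ext_reads, retained)
    differential: dict[str, DifferentialResult] = {}
    significant: dict[str, tuple[list[Peak], list[Peak]]] = {}
    allpeak: dict[str, dict] = {}
    for ct in CELL_TYPES:
        cols = [j for j, m in enumerate(retained) if m.cell_type == ct]
        if not cols:
            continue
        sub = CountMatrix(
            regions=counts_all.regions,
            samples=[retained[j] for j in cols],
            counts=counts_all.counts[:, cols],
        )
        model = NBDifferentialModel.from_samples(sub)
        res = model.fit()
        differential[ct] = res
        significant[ct] = res.select_significant(fc=config.fc, fdr=config.fdr)
        sig_ct = {m.sample_id: retained_signals[m.sample_id] for m in sub.samples}
        smat = region_signal_matrix(sig_ct, master)
        allpeak[ct] = allpeak_signal_comparison(
            smat, [m.condition for m in sub.samples]
        )

    # --- enhancers per cell type ---
    enhancer_sets: dict[str, EnhancerSet] = {}
    enhancer_stats: dict[str, dict] = {}
    for ct in CELL_TYPES:
        by_cond = {
            cond: consensus[(ct, cond)]
            for cond in CONDITIONS
            if (ct, cond) in consensus
        }
        if not by_cond:
            continue
        es = call_enhancers(
            by_cond, tss, genome, ct,
            promoter_flank=config.promoter_flank,
            half_width=config.enhancer_half_width,
        )
        enhancer_sets[ct] = es
        stats: dict = {"venn": es.venn}
        nc_r = es.condition_regions.get("NC", [])
        mut_r = es.condition_regions.get("MUT", [])
        stats["coverage"] = (
            coverage_fraction(nc_r, mut_r) if nc_r else
            {"nc_covered_by_mut": float("nan"), "mut_unique_fraction": float("nan")}
        )
        stats["locations"] = {}
        stats["snp_fraction"] = {}
        for cond, regions in (("NC", nc_r), ("MUT", mut_r)):
            cats, dist = annotate_locations(
                regions, tss, study.gene_spans,
                promoter_flank=config.promoter_flank,
            )
            stats["locations"][cond] = dist
            frac, _flags = (
                snp_fraction(regions, list(snps), window=config.snp_window)
                if snps and regions
                else (float("nan"), [])
            )
            stats["snp_fraction"][cond] = frac
        enhancer_stats[ct] = stats

    # --- motifs ---
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fg_by_group = {
        (ct, cond): [study.sequence(iv) for iv in enhancer_sets[ct].condition_regions.get(cond, [])]
        for ct in enhancer_sets
        for cond in CONDITIONS
        if enhancer_sets[ct].condition_regions.get(cond)
    }
    motif_table = MotifEnrichmentTable.build(
        list(pwms), fg_by_group, rng, bg_times=config.bg_times
    )
    condition_motifs = {
        ct: condition_differential_motifs(motif_table, ct, alpha=config.motif_alpha)
        for ct in enhancer_sets
    }
    spec_cts = [ct for ct in ("BC", "LP", "ML") if ct in enhancer_sets]
    specific = celltype_specific_tfs(
        motif_table, cell_types=spec_cts, condition="NC", alpha=config.motif_alpha
    )
    preservation = mut_preservation(specific, motif_table, alpha=config.motif_alpha)

    # --- cell-type gene H3K27ac change fractions ---
    gene_change: dict[str, dict] = {}
    if celltype_genes:
        for ct, genes in celltype_genes.items():
            if ct not in significant or not genes:
                continue
            up, down = significant[ct]
            gene_change[ct] = gene_change_fraction(up, down, list(genes), tss)

    return StudyResults(
        config=config,
        qc_report=qc_report,
        retained=retained,
        peaksets=retained_sets,
        pearson=pearson,
        consensus=consensus,
        master=master,
        counts=counts_all,
        differential=differential,
        significant=significant,
        allpeak=allpeak,
        enhancer_sets=enhancer_sets,
        enhancer_stats=enhancer_stats,
        motif_table=motif_table,
        condition_motifs=condition_motifs,
        specific_tfs=specific,
        preservation=preservation,
        gene_change=gene_change,
    )


@dataclass
class LoadedStudy:
    """A dataset loaded from disk (the file-based counterpart of
    :class:`~chipscape.simulate.Study`)."""

    genome: Genome
    tss: list[TssRecord]
    gene_spans: list[GenomicInterval]
    samples: list[SampleMeta]
    reads: dict[str, ReadSet]
    fasta_path: str | None = None
    _fasta: object = None

    def input_for(self, meta: SampleMeta) -> SampleMeta:
        for s in self.samples:
            if (
                s.role == "input"
                and s.cell_type == meta.cell_type
                and s.condition == meta.condition
            ):
                return s
        raise KeyError(f"no input sample for {meta.sample_id}")

    def sequence(self, iv: GenomicInterval) -> str:
        if self._fasta is None:
            from pyfaidx import Fasta

            self._fasta = Fasta(self.fasta_path)
        return str(self._fasta[iv.chrom][iv.start : iv.end]).upper()


def load_study(paths: Mapping[str, str]) -> LoadedStudy:
    """Load a dataset from the path map a dataset config carries
    (genome/chrom_sizes/genes/sample_sheet keys)."""
    from .coverage import reads_from_lists

    sizes = cio.read_chrom_sizes(paths["chrom_sizes"])
    genome = Genome(chrom_sizes=sizes, fasta_path=paths.get("genome"))
    tss, spans = cio.read_gene_table(paths["genes"])
    samples, sample_paths = cio.read_sample_sheet(paths["sample_sheet"])
    reads = {
        s.sample_id: reads_from_lists(cio.read_reads_bed(sample_paths[s.sample_id]))
        for s in samples
    }
    return LoadedStudy(
        genome=genome,
        tss=tss,
        gene_spans=spans,
        samples=samples,
        reads=reads,
        fasta_path=paths.get("genome"),
    )
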