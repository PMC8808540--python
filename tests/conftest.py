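"""Shared fixtures: the default synthetic study and its full analysis are
built once per session (they back the recovery and integration tests)."""

from __future__ import annotations

import numpy as np
import pytest

from chipscape.pipeline import AnalysisConfig, analyze_study
from chipscape.simulate import SimParams, simulate_study
from chipscape.types import Genome, GenomicInterval


@pytest.fixture(scope="session")
def study():
    """The default synthetic study (seed 17)."""
    return simulate_study(SimParams())


@pytest.fixture(scope="session")
def scaled_config(study):
    """Analysis config with QC and SNP thresholds scaled to the synthetic
    genome, as the dataset's config file prescribes."""
    return AnalysisConfig(
        min_peaks=study.params.min_peaks_qc,
        snp_window=study.params.snp_window,
    )


@pytest.fixture(scope="session")
def results(study, scaled_config):
    """Full pipeline output on the default study."""
    return analyze_study(study, scaled_config)


@pytest.fixture(scope="session")
def tiny_params():
    """A small fast study for CLI / file-based tests."""
    return SimParams(
        n_chroms=1,
        chrom_length=1_000_000,
        n_genes=60,
        n_shared=40,
        n_promoter_peaks=20,
        n_celltype=12,
        n_celltype_nc_only=3,
        n_celltype_mut_only=3,
        n_differential=6,
        n_replicates=2,
        reads_per_chip=40_000,
        reads_per_input=40_000,
        n_snps=30,
        min_peaks_qc=30,
        seed=17,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(17)


@pytest.fixture
def toy_genome():
    return Genome(chrom_sizes={"chr1": 100_000, "chr2": 50_000})


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
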