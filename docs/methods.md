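# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `chipscape`.

## Coordinates and interval semantics

All internal coordinates are 0-based half-open `[start, end)`, the native
BED/narrowPeak convention; 1-based inputs are converted at the reader
boundary. Two intervals overlap iff they share ≥ 1 bp under half-open
arithmetic, and this single threshold is used everywhere an overlap
decision is made: consensus components, promoter exclusion, blacklist
filtering, read counting, cross-condition enhancer identity and recovery
scoring. Strand is ignored for interval arithmetic except when deriving a
TSS (the 5′ end of the gene span per strand). Nearest-gene distance is
measured from region edges (0 when the TSS lies inside the region), with
ties broken toward the upstream feature and then by gene id — a fully
deterministic rule.

## Signal model

Reads are extended ±100 bp before binning, approximating fragment-length
coverage from 50-bp reads (250 bp total). A bin's count is the number of
extended reads overlapping it (not base-pair pileup averaged); this is the
simplest reproducible reading of window-based signal, and because every
comparison in the package is internal, the choice cancels out. The
normalized signal per bin is `(chip/N_chip − input/N_input) × 1e6`; it is
invariant to rescaling counts and depth together and antisymmetric under
swapping ChIP and input. Promoter windows (TSS ± 2 kb) are truncated at
chromosome edges rather than dropped, and the promoter matrix *sums*
signal per window (for fixed window sizes, summing versus averaging does
not change Pearson correlations). Correlations are computed on the raw
normalized signal without a log transform.

## Stand-in peak caller

The internal caller is a deliberate, documented stand-in for an external
MACS2-style caller — the pipeline accepts external narrowPeak files and
bypasses it. Per bin it computes a Poisson upper tail with
λ = max(genome-wide input rate, 10-kb centred local input rate) ×
(N_chip/N_input), BH-corrects across all bins of the sample, merges
adjacent significant bins (q < 0.05) and discards runs shorter than 200 bp.
The summit is the centre of the bin with the maximal ChIP count (leftmost
on ties). When the input track is empty the genome-wide ChIP mean serves
as λ, with a warning. No model building, duplicate handling or exact
q-value reproduction of any external tool is attempted.

## Consensus and master set

"Majority" is read strictly: a component needs contributions from
⌊n/2⌋+1 distinct replicates, so n = 2 requires both. Peak identity across
replicates is single-linkage overlap connectivity at ≥ 1 bp — the standard
consensus semantics when no fractional-overlap rule is specified; the
minimum-overlap requirement is configurable in the sense that components
are built from whatever peak sets are supplied. The consensus region is
the component's union span and inherits the summit of its highest-scoring
member; the master set is the overlap-merge of all groups' consensus
regions, sorted and disjoint.

## Negative-binomial differential test

`NBDifferentialModel` is a two-condition Wald test in the DESeq2
tradition, re-implemented against a calibration contract (controlled
type-I error, power on ≥ 2-fold planted effects) rather than numerical
identity with any external package:

* size factors by median-of-ratios over all-positive regions (total-count
  fallback with a warning);
* per-region dispersion by method of moments from pooled within-group
  variance of normalized counts, floored at 1e-8;
* a log-linear mean–dispersion trend fitted across informative regions,
  blended 50/50 with the per-region estimate **linearly**. The linear
  blend bounds the final dispersion below by half the trend; a log-space
  (geometric) blend lets regions whose sample variance randomly fell to
  the Poisson floor collapse the Wald SE and inflates the null tail
  (measured empirical type-I ≈ 0.11 at 3 vs 3);
* log₂ fold change from group means of normalized counts with
  pseudo-count 0.5 (bounded at zero counts), MUT in the numerator;
* delta-method SE under Var(q) = μ/s + αμ², and a **moderated-t**
  reference with df = 2(n₁+n₂−2): the within-group variance contributes
  n₁+n₂−2 residual df and the 50/50 trend shrinkage roughly the same
  prior df again (the limma heuristic). Measured on 3 vs 3
  negative-binomial simulations at dispersion 0.05 (2000 null + 200
  fold-4 regions): type-I error 0.047–0.053 at p < 0.05, realized FDP ≤
  0.05 among FC ≥ 2 & FDR < 0.05 selections, sign-correct recall ≥ 0.95.

BH correction is delegated to `statsmodels.stats.multitest` behind
`stats.bh_fdr` and cross-checked against a brute-force step-up in the
tests. The all-peak comparison reports per-condition medians of mean
region signal, the percent change of the MUT median, and a two-sided
paired t-test across regions (identical inputs are reported as p = 1
rather than an undefined statistic).

## Enhancer analyses

Enhancers are summit ± 500 bp windows of consensus H3K27ac peaks,
clipped at chromosome edges, with any window overlapping a promoter
(TSS ± 500 bp) removed; the absence of promoter overlap is re-asserted on
every emitted set. Cross-condition identity is ≥ 1 bp overlap of the 1-kb
windows; overlapping NC/MUT windows merge into one entity annotated on
the union span, which makes the NC-only/shared/MUT-only classes a true
partition (counts are conserved by construction). Location annotation is
a three-way priority classification — promoter-vicinity (< 2 kb from the
nearest promoter-window edge, measured enhancer-edge to promoter-edge) >
genic (overlaps a gene span) > distal intergenic — a simplification of
finer exon/intron taxonomies that preserves the contrasts the analyses
read off. SNP proximity uses the half-open window
`[start − w, end + w)` measured from enhancer edges (w configurable,
150 kb at human scale). A gene is "changed" when it is the nearest gene
of at least one significant differential region; the down fraction uses a
majority rule over the gene's regions with ties counted as down.

## Motif enrichment

PWMs (columns summing to 1, probabilities floored at 1e-3 before
log-odds) are scanned on both strands; a sequence is a hit when some
window reaches 0.8 of the motif's maximum achievable log-odds — there is
no universal PWM cutoff, and the recovery tests fix this operating point.
Positions containing N score −∞. Enrichment is a one-sided hypergeometric
test on sequences-with-≥1-hit, with the urn being foreground plus a
dinucleotide-shuffled background (Altschul–Erickson shuffle, seeded, 2×
the foreground count) — exact, brute-force verifiable, and sufficient for
the selection logic built on top; no binomial background weighting or
repeat masking is attempted. Selection uses raw p-value thresholds
(α = 10⁻⁴ for both the condition-differential and cell-type-specific
analyses), with BH q-values reported alongside for transparency.
Cell-type-specific TFs (enriched in exactly one of BC/LP/ML under NC) are
disjoint by construction; the preservation matrix counts, for each pair
(X, Y), the Y-specific motifs enriched in MUT X.

## Synthetic study generator

The generator emulates the post-alignment inputs of a sorted-cell,
two-condition histone-modification study at desk scale. Defaults (all
`SimParams` fields, chosen once as the study conditions):

* genome: 2 chromosomes × 5 Mb, i.i.d. bases at GC 0.41; 300 genes with
  ≥ 10 kb TSS spacing and 5–15 kb spans;
* landscape: 400 shared peaks; 150 promoter peaks centred on TSSs (active
  in every group, with per-cell-type lognormal strength, sd 0.4 — H3K27ac
  marks active promoters, and these drive realistic promoter-matrix
  correlation structure while exercising the promoter-exclusion filter);
  120 cell-type-specific peaks per cell type, of which 30 are NC-only and
  30 MUT-only; 60 condition-differential peaks per cell type at fold 4
  (half up, half down in MUT); widths uniform 600–2000 bp; placement by
  bounded rejection sampling with a 400-bp margin so that no non-promoter
  truth region (or its 1-kb enhancer window, or a called summit shifted
  by up to a few bins) can touch a promoter;
* reads: 3 replicates per (cell type, condition) at 200k reads plus one
  200k input per group; per-peak weights Gamma(shape 4) shared across
  replicates, jittered per replicate by lognormal(sd 0.1) (~10 %
  replicate CV), positions Normal(peak centre, 75 bp), 50-bp reads. The
  in-peak fraction is depth-corrected so the realized FrIP against the
  planted peaks hits the 0.3 target once uniform background reads falling
  into peaks are accounted for;
* motifs: sharp 10-mer PWMs (0.85/0.05 columns), one per cell type plus
  16 random decoys; each cell-type-specific region carries its cell
  type's consensus at the region centre on a random strand, and MUT-only
  BC regions additionally carry the LP motif (the "BC→LP shift"
  scenario);
* SNPs: 123 records, half placed within the (scaled) proximity window of
  MUT-BC-specific enhancers, the rest uniform;
* blacklist: 5 decoy regions that receive artifactual ChIP enrichment in
  every sample, so the blacklist filter has real work to do;
* desk-scale analysis thresholds written into the dataset config:
  QC `min_peaks` = 300 (the study emits ~700 peaks per full-depth sample;
  a depth/20 library falls far below) and SNP window 5 kb (123 SNPs ×
  10 kb ≈ 12 % of the 10 Mb genome, roughly the coverage fraction of
  123 × 300 kb windows on hg19). The human-scale values (10 000 and
  150 kb) remain the `AnalysisConfig` defaults.

Everything is deterministic given the seed; per-sample streams derive
from `(seed, crc32(sample_id))`. The ground truth (peak classes, weights,
per-group enhancer windows, motif assignment, SNPs, per-cell-type gene
lists) is emitted alongside the data as BED + JSON and suffices to score
every recovery test without reading the generator.

What the generator does **not** model: sequencing errors, duplicates, GC
and mappability bias, fragment-size variation, batch effects, and any
promoter/enhancer sequence realism beyond the planted consensus strings.
Passing recovery tests therefore demonstrate the pipeline's logic and
calibration under a clean read model, not performance on real libraries
— in particular real replicate dispersion is larger and peak boundaries
fuzzier than simulated here.

## Problem sizes and determinism

The default end-to-end run (32 samples × 200k reads on 10 Mb, ~1260
master regions, 20 PWMs × 8 enhancer groups) completes in roughly a
minute on one CPU; the calibration simulation uses 2200 regions at 3 vs
3. Pipeline outputs are byte-stable across reruns with the same config
and seed: all iteration orders are sorted, the motif background shuffle
is seeded from the config seed, and no stage depends on hash ordering.

## Known limitations

* The caller's bin granularity (100 bp) quantizes summits; enhancer
  windows can shift by up to ~1 bin against truth. Recovery is scored by
  set-level Jaccard with ≥ 1 bp matching for this reason.
* The NB test assumes a common dispersion per region across conditions
  and uses plug-in group means in the SE; its calibration is validated at
  the simulated replicate counts (2–3 per condition), not asymptotically.
* Venn counting on merged entities can, in principle, chain several
  same-condition windows through a bridging window of the other
  condition; with 1-kb windows and the generator's 2-kb placement margins
  this does not occur in practice.
* The location taxonomy folds exon/intron/UTR distinctions into "genic",
  and super-enhancer detection is out of scope.
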