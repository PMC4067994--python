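# Methods

## Read-depth model and normalization

The observable is the mean per-base depth `D[s,t]` of sample `s` over capture
target `t` (one exon). Depth is proportional to library size, per-target
capture efficiency, and the local copy number; the pipeline removes the
first two nuisance factors with a fixed two-step median contract:

1. library scaling: `D'[s,t] = D[s,t] / median_t D[s,·]`
2. batch ratio: `R[s,t] = D'[s,t] / median_{s'∈batch(s)} D'[s',t]`

so that `R ≈ CN/2` for a diploid locus. Medians (not means) make both steps
robust to the sample's own CNVs and to a minority of CNV carriers in the
batch; the contract fails only if more than half the batch is abnormal at a
target, or if a sample's median depth is dominated by CNVs (both are
pathological inputs that raise errors or are caught by QC flags downstream).
Properties guaranteed by construction and enforced by tests: per-target
batch median of R is exactly 1; scaling any sample's row of D leaves its R
unchanged; R is monotone in the sample's own depth.

Targets whose raw batch-median depth is below `min_depth = 20×` are masked
as uncallable — ratios with denominators that small are dominated by
sampling noise. The threshold is configurable.

### Sliding window

Smoothing is a windowed median over `w` same-gene unmasked targets
(`w` odd; windows never cross gene boundaries because panel targets are not
genomically contiguous). The default calling track is `w = 1`: single-exon
CNVs are real and clinically reportable on exon-resolution panels, and any
`w ≥ 3` median erases them. A `w = 3` track is intended as QC annotation,
not for calling.

## Copy states and segmentation

Per-target states are cut at ratios 0.2 / 0.7 / 1.3 (midway between the
ideal diploid levels 0, 0.5, 1, 1.5); exact boundary values resolve to the
lower-copy state. These thresholds are a package default — with the default
noise model the ratio SD per target is ≈ 0.05, so the margins are many
standard deviations wide; they are exposed in configuration for noisier
data.

Segmentation is run-length encoding of same-state consecutive unmasked
targets within one gene. There is no minimum event size; single-target
calls carry a `single_exon` flag as the stand-in for manual curation.
Masked targets inside a run do not split it but add
`low_coverage_neighbor`. Two post-processing rules:

- **segdup shadow merge** — a homozygous-deletion run adjacent to a
  het-looking run whose targets all lie in a segmental duplication is merged
  into one homozygous deletion with `segdup_overlap`: reads from the intact
  paralog map into the deleted exons and inflate their apparent depth
  (the classic artifact at gene–pseudogene loci).
- **contiguous multi-gene annotation** — compatible calls in chromosomally
  adjacent panel genes get `multi_gene_contiguous`; breakpoints between
  targeted exons cannot be mapped, so a megabase-scale deletion surfaces
  only as per-gene calls plus this annotation.

`CN = 2·R̄` is reported as a continuous estimate next to the discrete state.

Sex chromosomes: the cohorts this is designed for are de-identified, so no
sample sex is assumed; calls on chrX carry an `x_unknown_sex` flag and no
zygosity rather than guessing a baseline.

## Conversion detection

A gene-side deletion call converts when a duplication call on the linked
pseudogene covers ≥ `overlap_frac = 0.8` of the partner images of its exons
and copies are conserved: `|(2 − 2R̄_gene) − (2R̄_pseudo − 2)| ≤
reciprocity_tol = 0.6` copies. Alleles = 2 for a homozygous gene-side
deletion, 1 for heterozygous; consequently (CN_gene, CN_pseudo) = (0, 4)
and (1, 3) convert while (0, 3) and (1, 4) do not. Both tolerances absorb
depth noise and are configurable. Exon-image mapping uses the panel's
explicit `pseudo_partner` links, not sequence homology — panel designers
know the segdup structure, and tiling the pseudogene is precisely what makes
conversions detectable. Plain deletions (no pseudogene gain) are never
promoted. The caller reports exon spans in panel order and takes no position
on 5'/3' orientation of a converted block.

STRC-locus logic derives a per-allele status
(intact/deleted/converted/duplicated) from residual calls plus conversions,
marks CATSPER2 involvement, and calls DIS only for biallelic STRC deletion
together with homozygous CATSPER2 deletion. A CATSPER2-plus-pseudogene-only
deletion leaves STRC intact.

## Causative categories and cohort summaries

Per (sample, gene), precedence: homozygous deletion → `hom_cnv`; two CNV
alleles of different classes (or a biallelic conversion) → `biallelic_cnv`;
het CNV plus a het asserted-pathogenic small variant in the same recessive
gene → `hemizygous_cnv_plus_snv`; a `multi_gene_contiguous` call →
`contiguous_multi_gene`; otherwise `carrier_only`. A lone heterozygous CNV
in a dominant gene is never auto-causative: it is returned as carrier with
an `ad_review` flag plus a reading-frame annotation (sum of deleted exon
lengths mod 3), leaving the dominant-negative judgement to expert review.

Summaries count **alleles**: one record per CNV allele, so a homozygous
deletion contributes two records and a mixed biallelic patient one record
per class. Under this unit the per-class columns of the cohort table and
the carrier allele frequencies (`alleles / 2N`) are the same counts.
Percentages are rounded half-away-from-zero at the printed precision
(integers in the table, one decimal for cohort scalars). One convention
worth noting: the contiguous-deletion category is tallied per CNV — the
single patient carrying a two-gene deletion contributes both CNVs to that
category's percentage — while the other categories are tallied per patient.

### The packaged cohort records

The packaged fixture reconstructs a 686-patient diagnostic cohort at the
patient level: 143 CNV alleles in 104 patients, 50 patients with causative
CNVs (21 homozygous, 16 hemizygous + variant, 12 biallelic, 1 contiguous),
37 with causative STRC lesions, with the per-gene/per-class table and every
headline percentage asserted at build time. Within-patient assignment is
under-determined by published aggregates; the packaged assignment is one
fixed, internally consistent choice (it includes two biallelic STRC patients
whose second allele carries both a conversion and a duplication lesion —
the unique structure under which all published marginals close
simultaneously). Only marginals are meaningful; per-patient rows are
synthetic.

## Synthetic cohorts

The generator emulates capture-panel depth data: per-target efficiency
`eff_t = exp(N(0, 0.3))`, per-sample library factor `lib_s = exp(N(0,
0.2))` (both lognormal, median 1 — the normalization removes them exactly),
batches filled in order of up to 48 samples, and expected copy number from
spiked events (deletions subtract, duplications add, conversions move
copies to the pseudogene reciprocally). Per-base counts are negative
binomial with mean `base_depth·eff_t·lib_s·CN/2` (default 700×) and size
`dispersion` (default 10); the recorded per-target value is the mean over
the target's `L` bases, drawn exactly as `NB(L·μ, L·dispersion)/L`. At the
defaults this gives a per-target ratio CV of ≈ 5% on a 150 bp exon —
tight, realistic post-normalization tracks; `dispersion → ∞` is the Poisson
limit, smaller values are noisier.

What the generator does **not** model: GC/mappability bias, correlated
noise along the genome, mapping ambiguity between gene and pseudogene
(segdup read leakage is hand-constructed in tests, not simulated), sex
chromosomes, or read-level artifacts. Passing spike-in tests therefore
demonstrates the correctness of the normalization/calling machinery under
the stated noise model, not performance on real capture data, where batch
effects and paralog mapping are the dominant failure modes and manual
curation of flagged calls remains necessary.

Problem sizes used by the test suite and the acceptance script — 24-sample
cohorts (50 seeds) for spike-in sensitivity/false calls, a 64-sample cohort
with 4 homozygous + 4 heterozygous STRC-region deletions for the in-silico
MLPA-style concordance check, 50 seeds for conversion accuracy — were chosen
to give stable 100%/0 outcomes under the default noise model while keeping
the whole suite in the seconds range.

## Repeat burden

Elements (Alu, L1, segdup, simple repeat) count for a gene on ≥ 1 bp overlap
with the gene span (min target start to max target end, optionally
flanked); segdups require > 95% identity, the homology regime in which
non-allelic homologous recombination operates. Burdens are per kb of gene
span. The group comparison defaults to Welch's unequal-variance two-sample
t-test — the CNV-associated and remaining gene groups are unequal in size
and have no natural pairing, so a paired test is statistically ill-defined
here; a paired mode (by list order) is retained for fidelity experiments.
Reproducing any published burden p-values requires the true RepeatMasker
tracks and exact gene spans, which are external inputs; the package
validates the machinery against closed-form oracles instead.

## Numerical choices

- Medians use numpy's even-count midpoint convention throughout; the
  per-target batch median of ratios is 1 by construction for any batch size.
- Boundary ratios classify to the lower-copy state (≤ at deletion cuts,
  ≥ at the duplication cut).
- Duplication zygosity: `R̄ ≥ 1.75` (≈ 2 extra copies) is called on both
  alleles, else one.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; equal seeds give bit-identical cohorts.
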