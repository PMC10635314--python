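# Methods

This note documents the statistical procedures, the conventions chosen
where the underlying definitions leave room, the synthetic study
conditions, and what the validation suite does and does not establish.

## Sample model and quality control

A sample is one (patient, treatment cycle, compartment) combination;
compartments are CSF, PBMC, the infused product (cycle 0 by convention)
and post-therapy tumor. Cell QC is compartment-specific, with defaults
(mito% cap / min genes / min counts): CSF and PBMC 10 / 650 / 1200,
product 10 / 1300 / 2500, tumor 10 / 1500 / 2300. Boundary semantics are
not dictated by the thresholds themselves; we fix mito% strictly below
the cap and the gene/count floors inclusive (the common convention for
these cutoffs) and expose every boundary in configuration. QC is
idempotent and monotone in the thresholds, and both properties are
tested.

## Strict clonotype calling

Two cells share a clonotype iff the (V, J, C, CDR3nt) key of their
selected TRA and the (V, D, J, C, CDR3nt) key of their selected TRB
match exactly — nucleotide-level, gene-segment-level. TRA carries no D
segment, so none enters the α key; a missing β D segment is encoded as
the sentinel string `None` inside the key. A barcode is assigned only
with at least one productive, cell-associated contig on each locus.

Multi-chain cells: when a locus has several productive contigs (dual-TCR
cells, ambient material, doublets) we keep the contig with the highest
UMI count, breaking ties by read count, then lexicographic CDR3nt, then
gene names. The rule is deterministic, so the calls are invariant to
input row order (tested by permutation).

Normalization: a clonotype's per-sample frequency divides its cell count
by the sample's total *annotated* T cells, including T cells without a
recovered TCR. Whether the denominator should instead be TCR-recovered
cells is genuinely ambiguous in practice; both are implemented
(`denominator="all_t_cells" | "tcr_recovered"`), with the former the
default because recovered-TCR counts confound chain-capture efficiency
with clonality.

## Expansion tiers

Cutoffs are the 80th/95th/99th percentiles of the normalized frequencies
pooled over all (clonotype, sample) rows of the study. Conventions fixed
here because "top X%" underdetermines them:

* percentiles are linear-interpolation empirical quantiles;
* band membership is inclusive (≥ cutoff), so ties at a cutoff fall in
  the higher band — in a fully degenerate all-equal table every eligible
  row is "most expanded";
* pooling is over rows, not unique clonotypes, because frequencies are
  normalized per sample before pooling;
* count-1 rows participate in the pooled distribution (they are observed
  frequencies of the study) but can never be tiered; a flag excludes
  them from the pool if desired.

Rows with count ≤ 1 are unexpanded regardless of frequency: one cell is
no evidence of expansion however small the sample. Re-tiering any subset
under the original cutoffs reproduces the original labels (tested), so
tier labels can be carried across subset analyses.

## CAR positivity

A T cell is CAR⁺ at ≥ 3 construct-supporting reads (configurable).
Whether the count comes from the enrichment library, the expression
library, or their union is outside the package's scope: it accepts one
per-cell count and documents the ambiguity. Raising the threshold can
only shrink per-sample CAR⁺ fractions (tested), and every annotated T
cell receives exactly one call so downstream composition tests see a
partition.

## Composition testing

The statistic per cluster is log2(p₂/p₁) of the cluster's cell
proportion between two conditions, computed as a difference of logs so
that swapping the conditions negates it exactly. The null shuffles
condition labels over cells; p = (1 + #{|null| ≥ |obs|}) / (1 + N) with
N = 1000 by default, so p is never zero. Bootstrap CIs resample cells
with replacement within each condition (implemented as per-condition
multinomial draws, which is the same resampling distribution).
Benjamini–Hochberg FDR runs across clusters, and significance is the
conjunction FDR < α and |log2FD| > t with α = 0.05, t = 0.58 by default.

When a cluster has zero cells in either condition, 0.5 pseudo-cells are
added to both groups (numerator and denominator) for that cluster,
inside the permutation and bootstrap loops as well, keeping observed and
null statistics comparable and fold differences finite. For small inputs
`method="exact"` enumerates every assignment of cells to groups of the
observed sizes; the p-value is then the exact tail proportion (no +1
term, since the observed assignment is in the enumeration).

A practical note on power: with 1,000 permutations the smallest
attainable p is 1/1001, and BH over K clusters multiplies it by up to K,
so marginal effects in rare clusters cannot survive the FDR gate no
matter how the test is implemented. The power experiment therefore
plants its 2× shift in a cluster at 15% abundance — the monocyte-like
abundance class where such shifts are biologically reported — and
measures ≈ 0.95 detection at n = 2000 cells.

## PBMC↔CSF concordance

Pseudobulk is the arithmetic mean of raw counts over the cells of each
(patient, cycle, compartment, cell type) group (an optional log1p
transform exists but is off by default). Filters are applied in a fixed
order: (1) drop groups with fewer than 10 cells; (2) drop cell types
with fewer than 3 (patient, cycle)-matched PBMC–CSF pairs — cycles
present in one compartment only are unmatched and excluded; (3) within
each retained cell type, drop genes with zero mean count in at least
half of the retained samples, both compartments pooled. The order
matters (the gene rule judged against unmatched samples changes the
survivor set) and is asserted by a test. Per gene and cell type, OLS of
the CSF value on the PBMC value over matched pairs gives a two-sided
slope p-value; zero-variance predictors are flagged untestable and
excluded from the within-cell-type BH correction.

## Overlap and tumor enrichment

Membership is per patient: a clonotype is CSF-expanded if it is
non-unexpanded in *any* CSF sample of the patient (an any-cycle rule,
configurable in principle to one cycle); CSF-unexpanded means observed
in CSF but never expanded; PBMC/product/tumor membership is presence in
the respective frequency table. Intersection counts are exact and
checked against a nested-loop recount. The enrichment 2×2 is
(expanded / unexpanded) × (in tumor / not); the odds ratio uses a 0.5
Haldane–Anscombe correction when any cell is zero and is defined as 1
when the tumor column is entirely empty or full (no information either
way); the p-value is the two-sided Fisher exact test and the CI a Woolf
logit interval. On the published margins (11 of 69 expanded vs 12 of
6,128 unexpanded clonotypes found in tumor) this gives OR ≈ 96.7,
p ≈ 1.7 × 10⁻¹⁶.

## Synthetic study conditions

The generator's defaults are the package's reference conditions; all are
configurable, and all randomness flows from one seed through a single
generator consumed in a fixed order (fixed config ⇒ byte-identical
output).

* 3 patients × 4 cycles; 900 CSF, 600 PBMC, 500 product, 400 tumor
  cells per sample; blood-like composition (55% T cells), myeloid-heavy
  tumor (15% T).
* Background repertoire: 300 clones per patient under a power law with
  exponent 0.3; five planted expanders start at 1.5% of CSF T cells and
  double each cycle in CSF (flat at 1.5% in PBMC). These values were
  set so that the planted growth dominates the tier-threshold noise of
  background clones hovering at the cutoffs: with a heavier tail the
  expansion trajectory is no longer monotone run-to-run, and with a
  smaller start the early-cycle increments drown in multinomial noise.
  The heavy-tail property (top 1% of clones ≥ 10% of assigned cells)
  still holds through the planted/background mix.
* Chain emission: 10% of T cells lose one chain (exercising the pairing
  filter), 5% carry a doublet-like low-UMI secondary TRA, 3% emit a
  non-productive stray contig.
* CAR: CSF CAR⁺ schedule 0.4/0.3/0.2/0.1 by cycle, PBMC 0.05, product
  0.7, tumor 0; CAR⁻ cells draw background construct reads on {0, 1, 2}
  with probabilities (0.8, 0.15, 0.05) and CAR⁺ cells draw 3 + Poisson(5),
  so the 3-read boundary is genuinely exercised and the call equals the
  planted truth by construction.
* Composition: a 2× monocyte shift in "response-window" CSF samples
  (cycles 3–4).
* Gene panel: 60 genes, negative-binomial counts (dispersion 5) around
  lognormal group means; the first 10 genes tie the CSF group mean to
  2× the PBMC group mean with 10% multiplicative noise, the rest vary
  independently.
* Tumor: seeded from the patient's realized CSF repertoire — clones in
  the realized-expanded stratum (planted ids plus clones with > 1 CSF
  cell whose best per-cycle frequency reaches the patient's realized
  80th percentile) enter the tumor pool with probability 0.15,
  unexpanded observed clones with probability 0.002 (the rates implied
  by the published 11/69 vs 12/6128 margins), plus 30 tumor-private
  clones. The product pool is disjoint from the endogenous pool, so
  CSF-expanded clonotypes never trace to the product.

What the generator does *not* emulate: V(D)J recombination biology and
real gene-segment usage, somatic hypermutation or sequencing error,
ambient RNA and doublet structure beyond the stylized secondary chains,
batch effects, or realistic transcriptome covariance. Passing the
recovery tests therefore shows that the statistics find what they are
defined to find under controlled conditions — not that they are robust
to every artefact of real droplet data.

## Validation experiments and sizes

The suite's heavier checks (also re-run by `scripts/acceptance.py`) use
these problem sizes, chosen to give stable estimates at desk scale:
1,000 random toy repertoires (≤ 60 cells) for the clonotype oracle;
1,000 random tables for the tier oracle; 100 replicate default trials
(~2 × 10⁶ cells total) for expansion recall, trajectory monotonicity —
evaluated on the study-level trajectory, the per-cycle mean of the
patients' top-5%-tier proportions, with the per-patient fraction also
reported — and CAR interval coverage (Clopper–Pearson, pooled over
replicate × patient × cycle checks); 500 null replicates of 2,000 cells
for type-I calibration; 100 replicates for power; one 5-patient ×
2-cycle trial (10 matched pairs) for concordance recovery; 200 binomial
seeding replicates for OR coverage and recovery; and a double run of
the full pipeline for determinism.

## Known limitations

* The permutation and bootstrap engines hold an N × cells boolean matrix
  in memory; at 10⁶ cells and N = 1000 that is ~1 GB, so very large
  studies should batch the permutations.
* Exact enumeration is limited to ~2 × 10⁵ assignments.
* The concordance stage fits genes independently; patient random effects
  and mean–variance modelling (e.g. a negative-binomial GLM) are out of
  scope, as are CLR-based compositional alternatives to the proportion
  test.
* CDR3 similarity clustering, convergence analysis and antigen-specificity
  prediction are deliberately not implemented; the strict key is the
  unit of identity throughout.
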