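# clonodyn

Correlative single-cell analyses for longitudinal, multi-compartment
CAR T-cell trials — built for the setting where engineered T cells are
infused into the cerebral ventricles and the cerebrospinal fluid (CSF),
peripheral blood (PBMC), the infused product, and post-therapy tumor
are each sampled by scRNA-seq and scTCR-seq over treatment cycles. The
package is aimed at computational immunologists running (or reviewing)
such trials who need the repertoire and composition statistics as
tested, reusable code rather than one-off scripts.

## What it computes

Every sample is a (patient `upn`, treatment `cycle`, `compartment`)
combination. On top of that keying, the pipeline provides:

* **Strict clonotype calling.** A cell's clonotype is the exact
  (V, D, J, C, CDR3-nucleotide) key of both its α and β chain; a cell is
  assigned only if it has a productive, cell-associated TRA *and* TRB
  (highest-UMI contig per locus, deterministic tie-breaks). Per-sample
  frequencies are normalized by the sample's total annotated T cells.
* **Expansion tiers.** With normalized frequencies pooled across all
  samples of the study, a clonotype-sample pair with count > 1 is
  *expanded* when its frequency reaches the pooled 80th percentile,
  with bands at the top 20–5% (expanded), 5–1% (more expanded) and top
  1% (most expanded). Singleton observations are never tiered.
* **CAR transgene calls.** A T cell is CAR⁺ when ≥ 3 reads support the
  CAR construct; per-sample CAR⁺ fractions summarise transgene dynamics.
* **Composition testing.** Per-cluster log2 fold differences of cell
  proportions between two conditions, with a label-permutation null
  (p = (1 + #{|null| ≥ |obs|}) / (1 + N)), within-condition bootstrap
  CIs, Benjamini–Hochberg FDR, and the conjunction call
  FDR < 0.05 ∧ |log2FD| > 0.58 (1.1 / 1.3 for stricter analyses).
* **PBMC↔CSF expression concordance.** Pseudobulk mean counts per
  (patient, cycle, compartment, cell type); drop groups with < 10
  cells, cell types with < 3 matched PBMC–CSF pairs, and genes at zero
  in ≥ half of the retained samples; then per-gene OLS `CSF ~ PBMC`
  with FDR within cell type.
* **Repertoire overlap and tumor enrichment.** Upset-style membership
  of each clonotype in {CSF-expanded, CSF-unexpanded, PBMC, product,
  tumor}, and a 2×2 Fisher exact test of whether CSF-expanded
  clonotypes reach the tumor more often than unexpanded ones
  (Haldane–Anscombe-corrected odds ratio, Woolf CI).
* **A ground-truthed synthetic trial generator** (`clonodyn.simulate`)
  that plants every effect the pipeline is supposed to find: heavy-tailed
  repertoires with clones doubling per cycle in CSF only, a decaying
  CAR⁺ fraction with background construct reads in CAR⁻ cells,
  condition-dependent composition shifts, PBMC-coupled genes, and tumor
  repertoires seeded preferentially from CSF-expanded clones.

## Worked example

```bash
clonodyn simulate --seed 1 --out scratch/trial
clonodyn run-all --bundle scratch/trial --out scratch/run --seed 1
```

or stage by stage via the numbered scripts:

```bash
cd analysis
python 01_simulate_trial.py     # 19,900 cells over 28 samples
python 02_clonal_expansion.py
python 03_car_dynamics.py
python 06_overlap_enrichment.py
```

`02_clonal_expansion.py` prints (abridged):

```
1,313 strict clonotypes over 8,564 paired cells (964 barcodes lacked a chain pair)
tier cutoffs (80/95/99th pct of pooled normalized freq): [0.00699, 0.0116, 0.03396]

proportion of T cells in the top-5% tiers, by cycle:
cycle                  1      2      3      4
UPN01 CSF          0.047  0.229  0.317  0.559
      PBMC         0.102  0.087  0.082  0.100
```

The CSF top-tier share rises from 4.7% to 55.9% of T cells over four
cycles — the planted clonal expansion, recovered through QC, pairing,
frequency normalization and global tiering — while the matched blood
stays flat: blood does not mirror what happens at the infusion site.
`03_car_dynamics.py` shows the complementary transgene picture (CSF
CAR⁺ fraction falling 0.393 → 0.112 across cycles against a planted
0.4 → 0.1 schedule; product 0.69 CAR⁺; tumor 0.0), and
`06_overlap_enrichment.py` prints

```
UPN01: CSF-expanded in tumor 10/74, unexpanded in tumor 7/206
  odds ratio 4.4 (95% CI 1.6-12.1), Fisher p 3.67e-03
published margins: odds ratio 96.7, Fisher p 1.73e-16
CSF-expanded clonotypes in product: 0
```

i.e. clonotypes that expanded in CSF are over-represented in the tumor
and absent from the infused product, so the expanded response is
endogenous rather than carried in with the product.

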