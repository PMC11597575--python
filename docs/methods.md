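# Methods

This note documents the statistical models behind `coldseq`, the
choices made where the design was genuinely open, and what the bundled
synthetic-data generator does and does not emulate.

## Experimental design assumed

A bulk RNA-seq cold-stress design: one control condition (22 °C) and
one or more low-temperature treatments (0, 4, 10 °C), each with a small
number of biological replicates (default 3). Analysis is strictly
pairwise — each treatment is contrasted against the control on gene-level
counts; no multi-factor designs, batch terms, or trended/tagwise
dispersion are modelled.

## Negative-binomial exact test (`coldseq.de`)

Counts for gene *g* in sample *j* are modelled NB with mean
μ_gj = s_j·λ_gc and variance μ + φμ² (so φ = 0 is Poisson; φ is the
squared biological coefficient of variation). The pipeline is the
classical small-sample exact-test path:

1. **TMM normalisation.** Each sample's factor is the weighted trimmed
   mean of the gene-wise log2 ratios (M) against a reference sample,
   trimming 30 % of M each side and 5 % of abundance (A) each side,
   excluding genes with a zero in either sample, with delta-method
   inverse-variance weights; factors are rescaled to geometric mean 1.
   The reference is the sample whose upper-quartile CPM is closest to
   the mean upper quartile. `NBExactTest` also accepts user-supplied
   factors (`norm_factors`) for full control.
2. **Common dispersion.** A single φ shared by all genes maximises the
   conditional NB log-likelihood of each group's replicate vector given
   its sum, computed on pseudo-counts rescaled to a common
   (geometric-mean) effective library size. The maximiser is found by
   golden-section search on φ ∈ [1e-6, 10]; replicate vectors that are
   bit-identical drive the estimate to the lower bound. Simple scaling
   of pseudo-counts slightly distorts the Poisson part of the variance
   for samples far from the common depth; at the default ~10 % depth CV
   the effect on calibration is negligible (the type-I error check in
   the acceptance suite measures this directly).
3. **Exact test.** For NB groups with common dispersion and equal
   effective libraries, a group sum of n replicates is NB with size
   n/φ, and the conditional law of the treatment sum given the total z
   is beta-binomial BetaBinom(z, n_t/φ, n_c/φ) — the identity follows
   directly from the NB–gamma mixture. Tails are summed exactly from
   the log-pmf (per gene, the shorter tail; vectorised and chunked);
   scipy's `betabinom` agrees on small totals but its generic
   per-point CDF summation is too slow at totals of 10³–10⁵. The
   two-sided p doubles the smaller tail, capped at 1. At φ = 0 the
   conditional law is binomial(z, n_t/(n_c+n_t)) and scipy's closed
   form is used. Group sums of pseudo-counts are rounded to the nearest
   integer for the discrete test.
4. **Effect sizes.** logFC = log2((Σ_treat+0.5)/(Σ_ctrl+0.5) ·
   L_ctrl/L_treat) with effective library totals L; logCPM = log2 of
   the mean per-sample (count+0.5)/(effective library+1)·10⁶. The 0.5
   pseudo-count keeps zeros finite.
5. **Multiple testing.** Benjamini–Hochberg step-up (via statsmodels),
   returned in input order; genes with FDR < 0.01 are called DEGs.

## Top-N selection and Venn partitioning (`coldseq.ranking`)

Per contrast, induced genes are filtered by FDR < 0.01 (strict),
logCPM > 4 (strict) and logFC > 0, ranked by logFC descending with ties
broken by FDR ascending then gene ID — the tie rule is our choice, made
solely so the ordering is total and reproducible. The per-treatment top
sets are partitioned into *exclusive* Venn regions (genes in exactly a
given subset of treatments); region counts therefore sum to the size of
the union. The bundled `coldseq.published` table transcribes the
printed shared top-50 cold-induced gene lists of the Arabidopsis study
(31 genes in all three temperatures, 9 in 0&4 °C only, 8 in 4&10 °C
only, 2 in 0&10 °C only) and reconstructs each temperature's full set
by padding with placeholder IDs for the unpublished exclusive genes.

## Logistic-regression enrichment (`coldseq.enrichment`)

Every gene in the universe (all measured genes, never DEGs only) gets a
signed significance score x = sign(logFC)·(−log10 FDR), with FDR floored
at 1e-300 before the log so underflowed FDRs stay finite and sign(0)=0.
For each annotation term, membership y ∈ {0,1} is regressed on x:

    logit P(y = 1) = β₀ + β₁·x

by IRLS (max 100 iterations, deviance tolerance 1e-10). The per-term
enrichment score is sign(β₁)·(−log10 p_enrich). Terms with fewer than
`min_term_size` (default 5) in-universe members, or within
`min_term_size` of covering the whole universe, are skipped with a
recorded reason.

**p-value choice.** p_enrich defaults to the likelihood-ratio test of
β₁ against the intercept-only model. The Wald p (reported by standard
binomial GLM summaries) is available via `p_method="wald"` but is *not*
the default: x is heavy-tailed — a handful of strongly significant
genes can carry |x| of 100 or more — and those leverage points make the
Wald test of the slope anti-conservative under random membership,
while the LRT remains calibrated. The package's null-calibration
acceptance check measures this on 2,000 random-membership terms over a
10,000-gene synthetic contrast.

**Small terms.** For terms with only tens of members in a universe of
thousands, both Wald and LRT p-values deviate from uniformity under the
null (ordinary small-sample behaviour, aggravated by the heavy tail of
x). The calibration guarantee should be read as asymptotic in the term
size; rankings of strongly enriched terms are much less affected than
tail p-values. No multiple-testing correction is applied across terms
for ranking (matching the score's definition); a BH-adjusted column
(`fdr_enrich`) is emitted for convenience.

**Separation.** If membership is perfectly (or quasi-) separated along
x the ML slope diverges; IRLS flags |β₁| > 30, collapsing weights, or
non-convergence, and the term is refitted with Firth's Jeffreys-prior
penalised likelihood (Newton with step-halving), yielding finite
estimates; such fits carry `fit_method="firth"` and, under
`p_method="lrt"`, a penalised-likelihood-ratio p.

Heatmap matrices place the union of one namespace's terms on rows and
conditions on columns, filling score 0 where a term was not fitted for
a condition. Top-k biological-process rankings take the k most positive
(induced) or most negative (repressed) scores, ties broken by term ID.

## qPCR quantification (`coldseq.qpcr`)

ΔCt = Ct(target) − Ct(reference) within the same (condition,
replicate); relative expression is 2^−ΔCt, summarised per (condition,
gene) as mean ± SD over biological replicates, optionally divided by
the control condition's mean (fold change) since cold-stress figures
plot expression relative to 22 °C. Because ΔCt is a within-replicate
difference, adding any constant to all Ct values changes nothing.
Group comparisons use classical one-way ANOVA with Tukey HSD post-hoc
p-values (scipy); replicate values are sorted within groups first so
results are exactly invariant to replicate order, and designs with zero
within-group variance are returned flagged degenerate rather than given
a fabricated p. No amplification-efficiency correction or ΔΔCt
calibration is attempted.

## Synthetic data generator (`coldseq.simulate`)

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

- **Counts.** Per-gene baseline log2 abundances b_g ~ U(0, 12); library
  sizes log-normal with mean 5×10⁶ and CV 0.1 (conventional bulk
  RNA-seq depth and variation — the study reports no depth figures);
  NB dispersion φ = 0.1 (a typical bulk biological CV² ≈ 0.3²; again
  conventional, not study-derived); a fraction (default 0.1) of genes
  per treatment receives a planted signed log2 effect ~ N(0, 2).
  Expected sample totals are normalised to the drawn library size, so
  strong induction is compositionally compensated as in real
  sequencing. Optional nested mode makes each milder treatment's DE
  set a subset of the previous one, mimicking graded cold responses.
- **Annotation.** Terms draw members uniformly; planted terms draw with
  weight ∝ exp(strength · true_log2fc) (negated for "down" terms), so
  membership correlates with effect sign and size. Planted terms are
  BP-namespaced; the truth table records them.
- **Ct tables.** Reference-gene Ct ~ 20 + Gaussian noise per replicate;
  target Ct adds the condition's planted ΔCt effect plus Gaussian noise
  on the Ct scale (the standard qPCR error model).

All randomness flows through one seeded NumPy generator per call;
identical configuration and seed reproduce outputs bit-for-bit.

What the generator does **not** emulate: read-level artefacts (no FASTQ
simulation, mapping or quantification noise), splice isoforms, batch
effects, GC/length biases, correlated gene modules, or the GO graph's
ancestor-closure structure. Passing the synthetic checks therefore
validates the statistical machinery — normalisation, testing,
calibration, ranking, recovery — not robustness to upstream artefacts
in real data.

## Problem sizes used by tests and the acceptance script

Chosen as the smallest sizes at which the measured properties are
stable: null enrichment calibration on one 10,000-gene contrast with
2,000 random terms of 100–500 members; planted-term recovery on ten
5,000-gene simulations with 20 planted up-terms (strength 1) among 500;
DE type-I error on one 5,000-gene null contrast (φ = 0.1, 3 replicates);
logistic oracle agreement on 100 random fixtures of n ≤ 50 against a
dense-grid + polish maximiser; the φ→0 identity on a 50-gene toy
matrix; determinism on a full two-treatment pipeline run of 1,000
genes.

## Known limitations

- Common dispersion only; genes with atypical dispersion inherit the
  shared φ, so their p-values are mildly mis-scaled (no tagwise
  shrinkage, by scope).
- Pseudo-count library equalisation is approximate for strongly uneven
  depths (see above).
- Small-term enrichment p-values are asymptotically, not exactly,
  calibrated.
- Annotation is taken as given: no propagation of gene membership up
  the GO hierarchy.
- DEG totals from any given real dataset depend on upstream
  quantification and software versions; the package validates against
  planted ground truth, not against any published DEG census.
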