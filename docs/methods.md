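# Methods

This note documents the statistical models behind each module, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Summary-statistics handling

Records are per-variant marginal associations (β, SE, p, effect-allele
frequency, N, optional imputation quality) on GRCh37 1-based coordinates.
Harmonization matches GWAS and QTL files on (chromosome, position): where
the QTL effect allele equals the GWAS other allele, the QTL β is negated and
its frequency replaced by 1 − f; the complement-strand orientations are also
accepted for unambiguous variants. Strand-ambiguous variants (A/T, C/G) are
dropped outright rather than resolved by allele frequency — frequencies near
0.5 make frequency-based resolution unreliable, and dropping is the
conservative default. Multi-allelic sites split across rows are resolved by
keeping the row whose alleles match the partner file, then lowest p. QC
keeps MAF ≥ 0.05 (boundary inclusive) and imputation r² > 0.5 (strict);
missing quality passes, treating genotyped variants as trusted. Risk loci
are ±1 Mb windows around variants with p ≤ 5 × 10⁻⁸ (inclusive); interval
overlap is closed at both ends.

## Colocalization

Per-SNP log approximate Bayes factors use Wakefield's asymptotic form with a
Gaussian effect prior; prior effect SD defaults are 0.2 for quantitative
traits and 0.15 for case-control traits on the log-odds scale — the widely
used defaults for this model. With S1 = Σᵢ ABF1ᵢ, S2 = Σᵢ ABF2ᵢ and
S12 = Σᵢ ABF1ᵢ·ABF2ᵢ, the unnormalized hypothesis masses are

    H0 = 1, H1 = p1·S1, H2 = p2·S2, H3 = p1·p2·(S1·S2 − S12), H4 = p12·S12,

which is exactly the sum over all single-SNP and ordered-pair causal
configurations; the test suite checks this equivalence against a literal
enumeration oracle to 1e-10. All accumulation uses log-sum-exp (the
H3 difference via signed log-sum-exp), so arbitrarily large ABFs cannot
overflow; posteriors sum to 1 to 1e-12 and a single-SNP region yields
PPH3 = 0 exactly. The model assumes at most one causal variant per trait
per region; no conditioning or masking extension is provided. Per-SNP H4
contributions are the softmax of labf1 + labf2 (invariant to common
shifts); the top SNV is the argmax, ties broken by lowest genomic position.

Splicing-vs-expression classification: a gene is "expression" when its
gene-level PPH4 clears the 0.75 gate (this takes precedence), "splicing"
when some exon clears the gate while the gene-level evidence favours
distinct variants (gene PPH3 > gene PPH4), else "none".

## TWAS / MWAS

The feature statistic is z = wᵀz_gwas / √(wᵀRw). Two transparent weight
schemes stand in for externally trained predictive models and are always
carried as an annotation on the results: `top1` (indicator of the
minimum-p QTL SNV, ties to the lowest position) and `marginal`
(w_i = z_qtl,i). At the statistic level no ridge is applied, so the exact
algebraic identities hold (a one-hot weight returns that SNP's z; the
two-SNP example equals 2/√3). When R is estimated from a finite reference
panel the pipeline shrinks it, R ← (1−λ)R + λI with λ = 0.01, before
computing the denominator; the ridge lives at the pipeline layer rather
than inside the statistic so that exactness and stability are separately
controllable. FDR is Benjamini–Hochberg step-up (via statsmodels) at 0.05,
computed separately per analysis type (expression, splicing, methylation),
mirroring separately reported result lists. Conditional analysis is one
round of greedy residualization: the largest-|z| significant feature is
selected, every other feature's GWAS z-vector is residualized on the
selected feature's normalized predicted-expression direction, and features
whose conditional p ≥ 0.05 are labeled joint. This answers the single-vs-
joint question without replicating a full joint model.

## cis-mQTL

OLS of methylation beta values (not M-values — the association is defined on
the measurement scale; an M-value switch exists but is off by default) on
genotype dosage plus covariates; two-sided t-test on the genotype
coefficient. The scan residualizes both methylation and dosage on the
covariate design once (Frisch–Waugh), which is algebraically identical to
the full fit and is verified against it to 1e-8 in the tests. Categorical
covariates are dummy-encoded; missing covariate cells trigger logged
listwise deletion; rank-deficient designs fail naming the offending column.
The 500-kb window around the target SNV and the 10-kb CpG-to-gene mapping
are inclusive at their boundaries; the gene mapping is distance to either
transcription terminus, strand-ignorant. BH-FDR is computed across all
SNV–CpG tests in the scan (a global rather than per-SNV correction — the
more conservative reading of an ambiguous convention; the threshold is a
config key), and per SNV the minimum-p pair is retained when its q ≤ 0.05.

## Evidence intersection

Expression candidates need strong colocalization (PPH4 ≥ 0.75) in at least
one tissue of at least one dataset AND TWAS q ≤ 0.05 — a union over tissues
and datasets on the colocalization side, cross-tissue on the TWAS side
(reference expression panels are typically cortex-only, so requiring
same-tissue agreement would be vacuous). Splicing candidates need the
splicing classification in some tissue AND a significant isoform in the
splicing TWAS. Direction is the sign of the TWAS z (colocalization carries
no sign). A gene qualifying through both routes is reported once under
expression with a splicing flag, surfacing rather than hiding the
ambiguity. Methylation overlap is annotation-only by construction. The
candidate set is monotone: relaxing either gate can only add candidates.

## Cell type and coexpression

Prevalence enrichment divides a gene's mean expression in one cell type by
the mean expression across the other types, computed as the unweighted mean
of the other per-type means so that unequal numbers of profiled cells per
type do not bias the ratio (the pooled-cell alternative would). A zero
denominator yields +inf with a warning; argmax ties break lexicographically
and are flagged. Module eigengenes are the first right singular vector of
the row-standardized module expression, sign-fixed so the mean member-gene
correlation is non-negative. kME is the absolute Pearson correlation with
the eigengene — absolute rather than squared realizes a 0–1 membership
while preserving the published 0.76 relevance threshold's meaning (strict
inequality at the boundary); a squared switch is provided. Marker
enrichment is the hypergeometric upper tail (one-sided Fisher exact);
module cell type is the minimum-p marker set.

## Network permutation

A mendelian protein counts as connected when it is adjacent to a seed or to
any first-degree interactor of a seed (two hops; the hop depth is a
parameter). Connections are set-valued — each mendelian protein counts once
regardless of how many paths reach it. The empirical p-value uses the
add-one (permutation-inclusive) convention p = (1 + #{null ≥ obs})/(B + 1),
which is never zero and whose minimum, 1/(B+1) with B = 1000 controls, is
consistent with a reported bound of p < 10⁻³ when the observed count
exceeds every control. Control seed sets are drawn uniformly without
replacement within a set, independently across the B sets, from the
118-gene null pool; edge scores are accepted and thresholdable
(score_min, default 0) but not re-derived. The B-loop uses a boolean
adjacency matrix internally; the tests verify it agrees with the
reference graph-walking builder.

## Synthetic data: what it emulates and what it does not

Genotypes: two AR(1) Gaussian-copula haplotypes per individual, thresholded
at MAF-matched normal quantiles. This reproduces exponentially decaying
pairwise LD and Hardy–Weinberg dosages at negligible cost, which is what
the colocalization and TWAS machinery is sensitive to. It does not emulate
recombination hotspots, population structure, long-range LD, or selection;
calibration results therefore speak to the statistical machinery, not to
demographic realism. Case-control summary statistics come from actual
per-SNP logistic regressions on a simulated cohort (a vectorized
two-parameter Newton solver with a small-ridge fallback on separation), so
standard errors and their finite-sample behaviour are realistic rather
than asymptotic formulas; quantitative-trait statistics come from per-SNP
OLS on a disjoint cohort. The case-control design sets the liability
intercept so the expected case fraction matches the requested design;
realized counts vary binomially around it.

Methylation M-values include planted nonzero coefficients for age, sex, two
ancestry components, batch and post-mortem interval, so covariate
adjustment is testable; an optional knob correlates batch assignment with
genotype to create a genuine confounder. Values are inverse-logit
transformed, hence strictly in (0, 1). Cell-type expression plants markers
at a specified fold-change with log-normal noise whose mean is corrected so
the planted fold is exact in expectation. Interactomes place Erdős–Rényi
edges among background, pool and mendelian nodes (seed proteins receive
only planted seed–internode–mendelian bridges, mirroring a curated seed
interactome) with uniform [0.5, 1] confidence scores.

All generators are pure functions of (configuration, seed) with no global
random state.

## Problem sizes used in the calibration suite

The heavier checks run at sizes chosen to make their distributional claims
sharp while staying desk-scale: colocalization parameter recovery uses 100
replicates of 50-SNP regions (ρ = 0.9) with 5,000 cases, 5,000 controls and
300 QTL samples — the shared-causal design yields median PPH4 well above
the 0.75 gate, and the distinct-causal design (causal pair at r² < 0.1)
favours PPH3 in a majority of replicates. TWAS null calibration uses 10,000
replicates of small (8-SNP) regions with 250/250 case-control and 150 QTL
samples. mQTL recovery uses 100 replicates of a 5-SNV, 20-CpG window at
n = 150 with a 0.5 logit-scale planted effect. Permutation-null uniformity
uses 500 outer replicates on a ~500-node graph with 100 mendelian targets:
the large target set spreads the discrete connectivity counts so the
Kolmogorov–Smirnov comparison against the uniform distribution is
informative; with only a handful of reachable targets the count
distribution is too lumpy for p-values to be near-uniform, which is a
property of discreteness, not of the test's validity.

## Known limitations

- One causal variant per trait per region in the colocalization model; no
  SuSiE-style multi-signal extension, eCAVIAR, or proportional testing.
- Weight schemes are deliberately simple marginal summaries, not
  cross-validated predictive models; TWAS results are scheme-annotated and
  not comparable across schemes.
- Conditional analysis is single-round greedy; it distinguishes joint from
  independent signals but does not produce a joint model fit.
- No methylation array normalization, probe QC, or cell-composition
  deconvolution; the mQTL module starts from clean beta values.
- Coexpression modules are inputs; the package does not construct them
  (no topological-overlap clustering).
- No literature mining or interaction-evidence QC; interactome scores are
  accepted as given.
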