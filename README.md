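# locusweave

Multi-omic candidate-gene prioritization for GWAS risk loci.

A genome-wide association study narrows disease risk down to a locus — a
megabase-scale region holding many genes — but not to the causal gene or the
mechanism through which risk acts. `locusweave` implements the integrative
pipeline used to close that gap for complex neurodegenerative disease:
combine GWAS summary statistics with brain-derived molecular quantitative
trait loci (expression, splicing, methylation), keep only genes supported by
two independent statistical routes, and characterize the survivors by cell
type, coexpression module and protein-interaction context.

It is aimed at statistical geneticists and computational biologists who work
with summary statistics; all methods run from tab-delimited summary files and
need no individual-level genotype data (a small LD reference or simulation
truth supplies the SNP correlation matrix).

## What it computes

**Colocalization** (`locusweave.coloc`). For each SNP the evidence of
association is summarized by Wakefield's approximate Bayes factor computed
from the effect estimate β and its standard error under a N(0, W) effect
prior:

    V = se²,  r = W/(W+V),  z = β/se,  log ABF = ½ log(1−r) + r z²/2

Assuming at most one causal variant per trait in the region, the posterior
probabilities of five hypotheses — H0 no association, H1/H2 association with
one trait only, H3 two distinct causal variants, H4 one shared variant —
follow from the per-SNP ABFs with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵.
PPH4 ≥ 0.75 counts as strong colocalization; an exon that colocalizes
(exon PPH4 ≥ 0.75) while the whole gene does not (gene PPH3 > gene PPH4)
flags a splicing rather than an expression mechanism.

**TWAS / MWAS** (`locusweave.twas`). Gene- or CpG-level association from
summary statistics: given SNP weights w predictive of the molecular trait
and GWAS z-scores, `z_feature = wᵀz / √(wᵀRw)` with R the LD matrix;
Benjamini–Hochberg FDR at 0.05 genome-wide, plus a greedy conditional pass
separating single from joint signals at multi-hit loci.

**cis-mQTL mapping** (`locusweave.mqtl`). OLS of methylation beta values on
genotype dosage with covariates (age at death, sex, ancestry components,
batch, post-mortem interval) for every CpG within 500 kb of a target SNV;
per SNV the strongest pair is retained at 5% FDR and CpGs map to genes
within 10 kb of a transcription start or end.

**Evidence intersection** (`locusweave.integrate`). A gene becomes a
candidate only when colocalization and TWAS agree (expression route) or the
splicing classification and the splicing TWAS agree (splicing route);
methylation hits annotate but never create candidates.

**Annotation** (`locusweave.celltype`). Cell-type expression prevalence
(mean in one type over the mean across the other types), module eigengenes,
kME module membership (|Pearson r| with the eigengene, relevant above 0.76),
and Fisher exact marker enrichment.

**Network permutation** (`locusweave.netperm`). Candidate ("seed") proteins
are scored by how many mendelian disease proteins their interactome reaches
within two hops; significance comes from 1000 control seed sets drawn from a
118-gene null pool, with the add-one empirical p-value
`(1 + #{null ≥ observed}) / (B + 1)`.

**Synthetic data** (`locusweave.simulate`). Every input the pipeline needs —
LD-structured genotypes via an AR(1) Gaussian copula, case-control and
quantitative trait summary statistics with shared/distinct/absent causal
variants, methylation with planted covariate structure, cell-type-structured
expression, and interactomes with planted seed-to-mendelian bridges — can be
generated with known truth for testing and calibration.

## Worked example

Simulate a 50-SNP region where one variant both raises disease risk
(5,000 cases / 5,000 controls, log-OR 0.3 per allele) and increases a gene's
expression (300 samples, 1 SD per allele), then colocalize:

```sh
locusweave simulate --n-snps 50 --scenario shared --n-cases 5000 \
    --n-controls 5000 --n-qtl 300 --seed 7 --out-prefix demo
locusweave coloc --gwas demo_gwas.tsv --qtl demo_qtl.tsv --feature-id DEMO_GENE
```

```
feature_id  level  n_snps  pph0      pph1      pph2      pph3      pph4                top_snv   strong_coloc
DEMO_GENE   gene   50      2.1e-29   2.3e-16   8.9e-17   5.9e-12   0.9999999999941334  snp_0025  True
```

PPH4 ≈ 1: essentially all posterior mass is on a single shared causal
variant, and the top per-SNP contribution points at `snp_0025` — the variant
the simulation actually planted. The TWAS route agrees:

```sh
locusweave twas --gwas demo_gwas.tsv --qtl demo_qtl.tsv --ld demo_ld.tsv --scheme top1
```

```
feature_id  scheme  z                  p          q          significant
DEMO_GENE   top1    9.236717912221723  2.54e-20   2.54e-20   True
```

A gene with both kinds of support (and a positive direction, from the sign
of z) would enter the candidate table that `locusweave run --config cfg.yaml`
assembles end to end; see `locusweave run --help` for the pipeline config.

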