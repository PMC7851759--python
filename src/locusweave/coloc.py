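"""Bayesian colocalization of two association signals from summary statistics.

Per-SNP evidence is summarized by Wakefield's approximate Bayes factor
computed from the effect estimate and its standard error under a Gaussian
effect prior with variance W = prior_sd**2:

    V = se**2,  r = W / (W + V),  z = beta / se
    log ABF = 0.5 * log(1 - r) + 0.5 * r * z**2

Assuming at most one causal variant per trait in the region, the posterior
mass of the five hypotheses (no association; trait-1 only; trait-2 only; two
distinct causal variants; one shared causal variant) follows from the
per-SNP ABFs and the prior probabilities p1, p2, p12 that a SNP is causal
for trait 1, trait 2, or both.  All accumulation is done in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

logger = logging.getLogger(__name__)

#: PPH4 at or above this value counts as strong evidence for colocalization.
STRONG_COLOC_PPH4 = 0.75


@dataclass(frozen=True)
class PriorConfig:
    """Colocalization priors.

    ``p1`` / ``p2``: prior probability that a SNP is causal for trait 1 /
    trait 2 alone; ``p12``: for both.  ``prior_sd_quant`` and ``prior_sd_cc``
    are the Gaussian effect-prior SDs used for quantitative and case-control
    (log-odds) traits respectively.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.2
    prior_sd_cc: float = 0.15

    def __post_init__(self):
        if not 0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.prior_sd_quant <= 0 or self.prior_sd_cc <= 0:
            raise ValueError("prior effect SDs must be positive")

    def prior_sd(self, trait_type: str) -> float:
        if trait_type == "cc":
            return self.prior_sd_cc
        if trait_type == "quant":
            return self.prior_sd_quant
        raise ValueError(f"unknown trait type {trait_type!r}")


@dataclass
class ColocPosterior:
    """Posterior probabilities of the five colocalization hypotheses."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    per_snp_h4: np.ndarray
    top_snv: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


@dataclass
class FeatureColocResult:
    """Colocalization result for one molecular feature in one tissue/dataset."""

    feature_id: str
    posterior: ColocPosterior
    tissue: str = ""
    dataset: str = ""
    strong_coloc: bool = False
    feature_level: str = "gene"  # gene or exon
    snv_ids: list[str] = field(default_factory=list)


def wakefield_log_abf(beta, se, prior_sd: float):
    """Natural-log approximate Bayes factor of association vs null.

    Vectorized over ``beta`` / ``se``.  As ``prior_sd`` shrinks to zero the
    prior puts no mass on nonzero effects and the log ABF goes to 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    v = se ** 2
    w = prior_sd ** 2
    r = w / (w + v)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z * z


def coloc_posteriors(labf1, labf2, priors: PriorConfig = PriorConfig()
                     ) -> ColocPosterior:
    """Five-hypothesis posterior from per-SNP log ABFs of the two traits.

    Unnormalized hypothesis masses (S1, S2, S12 are sums of exponentiated
    log ABFs, accumulated with log-sum-exp):

        H0 = 1,  H1 = p1*S1,  H2 = p2*S2,
        H3 = p1*p2*(S1*S2 - S12),  H4 = p12*S12

    A single-SNP region has S1*S2 - S12 = 0, hence PPH3 = 0 exactly.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape:
        raise ValueError("log ABF vectors must have equal length")
    if labf1.size == 0:
        raise ValueError("empty log ABF vectors")
    n = labf1.size

    ls1 = logsumexp(labf1)
    ls2 = logsumexp(labf2)
    ls12 = logsumexp(labf1 + labf2)
    lh = np.full(5, -np.inf)
    lh[0] = 0.0
    lh[1] = np.log(priors.p1) + ls1
    lh[2] = np.log(priors.p2) + ls2
    # S1*S2 - S12 = sum over ordered pairs i != j of ABF1_i * ABF2_j
    diff, sign = logsumexp([ls1 + ls2, ls12], b=[1.0, -1.0], return_sign=True)
    if n > 1 and sign > 0:
        lh[3] = np.log(priors.p1) + np.log(priors.p2) + diff
    lh[4] = np.log(priors.p12) + ls12
    post = softmax(lh)
    per_snp = softmax(labf1 + labf2)
    return ColocPosterior(*post, n_snps=n, per_snp_h4=per_snp)


def colocalize_feature(gwas: pd.DataFrame, qtl: pd.DataFrame,
                       priors: PriorConfig = PriorConfig(),
                       trait_types: tuple[str, str] = ("cc", "quant"),
                       feature_id: str = "", tissue: str = "", dataset: str = "",
                       feature_level: str = "gene") -> FeatureColocResult:
    """Colocalize a harmonized, QC-filtered GWAS/QTL pair for one feature.

    ``trait_types`` selects the effect-prior SD per trait (case-control uses
    the log-odds-scale prior).  The top SNV is the argmax per-SNP
    contribution to the shared-variant hypothesis, ties broken by lowest
    genomic position.
    """
    if len(gwas) != len(qtl):
        raise ValueError("GWAS and QTL frames must be row-aligned")
    if len(gwas) < 2:
        logger.warning("feature %s: only %d SNP(s); PPH3 is 0 by construction",
                       feature_id, len(gwas))
    labf1 = wakefield_log_abf(gwas["beta"].to_numpy(), gwas["se"].to_numpy(),
                              priors.prior_sd(trait_types[0]))
    labf2 = wakefield_log_abf(qtl["beta"].to_numpy(), qtl["se"].to_numpy(),
                              priors.prior_sd(trait_types[1]))
    post = coloc_posteriors(labf1, labf2, priors)
    best = np.max(post.per_snp_h4)
    tied = np.flatnonzero(post.per_snp_h4 >= best - 0.0)
    if len(tied) > 1:
        tied = tied[np.argsort(gwas["pos"].to_numpy()[tied], kind="stable")]
    post.top_snv = str(gwas["variant_id"].iloc[int(tied[0])])
    return FeatureColocResult(
        feature_id=feature_id, posterior=post, tissue=tissue, dataset=dataset,
        strong_coloc=bool(post.pph4 >= STRONG_COLOC_PPH4),
        feature_level=feature_level,
        snv_ids=list(gwas["variant_id"]))


def classify_splicing(gene_result: FeatureColocResult,
                      exon_results: list[FeatureColocResult],
                      pph4_thresh: float = STRONG_COLOC_PPH4) -> str:
    """Classify a gene's colocalization as expression, splicing, or none.

    ``expression``: the whole-gene signal colocalizes (gene PPH4 at or above
    the threshold); takes precedence.  ``splicing``: some exon colocalizes
    while the gene-level evidence argues against a shared variant
    (gene PPH3 > gene PPH4).  Otherwise ``none``.
    """
    gp = gene_result.posterior
    if gp.pph4 >= pph4_thresh:
        return "expression"
    best_exon = max((r.posterior.pph4 for r in exon_results), default=0.0)
    if best_exon >= pph4_thresh and gp.pph3 > gp.pph4:
        return "splicing"
    return "none"


def results_to_frame(results: list[FeatureColocResult],
                     classifications: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabulate per-feature colocalization results (one row per feature x tissue)."""
    rows = []
    for r in results:
        p = r.posterior
        rows.append({
            "feature_id": r.feature_id, "dataset": r.dataset, "tissue": r.tissue,
            "level": r.feature_level, "n_snps": p.n_snps,
            "pph0": p.pph0, "pph1": p.pph1, "pph2": p.pph2,
            "pph3": p.pph3, "pph4": p.pph4,
            "top_snv": p.top_snv, "strong_coloc": r.strong_coloc,
            "classification": (classifications or {}).get(r.feature_id, ""),
        })
    return pd.DataFrame(rows)
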