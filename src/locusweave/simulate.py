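"""Synthetic-data generators with the statistical structure the pipeline assumes.

Every generator is a pure function of its arguments and a seed: identical
inputs give identical outputs, and no global random state is touched.
Genotypes are produced by thresholding an AR(1) Gaussian copula at
MAF-matched quantiles (two haplotypes per individual), which yields the
exponentially decaying linkage-disequilibrium profile of a small cis region
at desk-scale cost.  Case-control summary statistics come from per-SNP
logistic regressions on a simulated cohort, so downstream handling of
standard errors sees realistic finite-sample behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimRegionConfig:
    """Layout of a simulated cis region.

    ``rho`` is the AR(1) correlation of adjacent latent Gaussians (LD decays
    as rho**distance on the latent scale); MAFs are drawn uniformly in
    ``maf_range``.
    """

    n_snps: int
    rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= low <= high <= 0.5")


@dataclass(frozen=True)
class CausalConfig:
    """Which causal regime generated a (trait, molecular) pair of signals.

    Scenarios mirror the five colocalization hypotheses: ``null`` (no causal
    variant), ``gwas_only``, ``qtl_only``, ``distinct`` (two different causal
    variants) and ``shared`` (one variant drives both).
    """

    scenario: str = "shared"
    causal_index_trait: int = 0
    causal_index_qtl: int = 0
    beta_trait: float = 0.3
    beta_qtl: float = 1.0

    def __post_init__(self):
        if self.scenario not in {"shared", "distinct", "gwas_only", "qtl_only", "null"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "shared" and self.causal_index_trait != self.causal_index_qtl:
            raise ValueError("shared scenario requires equal causal indices")
        if self.scenario == "distinct" and self.causal_index_trait == self.causal_index_qtl:
            raise ValueError("distinct scenario requires different causal indices")


def _ar1_gaussian(rng, n, m, rho):
    """n x m matrix, rows are AR(1) N(0,1) series along the columns."""
    z = rng.standard_normal((n, m))
    if rho > 0 and m > 1:
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
    return z


def simulate_ld_genotypes(cfg: SimRegionConfig, n_individuals: int
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosage matrix (individuals x SNPs, 0/1/2), empirical LD, and MAFs.

    Two AR(1) Gaussian haplotypes per individual are thresholded at the
    normal quantile of each SNP's MAF; the returned LD matrix is the
    empirical Pearson correlation of the dosages (monomorphic columns get
    zero off-diagonal correlation).
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    thresh = stats.norm.ppf(mafs)
    h1 = _ar1_gaussian(rng, n_individuals, cfg.n_snps, cfg.rho) < thresh
    h2 = _ar1_gaussian(rng, n_individuals, cfg.n_snps, cfg.rho) < thresh
    geno = (h1.astype(np.int8) + h2.astype(np.int8))
    with np.errstate(invalid="ignore", divide="ignore"):
        ld = np.corrcoef(geno.astype(float), rowvar=False)
    ld = np.atleast_2d(ld)
    ld[np.isnan(ld)] = 0.0
    np.fill_diagonal(ld, 1.0)
    return geno, ld, mafs


def default_positions(n_snps: int, chrom: str = "1", start: int = 1_000_000,
                      spacing: int = 2_000) -> pd.DataFrame:
    """Evenly spaced variant metadata for a simulated region."""
    return pd.DataFrame({
        "variant_id": [f"snp_{i:04d}" for i in range(n_snps)],
        "chrom": chrom,
        "pos": start + spacing * np.arange(n_snps),
    })


def marginal_linear(genotypes: np.ndarray, y: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple linear regression (vectorized): beta, se, p."""
    n = len(y)
    g = genotypes - genotypes.mean(axis=0)
    yc = y - y.mean()
    sgg = (g * g).sum(axis=0)
    sgg = np.where(sgg <= 0, np.nan, sgg)
    beta = g.T @ yc / sgg
    rss = (yc * yc).sum() - beta * beta * sgg
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sgg)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return beta, se, p


def marginal_logistic(genotypes: np.ndarray, y: np.ndarray, max_iter: int = 30,
                      tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression with intercept, Newton-solved in parallel.

    SNPs whose fit fails to converge or drifts toward separation are refit
    with a small ridge on the Hessian (logged once per call).
    """
    n, m = genotypes.shape
    g = genotypes.astype(float)
    a = np.full(m, np.log(y.mean() / (1 - y.mean())))
    b = np.zeros(m)
    ridge = np.zeros(m)
    for _ in range(max_iter):
        eta = a + b * g
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        grad_a = r.sum(axis=0) - ridge * 0.0
        grad_b = (r * g).sum(axis=0) - ridge * b
        h_aa = w.sum(axis=0)
        h_ab = (w * g).sum(axis=0)
        h_bb = (w * g * g).sum(axis=0) + ridge
        det = h_aa * h_bb - h_ab * h_ab
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        da = (h_bb * grad_a - h_ab * grad_b) / det
        db = (h_aa * grad_b - h_ab * grad_a) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        a += da
        b += db
        diverging = (np.abs(b) > 15) & (ridge == 0)
        if diverging.any():
            logger.warning("logistic separation in %d SNP(s); refitting with ridge",
                           int(diverging.sum()))
            ridge[diverging] = 1e-2
            a[diverging] = np.log(y.mean() / (1 - y.mean()))
            b[diverging] = 0.0
            continue
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < tol:
            break
    eta = a + b * g
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    h_aa = w.sum(axis=0)
    h_ab = (w * g).sum(axis=0)
    h_bb = (w * g * g).sum(axis=0) + ridge
    det = h_aa * h_bb - h_ab * h_ab
    se = np.sqrt(h_aa / det)
    z = b / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return b, se, p


def _sumstat_frame(meta: pd.DataFrame, beta, se, p, eaf, n) -> pd.DataFrame:
    """Assemble a canonical sumstats frame; the counted dosage allele is A."""
    return pd.DataFrame({
        "variant_id": meta["variant_id"].to_numpy(),
        "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(),
        "effect_allele": "A",
        "other_allele": "G",
        "beta": beta,
        "se": se,
        "pvalue": np.clip(p, np.nextafter(0, 1), 1.0),
        "eaf": eaf,
        "n": n,
        "info": np.nan,
    })


def simulate_trait_pair(genotypes: np.ndarray, causal: CausalConfig,
                        n_cases: int, n_controls: int, n_qtl: int, seed: int,
                        positions: pd.DataFrame | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary statistics for a case-control trait and a quantitative QTL trait.

    The genotype matrix is split into disjoint cohorts: the first
    ``n_cases + n_controls`` rows form the case-control cohort (disease via a
    logistic liability on the causal dosage, intercept set so the expected
    case fraction matches the design) and the next ``n_qtl`` rows the QTL
    cohort (linear model with N(0,1) noise).  Marginal per-SNP summary
    statistics are computed by logistic / linear regression respectively.
    """
    n_gwas = n_cases + n_controls
    if genotypes.shape[0] < n_gwas + n_qtl:
        raise ValueError(
            f"genotype pool has {genotypes.shape[0]} individuals; "
            f"{n_gwas + n_qtl} needed for disjoint cohorts")
    m = genotypes.shape[1]
    if max(causal.causal_index_trait, causal.causal_index_qtl) >= m:
        raise ValueError("causal index out of range")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = default_positions(m)

    g_cc = genotypes[:n_gwas].astype(float)
    g_qtl = genotypes[n_gwas:n_gwas + n_qtl].astype(float)

    bt = causal.beta_trait if causal.scenario in {"shared", "distinct", "gwas_only"} else 0.0
    bq = causal.beta_qtl if causal.scenario in {"shared", "distinct", "qtl_only"} else 0.0

    gc = g_cc[:, causal.causal_index_trait]
    alpha = np.log(n_cases / n_controls) - bt * gc.mean()
    pcase = 1.0 / (1.0 + np.exp(-(alpha + bt * gc)))
    y = (rng.random(n_gwas) < pcase).astype(float)
    if y.sum() in (0, n_gwas):  # degenerate draw at tiny n
        y[rng.integers(n_gwas)] = 1.0 - y[0]
    beta_g, se_g, p_g = marginal_logistic(g_cc, y)
    gwas = _sumstat_frame(positions, beta_g, se_g, p_g,
                          g_cc.mean(axis=0) / 2.0, n_gwas)

    expr = bq * g_qtl[:, causal.causal_index_qtl] + rng.standard_normal(n_qtl)
    beta_q, se_q, p_q = marginal_linear(g_qtl, expr)
    qtl = _sumstat_frame(positions, beta_q, se_q, p_q,
                         g_qtl.mean(axis=0) / 2.0, n_qtl)
    return gwas, qtl


#: Planted covariate coefficients on the logit (M-value) scale — all nonzero
#: so that covariate adjustment is testable downstream.
METHYLATION_COVARIATE_EFFECTS = {
    "age": 0.01, "sex": 0.3, "pc1": 0.2, "pc2": -0.2, "pmi": 0.02,
}
_BATCH_OFFSETS = {"b1": 0.0, "b2": 0.4, "b3": -0.3}


def simulate_methylation(genotypes: np.ndarray, snv_positions: pd.DataFrame,
                         planted: tuple[int, int, float], seed: int,
                         n_cpgs: int = 20, noise_sd: float = 0.5,
                         batch_genotype_confounding: float = 0.0
                         ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Methylation beta values around a target SNV plus a covariate table.

    ``planted = (snv_index, cpg_index, effect)`` plants ``effect`` (logit /
    M-value scale, per allele) of the indexed SNV on the indexed CpG; all
    other CpG-SNV effects are zero.  M-values include age, sex, two ancestry
    components, batch and post-mortem-interval terms with fixed nonzero
    coefficients, then are inverse-logit transformed, so every value lies
    strictly in (0, 1).  ``batch_genotype_confounding`` > 0 skews batch
    assignment by the planted SNV's genotype, creating a testable confounder.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.shape[0]
    snv_index, cpg_index, effect = planted
    center = int(snv_positions["pos"].iloc[snv_index])
    cpg_pos = np.sort(rng.integers(center - 400_000, center + 400_000, size=n_cpgs))
    cpg_ids = [f"cg{i:06d}" for i in range(n_cpgs)]

    g = genotypes[:, snv_index].astype(float)
    batch_p = np.clip(0.5 + batch_genotype_confounding * (g - g.mean()), 0.05, 0.95)
    batch = np.where(rng.random(n) < batch_p, "b2",
                     np.where(rng.random(n) < 0.5, "b1", "b3"))
    cov = pd.DataFrame({
        "age": rng.normal(75, 8, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "pc1": rng.standard_normal(n),
        "pc2": rng.standard_normal(n),
        "batch": batch,
        "pmi": rng.normal(12, 4, size=n),
    })
    cov_term = sum(coef * cov[name].to_numpy()
                   for name, coef in METHYLATION_COVARIATE_EFFECTS.items())
    cov_term = cov_term + np.vectorize(_BATCH_OFFSETS.get)(batch)

    intercepts = rng.normal(0.0, 1.0, size=n_cpgs)
    mvals = (intercepts[:, None] + cov_term[None, :]
             + noise_sd * rng.standard_normal((n_cpgs, n)))
    mvals[cpg_index] += effect * g
    beta_values = 1.0 / (1.0 + np.exp(-mvals))
    eps = np.finfo(float).tiny
    beta_values = np.clip(beta_values, eps, 1.0 - eps)
    beta_df = pd.DataFrame(beta_values, index=cpg_ids,
                           columns=[f"s{i:04d}" for i in range(n)])
    return beta_df, pd.Series(cpg_pos, index=cpg_ids, name="pos"), cov


def simulate_celltype_expression(n_genes: int, cell_types: list[str],
                                 markers_per_type: int, fold: float, seed: int,
                                 n_cells_per_type: int = 100,
                                 noise_sd: float = 0.25
                                 ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Expression matrix with planted cell-type markers.

    Each gene gets a baseline mean; marker genes are ``fold`` times higher in
    their own cell type.  Returns (genes x cells expression, per-cell type
    labels, marker truth table with columns gene_id / marker_type).
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    rng = np.random.default_rng(seed)
    n_types = len(cell_types)
    if markers_per_type * n_types > n_genes:
        raise ValueError("not enough genes for the requested markers")
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    base = rng.uniform(1.0, 5.0, size=n_genes)
    mean = np.tile(base[:, None], (1, n_types))
    truth = []
    k = 0
    for t, ct in enumerate(cell_types):
        for _ in range(markers_per_type):
            mean[k, t] *= fold
            truth.append({"gene_id": gene_ids[k], "marker_type": ct})
            k += 1
    labels = np.repeat(cell_types, n_cells_per_type)
    cols = np.repeat(np.arange(n_types), n_cells_per_type)
    expr = mean[:, cols] * np.exp(noise_sd * rng.standard_normal((n_genes, len(labels)))
                                  - 0.5 * noise_sd ** 2)
    cells = [f"cell_{i:05d}" for i in range(len(labels))]
    return (pd.DataFrame(expr, index=gene_ids, columns=cells),
            pd.Series(labels, index=cells, name="cell_type"),
            pd.DataFrame(truth))


def write_genotypes(genotypes: np.ndarray, variant_ids: list[str], path) -> None:
    """Write a dosage matrix as gzipped TSV (variants as columns)."""
    pd.DataFrame(genotypes, columns=variant_ids).to_csv(
        path, sep="\t", index=False, compression="gzip")


def read_genotypes(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", compression="gzip")
    return df.to_numpy(dtype=np.int8), list(df.columns)


def simulate_interactome(n_background: int, p_edge: float, seeds: list[str],
                         mendelian: list[str], n_bridges: int, pool_size: int,
                         seed: int) -> tuple[nx.Graph, list[str]]:
    """Scored PPI graph with planted seed-to-mendelian bridges and a null pool.

    The background is an Erdos-Renyi graph over background, pool and
    mendelian nodes (seed proteins receive only planted edges, mirroring a
    curated seed interactome).  Exactly ``n_bridges`` two-hop paths
    seed - internode - mendelian are planted to distinct mendelian proteins.
    Edge confidence scores are uniform on [0.5, 1].
    """
    seeds, mendelian = list(seeds), list(mendelian)
    pool = [f"pool_{i:04d}" for i in range(pool_size)]
    overlap = (set(seeds) & set(mendelian)) | (set(seeds) & set(pool)) \
        | (set(mendelian) & set(pool))
    if overlap:
        raise ValueError(f"seeds/mendelian/pool must be disjoint; shared: {sorted(overlap)}")
    if n_bridges > len(mendelian):
        raise ValueError("n_bridges cannot exceed the number of mendelian proteins")
    rng = np.random.default_rng(seed)
    background = [f"bg_{i:05d}" for i in range(n_background)]
    random_nodes = background + pool + mendelian

    G = nx.Graph()
    G.add_nodes_from(seeds + random_nodes)
    if p_edge > 0 and len(random_nodes) > 1:
        idx_i, idx_j = np.triu_indices(len(random_nodes), k=1)
        pick = rng.random(len(idx_i)) < p_edge
        scores = rng.uniform(0.5, 1.0, size=int(pick.sum()))
        for a, b, s in zip(idx_i[pick], idx_j[pick], scores):
            G.add_edge(random_nodes[a], random_nodes[b], score=float(s))
    for i in range(n_bridges):
        s = seeds[i % len(seeds)]
        inter = f"inter_{i:03d}"
        G.add_edge(s, inter, score=float(rng.uniform(0.5, 1.0)))
        G.add_edge(inter, mendelian[i], score=float(rng.uniform(0.5, 1.0)))
    return G, pool
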