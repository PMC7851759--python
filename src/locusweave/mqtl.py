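"""Cis methylation-QTL mapping: covariate-adjusted linear scans around target SNVs.

For each SNV, every CpG within a 500-kb window is tested with an ordinary
least-squares model of methylation beta values on genotype dosage plus
covariates (age at death, sex, population-stratification components, batch,
post-mortem interval).  BH-FDR is applied across all tests in the scan and,
per SNV, the strongest (minimum-p) pair is retained if it passes a 5% FDR.
CpGs map to genes when they lie within 10 kb of a gene's transcription start
or end position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import GeneAnnotation
from .twas import bh_fdr

logger = logging.getLogger(__name__)

MQTL_WINDOW_BP = 500_000
CPG_GENE_FLANK_BP = 10_000
MQTL_FDR_ALPHA = 0.05


@dataclass
class MqtlPair:
    """One tested SNV-CpG association."""

    snv_id: str
    cpg_id: str
    beta_hat: float
    se: float
    pvalue: float
    qvalue: float = np.nan

    @property
    def direction(self) -> int:
        return int(np.sign(self.beta_hat))


def _to_mvalues(beta_values: np.ndarray) -> np.ndarray:
    b = np.clip(beta_values, 1e-12, 1 - 1e-12)
    return np.log2(b / (1.0 - b))


def build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Covariate design matrix with intercept; categoricals dummy-encoded.

    Rows with any missing covariate are dropped (listwise deletion, logged).
    Returns (design, column names, boolean keep-mask over input rows).
    """
    keep = ~covariates.isna().any(axis=1)
    if (~keep).any():
        logger.info("listwise deletion removed %d sample(s) with missing covariates",
                    int((~keep).sum()))
    cov = covariates.loc[keep]
    parts = [pd.Series(1.0, index=cov.index, name="intercept")]
    for col in cov.columns:
        if pd.api.types.is_numeric_dtype(cov[col]):
            parts.append(cov[col].astype(float))
        else:
            dummies = pd.get_dummies(cov[col], prefix=col, drop_first=True)
            parts.extend(dummies[c].astype(float) for c in dummies)
    design = pd.concat(parts, axis=1)
    return design.to_numpy(), list(design.columns), keep.to_numpy()


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    bad = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if bad.any():
        offenders = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; offending column(s): {offenders}")


def fit_cis_mqtl(dosage: np.ndarray, cpg_values: np.ndarray,
                 covariates: pd.DataFrame, use_mvalues: bool = False
                 ) -> tuple[float, float, float]:
    """OLS of one CpG on one SNV's dosage with covariate adjustment.

    Returns (beta_hat, se, two-sided p) for the genotype coefficient, from a
    t-test with n - p degrees of freedom.  Association is on beta values
    directly by default; ``use_mvalues`` switches to logit-transformed
    M-values.
    """
    y = np.asarray(cpg_values, dtype=float)
    if use_mvalues:
        y = _to_mvalues(y)
    C, names, keep = build_design(covariates)
    g = np.asarray(dosage, dtype=float)[keep]
    y = y[keep]
    if np.var(y) == 0:
        raise ValueError("constant CpG vector: genotype standard error undefined")
    X = np.column_stack([C, g])
    names = names + ["genotype"]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"too few samples ({n}) for {p} parameters")
    _check_rank(X, names)
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    if se == 0:
        raise ValueError("zero residual variance: standard error undefined")
    beta_hat = float(coef[-1])
    pval = 2.0 * stats.t.sf(abs(beta_hat) / se, df=df)
    return beta_hat, se, float(pval)


def scan_windows(snv_meta: pd.DataFrame, snv_dosages: np.ndarray,
                 cpg_beta: pd.DataFrame, cpg_pos: pd.Series,
                 covariates: pd.DataFrame, window_bp: int = MQTL_WINDOW_BP,
                 fdr_alpha: float = MQTL_FDR_ALPHA, use_mvalues: bool = False,
                 cpg_chrom: pd.Series | None = None
                 ) -> pd.DataFrame:
    """Test all in-window SNV-CpG pairs; retain each SNV's strongest pair at FDR.

    ``snv_meta`` needs columns variant_id/chrom/pos with ``snv_dosages`` row-
    aligned (SNVs x samples); ``cpg_beta`` is CpGs x samples with ``cpg_pos``
    indexed by CpG id.  Tests use the Frisch-Waugh residualization of both
    genotype and methylation on the covariates, which is numerically
    identical to the full OLS fit.  BH-FDR is computed across all tests in
    the scan; the returned frame has one row per tested pair with a
    ``retained`` flag marking each SNV's minimum-p pair when its q is at or
    below ``fdr_alpha``.
    """
    Y = cpg_beta.to_numpy(dtype=float)
    if use_mvalues:
        Y = _to_mvalues(Y)
    C, names, keep = build_design(covariates)
    _check_rank(C, names)
    G = np.asarray(snv_dosages, dtype=float)[:, keep]
    Y = Y[:, keep]
    q_mat, _ = np.linalg.qr(C)
    Gr = G.T - q_mat @ (q_mat.T @ G.T)          # samples x snvs
    Yr = Y.T - q_mat @ (q_mat.T @ Y.T)          # samples x cpgs
    n = Gr.shape[0]
    df = n - C.shape[1] - 1

    cpg_ids = list(cpg_beta.index)
    pos = cpg_pos.reindex(cpg_ids).to_numpy()
    rows = []
    for i, snv in enumerate(snv_meta.itertuples()):
        in_win = np.abs(pos - snv.pos) <= window_bp
        if cpg_chrom is not None:
            in_win &= cpg_chrom.reindex(cpg_ids).to_numpy() == snv.chrom
        g = Gr[:, i]
        sgg = float(g @ g)
        if sgg <= 0:
            logger.warning("SNV %s has no residual genotype variance; skipped",
                           snv.variant_id)
            continue
        for j in np.flatnonzero(in_win):
            y = Yr[:, j]
            beta = float(g @ y) / sgg
            rss = float(y @ y) - beta * beta * sgg
            sigma2 = max(rss, 0.0) / df
            se = np.sqrt(sigma2 / sgg)
            if se == 0:
                continue
            p = 2.0 * stats.t.sf(abs(beta) / se, df=df)
            rows.append({"snv_id": snv.variant_id, "cpg_id": cpg_ids[j],
                         "beta": beta, "se": se,
                         "pvalue": max(float(p), np.nextafter(0, 1))})
    out = pd.DataFrame(rows, columns=["snv_id", "cpg_id", "beta", "se", "pvalue"])
    if len(out) == 0:
        out["qvalue"] = []
        out["retained"] = []
        return out
    q, _ = bh_fdr(out["pvalue"].to_numpy(), alpha=fdr_alpha)
    out["qvalue"] = q
    best = out.groupby("snv_id")["pvalue"].idxmin()
    out["retained"] = False
    out.loc[best, "retained"] = out.loc[best, "qvalue"] <= fdr_alpha
    out["direction"] = np.sign(out["beta"]).astype(int)
    return out


def map_cpg_to_gene(cpg_pos: int, cpg_chrom: str, genes: list[GeneAnnotation],
                    flank_bp: int = CPG_GENE_FLANK_BP) -> list[str]:
    """Genes whose transcription start or end lies within ``flank_bp`` of the CpG.

    Boundaries are inclusive; zero, one, or several genes may be returned.
    """
    hits = []
    for g in genes:
        if g.chrom != cpg_chrom:
            continue
        if min(abs(cpg_pos - g.start), abs(cpg_pos - g.end)) <= flank_bp:
            hits.append(g.gene_id)
    return hits
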