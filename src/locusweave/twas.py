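"""Weighted gene/CpG-level association from GWAS summary statistics (TWAS/MWAS).

Given per-SNP weights w predictive of a molecular feature and the GWAS
z-scores over the same SNPs, the feature-level association statistic is

    z_feature = w' z_gwas / sqrt(w' R w)

with R the SNP correlation (LD) matrix.  Genome-wide significance is judged
by Benjamini-Hochberg FDR at 0.05, separately per analysis type (expression,
splicing, methylation).  A greedy conditional pass distinguishes single from
joint signals when several features at one locus are significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FDR_ALPHA = 0.05
#: Ridge applied to estimated LD matrices at the pipeline level.
LD_RIDGE = 0.01


@dataclass
class WeightSet:
    """Per-SNP weights predicting one molecular feature."""

    feature_id: str
    snv_ids: list[str]
    w: np.ndarray
    training_scheme: str = "top1"

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if len(self.w) != len(self.snv_ids):
            raise ValueError("weight vector and SNV list lengths differ")
        if not np.any(self.w != 0):
            raise ValueError(f"{self.feature_id}: all weights are zero")


@dataclass
class LdMatrix:
    """SNP Pearson dosage-correlation matrix with its SNV labels."""

    snv_ids: list[str]
    R: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.snv_ids)
        if self.R.shape != (n, n):
            raise ValueError("R shape does not match snv_ids")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if np.linalg.eigvalsh(self.R).min() < -1e-8 - 1e-12:
            logger.warning("LD matrix has negative eigenvalues beyond tolerance")

    def subset(self, snv_ids: list[str]) -> "LdMatrix":
        idx = [self.snv_ids.index(s) for s in snv_ids]
        return LdMatrix(list(snv_ids), self.R[np.ix_(idx, idx)])


@dataclass
class TwasResult:
    feature_id: str
    z_twas: float
    pvalue: float
    qvalue: float = np.nan
    significant: bool = False
    conditional_z: float | None = None
    conditional_label: str = ""
    scheme: str = ""


def twas_zscore(weights: WeightSet, gwas_z: np.ndarray, ld: LdMatrix,
                ridge: float = 0.0) -> float:
    """Feature-level z statistic w'z / sqrt(w'Rw).

    ``ridge`` shrinks R toward the identity, R <- (1-ridge) R + ridge I,
    which stabilizes the denominator when R is estimated from a finite
    reference panel; at ridge=0 the statistic is exact for the given R.
    Invariant to positive rescaling of w.
    """
    w = weights.w
    z = np.asarray(gwas_z, dtype=float)
    if len(z) != len(w):
        raise ValueError("gwas_z length does not match weights")
    R = ld.R
    if ridge > 0:
        R = (1.0 - ridge) * R + ridge * np.eye(len(w))
    denom = float(w @ R @ w)
    if denom <= 0:
        raise ValueError(f"{weights.feature_id}: non-positive w'Rw ({denom:g})")
    return float(w @ z) / np.sqrt(denom)


def train_weights(qtl: pd.DataFrame, scheme: str = "top1",
                  feature_id: str = "") -> WeightSet:
    """Transparent weight schemes from marginal QTL summary statistics.

    ``top1``: weight 1 on the minimum-p SNV (ties broken by lowest genomic
    position), 0 elsewhere.  ``marginal``: w_i = z_i = beta_i / se_i for all
    SNVs.  These are deliberately simple, labeled stand-ins for externally
    trained predictive models; results carry the scheme annotation.
    """
    if len(qtl) == 0:
        raise ValueError("empty QTL frame")
    snv_ids = list(qtl["variant_id"])
    if scheme == "top1":
        order = np.lexsort((qtl["pos"].to_numpy(), qtl["pvalue"].to_numpy()))
        w = np.zeros(len(qtl))
        w[order[0]] = 1.0
    elif scheme == "marginal":
        w = (qtl["beta"] / qtl["se"]).to_numpy()
        if not np.any(w != 0):
            w = np.zeros(len(qtl))
            w[0] = 1.0
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return WeightSet(feature_id=feature_id, snv_ids=snv_ids, w=w,
                     training_scheme=scheme)


def bh_fdr(pvalues, alpha: float = FDR_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (qvalues, significance flags at ``alpha``).

    q-values are BH-adjusted p-values with the cumulative-minimum
    monotonicity enforcement; a feature is significant iff q <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def run_twas(weight_sets: list[WeightSet], gwas_z_by_snv: dict[str, float],
             ld: LdMatrix, alpha: float = FDR_ALPHA,
             ridge: float = LD_RIDGE) -> list[TwasResult]:
    """TWAS/MWAS over many features with genome-wide BH-FDR."""
    results = []
    for ws in weight_sets:
        z_vec = np.array([gwas_z_by_snv[s] for s in ws.snv_ids])
        sub = ld.subset(ws.snv_ids) if ws.snv_ids != ld.snv_ids else ld
        z = twas_zscore(ws, z_vec, sub, ridge=ridge)
        p = 2.0 * stats.norm.sf(abs(z))
        results.append(TwasResult(feature_id=ws.feature_id, z_twas=z,
                                  pvalue=max(p, np.nextafter(0, 1)),
                                  scheme=ws.training_scheme))
    q, sig = bh_fdr([r.pvalue for r in results], alpha=alpha)
    for r, qi, si in zip(results, q, sig):
        r.qvalue = float(qi)
        r.significant = bool(si)
    return results


def conditional_analysis(results: list[TwasResult], weights: dict[str, WeightSet],
                         gwas_z: np.ndarray, ld: LdMatrix,
                         alpha: float = 0.05, ridge: float = 0.0
                         ) -> dict[str, tuple[float, str]]:
    """Greedy conditional pass over one locus's significant features.

    The feature with the largest |z| is selected; every other feature's GWAS
    z-vector is residualized on the selected feature's normalized predicted-
    expression direction,

        z' = z - R w~ (w~' z) / (w~' R w~),   w~ = w / sqrt(w' R w),

    and its statistic recomputed.  Features whose conditional p >= ``alpha``
    are labeled "joint" (their signal is explained by the selected feature);
    the rest are "independent".  Returns feature_id -> (conditional z, label).
    """
    sig = [r for r in results if r.significant]
    if len(sig) < 2:
        return {r.feature_id: (r.z_twas, "selected") for r in sig}
    sig = sorted(sig, key=lambda r: -abs(r.z_twas))
    top = sig[0]
    R = ld.R
    if ridge > 0:
        R = (1.0 - ridge) * R + ridge * np.eye(len(ld.snv_ids))
    idx = {s: i for i, s in enumerate(ld.snv_ids)}

    def embed(ws: WeightSet) -> np.ndarray:
        full = np.zeros(len(ld.snv_ids))
        for s, wi in zip(ws.snv_ids, ws.w):
            full[idx[s]] += wi
        return full

    w_top = embed(weights[top.feature_id])
    denom = float(w_top @ R @ w_top)
    w_tilde = w_top / np.sqrt(denom)
    z = np.asarray(gwas_z, dtype=float)
    z_resid = z - R @ w_tilde * float(w_tilde @ z) / float(w_tilde @ R @ w_tilde)

    out = {top.feature_id: (top.z_twas, "selected")}
    for r in sig[1:]:
        w = embed(weights[r.feature_id])
        d = float(w @ R @ w)
        if d <= 0:
            logger.warning("%s: singular denominator in conditional pass; skipped",
                           r.feature_id)
            continue
        cz = float(w @ z_resid) / np.sqrt(d)
        p = 2.0 * stats.norm.sf(abs(cz))
        label = "joint" if p >= alpha else "independent"
        out[r.feature_id] = (cz, label)
        r.conditional_z = cz
        r.conditional_label = label
    return out


def results_to_frame(results: list[TwasResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": r.feature_id, "scheme": r.scheme, "z": r.z_twas,
        "p": r.pvalue, "q": r.qvalue, "significant": r.significant,
        "conditional_z": r.conditional_z, "conditional_label": r.conditional_label,
    } for r in results])


def write_weights(weight_sets: list[WeightSet], path) -> None:
    rows = [{"feature_id": ws.feature_id, "snv_id": s, "weight": wi,
             "scheme": ws.training_scheme}
            for ws in weight_sets for s, wi in zip(ws.snv_ids, ws.w)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
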