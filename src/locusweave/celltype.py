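"""Cell-type specificity and coexpression-module annotation of candidate genes.

Expression prevalence of a gene in a cell type is its mean expression in
that type divided by the mean expression across all other types (here the
unweighted mean of the other per-type means, so type sizes do not bias the
ratio); the primary cell type is the one with the highest enrichment.
Coexpression modules are summarized by their eigengene (first principal
component of the standardized member-gene expression), a gene's module
membership kME is its absolute Pearson correlation with that eigengene, and
module-to-cell-type assignment uses a one-sided Fisher exact test of marker
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: kME above this value marks a gene as among a module's most relevant genes.
KME_RELEVANT = 0.76


@dataclass
class PrevalenceProfile:
    gene_id: str
    enrichment: dict[str, float]
    primary_type: str
    ambiguous: bool = False


@dataclass
class ModuleMembership:
    gene_id: str
    module_id: str
    kme: float
    relevant: bool = False


def prevalence_enrichment(expr: pd.DataFrame, cell_labels: pd.Series,
                          gene_id: str) -> PrevalenceProfile:
    """Per-cell-type expression-prevalence enrichment of one gene.

    ``expr`` is genes x cells; ``cell_labels`` maps cell -> type.  A zero
    denominator (gene silent outside the type) gives +inf with a warning;
    ties at the maximum are broken by lexicographic type order and flagged.
    """
    labels = cell_labels.reindex(expr.columns)
    types = sorted(labels.dropna().unique())
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    if gene_id not in expr.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    x = expr.loc[gene_id]
    type_means = {t: float(x[labels == t].mean()) for t in types}
    enrichment = {}
    for t in types:
        others = [type_means[u] for u in types if u != t]
        denom = float(np.mean(others))
        if denom == 0:
            logger.warning("%s: zero mean expression outside %s; enrichment set to inf",
                           gene_id, t)
            enrichment[t] = np.inf if type_means[t] > 0 else 1.0
        else:
            enrichment[t] = type_means[t] / denom
    best = max(enrichment.values())
    winners = [t for t in types if enrichment[t] == best]
    return PrevalenceProfile(gene_id=gene_id, enrichment=enrichment,
                             primary_type=winners[0], ambiguous=len(winners) > 1)


def module_eigengene(expr: pd.DataFrame) -> np.ndarray:
    """First principal component of a module's standardized expression.

    Rows (genes) are standardized to mean 0, SD 1 (zero-variance rows are
    dropped with a warning); the first right singular vector is returned with
    its sign fixed so the mean correlation with member genes is non-negative.
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 samples")
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance gene row(s)", int((sd == 0).sum()))
        X = X[sd > 0]
        sd = sd[sd > 0]
        if X.shape[0] < 2:
            raise ValueError("fewer than 2 informative genes after dropping")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    corr = Z @ eig  # proportional to per-gene correlation with the eigengene
    if corr.mean() < 0:
        eig = -eig
    return eig


def module_membership(gene_expr: np.ndarray, eigengene: np.ndarray,
                      squared: bool = False) -> float:
    """kME: the gene's absolute (or squared) Pearson correlation with the eigengene."""
    x = np.asarray(gene_expr, dtype=float)
    e = np.asarray(eigengene, dtype=float)
    if len(x) != len(e) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(e) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(np.corrcoef(x, e)[0, 1])
    return r * r if squared else abs(r)


def assign_gene_to_module(gene_expr: np.ndarray,
                          eigengenes: dict[str, np.ndarray],
                          gene_id: str = "",
                          kme_thresh: float = KME_RELEVANT) -> ModuleMembership:
    """Assign a gene to the module maximizing kME; relevant iff kME > threshold
    (strict).  Ties broken by lexicographic module id."""
    kmes = {m: module_membership(gene_expr, e) for m, e in eigengenes.items()}
    best = max(kmes.values())
    module = sorted(m for m, v in kmes.items() if v == best)[0]
    return ModuleMembership(gene_id=gene_id, module_id=module, kme=best,
                            relevant=best > kme_thresh)


def fisher_marker_enrichment(module_genes: set, markers: set,
                             universe: set) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of module-marker overlap.

    Returns (sample odds ratio, hypergeometric upper-tail p of observing at
    least the seen overlap).  Empty module or marker set gives p = 1 with a
    warning.
    """
    if not module_genes <= universe or not markers <= universe:
        raise ValueError("module genes and markers must be subsets of the universe")
    if not module_genes or not markers:
        logger.warning("empty module or marker set; p = 1")
        return np.nan, 1.0
    a = len(module_genes & markers)
    b = len(module_genes - markers)
    c = len(markers - module_genes)
    d = len(universe - module_genes - markers)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def assign_module_cell_type(module_genes: set, marker_sets: dict[str, set],
                            universe: set) -> tuple[str, pd.DataFrame]:
    """Module's cell type = marker set with minimum enrichment p."""
    rows = []
    for ct, markers in sorted(marker_sets.items()):
        odds, p = fisher_marker_enrichment(module_genes, markers & universe, universe)
        rows.append({"cell_type": ct, "odds_ratio": odds, "pvalue": p})
    table = pd.DataFrame(rows)
    return table.loc[table["pvalue"].idxmin(), "cell_type"], table
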