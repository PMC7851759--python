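"""Evidence intersection across colocalization, TWAS/MWAS and methylation,
plus the end-to-end synthetic pipeline driver.

A gene becomes an expression candidate when it shows strong colocalization
(PPH4 at or above the gate) in at least one tissue of at least one dataset
AND is TWAS-significant at the FDR gate; a splicing candidate when the
exon-vs-gene splicing classification fires AND at least one isoform is
significant in the splicing TWAS.  Methylation results only annotate
existing candidates; they never add new ones.  A gene qualifying as both is
reported once under expression with a splicing flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _st

from . import __version__
from . import coloc as _coloc
from . import mqtl as _mqtl
from . import netperm as _netperm
from . import simulate as _sim
from . import sumstats as _ss
from . import twas as _twas

logger = logging.getLogger(__name__)


@dataclass
class CandidateEvidence:
    """Integrated per-gene evidence row (Tables 1-3 layout)."""

    gene_id: str
    mechanism: str  # expression or splicing
    coloc_support: list = field(default_factory=list)  # (dataset, tissue, pph4)
    twas_z: float = np.nan
    twas_q: float = np.nan
    direction: str = ""  # positive / negative, from the TWAS z sign
    methylation_overlap: list = field(default_factory=list)  # (cpg_id, direction)
    locus: str = ""
    also_splicing: bool = False
    exon_vs_gene_note: str = ""


def _direction(z: float) -> str:
    return "positive" if z > 0 else "negative"


def intersect_expression(coloc_results: list[_coloc.FeatureColocResult],
                         twas_results: list[_twas.TwasResult],
                         pph4_thresh: float = _coloc.STRONG_COLOC_PPH4,
                         fdr_alpha: float = _twas.FDR_ALPHA
                         ) -> list[CandidateEvidence]:
    """Genes with strong gene-level colocalization anywhere AND TWAS q <= alpha."""
    twas_by_gene = {r.feature_id: r for r in twas_results}
    support: dict[str, list] = {}
    for r in coloc_results:
        if r.feature_level == "gene" and r.posterior.pph4 >= pph4_thresh:
            support.setdefault(r.feature_id, []).append(
                (r.dataset, r.tissue, r.posterior.pph4))
    out = []
    for gene in sorted(support):
        t = twas_by_gene.get(gene)
        if t is None or t.qvalue > fdr_alpha:
            continue
        out.append(CandidateEvidence(
            gene_id=gene, mechanism="expression", coloc_support=support[gene],
            twas_z=t.z_twas, twas_q=t.qvalue, direction=_direction(t.z_twas)))
    return out


def intersect_splicing(exon_results: list[_coloc.FeatureColocResult],
                       gene_results: list[_coloc.FeatureColocResult],
                       splicing_twas: list[_twas.TwasResult],
                       exon_to_gene: dict[str, str],
                       isoform_to_gene: dict[str, str] | None = None,
                       pph4_thresh: float = _coloc.STRONG_COLOC_PPH4,
                       fdr_alpha: float = _twas.FDR_ALPHA
                       ) -> list[CandidateEvidence]:
    """Genes whose coloc pattern is splicing-like AND with a significant isoform.

    The splicing classification (best exon PPH4 at/above the gate while the
    gene-level evidence favours distinct variants) is evaluated per gene and
    tissue/dataset; genes classified as expression anywhere are never
    emitted here (precedence).  ``isoform_to_gene`` maps splicing-TWAS
    feature ids to genes (identity if omitted).
    """
    iso_map = isoform_to_gene or {r.feature_id: r.feature_id for r in splicing_twas}
    sig_iso: dict[str, list[_twas.TwasResult]] = {}
    for r in splicing_twas:
        if r.qvalue <= fdr_alpha:
            sig_iso.setdefault(iso_map.get(r.feature_id, r.feature_id), []).append(r)

    genes = sorted({exon_to_gene[r.feature_id] for r in exon_results
                    if r.feature_id in exon_to_gene})
    out = []
    for gene in genes:
        g_res = [r for r in gene_results if r.feature_id == gene]
        classes = set()
        splice_support = []
        note = ""
        for gr in g_res:
            exons = [r for r in exon_results
                     if exon_to_gene.get(r.feature_id) == gene
                     and (r.dataset, r.tissue) == (gr.dataset, gr.tissue)]
            cls = _coloc.classify_splicing(gr, exons, pph4_thresh=pph4_thresh)
            classes.add(cls)
            if cls == "splicing" and exons:
                best = max(exons, key=lambda r: r.posterior.pph4)
                splice_support.append((gr.dataset, gr.tissue, best.posterior.pph4))
                note = (f"exon {best.feature_id} PPH4={best.posterior.pph4:.2f} vs "
                        f"gene PPH3={gr.posterior.pph3:.2f}>PPH4={gr.posterior.pph4:.2f}")
        if "expression" in classes or "splicing" not in classes:
            continue
        if gene not in sig_iso:
            continue
        t = max(sig_iso[gene], key=lambda r: abs(r.z_twas))
        out.append(CandidateEvidence(
            gene_id=gene, mechanism="splicing", coloc_support=splice_support,
            twas_z=t.z_twas, twas_q=t.qvalue, direction=_direction(t.z_twas),
            exon_vs_gene_note=note))
    return out


def overlay_methylation(candidates: list[CandidateEvidence],
                        mwas_genes: list[tuple[str, str, str]]
                        ) -> list[CandidateEvidence]:
    """Annotate candidates with overlapping methylation hits (set intersection).

    ``mwas_genes`` rows are (gene_id, cpg_id, direction).  Candidate
    membership is unchanged: an MWAS gene absent from the candidates adds
    nothing.
    """
    by_gene: dict[str, list] = {}
    for gene, cpg, direction in mwas_genes:
        by_gene.setdefault(gene, []).append((cpg, direction))
    for c in candidates:
        c.methylation_overlap = list(by_gene.get(c.gene_id, []))
    return candidates


def candidates_to_frame(candidates: list[CandidateEvidence]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": c.gene_id, "mechanism": c.mechanism,
        "locus": c.locus, "direction": c.direction,
        "twas_z": c.twas_z, "twas_q": c.twas_q,
        "coloc_support": ";".join(f"{d}:{t}:{p:.3f}" for d, t, p in c.coloc_support),
        "methylation_overlap": ";".join(f"{cpg}:{d}" for cpg, d in c.methylation_overlap),
        "also_splicing": c.also_splicing,
        "exon_vs_gene": c.exon_vs_gene_note,
    } for c in candidates])


# ---------------------------------------------------------------------------
# pipeline driver

_REQUIRED_SECTIONS = ["seed", "out_dir", "simulate"]

DEFAULT_THRESHOLDS = {
    "gwas_p": 5e-8, "locus_window_bp": 1_000_000, "cis_window_bp": 1_000_000,
    "pph4": 0.75, "fdr": 0.05, "mqtl_window_bp": 500_000,
    "cpg_gene_flank_bp": 10_000, "maf_min": 0.05, "info_min": 0.5,
}


def load_config(path) -> dict:
    """Load and schema-check a pipeline YAML config (fatal before any work)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    for key in _REQUIRED_SECTIONS:
        if key not in cfg:
            raise ValueError(f"config missing required field: {key}")
    sim = cfg["simulate"]
    for key in ("n_snps", "n_cases", "n_controls", "n_qtl", "genes"):
        if key not in sim:
            raise ValueError(f"config missing required field: simulate.{key}")
    for i, g in enumerate(sim["genes"]):
        if "gene_id" not in g:
            raise ValueError(f"config missing required field: simulate.genes[{i}].gene_id")
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(cfg.get("thresholds", {}))
    cfg["thresholds"] = thr
    return cfg


def _simulate_gene_region(gcfg: dict, sim: dict, chrom: str, seed: int):
    """One gene's region: genotypes, GWAS/QTL sumstats, optional exon traits."""
    m = sim["n_snps"]
    region = _sim.SimRegionConfig(n_snps=m, rho=sim.get("rho", 0.9), seed=seed)
    n_pool = sim["n_cases"] + sim["n_controls"] + sim["n_qtl"]
    geno, ld, _ = _sim.simulate_ld_genotypes(region, n_pool)
    positions = _sim.default_positions(m, chrom=chrom)

    mech = gcfg.get("mechanism", "expression")
    ci = gcfg.get("causal_index", m // 2)
    if mech == "expression":
        causal = _sim.CausalConfig("shared", ci, ci,
                                   gcfg.get("beta_trait", 0.3), gcfg.get("beta_qtl", 1.0))
    elif mech == "splicing":
        cj = (ci + max(3, m // 3)) % m
        causal = _sim.CausalConfig("distinct", ci, cj,
                                   gcfg.get("beta_trait", 0.3), gcfg.get("beta_qtl", 1.0))
    elif mech == "none":
        causal = _sim.CausalConfig("gwas_only", ci, ci, gcfg.get("beta_trait", 0.3), 0.0)
    else:
        raise ValueError(f"unknown mechanism {mech!r} for {gcfg['gene_id']}")
    gwas, qtl = _sim.simulate_trait_pair(
        geno, causal, sim["n_cases"], sim["n_controls"], sim["n_qtl"],
        seed=seed + 1, positions=positions)

    exon_qtl = None
    if mech == "splicing":
        exon_causal = _sim.CausalConfig("shared", ci, ci,
                                        gcfg.get("beta_trait", 0.3),
                                        gcfg.get("beta_qtl", 1.0))
        _, exon_qtl = _sim.simulate_trait_pair(
            geno, exon_causal, sim["n_cases"], sim["n_controls"], sim["n_qtl"],
            seed=seed + 2, positions=positions)
    return geno, positions, gwas, qtl, exon_qtl


def run_pipeline(config_path) -> dict:
    """Execute the synthetic end-to-end pipeline from a YAML config.

    Stages: simulate regions per configured gene -> harmonize + QC -> risk
    locus selection -> gene/exon colocalization -> TWAS (expression and
    splicing, separate BH-FDR) -> cis-mQTL scan -> evidence intersection ->
    interactome permutation test.  All stage tables are written under
    ``out_dir`` along with a run manifest; re-running with the same config
    and seed reproduces the outputs.
    """
    cfg = load_config(config_path)
    seed = int(cfg["seed"])
    thr = cfg["thresholds"]
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = cfg["simulate"]
    n_gwas = sim["n_cases"] + sim["n_controls"]

    genes_ann: list[_ss.GeneAnnotation] = []
    gene_coloc: list[_coloc.FeatureColocResult] = []
    exon_coloc: list[_coloc.FeatureColocResult] = []
    exon_to_gene: dict[str, str] = {}
    expr_twas_inputs = []
    splice_twas_inputs = []
    all_gwas = []
    region_store = {}

    for i, gcfg in enumerate(sim["genes"]):
        gene_id = gcfg["gene_id"]
        chrom = str(i + 1)
        geno, positions, gwas, qtl, exon_qtl = _simulate_gene_region(
            gcfg, sim, chrom, seed + 1000 * i)
        gwas_h, qtl_h = _ss.harmonize_pair(gwas, qtl)
        gwas_h = _ss.filter_qc(gwas_h, thr["maf_min"], thr["info_min"])
        qtl_h = qtl_h[qtl_h["variant_id"].isin(gwas_h["variant_id"])].reset_index(drop=True)
        genes_ann.append(_ss.GeneAnnotation(
            gene_id, chrom, int(positions["pos"].min()), int(positions["pos"].max())))
        all_gwas.append(gwas_h)
        region_store[gene_id] = (geno, gwas_h, qtl_h)

        res = _coloc.colocalize_feature(
            gwas_h, qtl_h, feature_id=gene_id, tissue="sim_tissue",
            dataset="sim", feature_level="gene")
        gene_coloc.append(res)
        expr_twas_inputs.append((gene_id, gwas_h, qtl_h, geno))

        if exon_qtl is not None:
            exon_qtl = exon_qtl[exon_qtl["variant_id"].isin(gwas_h["variant_id"])
                                ].reset_index(drop=True)
            exon_id = f"{gene_id}_exon1"
            exon_to_gene[exon_id] = gene_id
            exon_coloc.append(_coloc.colocalize_feature(
                gwas_h, exon_qtl, feature_id=exon_id, tissue="sim_tissue",
                dataset="sim", feature_level="exon"))
            splice_twas_inputs.append((exon_id, gwas_h, exon_qtl, geno))

    gwas_all = pd.concat(all_gwas, ignore_index=True)
    loci = _ss.select_risk_loci(gwas_all, genes_ann, thr["gwas_p"],
                                thr["locus_window_bp"])
    locus_of = {g: loc.lead_snv + "@" + loc.chrom
                for loc in loci for g in loc.genes}

    scheme = cfg.get("twas", {}).get("scheme", "marginal")

    def _twas_block(inputs):
        results = []
        for fid, gwas_h, qtl_h, geno in inputs:
            ws = _twas.train_weights(qtl_h, scheme=scheme, feature_id=fid)
            keep = gwas_h["variant_id"].isin(ws.snv_ids)
            z = (gwas_h.loc[keep, "beta"] / gwas_h.loc[keep, "se"]).to_numpy()
            ld_est = np.corrcoef(geno[n_gwas:].astype(float), rowvar=False)
            ld_est = np.atleast_2d(np.nan_to_num(ld_est))
            np.fill_diagonal(ld_est, 1.0)
            idx = [list(qtl_h["variant_id"]).index(s) for s in ws.snv_ids]
            ld = _twas.LdMatrix(ws.snv_ids, ld_est[np.ix_(idx, idx)])
            zstat = _twas.twas_zscore(ws, z, ld, ridge=_twas.LD_RIDGE)
            results.append(_twas.TwasResult(
                feature_id=fid, z_twas=zstat,
                pvalue=max(2 * _st.norm.sf(abs(zstat)), np.nextafter(0, 1)),
                scheme=scheme))
        if results:
            q, s = _twas.bh_fdr([r.pvalue for r in results], alpha=thr["fdr"])
            for r, qi, si in zip(results, q, s):
                r.qvalue, r.significant = float(qi), bool(si)
        return results

    expr_twas = _twas_block(expr_twas_inputs)
    splice_twas = _twas_block(splice_twas_inputs)

    # cis-mQTL stage on the first configured gene's region
    mq = cfg.get("mqtl", {})
    mqtl_table = pd.DataFrame()
    mwas_genes: list[tuple[str, str, str]] = []
    if mq:
        region = _sim.SimRegionConfig(n_snps=sim["n_snps"], rho=sim.get("rho", 0.9),
                                      seed=seed + 77)
        geno_m, _, _ = _sim.simulate_ld_genotypes(region, mq.get("n_samples", 150))
        positions = _sim.default_positions(sim["n_snps"], chrom="1")
        ci = sim["genes"][0].get("causal_index", sim["n_snps"] // 2)
        beta_df, cpg_pos, cov = _sim.simulate_methylation(
            geno_m, positions, planted=(ci, mq.get("planted_cpg", 0),
                                        mq.get("planted_effect", 0.5)),
            seed=seed + 78, n_cpgs=mq.get("n_cpgs", 20))
        snv_meta = positions.iloc[[ci]].reset_index(drop=True)
        mqtl_table = _mqtl.scan_windows(
            snv_meta, geno_m.T[[ci]], beta_df, cpg_pos, cov,
            window_bp=thr["mqtl_window_bp"], fdr_alpha=thr["fdr"])
        for r in mqtl_table[mqtl_table["retained"]].itertuples():
            pos = int(cpg_pos[r.cpg_id])
            for gid in _mqtl.map_cpg_to_gene(pos, "1", genes_ann,
                                             thr["cpg_gene_flank_bp"]):
                mwas_genes.append((gid, r.cpg_id,
                                   "positive" if r.beta > 0 else "negative"))

    candidates = intersect_expression(gene_coloc, expr_twas,
                                      pph4_thresh=thr["pph4"], fdr_alpha=thr["fdr"])
    splicing_candidates = intersect_splicing(
        exon_coloc, gene_coloc, splice_twas, exon_to_gene,
        isoform_to_gene=exon_to_gene,
        pph4_thresh=thr["pph4"], fdr_alpha=thr["fdr"])
    expr_ids = {c.gene_id for c in candidates}
    for c in candidates:
        if any(s.gene_id == c.gene_id for s in splicing_candidates):
            c.also_splicing = True
    candidates += [s for s in splicing_candidates if s.gene_id not in expr_ids]
    for c in candidates:
        c.locus = locus_of.get(c.gene_id, "")
    overlay_methylation(candidates, mwas_genes)

    # interactome permutation stage
    np_cfg = cfg.get("netperm", {})
    perm = None
    if np_cfg:
        seeds_list = [c.gene_id for c in candidates] or ["seed_0"]
        mendelian = [f"mend_{i:02d}" for i in range(np_cfg.get("n_mendelian", 20))]
        G, pool = _sim.simulate_interactome(
            n_background=np_cfg.get("n_background", 300),
            p_edge=np_cfg.get("p_edge", 0.005),
            seeds=seeds_list, mendelian=mendelian,
            n_bridges=min(np_cfg.get("n_bridges", 9), len(mendelian)),
            pool_size=np_cfg.get("pool_size", _netperm.NULL_POOL_SIZE),
            seed=seed + 99)
        perm = _netperm.permutation_test(
            G, set(seeds_list), set(mendelian), pool,
            B=np_cfg.get("B", 1000), rng_seed=seed + 100)

    # write stage outputs
    coloc_tbl = _coloc.results_to_frame(gene_coloc + exon_coloc)
    coloc_tbl.to_csv(out_dir / "coloc.tsv", sep="\t", index=False)
    _twas.results_to_frame(expr_twas).to_csv(out_dir / "twas_expression.tsv",
                                             sep="\t", index=False)
    _twas.results_to_frame(splice_twas).to_csv(out_dir / "twas_splicing.tsv",
                                               sep="\t", index=False)
    if len(mqtl_table):
        mqtl_table.to_csv(out_dir / "mqtl.tsv", sep="\t", index=False)
    cand_tbl = candidates_to_frame(candidates)
    cand_tbl.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame([{"lead_snv": l.lead_snv, "chrom": l.chrom, "lead_pos": l.lead_pos,
                   "window_start": l.window[0], "window_end": l.window[1],
                   "genes": ";".join(l.genes)} for l in loci]
                 ).to_csv(out_dir / "loci.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__, "seed": seed, "thresholds": thr,
        "n_loci": len(loci), "n_candidates": len(candidates),
        "candidates": [c.gene_id for c in candidates],
    }
    if perm is not None:
        manifest["netperm"] = _netperm.result_to_json_dict(perm)
        with open(out_dir / "netperm.json", "w") as fh:
            json.dump(manifest["netperm"], fh, indent=2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %d loci, %d candidates", len(loci), len(candidates))
    return {"loci": loci, "coloc": gene_coloc + exon_coloc,
            "twas_expression": expr_twas, "twas_splicing": splice_twas,
            "mqtl": mqtl_table, "candidates": candidates, "netperm": perm,
            "manifest": manifest}
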