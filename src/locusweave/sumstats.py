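"""Reading, validation, harmonization and windowing of GWAS/QTL summary statistics.

Summary statistics are carried as pandas DataFrames with the canonical columns
listed in :data:`SUMSTAT_COLUMNS` (one row per variant association).  All
genomic coordinates are 1-based inclusive (GRCh37 convention); BED output is
converted to 0-based half-open at the writer only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for a summary-statistics frame.
SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue", "eaf", "n", "info",
]

#: Default aliases accepted for each canonical column (lower-cased match).
DEFAULT_DIALECT = {
    "variant_id": ["variant_id", "snp", "rsid", "markername", "id"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "effect_allele": ["effect_allele", "a1", "allele1", "ea"],
    "other_allele": ["other_allele", "a2", "allele2", "oa", "nea"],
    "beta": ["beta", "b", "effect", "log_odds"],
    "se": ["se", "standard_error", "stderr"],
    "pvalue": ["pvalue", "p", "pval", "p_value"],
    "eaf": ["eaf", "freq", "af", "effect_allele_frequency", "maf"],
    "n": ["n", "n_total", "samplesize", "sample_size"],
    "info": ["info", "imputation_quality", "r2", "info_score"],
}

VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's marginal association with a trait or molecular feature.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for
    case-control traits); ``eaf`` its frequency; ``info`` the imputation
    quality (NaN when genotyped / unknown).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float
    n: int
    info: float = float("nan")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene interval, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class RiskLocus:
    """A genome-wide-significant lead SNV and the genes within its window."""

    lead_snv: str
    chrom: str
    lead_pos: int
    window: tuple[int, int]
    genes: list[str] = field(default_factory=list)


def frame_to_records(df: pd.DataFrame) -> list[VariantAssoc]:
    """Convert a canonical sumstats frame to VariantAssoc records."""
    return [VariantAssoc(**{k: row[k] for k in SUMSTAT_COLUMNS}) for _, row in df.iterrows()]


def records_to_frame(records: list[VariantAssoc]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=SUMSTAT_COLUMNS)


def _resolve_columns(header: list[str], dialect: dict | None) -> dict[str, str]:
    """Map canonical names to file column names; fatal if a required one is absent."""
    aliases = {k: list(v) for k, v in DEFAULT_DIALECT.items()}
    if dialect:
        for canon, name in dialect.items():
            aliases.setdefault(canon, []).insert(0, name.lower())
    lower = {h.lower(): h for h in header}
    mapping = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lower:
                mapping[canon] = lower[name]
                break
    required = [c for c in SUMSTAT_COLUMNS if c != "info"]
    missing = [c for c in required if c not in mapping]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return mapping


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw sumstats frame into (valid, rejected-with-reason).

    Invariants enforced: se > 0, 0 <= eaf <= 1, 0 < pvalue <= 1, both alleles
    single A/C/G/T bases, effect allele != other allele.
    """
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        nonlocal reasons
        mask = mask.fillna(True) if mask.dtype == object else mask
        reasons = reasons.mask((reasons == "") & mask, reason)

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    flag(~(ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES)), "non-SNV alleles")
    flag(ea == oa, "identical alleles")
    flag(~(pd.to_numeric(df["se"], errors="coerce") > 0), "se not positive")
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    flag(~((eaf >= 0) & (eaf <= 1)), "eaf outside [0, 1]")
    p = pd.to_numeric(df["pvalue"], errors="coerce")
    flag(~((p > 0) & (p <= 1)), "pvalue outside (0, 1]")
    flag(pd.to_numeric(df["pos"], errors="coerce").isna(), "unparsable position")

    bad = reasons != ""
    rejected = df.loc[bad].assign(reason=reasons[bad])
    valid = df.loc[~bad].copy()
    valid["effect_allele"] = ea[~bad]
    valid["other_allele"] = oa[~bad]
    for col in ("beta", "se", "pvalue", "eaf", "info"):
        valid[col] = pd.to_numeric(valid[col], errors="coerce")
    valid["pos"] = valid["pos"].astype(np.int64)
    valid["n"] = pd.to_numeric(valid["n"], errors="coerce").astype(np.int64)
    valid["chrom"] = valid["chrom"].astype(str)
    if len(rejected):
        logger.warning("rejected %d/%d rows: %s", len(rejected), len(df),
                       rejected["reason"].value_counts().to_dict())
    return valid.reset_index(drop=True), rejected


def read_sumstats(path, dialect: dict | None = None,
                  return_rejects: bool = False):
    """Read a tab-delimited summary-statistics file into a validated frame.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file with a header line.  Lines starting with ``#`` are
        treated as provenance comments and skipped.
    dialect : dict, optional
        Overrides mapping canonical column name -> file column name, merged
        over :data:`DEFAULT_DIALECT`.
    return_rejects : bool
        Also return the frame of rejected rows with their reasons.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    mapping = _resolve_columns(list(raw.columns), dialect)
    out = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    if "info" not in out:
        out["info"] = np.nan
    out = out[SUMSTAT_COLUMNS]
    valid, rejected = validate_sumstats(out)
    if return_rejects:
        return valid, rejected
    return valid


def write_sumstats(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a canonical sumstats frame with a provenance header line."""
    from . import __version__
    with open(path, "w") as fh:
        extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in params.items())
        fh.write(f"# locusweave {__version__}{extra}\n")
        df.to_csv(fh, sep="\t", index=False)


def _dedupe_positions(df: pd.DataFrame, partner: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicated (chrom, pos): keep the row whose alleles match the
    partner file; among several matches, keep the lowest p."""
    key = ["chrom", "pos"]
    dup = df.duplicated(key, keep=False)
    if not dup.any():
        return df
    partner_alleles = partner.set_index(key)[["effect_allele", "other_allele"]]
    keep = [df.loc[~dup]]
    n_dropped = 0
    for (chrom, pos), grp in df.loc[dup].groupby(key):
        try:
            pa = partner_alleles.loc[(chrom, pos)]
            pset = {pa["effect_allele"], pa["other_allele"]}
            match = grp[[a in pset and b in pset for a, b in
                         zip(grp["effect_allele"], grp["other_allele"])]]
        except KeyError:
            match = grp.iloc[0:0]
        if len(match) == 0:
            match = grp
        keep.append(match.sort_values("pvalue").iloc[:1])
        n_dropped += len(grp) - 1
    if n_dropped:
        logger.info("resolved %d duplicate-position rows", n_dropped)
    return pd.concat(keep).sort_values(["chrom", "pos"]).reset_index(drop=True)


def harmonize_pair(gwas: pd.DataFrame, qtl: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align a QTL sumstats frame to a GWAS frame on shared variants.

    Variants are matched on (chrom, pos).  Where the QTL effect allele equals
    the GWAS other allele, the QTL beta is negated and its eaf replaced by
    1 - eaf.  Strand-ambiguous variants (A/T, C/G) and allele pairs matching
    neither orientation are dropped.  Returns the two frames row-aligned on
    the retained variants, with string-equal effect alleles.
    """
    key = ["chrom", "pos"]
    gwas = _dedupe_positions(gwas, qtl)
    qtl = _dedupe_positions(qtl, gwas)
    merged = gwas.merge(qtl, on=key, suffixes=("_g", "_q"))
    if len(merged) == 0:
        raise ValueError(
            "no overlapping variants between GWAS and QTL frames "
            f"({len(gwas)} vs {len(qtl)} input variants)")

    ea_g, oa_g = merged["effect_allele_g"], merged["other_allele_g"]
    ea_q, oa_q = merged["effect_allele_q"], merged["other_allele_q"]

    ambiguous = [(a, b) in AMBIGUOUS_PAIRS for a, b in zip(ea_g, oa_g)]
    ambiguous = np.array(ambiguous)
    same = (ea_q == ea_g) & (oa_q == oa_g)
    flipped = (ea_q == oa_g) & (oa_q == ea_g)
    # allow the QTL file to report on the opposite strand (non-ambiguous only)
    ea_qc = ea_q.str.translate(_COMPLEMENT)
    oa_qc = oa_q.str.translate(_COMPLEMENT)
    same_strand = (ea_qc == ea_g) & (oa_qc == oa_g)
    flipped_strand = (ea_qc == oa_g) & (oa_qc == ea_g)

    keep = ~ambiguous & (same | flipped | same_strand | flipped_strand)
    n_amb = int((ambiguous & (same | flipped | same_strand | flipped_strand)).sum())
    n_mismatch = int((~(same | flipped | same_strand | flipped_strand) & ~ambiguous).sum())
    if n_amb or n_mismatch:
        logger.info("harmonize: dropped %d strand-ambiguous and %d allele-mismatched variants",
                    n_amb, n_mismatch)
    merged = merged.loc[keep].reset_index(drop=True)
    flip = (flipped | flipped_strand)[keep].reset_index(drop=True)

    g_cols = {c: f"{c}_g" for c in SUMSTAT_COLUMNS if c not in key}
    gwas_out = merged[key].assign(**{c: merged[s] for c, s in g_cols.items()})[SUMSTAT_COLUMNS]
    qtl_out = merged[key].assign(**{c: merged[f"{c}_q"] for c in g_cols})[SUMSTAT_COLUMNS]
    qtl_out.loc[flip, "beta"] = -qtl_out.loc[flip, "beta"]
    qtl_out.loc[flip, "eaf"] = 1.0 - qtl_out.loc[flip, "eaf"]
    # after alignment the QTL alleles are expressed on the GWAS orientation
    qtl_out["effect_allele"] = gwas_out["effect_allele"]
    qtl_out["other_allele"] = gwas_out["other_allele"]
    order = np.lexsort((gwas_out["pos"].to_numpy(), gwas_out["chrom"].to_numpy()))
    return (gwas_out.iloc[order].reset_index(drop=True),
            qtl_out.iloc[order].reset_index(drop=True))


def filter_qc(df: pd.DataFrame, maf_min: float = 0.05,
              info_min: float = 0.5) -> pd.DataFrame:
    """Minor-allele-frequency and imputation-quality filter.

    Keeps records with MAF = min(eaf, 1 - eaf) >= ``maf_min`` (boundary
    inclusive) and imputation quality strictly above ``info_min``; a missing
    info value passes.
    """
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    info_ok = df["info"].isna() | (df["info"] > info_min)
    return df.loc[(maf >= maf_min) & info_ok].reset_index(drop=True)


def select_risk_loci(gwas: pd.DataFrame, genes: list[GeneAnnotation],
                     p_thresh: float = 5e-8, window_bp: int = 1_000_000,
                     dedupe_genes: bool = False) -> list[RiskLocus]:
    """One locus per genome-wide-significant SNV (p <= ``p_thresh``, inclusive),
    listing every gene whose interval overlaps +/- ``window_bp`` of the lead.

    With ``dedupe_genes`` a gene already assigned to an earlier (lower-p
    ordered by position) locus on the same chromosome is not listed again.
    """
    hits = gwas.loc[gwas["pvalue"] <= p_thresh].sort_values(["chrom", "pos"])
    loci: list[RiskLocus] = []
    assigned: set[str] = set()
    for _, row in hits.iterrows():
        lo, hi = row["pos"] - window_bp, row["pos"] + window_bp
        in_window = [g.gene_id for g in genes
                     if g.chrom == row["chrom"] and g.start <= hi and g.end >= lo]
        if dedupe_genes:
            in_window = [g for g in in_window if g not in assigned]
            assigned.update(in_window)
        loci.append(RiskLocus(lead_snv=row["variant_id"], chrom=row["chrom"],
                              lead_pos=int(row["pos"]), window=(int(lo), int(hi)),
                              genes=in_window))
    return loci


def extract_cis_window(df: pd.DataFrame, anchor, window_bp: int) -> pd.DataFrame:
    """Variants within ``window_bp`` (closed boundaries) of a gene or point anchor.

    ``anchor`` is a :class:`GeneAnnotation` (window around the gene body) or a
    ``(chrom, pos)`` tuple (window around the point, e.g. a target SNV).
    """
    if isinstance(anchor, GeneAnnotation):
        chrom, start, end = anchor.chrom, anchor.start, anchor.end
    else:
        try:
            chrom, pos = anchor
            start = end = int(pos)
        except (TypeError, ValueError):
            raise ValueError(f"cannot resolve anchor {anchor!r} to an interval")
    mask = ((df["chrom"] == str(chrom))
            & (df["pos"] >= start - window_bp)
            & (df["pos"] <= end + window_bp))
    return df.loc[mask].reset_index(drop=True)


def read_gene_annotation(path, dialect: str = "bed") -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open) or a 1-based TSV.

    The TSV dialect expects a header with columns gene_id, chrom, start, end
    and optionally strand.
    """
    if dialect == "bed":
        raw = pd.read_csv(path, sep="\t", comment="#", header=None,
                          names=["chrom", "start", "end", "gene_id", "score", "strand"],
                          usecols=range(6))
        return [GeneAnnotation(r.gene_id, str(r.chrom), int(r.start) + 1, int(r.end),
                               r.strand if r.strand in "+-" else "+")
                for r in raw.itertuples()]
    if dialect == "tsv1":
        raw = pd.read_csv(path, sep="\t", comment="#")
        return [GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.start), int(r.end),
                               getattr(r, "strand", "+"))
                for r in raw.itertuples()]
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gene_annotation_bed(genes: list[GeneAnnotation], path,
                              params: dict | None = None) -> None:
    """Write gene intervals as BED (converted to 0-based half-open here)."""
    from . import __version__
    with open(path, "w") as fh:
        extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in params.items())
        fh.write(f"# locusweave {__version__}{extra}\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
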