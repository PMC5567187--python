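"""The double-hit model: GWAS summary statistics meet the methylome.

A candidate gene must be hit twice: carry a nominally associated
(P < 0.05), deleterious (CADD > 15), protein-relevant (nonsynonymous or
stopgain, exonic or splicing) SNP, *and* hold at least one significantly
differentially methylated probe (P_BH < 0.05). Before that filter, the raw
overlap between all GWAS-implicated genes and all differentially
methylated genes is tested hypergeometrically against a genome-wide
background.

Functional class, amino-acid consequence, and CADD score are consumed as
input columns of the summary-statistics table (external annotation, not
recomputed here). Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dmp import DmpResult
from .enrichment import hypergeom_upper_tail

logger = logging.getLogger("doublehit")

__all__ = [
    "filter_gwas",
    "double_hit_overlap",
    "candidate_filter",
    "probe_snp_colocalization",
    "HG19_GENE_UNIVERSE",
]

#: Unique protein-coding/annotated genes in the UCSC HG19 model — the
#: default background for the genome-wide overlap test. Configurable.
HG19_GENE_UNIVERSE = 25_318

SNP_COLUMNS = ["rsid", "chromosome", "position", "gwas_p", "func_class",
               "consequence", "cadd", "gene_symbol"]

FUNC_CLASSES = {"exonic", "splicing", "UTR5", "UTR3", "intronic", "intergenic", "ncRNA", "other"}
CODING_CONSEQUENCES = {"nonsynonymous", "synonymous", "stopgain", "stoploss", "none"}


def _norm_chrom(series: pd.Series) -> pd.Series:
    """Normalize chr1/1 naming conventions (logged once if mixed)."""
    s = series.astype(str).str.strip()
    stripped = s.str.replace("^chr", "", regex=True, case=False)
    if (stripped != s).any() and (stripped == s).any():
        logger.info("chromosome naming mixed (chrN and N); normalized to bare names")
    return stripped.str.upper()


def filter_gwas(
    snps: pd.DataFrame, p_threshold: float = 0.05, blacklist: set[str] | None = None
) -> tuple[pd.DataFrame, set[str]]:
    """Keep nominally associated SNPs (strict gwas_p < threshold) and drop
    blacklisted ("spurious") genes; return retained rows and the unique
    mapped gene set."""
    blacklist = {g.upper() for g in (blacklist or set())}
    keep = snps.loc[snps["gwas_p"] < p_threshold].copy()
    if blacklist:
        keep = keep.loc[~keep["gene_symbol"].astype(str).str.upper().isin(blacklist)]
    genes = set(keep["gene_symbol"].astype(str).str.upper())
    genes.discard("NAN")
    return keep, genes


def double_hit_overlap(
    gwas_genes: set[str],
    dmp_genes: set[str],
    M: int = HG19_GENE_UNIVERSE,
) -> dict:
    """Hypergeometric upper-tail test of GWAS-gene / DMP-gene overlap.

    K = |GWAS genes|, N = |DMP genes|, x = |intersection| in a universe of
    M genes. Same statistic and code path as set enrichment.
    """
    gwas_genes = {g.upper() for g in gwas_genes}
    dmp_genes = {g.upper() for g in dmp_genes}
    if not gwas_genes or not dmp_genes:
        raise ValueError("both gene sets must be nonempty")
    if M < len(gwas_genes | dmp_genes):
        raise ValueError(f"universe M={M} smaller than the union of the two sets")
    overlap = sorted(gwas_genes & dmp_genes)
    K, N, x = len(gwas_genes), len(dmp_genes), len(overlap)
    return {
        "M": M, "K": K, "N": N, "x": x,
        "p": hypergeom_upper_tail(M, K, N, x),
        "overlap_genes": overlap,
    }


def candidate_filter(
    snps: pd.DataFrame,
    dmp: DmpResult | pd.DataFrame,
    p_threshold: float = 0.05,
    cadd_threshold: float = 15.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Emit the double-hit candidate table (one row per retained SNP).

    A SNP is retained iff gwas_p < 0.05, func_class in {exonic, splicing},
    consequence in {nonsynonymous, stopgain}, CADD > 15 (all strict), and
    its gene has >=1 probe with methylation p_bh < alpha. ``dmp`` is either
    a DmpResult or a per-probe table with columns gene (or gene_symbol),
    probe_id, p_bh, t_stat (+ optional island_relation/region). Each row
    carries the gene's best probe (smallest p_bh), the direction from the
    t sign, and min(gwas_p) over the gene's SNPs in the *unfiltered* table
    (intronic and intergenic included).
    """
    probe_table = _dmp_probe_table(dmp)
    sig = probe_table.loc[probe_table["p_bh"] < alpha]
    # best probe per gene = smallest methylation p_bh
    best = sig.sort_values(["p_bh", "probe_id"], kind="stable").drop_duplicates("gene")
    best = best.set_index("gene")

    gene_upper = snps["gene_symbol"].astype(str).str.upper()
    min_p = snps.assign(_g=gene_upper).groupby("_g")["gwas_p"].min()

    cons_ok = snps["consequence"].isin(["nonsynonymous", "stopgain"])
    func_ok = snps["func_class"].isin(["exonic", "splicing"])
    cadd = pd.to_numeric(snps["cadd"], errors="coerce")
    keep = (
        (snps["gwas_p"] < p_threshold)
        & func_ok
        & cons_ok
        & (cadd > cadd_threshold)
        & gene_upper.isin(best.index)
    )
    dropped_no_dmp = int((func_ok & cons_ok & (cadd > cadd_threshold)
                          & (snps["gwas_p"] < p_threshold)
                          & ~gene_upper.isin(probe_table["gene"])).sum())
    if dropped_no_dmp:
        logger.warning("candidate_filter: %d passing SNPs mapped to genes absent from the methylation annotation", dropped_no_dmp)

    rows = []
    for i in snps.index[keep]:
        gene = gene_upper.at[i]
        probe = best.loc[gene]
        rows.append({
            "gene_symbol": gene,
            "chromosome": snps.at[i, "chromosome"],
            "strand": snps.at[i, "strand"] if "strand" in snps.columns else ".",
            "rsid": snps.at[i, "rsid"],
            "gwas_p": float(snps.at[i, "gwas_p"]),
            "location": snps.at[i, "func_class"],
            "consequence": snps.at[i, "consequence"],
            "cadd": float(cadd.at[i]),
            "min_p_for_gene": float(min_p.at[gene]),
            "probe_id": probe["probe_id"],
            "dmp_p_bh": float(probe["p_bh"]),
            "region": probe.get("island_relation", "."),
            "t_stat": float(probe["t_stat"]),
            "direction": "hyper" if probe["t_stat"] > 0 else "hypo",
        })
    out = pd.DataFrame(rows, columns=[
        "gene_symbol", "chromosome", "strand", "rsid", "gwas_p", "location",
        "consequence", "cadd", "min_p_for_gene", "probe_id", "dmp_p_bh",
        "region", "t_stat", "direction",
    ])
    out = out.sort_values(["direction", "gwas_p"], ascending=[False, True], kind="stable").reset_index(drop=True)
    n_hyper = out.loc[out["direction"] == "hyper", "gene_symbol"].nunique()
    n_hypo = out.loc[out["direction"] == "hypo", "gene_symbol"].nunique()
    logger.info("candidate_filter: %d SNPs, %d genes (%d hyper, %d hypo)",
                len(out), out["gene_symbol"].nunique(), n_hyper, n_hypo)
    return out


def _dmp_probe_table(dmp: DmpResult | pd.DataFrame) -> pd.DataFrame:
    """Normalize either a DmpResult or a flat probe table to
    columns gene/probe_id/p_bh/t_stat/island_relation."""
    if isinstance(dmp, DmpResult):
        rec = dmp.records
        rows = []
        for probe, row in rec.iterrows():
            for gene in row["gene_symbols"]:
                rows.append({"gene": gene, "probe_id": probe, "p_bh": row["p_bh"],
                             "t_stat": row["t_stat"],
                             "island_relation": row.get("island_relation", ".")})
        return pd.DataFrame(rows, columns=["gene", "probe_id", "p_bh", "t_stat", "island_relation"])
    df = dmp.copy()
    if "gene" not in df.columns:
        df = df.rename(columns={"gene_symbol": "gene"})
    if "island_relation" not in df.columns:
        df["island_relation"] = "."
    df["gene"] = df["gene"].astype(str).str.upper()
    return df[["gene", "probe_id", "p_bh", "t_stat", "island_relation"]]


def probe_snp_colocalization(
    snps: pd.DataFrame, probe_ann: pd.DataFrame, window: int = 0
) -> pd.DataFrame:
    """SNPs landing inside a probe's target CpG site (position, position+1),
    widened by ±window bases. Chromosome naming is normalized on both sides.
    Default window 0 = exact containment in the 2-bp CpG dinucleotide."""
    if snps.empty or probe_ann.empty:
        return pd.DataFrame(columns=["rsid", "probe_id", "chromosome", "snp_position", "probe_position"])
    s_chr = _norm_chrom(snps["chromosome"])
    p_chr = _norm_chrom(probe_ann["chromosome"])
    hits = []
    probes_by_chr = {c: sub for c, sub in probe_ann.assign(_chr=p_chr).groupby("_chr")}
    for i in snps.index:
        c = s_chr.at[i]
        if c not in probes_by_chr:
            continue
        sub = probes_by_chr[c]
        pos = int(snps.at[i, "position"])
        lo = sub["position"].astype(int) - window
        hi = sub["position"].astype(int) + 1 + window
        inside = sub.index[(pos >= lo) & (pos <= hi)]
        for probe in inside:
            hits.append({
                "rsid": snps.at[i, "rsid"],
                "probe_id": probe,
                "chromosome": c,
                "snp_position": pos,
                "probe_position": int(sub.at[probe, "position"]),
            })
    return pd.DataFrame(hits, columns=["rsid", "probe_id", "chromosome", "snp_position", "probe_position"])
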