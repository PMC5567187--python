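"""Per-probe case/control differential methylation.

Pooled-variance two-sample Student t-tests per probe, Benjamini-Hochberg
FDR correction across all tested probes, hyper/hypo direction calls from
the t-statistic sign (on zero-mean-normalized data, a positive t means the
case group sits above the cohort average: hypermethylated), gene
annotation of significant probes, and single-gene probe reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import BetaMatrix

logger = logging.getLogger("doublehit")

__all__ = ["DmpResult", "student_t_per_probe", "bh_adjust", "call_dmps", "gene_probe_report"]

#: Named contrasts: (case-group label, reference-group label).
CONTRASTS = {
    "FTD_vs_control": ("case_FTD", "control"),
    "FTDALS_vs_control": ("case_FTDALS", "control"),
    "control_vs_external": ("control", "external_control"),
}

_TINY_P = np.nextafter(0.0, 1.0)


def student_t_per_probe(
    m: BetaMatrix, group_a: str, group_b: str, welch: bool = False
) -> pd.DataFrame:
    """Row-wise pooled-variance Student t (df = n_a + n_b - 2), two-sided p.

    ``welch`` switches to the unequal-variance form with Welch-Satterthwaite
    degrees of freedom; the pooled form is the default.

    Degenerate probes: zero pooled variance with equal means gives t=0, p=1;
    zero pooled variance with unequal means gives p at the smallest
    representable positive value (flagged in the ``degenerate`` column).
    """
    groups = m.groups()
    ia = np.flatnonzero((groups == group_a).to_numpy())
    ib = np.flatnonzero((groups == group_b).to_numpy())
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {group_a}: {len(ia)}, {group_b}: {len(ib)}"
        )
    X = m.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before testing")
    A, B = X[:, ia], X[:, ib]
    na, nb = A.shape[1], B.shape[1]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss_a = ((A - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((B - mean_b[:, None]) ** 2).sum(axis=1)
    if welch:
        va, vb = ss_a / (na - 1) / na, ss_b / (nb - 1) / nb
        se = np.sqrt(va + vb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        df = np.where(np.isfinite(df), df, na + nb - 2)
    else:
        df = na + nb - 2
        pooled = (ss_a + ss_b) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    degenerate = se <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero variance, unequal means: infinitely strong evidence at machine scale
    blown = degenerate & (diff != 0)
    t = t.copy()
    t[blown] = np.sign(diff[blown]) * np.inf
    p = np.where(blown, _TINY_P, p)
    p = np.where(degenerate & ~blown, 1.0, p)
    if blown.any():
        logger.warning("student_t_per_probe: %d zero-variance probes with unequal means", int(blown.sum()))
    return pd.DataFrame(
        {"t_stat": t, "p": p, "case_mean": mean_a, "control_mean": mean_b,
         "degenerate": degenerate},
        index=m.probe_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DmpResult:
    """Genome-wide differential methylation outcome for one contrast."""

    records: pd.DataFrame  # per probe: gene_symbols, region_class, island_relation, t_stat, p, p_bh, direction, means
    contrast: str
    n_tests: int
    alpha: float = 0.05
    significant_probes: set = field(default_factory=set)
    significant_genes: set = field(default_factory=set)

    @property
    def hyper_probes(self) -> set:
        r = self.records
        return set(r.index[(r["p_bh"] < self.alpha) & (r["t_stat"] > 0)])

    @property
    def hypo_probes(self) -> set:
        r = self.records
        return set(r.index[(r["p_bh"] < self.alpha) & (r["t_stat"] < 0)])

    def genes_of(self, probes) -> set:
        out = set()
        for p in probes:
            out.update(self.records.at[p, "gene_symbols"])
        return out

    def summary(self) -> dict:
        return {
            "contrast": self.contrast,
            "n_tests": self.n_tests,
            "alpha": self.alpha,
            "n_significant_probes": len(self.significant_probes),
            "n_significant_genes": len(self.significant_genes),
            "n_hyper_probes": len(self.hyper_probes),
            "n_hypo_probes": len(self.hypo_probes),
        }


def _split_genes(entry) -> list[str]:
    if entry is None or (isinstance(entry, float) and np.isnan(entry)):
        return []
    return [g.strip().upper() for g in str(entry).split(";") if g.strip() and g.strip().lower() != "nan"]


def call_dmps(
    m: BetaMatrix,
    ann: pd.DataFrame,
    contrast: str = "FTDALS_vs_control",
    alpha: float = 0.05,
    welch: bool = False,
) -> DmpResult:
    """Test every probe, BH-correct across probes, annotate and partition.

    A probe can map to several genes (semicolon-separated in the
    annotation), so unique significant-gene counts can exceed the
    significant-probe count. Correction is across the number of probes
    tested; that count is exposed as ``n_tests``.
    """
    if contrast in CONTRASTS:
        group_a, group_b = CONTRASTS[contrast]
    elif isinstance(contrast, (tuple, list)) and len(contrast) == 2:
        group_a, group_b = contrast
        contrast = f"{group_a}_vs_{group_b}"
    else:
        raise ValueError(f"unknown contrast: {contrast!r}")
    groups = m.groups()
    for g in (group_a, group_b):
        if (groups == g).sum() == 0:
            raise ValueError(f"contrast group {g!r} has no samples")

    tests = student_t_per_probe(m, group_a, group_b, welch=welch)
    tests["p_bh"] = bh_adjust(tests["p"].to_numpy())
    a = ann.loc[m.probe_ids]
    tests["gene_symbols"] = [_split_genes(g) for g in a["gene_symbol"]]
    tests["region_class"] = a["region_class"].to_numpy()
    tests["island_relation"] = a["island_relation"].to_numpy()
    tests["direction"] = np.where(tests["t_stat"] > 0, "hyper", "hypo")

    sig = tests.index[tests["p_bh"] < alpha]
    genes = set()
    for p in sig:
        genes.update(tests.at[p, "gene_symbols"])
    result = DmpResult(
        records=tests,
        contrast=contrast,
        n_tests=len(tests),
        alpha=alpha,
        significant_probes=set(sig),
        significant_genes=genes,
    )
    logger.info("call_dmps: %s", result.summary())
    return result


def gene_probe_report(result: DmpResult, genes: list[str]) -> pd.DataFrame:
    """All probes for each requested gene, with the genome-wide p_bh.

    A lookup within the genome-wide result — no re-correction. Genes with no
    probes appear with a warning and contribute no rows.
    """
    rows = []
    wanted = [g.upper() for g in genes]
    rec = result.records
    for gene in wanted:
        mask = rec["gene_symbols"].map(lambda gs, gene=gene: gene in gs)
        sub = rec.loc[mask]
        if sub.empty:
            logger.warning("gene_probe_report: gene %s has no probes in the result", gene)
            continue
        for probe, row in sub.iterrows():
            rows.append(
                {"gene": gene, "probe_id": probe, "region_class": row["region_class"],
                 "island_relation": row["island_relation"], "t_stat": row["t_stat"],
                 "p": row["p"], "p_bh": row["p_bh"], "direction": row["direction"]}
            )
    return pd.DataFrame(rows, columns=["gene", "probe_id", "region_class", "island_relation",
                                       "t_stat", "p", "p_bh", "direction"])
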