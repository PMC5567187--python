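"""Expression-based validation meta-analysis.

Candidate (differentially methylated) genes are checked against
independent case/control expression studies: each study gets a
moderated-t differential-expression analysis with empirical-Bayes variance
shrinkage, BH correction over that study's own assayed genes, and a gene
counts as validated when it is significant in at least one study. A
Fisher exact test reports study-level overrepresentation of the query
among the DE genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .dmp import bh_adjust

logger = logging.getLogger("doublehit")

__all__ = [
    "ValidationSet",
    "ValidationOutcome",
    "moderated_t",
    "validate_genes",
    "fisher_overrepresentation",
]


@dataclass
class ValidationSet:
    """One independent expression study: genes x samples plus class labels.

    Gene symbols are uppercased; duplicated symbols keep the max-variance
    row (the usual probe-collapse rule). The per-study assayed-gene count is
    the BH divisor for that study.
    """

    name: str
    expr: pd.DataFrame
    labels: pd.Series  # per sample: "case" / "control"

    def __post_init__(self) -> None:
        self.expr = self.expr.copy()
        self.expr.index = self.expr.index.astype(str).str.upper()
        if self.expr.index.duplicated().any():
            df = self.expr.assign(_var=self.expr.var(axis=1))
            df = df.sort_values("_var", ascending=False)
            df = df[~df.index.duplicated(keep="first")].drop(columns="_var")
            self.expr = df.sort_index()
        self.labels = pd.Series(self.labels, index=self.expr.columns)
        for cls in ("case", "control"):
            if (self.labels == cls).sum() < 2:
                raise ValueError(f"{self.name}: need >=2 {cls} samples")

    @property
    def platform_gene_count(self) -> int:
        return self.expr.shape[0]


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Moments are matched on the log sample variances: with z = log s^2 and
    residual df d, E[z] and Var[z] identify the prior df d0 and scale s0^2
    through digamma/trigamma relations. Spread at or below what sampling
    alone explains gives d0 = inf (all variances shrunk to a common s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - special.polygamma(1, df_resid / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    expr: pd.DataFrame,
    labels,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Per-gene case-vs-control moderated t with EB variance shrinkage.

    The per-gene pooled variance s_g^2 (residual df d_g = n-2) is shrunk to
    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g); the moderated t uses
    d0 + d_g degrees of freedom. The prior (d0, s0^2) is estimated by
    method of moments on the log sample variances unless injected (d0=0
    recovers the ordinary t; d0=inf pools every gene to s0^2).
    """
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    ic = np.flatnonzero((labels == "case").to_numpy())
    ik = np.flatnonzero((labels == "control").to_numpy())
    if len(ic) < 2 or len(ik) < 2:
        raise ValueError("need >=2 samples per class")
    X = expr.to_numpy(dtype=float)
    A, B = X[:, ic], X[:, ik]
    na, nb = len(ic), len(ik)
    d_g = na + nb - 2
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    s2 = (((A - mean_a[:, None]) ** 2).sum(axis=1)
          + ((B - mean_b[:, None]) ** 2).sum(axis=1)) / d_g

    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_variance_prior(s2, d_g)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
        if not np.isfinite(d0):
            logger.info("moderated_t: d0=inf (variance spread within sampling noise); full pooling")

    if d0 == 0:
        s2_tilde, df_total = s2, float(d_g)
    elif np.isinf(d0):
        s2_tilde, df_total = np.full_like(s2, s0_sq), np.inf
    else:
        s2_tilde = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = float(d0 + d_g)
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    bad = se <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(bad, 0.0, diff / np.where(bad, 1.0, se))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(bad & (diff == 0), 1.0, p)
    p = np.where(bad & (diff != 0), np.nextafter(0.0, 1.0), p)
    return pd.DataFrame(
        {"t_mod": t, "p": p, "log_fc": diff, "s2": s2, "s2_tilde": s2_tilde,
         "d0": d0, "df_total": df_total},
        index=expr.index,
    )


@dataclass
class ValidationOutcome:
    de_genes_by_set: dict[str, set[str]]
    validating_sets: dict[str, list[str]]     # query gene -> study names
    not_assayed: dict[str, list[str]]         # query gene -> studies lacking it
    fisher_p_by_set: dict[str, float]
    ranking: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_validated(self) -> int:
        return sum(1 for sets in self.validating_sets.values() if sets)


def validate_genes(
    query_genes,
    sets: list[ValidationSet],
    alpha: float = 0.05,
    require_direction: bool = False,
    directions: dict[str, str] | None = None,
) -> ValidationOutcome:
    """Meta-analysis across validation studies.

    Per study: moderated t, BH over that study's own assayed genes, DE at
    p_bh < alpha. A query gene is validated by a study when significant
    there; absence from a study's platform is "not assayed", distinct from
    not-DE. Genes are ranked by number of validating studies, ties by best
    p_bh.

    With ``require_direction`` a stricter rule applies: a significant gene
    only validates when its expression change opposes its methylation
    direction (``directions`` maps gene -> "hyper"/"hypo"; promoter
    hypermethylation is expected to silence, so hyper pairs with
    down-regulation and hypo with up-regulation). Off by default.
    """
    if not sets:
        raise ValueError("need >=1 validation set")
    if require_direction and not directions:
        raise ValueError("require_direction needs a gene -> hyper/hypo map")
    directions = {str(g).upper(): d for g, d in (directions or {}).items()}
    query = sorted({str(g).upper() for g in query_genes})
    de_by_set: dict[str, set[str]] = {}
    best_p: dict[str, float] = {g: 1.0 for g in query}
    validating: dict[str, list[str]] = {g: [] for g in query}
    missing: dict[str, list[str]] = {g: [] for g in query}
    fisher_p: dict[str, float] = {}
    for vs in sets:
        res = moderated_t(vs.expr, vs.labels)
        res["p_bh"] = bh_adjust(res["p"].to_numpy())
        de = set(res.index[res["p_bh"] < alpha])
        de_by_set[vs.name] = de
        if not de:
            logger.info("validate_genes: %s yielded no DE genes", vs.name)
        platform = set(res.index)
        for g in query:
            if g not in platform:
                missing[g].append(vs.name)
            elif g in de:
                if require_direction:
                    want = directions.get(g)
                    fc = float(res.at[g, "log_fc"])
                    concordant = (want == "hyper" and fc < 0) or (want == "hypo" and fc > 0)
                    if not concordant:
                        continue
                validating[g].append(vs.name)
                best_p[g] = min(best_p[g], float(res.at[g, "p_bh"]))
        q_on_platform = [g for g in query if g in platform]
        fisher_p[vs.name] = (
            fisher_overrepresentation(q_on_platform, de, platform) if q_on_platform else 1.0
        )
    ranking = pd.DataFrame(
        {"gene": query,
         "n_validating_sets": [len(validating[g]) for g in query],
         "best_p_bh": [best_p[g] for g in query],
         "validating_sets": [",".join(validating[g]) for g in query]}
    ).sort_values(["n_validating_sets", "best_p_bh", "gene"],
                  ascending=[False, True, True], kind="stable").reset_index(drop=True)
    return ValidationOutcome(
        de_genes_by_set=de_by_set,
        validating_sets=validating,
        not_assayed=missing,
        fisher_p_by_set=fisher_p,
        ranking=ranking,
    )


def fisher_overrepresentation(query_genes, de_genes, platform_genes) -> float:
    """Two-sided Fisher exact on {query/not} x {DE/not} over the platform."""
    platform = {str(g).upper() for g in platform_genes}
    if not platform:
        raise ValueError("empty platform universe")
    query = {str(g).upper() for g in query_genes} & platform
    de = {str(g).upper() for g in de_genes} & platform
    a = len(query & de)
    b = len(query - de)
    c = len(de - query)
    d = len(platform) - a - b - c
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
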