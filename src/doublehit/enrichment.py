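"""Specificity-set construction and hypergeometric overrepresentation.

Two uses share one code path: (1) tissue/brain-region specificity sets are
built from an expression atlas (per-tissue t-test against all remaining
samples, BH across genes, absolute fold-difference > 1.5) and a query gene
list is tested against them; (2) arbitrary GMT collections (pathways) are
tested the same way. The statistic is the hypergeometric upper tail
P(X >= x) for an overlap of x between a size-N query and a size-K set in a
size-M universe, BH-corrected across the sets tested in one call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import bh_adjust

logger = logging.getLogger("doublehit")

__all__ = [
    "SpecificitySetConfig",
    "GeneSetCollection",
    "build_specificity_sets",
    "hypergeom_upper_tail",
    "enrich",
    "filter_brain_sets",
]


@dataclass
class SpecificitySetConfig:
    fold_threshold: float = 1.5   # strict: FD > 1.5 or FD < 1/1.5
    alpha: float = 0.05           # on BH-adjusted t-test p-values
    min_set_size: int = 1

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit universe of size M.

    M is supplied, never inferred silently: the published analyses fix it
    per resource (16,115 for a GTEx-style atlas, 25,318 for an HG19 pathway
    background, and so on).
    """

    name: str
    sets: dict[str, set[str]]
    universe_size: int
    universe: set[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sets = {n: {g.upper() for g in s} for n, s in self.sets.items()}
        union = set().union(*self.sets.values()) if self.sets else set()
        if self.universe is not None:
            self.universe = {g.upper() for g in self.universe}
            union |= self.universe
        if self.universe_size < len(union):
            raise ValueError(
                f"universe_size {self.universe_size} smaller than union of sets ({len(union)})"
            )


def build_specificity_sets(
    expr: pd.DataFrame,
    tissue_labels,
    cfg: SpecificitySetConfig | None = None,
    name: str = "specificity",
) -> GeneSetCollection:
    """One gene set per tissue: genes over-/under-expressed there.

    Per tissue, each gene is tested tissue-vs-rest with a pooled-variance
    Student t-test; p-values are BH-corrected across genes within the
    tissue; a gene enters the set when p_bh <= alpha and the linear-scale
    fold difference mean_in/mean_out exceeds the threshold in either
    direction (FD > 1.5 or FD < 1/1.5, strict). Expression must be
    nonnegative on a linear scale — fold differences on shifted or signed
    scales are refused. No exclusivity: a gene may appear in several
    tissues' sets. Universe M = genes in the atlas.
    """
    cfg = cfg or SpecificitySetConfig()
    X = expr.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("expression must be nonnegative linear-scale values")
    tissue_labels = pd.Series(np.asarray(tissue_labels), index=expr.columns)
    tissues = list(pd.unique(tissue_labels))
    if len(tissues) < 2:
        raise ValueError("need >=2 tissues")
    sets: dict[str, set[str]] = {}
    genes = expr.index.astype(str).str.upper()
    for tissue in tissues:
        mask = (tissue_labels == tissue).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"tissue {tissue!r} needs >=2 samples on both sides")
        inside, outside = X[:, mask], X[:, ~mask]
        t, p = stats.ttest_ind(inside, outside, axis=1, equal_var=True)
        p = np.where(np.isfinite(p), p, 1.0)
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        p_bh = bh_adjust(p)
        mean_in, mean_out = inside.mean(axis=1), outside.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fd = mean_in / mean_out
        up = fd > cfg.fold_threshold
        down = fd < 1.0 / cfg.fold_threshold
        keep = (p_bh <= cfg.alpha) & (up | down) & np.isfinite(fd)
        member = set(genes[keep])
        if len(member) >= cfg.min_set_size:
            sets[str(tissue)] = member
    return GeneSetCollection(
        name=name, sets=sets, universe_size=expr.shape[0], universe=set(genes)
    )


def hypergeom_upper_tail(M: int, K: int, N: int, x: int) -> float:
    """Exact P(X >= x) for X ~ Hypergeometric(M, K, N), log-space stable."""
    if not (0 <= x <= min(K, N) <= M) or K > M or N > M:
        raise ValueError(f"inconsistent counts M={M}, K={K}, N={N}, x={x}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, M, K, N))


def enrich(query_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric test of a gene list against every set in a collection.

    The query is uppercased, deduplicated, and intersected with the
    collection universe (when one is carried) before testing; BH correction
    spans exactly the sets tested in this call. Rows sorted by p_bh.
    """
    query = {str(g).upper() for g in query_genes}
    if not query:
        raise ValueError("empty query gene list")
    if collection.universe is not None:
        inside = query & collection.universe
        logger.info("enrich: %d/%d query genes in universe %r",
                    len(inside), len(query), collection.name)
        if not inside:
            raise ValueError("query has no genes in the collection universe")
        query = inside
    M, N = collection.universe_size, len(query)
    rows = []
    for set_name, members in collection.sets.items():
        K = len(members)
        overlap = sorted(query & members)
        x = len(overlap)
        rows.append({
            "set_name": set_name, "M": M, "K": K, "N": N, "x": x,
            "p": hypergeom_upper_tail(M, K, N, x),
            "overlap_genes": overlap,
        })
    result = pd.DataFrame(rows)
    result["p_bh"] = bh_adjust(result["p"].to_numpy())
    result = result.sort_values(["p_bh", "p", "set_name"], kind="stable").reset_index(drop=True)
    return result[["set_name", "M", "K", "N", "x", "p", "p_bh", "overlap_genes"]]


def filter_brain_sets(collection: GeneSetCollection, keywords) -> GeneSetCollection:
    """A-priori restriction to sets whose name matches any keyword
    (case-insensitive substring); lowers the multiple-testing burden."""
    keywords = [str(k).upper() for k in keywords]
    if not keywords:
        raise ValueError("keyword list must be nonempty")
    kept = {
        name: genes
        for name, genes in collection.sets.items()
        if any(k in name.upper() for k in keywords)
    }
    if not kept:
        logger.warning("filter_brain_sets: no set name matched %s", keywords)
    else:
        logger.info("filter_brain_sets: retained %d/%d sets", len(kept), len(collection.sets))
    return GeneSetCollection(
        name=f"{collection.name}|filtered",
        sets=kept,
        universe_size=collection.universe_size,
        universe=collection.universe,
    )
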