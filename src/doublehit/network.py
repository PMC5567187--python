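"""Thresholded Spearman co-expression network and degree prioritization.

Candidate genes are connected when their expression profiles are strongly
rank-correlated (|rho| > 0.6, pairwise P < 0.001, both strict); gene
degree in the resulting graph ranks genes by putative regulatory
importance.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("doublehit")

__all__ = ["spearman_matrix", "build_network", "degree_prioritize"]


def spearman_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p over genes (rows).

    Ties get average ranks; p comes from the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)). Constant genes have undefined rank
    correlation and are dropped with a warning. Requires >=5 samples.
    """
    n = expr.shape[1]
    if n < 5:
        raise ValueError("need >=5 samples for rank correlations")
    X = expr.to_numpy(dtype=float)
    constant = np.nanstd(X, axis=1) == 0
    if constant.any():
        logger.warning("spearman_matrix: dropping %d constant genes", int(constant.sum()))
        expr = expr.loc[~constant]
        X = X[~constant]
    if expr.shape[0] < 2:
        raise ValueError("fewer than 2 variable genes")
    ranks = stats.rankdata(X, axis=1)  # average ranks for ties
    rho = np.corrcoef(ranks)
    np.clip(rho, -1.0, 1.0, out=rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(p), p, 0.0)  # |rho|=1 -> t=inf -> p=0
    np.fill_diagonal(p, 0.0)
    genes = expr.index
    return (pd.DataFrame(rho, index=genes, columns=genes),
            pd.DataFrame(p, index=genes, columns=genes))


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    r_min: float = 0.6,
    p_max: float = 0.001,
    node_attrs: pd.DataFrame | None = None,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Edge iff |rho| > r_min and p < p_max (both strict).

    Isolated genes are removed by default — the network reports only
    co-expressed genes — unless ``keep_isolated``. ``node_attrs`` (indexed
    by gene; e.g. direction, cadd, has_snp) is joined onto the nodes.
    """
    if rho.shape != p.shape or list(rho.index) != list(p.index):
        raise ValueError("rho and p matrices must be conformant")
    genes = list(rho.index)
    G = nx.Graph()
    G.add_nodes_from(genes)
    R, P = rho.to_numpy(), p.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = (np.abs(R[iu, ju]) > r_min) & (P[iu, ju] < p_max)
    for i, j in zip(iu[mask], ju[mask]):
        r = float(R[i, j])
        G.add_edge(genes[i], genes[j], rho=r, p=float(P[i, j]),
                   sign="positive" if r > 0 else "negative")
    if not keep_isolated:
        G.remove_nodes_from([n for n in genes if G.degree(n) == 0])
    if node_attrs is not None:
        for gene in G.nodes:
            if gene in node_attrs.index:
                for key, val in node_attrs.loc[gene].items():
                    if isinstance(val, float) and np.isnan(val):
                        continue  # GraphML cannot carry missing attributes
                    if isinstance(val, np.generic):
                        val = val.item()
                    G.nodes[gene][key] = val
    for gene in G.nodes:
        G.nodes[gene]["degree"] = G.degree(gene)
    logger.info("build_network: %d nodes, %d edges (|rho|>%g, p<%g)",
                G.number_of_nodes(), G.number_of_edges(), r_min, p_max)
    return G


def degree_prioritize(net: nx.Graph) -> pd.DataFrame:
    """Genes ranked by network degree (descending), ties by symbol.

    Degrees are cross-checked against an independent incident-edge count
    from the edge list before reporting.
    """
    counted: dict = {n: 0 for n in net.nodes}
    for a, b in net.edges:
        counted[a] += 1
        counted[b] += 1
    for n in net.nodes:
        if counted[n] != net.degree(n):  # pragma: no cover - internal consistency
            raise AssertionError(f"degree mismatch for {n}")
    table = pd.DataFrame(
        {"gene": list(counted), "degree": [counted[n] for n in counted]}
    ).sort_values(["degree", "gene"], ascending=[False, True], kind="stable").reset_index(drop=True)
    return table
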