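"""Methylation preprocessing: batch adjustment, probe filtering, imputation,
zero-mean normalization.

The cascade runs in a fixed order — empirical-Bayes batch adjustment, probe
filtering, K-nearest-neighbour imputation, per-probe zero-mean normalization —
and every step is pure (input containers are never mutated).

Beta values are the methylated fraction at a CpG probe, bounded in [0, 1];
after zero-mean normalization values are relative: above 0 means
hypermethylated relative to the cohort average, below 0 hypomethylated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("doublehit")

#: Gene-region classes kept by the proximity filter (probe lies in or near
#: its annotated gene). Probes outside these classes are treated as
#: intergenic and dropped.
GENIC_REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: Closed vocabulary for the region_class annotation column.
REGION_CLASSES = GENIC_REGION_CLASSES + ("intergenic", "other")

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "open_sea")

GROUP_LABELS = ("case_FTD", "case_FTDALS", "control", "external_control")


@dataclass
class BetaMatrix:
    """Probes-by-samples methylation matrix with per-sample metadata.

    values : DataFrame, probe ids on the index, sample ids on the columns.
    sample_meta : DataFrame indexed by sample id with at least a ``group``
        column (case_FTD / case_FTDALS / control) and a ``batch`` column.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids in BetaMatrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in BetaMatrix")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        # align metadata to column order
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    def batches(self) -> pd.Series:
        return self.sample_meta["batch"]

    def copy_with(self, values: pd.DataFrame) -> "BetaMatrix":
        return BetaMatrix(values=values, sample_meta=self.sample_meta.copy())


def validate_annotation(ann: pd.DataFrame, probes: pd.Index) -> None:
    """Every probe must be annotated and region classes must be known."""
    missing = probes.difference(ann.index)
    if len(missing):
        raise ValueError(f"probes missing from annotation: {list(missing[:5])}")
    bad = ann.loc[probes, "region_class"][~ann.loc[probes, "region_class"].isin(REGION_CLASSES)]
    if len(bad):
        raise ValueError(
            "unknown region_class values for probes: "
            + ", ".join(f"{p}={v}" for p, v in bad.head(5).items())
        )


# ---------------------------------------------------------------------------
# ComBat-style parametric empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

def _combat_priors(gamma_hat: np.ndarray, delta_hat_sq: np.ndarray):
    """Method-of-moments hyperparameters for one batch.

    Normal prior on the additive effect (mean/variance of the per-probe
    estimates); inverse-gamma prior on the multiplicative effect, with shape
    a and scale b matched to the mean and variance of the per-probe scale
    estimates.
    """
    gamma_bar = float(np.mean(gamma_hat))
    tau_sq = float(np.var(gamma_hat, ddof=1)) if gamma_hat.size > 1 else 0.0
    m = float(np.mean(delta_hat_sq))
    s2 = float(np.var(delta_hat_sq, ddof=1)) if delta_hat_sq.size > 1 else 0.0
    if s2 <= 0:
        a_prior, b_prior = np.inf, np.inf  # degenerate: no spread to learn from
    else:
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
    return gamma_bar, tau_sq, a_prior, b_prior


def _combat_shrink(z_batch: np.ndarray, gamma_hat: np.ndarray, delta_hat_sq: np.ndarray,
                   gamma_bar: float, tau_sq: float, a_prior: float, b_prior: float,
                   tol: float = 1e-6, max_iter: int = 500):
    """Iterative EB posterior estimates of per-probe batch location/scale."""
    n = np.sum(~np.isnan(z_batch), axis=1).astype(float)
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat_sq.copy()
    if not np.isfinite(a_prior):
        # no information in the scale spread: keep raw estimates for scale,
        # shrink location only
        if tau_sq > 0:
            gamma_star = (n * tau_sq * gamma_hat + delta_star * gamma_bar) / (n * tau_sq + delta_star)
        else:
            gamma_star = np.full_like(gamma_hat, gamma_bar)
        return gamma_star, delta_star
    for _ in range(max_iter):
        g_new = (n * tau_sq * gamma_hat + delta_star * gamma_bar) / (n * tau_sq + delta_star)
        resid_sq = np.nansum((z_batch - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * resid_sq + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(np.max(np.abs(g_new - gamma_star) / (np.abs(gamma_star) + 1e-12)),
                     np.max(np.abs(d_new - delta_star) / (delta_star + 1e-12)))
        gamma_star, delta_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta_star


def combat_adjust(
    m: BetaMatrix,
    batch_labels: pd.Series | None = None,
    scale: str = "beta",
) -> BetaMatrix:
    """Remove additive and multiplicative batch effects, EB-shrunk.

    Parametric empirical-Bayes location/scale adjustment: each probe is
    standardized against its pooled (batch-design) fit, per-batch per-probe
    location and scale effects are estimated, shrunk toward batch-level
    priors (normal on location, inverse-gamma on scale, hyperparameters by
    method of moments), and the standardized data are back-transformed.

    ``scale`` selects the working scale: "beta" (default) adjusts the raw
    bounded values; "logit" transforms to log(beta/(1-beta)) first and back
    afterwards, which respects the [0, 1] support at the cost of direct
    interpretability.

    Missing cells are tolerated: all moments use available cells only, and
    missing cells stay missing. A single batch is a no-op (copy returned).
    Probes with zero pooled variance are adjusted by location only.
    """
    if scale not in ("beta", "logit"):
        raise ValueError("scale must be 'beta' or 'logit'")
    if scale == "logit":
        eps = 1e-6
        v = m.values.clip(eps, 1 - eps)
        logit = np.log(v / (1 - v))
        adjusted = combat_adjust(m.copy_with(logit), batch_labels, scale="beta")
        back = 1.0 / (1.0 + np.exp(-adjusted.values))
        return m.copy_with(back)
    if batch_labels is None:
        batch_labels = m.batches()
    batch_labels = pd.Series(batch_labels, index=m.sample_ids)
    batches = list(pd.unique(batch_labels))
    if len(batches) < 2:
        return m.copy_with(m.values.copy())
    counts = batch_labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batch with <2 samples: {small.index.tolist()}")

    X = m.values.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    batch_idx = {b: np.flatnonzero((batch_labels == b).to_numpy()) for b in batches}
    obs = ~np.isnan(X)

    # pooled fit: weighted grand mean over batch means, pooled residual var
    batch_means = np.column_stack([np.nanmean(X[:, idx], axis=1) for b, idx in batch_idx.items()])
    n_obs_batch = np.column_stack([obs[:, idx].sum(axis=1) for b, idx in batch_idx.items()]).astype(float)
    with np.errstate(invalid="ignore"):
        grand_mean = np.nansum(batch_means * n_obs_batch, axis=1) / n_obs_batch.sum(axis=1)
    resid = X.copy()
    for j, (b, idx) in enumerate(batch_idx.items()):
        resid[:, idx] = X[:, idx] - batch_means[:, j][:, None]
    n_obs_total = obs.sum(axis=1).astype(float)
    pooled_var = np.nansum(resid**2, axis=1) / n_obs_total
    constant = pooled_var <= 1e-12
    if constant.any():
        logger.info("combat_adjust: %d constant probes adjusted by location only", int(constant.sum()))
    sd = np.sqrt(np.where(constant, 1.0, pooled_var))

    Z = (X - grand_mean[:, None]) / sd[:, None]

    adjusted = np.empty_like(Z)
    for j, (b, idx) in enumerate(batch_idx.items()):
        Zb = Z[:, idx]
        gamma_hat = np.nanmean(Zb, axis=1)
        nb = obs[:, idx].sum(axis=1).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            delta_hat_sq = np.nansum((Zb - gamma_hat[:, None]) ** 2, axis=1) / np.maximum(nb - 1, 1)
        delta_hat_sq = np.where(delta_hat_sq <= 1e-12, 1.0, delta_hat_sq)
        gamma_bar, tau_sq, a_prior, b_prior = _combat_priors(gamma_hat, delta_hat_sq)
        gamma_star, delta_star = _combat_shrink(
            Zb, gamma_hat, delta_hat_sq, gamma_bar, tau_sq, a_prior, b_prior
        )
        scale = np.sqrt(np.where(constant, 1.0, delta_star))
        adjusted[:, idx] = (Zb - gamma_star[:, None]) / scale[:, None]

    out = adjusted * sd[:, None] + grand_mean[:, None]
    out[~obs] = np.nan
    return m.copy_with(pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids))


# ---------------------------------------------------------------------------
# Probe filter cascade
# ---------------------------------------------------------------------------

#: Filter rules in application order; the first failing rule claims the probe.
FILTER_RULES = ("missingness", "xy_chromosome", "snp_maf", "control_probe", "blacklist", "region")


@dataclass
class FilterThresholds:
    max_missing_frac: float = 0.20  # strict: removed only when frac > threshold
    max_snp_maf: float = 0.10       # strict: removed only when MAF > threshold


@dataclass
class FilterReport:
    """Per-rule removal counts; conservation (removed + retained = input) holds."""

    input_probes: int
    removed: dict[str, int] = field(default_factory=dict)
    retained_probes: int = 0
    retained_genes: int = 0

    def to_dict(self) -> dict:
        return {
            "input_probes": self.input_probes,
            "removed": dict(self.removed),
            "retained_probes": self.retained_probes,
            "retained_genes": self.retained_genes,
        }


def filter_probes(
    m: BetaMatrix,
    ann: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the probe filter cascade; each probe is accounted for once.

    Rules, in order: missingness > 20% of samples; X/Y chromosome; common SNP
    in the probe (MAF > 0.1); control probe; blacklisted ("spurious") probe;
    probe not in a genic region class (TSS1500/TSS200/5UTR/1stExon/Body/3UTR).
    Both fraction thresholds are strict (boundary probes retained).
    """
    thresholds = thresholds or FilterThresholds()
    validate_annotation(ann, m.probe_ids)
    a = ann.loc[m.probe_ids]
    X = m.values

    missing_frac = X.isna().mean(axis=1)
    chrom = a["chromosome"].astype(str).str.replace("chr", "", regex=False).str.upper()
    maf = pd.to_numeric(a.get("snp_maf"), errors="coerce")

    fails = {
        "missingness": (missing_frac > thresholds.max_missing_frac).to_numpy(),
        "xy_chromosome": chrom.isin(["X", "Y"]).to_numpy(),
        "snp_maf": (maf > thresholds.max_snp_maf).fillna(False).to_numpy(),
        "control_probe": a["control_probe"].astype(bool).to_numpy(),
        "blacklist": a["blacklist"].astype(bool).to_numpy(),
        "region": (~a["region_class"].isin(GENIC_REGION_CLASSES)).to_numpy(),
    }

    removed = {}
    claimed = np.zeros(len(X), dtype=bool)
    for rule in FILTER_RULES:
        hit = fails[rule] & ~claimed
        removed[rule] = int(hit.sum())
        claimed |= hit

    keep = ~claimed
    kept = m.copy_with(X.loc[keep])
    genes = a.loc[keep, "gene_symbol"].dropna()
    gene_set = {g for entry in genes for g in str(entry).split(";") if g and g != "nan"}
    report = FilterReport(
        input_probes=len(X),
        removed=removed,
        retained_probes=int(keep.sum()),
        retained_genes=len(gene_set),
    )
    logger.info("filter_probes: %s", report.to_dict())
    return kept, report


# ---------------------------------------------------------------------------
# K-nearest-neighbour imputation
# ---------------------------------------------------------------------------

def _masked_probe_distances(X: np.ndarray) -> np.ndarray:
    """All-pairs probe distances over shared observed samples.

    Euclidean distance over the samples where both probes are observed,
    rescaled by sqrt(total / shared) so that distances computed over
    different overlap sizes are comparable. Pairs with no shared samples
    get +inf.
    """
    obs = ~np.isnan(X)
    Xf = np.where(obs, X, 0.0)
    W = obs.astype(float)
    sq = Xf**2
    # sum over shared samples of (x - y)^2, via masked cross-products
    d2 = sq @ W.T + W @ sq.T - 2.0 * (Xf @ Xf.T)
    shared = W @ W.T
    total = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared > 0, np.maximum(d2, 0.0) * (total / shared), np.inf)
    np.fill_diagonal(d2, np.inf)
    finite = np.isfinite(d2)
    out = np.full_like(d2, np.inf)
    out[finite] = np.sqrt(d2[finite])
    return out


def knn_impute(m: BetaMatrix, k: int = 3) -> BetaMatrix:
    """Impute missing cells from the k nearest probes observed at that sample.

    For a missing cell (probe p, sample s) the k probes closest to p — by
    overlap-rescaled Euclidean distance, among probes observed at s — donate
    the unweighted mean of their values at s. If no candidate probe is
    observed at s the probe's own mean is used (logged). A probe with no
    observed value at all is an error.
    """
    X = m.values.to_numpy(dtype=float).copy()
    obs = ~np.isnan(X)
    if not (~obs).any():
        return m.copy_with(m.values.copy())
    empty = ~obs.any(axis=1)
    if empty.any():
        raise ValueError(f"probes with no observed values: {list(m.probe_ids[empty][:5])}")

    dist = _masked_probe_distances(X)
    probe_means = np.nanmean(np.where(obs, X, np.nan), axis=1)
    fallback = 0
    miss_rows, miss_cols = np.nonzero(~obs)
    for p, s in zip(miss_rows, miss_cols):
        candidates = np.flatnonzero(obs[:, s] & np.isfinite(dist[p]))
        if candidates.size == 0:
            X[p, s] = probe_means[p]
            fallback += 1
            continue
        order = candidates[np.argsort(dist[p, candidates], kind="stable")]
        neighbors = order[:k]
        X[p, s] = float(np.mean(X[neighbors, s]))
    if fallback:
        logger.info("knn_impute: %d cells fell back to the probe mean", fallback)
    return m.copy_with(pd.DataFrame(X, index=m.probe_ids, columns=m.sample_ids))


def zero_mean_normalize(m: BetaMatrix) -> BetaMatrix:
    """Center each probe across all samples (cases and controls together).

    On the resulting relative scale, hypermethylation sits above 0 and
    hypomethylation below 0; downstream direction calls rely on this.
    """
    X = m.values
    if X.isna().any().any():
        raise ValueError("zero_mean_normalize requires a complete matrix (impute first)")
    return m.copy_with(X.sub(X.mean(axis=1), axis=0))


def preprocess(
    m: BetaMatrix,
    ann: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    knn_k: int = 3,
    adjust_batches: bool = True,
    combat_scale: str = "beta",
) -> tuple[BetaMatrix, FilterReport]:
    """Full cascade in fixed order: batch adjust, filter, impute, center."""
    logger.info("preprocess order: combat_adjust -> filter_probes -> knn_impute -> zero_mean_normalize")
    if adjust_batches:
        m = combat_adjust(m, scale=combat_scale)
    m, report = filter_probes(m, ann, thresholds)
    m = knn_impute(m, k=knn_k)
    m = zero_mean_normalize(m)
    return m, report
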