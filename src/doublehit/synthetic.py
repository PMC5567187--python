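"""Synthetic cohort, GWAS, atlas, and validation-set generators.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: bounded bimodal beta values
with batch location/scale effects and a designated set of truly
differential probes; GWAS summary tables with designated risk genes
carrying deleterious exonic SNPs; tissue-structured expression with
designated tissue-specific genes; correlated gene blocks for network
recovery; and GMT collections with planted overlaps. All generators are
deterministic given their seed.

The packaged candidate-list fixture (30 published risk SNPs over 26 genes
for FTD-ALS, plus clearly flagged synthetic distractor rows that each
violate exactly one filter criterion) is exposed through
:func:`table1_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .qc import GENIC_REGION_CLASSES, ISLAND_RELATIONS, BetaMatrix

__all__ = [
    "MethylSimConfig",
    "GwasSimConfig",
    "AtlasSimConfig",
    "simulate_methylation",
    "simulate_gwas",
    "simulate_expression_atlas",
    "simulate_coexpression_blocks",
    "simulate_validation_sets",
    "simulate_gmt",
    "table1_fixture",
]


def _logit(x):
    return np.log(x / (1.0 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Methylation cohort
# ---------------------------------------------------------------------------

@dataclass
class MethylSimConfig:
    """Blood-methylome cohort simulator settings.

    Defaults match the planted-signal recovery conditions used throughout
    the test-suite: a 50/50 case-control contrast over 1,000 probes with 50
    truly differential probes at an absolute beta-scale effect of 0.15,
    two batches, and light (1%) missingness. ``noise_sd`` is the per-probe
    beta-scale noise level; the cohort data give no per-probe variance to
    copy, so this is a free parameter of the generator.
    """

    n_cases: int = 50
    n_controls: int = 50
    n_probes: int = 1000
    n_true_dmp: int = 50
    delta_beta: float = 0.15
    batch_count: int = 2
    batch_shift: float = 0.05
    batch_scale: float = 1.1
    missing_rate: float = 0.01
    noise_sd: float = 0.05
    case_group: str = "case_FTDALS"
    #: genes given a fixed probe count in the annotation, mirroring the
    #: known-marker probe structure of the 450K array (12 GRN probes, one
    #: MAPT probe, four C9orf72 probes)
    marker_probe_counts: tuple[tuple[str, int], ...] = (("GRN", 12), ("MAPT", 1), ("C9ORF72", 4))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_dmp > self.n_probes:
            raise ValueError("n_true_dmp must not exceed n_probes")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_true_dmp > 0 and self.n_cases == 0:
            raise ValueError("differential probes need at least one case")
        if not 0 <= abs(self.delta_beta) < 0.9:
            raise ValueError(
                f"delta_beta={self.delta_beta} pushes case means outside [0, 1] "
                "for any admissible baseline"
            )
        if self.batch_count < 1:
            raise ValueError("batch_count must be >= 1")


def simulate_methylation(
    cfg: MethylSimConfig,
) -> tuple[BetaMatrix, pd.DataFrame, dict[str, int]]:
    """Simulate (BetaMatrix, probe annotation, truth).

    Values are drawn on the logit scale around per-probe baselines from a
    bimodal (low/high methylated) mixture, inverse-transformed, and clipped
    to [0, 1] — preserving bounded support with the heteroscedasticity real
    beta values show. Exactly ``n_true_dmp`` probes carry a case-mean shift
    of ±delta_beta; ``truth`` maps each such probe id to its sign. Batch
    labels go round-robin; batch b adds a location offset ``batch_shift*b``
    (beta scale) and inflates noise by ``batch_scale**b``. Missingness is
    uniform over cells at ``missing_rate``.

    The annotation gives every downstream filter targets: ~3 probes per
    gene, a small intergenic and X/Y fraction, SNP-flagged probes with MAF,
    control probes, and blacklisted probes. Truly differential probes are
    always clean (autosomal, genic, unflagged) so they survive the QC
    cascade.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_cases + cfg.n_controls
    probes = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    groups = [cfg.case_group] * cfg.n_cases + ["control"] * cfg.n_controls
    batches = [f"batch{i % cfg.batch_count}" for i in range(n_samples)]

    # annotation first: flags decide which probes may carry planted signal
    ann = _simulate_annotation(cfg, rng, probes)
    clean = (
        (~ann["chromosome"].isin(["X", "Y"]))
        & ann["region_class"].isin(GENIC_REGION_CLASSES)
        & ~ann["control_probe"]
        & ~ann["blacklist"]
        & ~(ann["snp_maf"].fillna(0) > 0.1)
    )
    clean_probes = ann.index[clean]
    if len(clean_probes) < cfg.n_true_dmp:
        raise ValueError("not enough clean probes to place the planted signal")
    truth_ids = list(rng.choice(clean_probes, size=cfg.n_true_dmp, replace=False))
    signs = rng.choice([-1, 1], size=cfg.n_true_dmp)
    truth = {p: int(s) for p, s in zip(truth_ids, signs)}

    # bimodal baselines, kept away from the bounds
    low = rng.beta(2.0, 8.0, size=cfg.n_probes)
    high = rng.beta(8.0, 2.0, size=cfg.n_probes)
    base = np.where(rng.random(cfg.n_probes) < 0.5, low, high)
    margin = abs(cfg.delta_beta) + 0.02
    base = np.clip(base, margin, 1.0 - margin)

    idx = {p: i for i, p in enumerate(probes)}
    case_mean = base.copy()
    for p, s in truth.items():
        case_mean[idx[p]] = base[idx[p]] + s * cfg.delta_beta

    sd_logit = cfg.noise_sd / (base * (1.0 - base))
    batch_index = np.array([i % cfg.batch_count for i in range(n_samples)])
    is_case = np.array([g != "control" for g in groups])

    mean_mat = np.where(is_case[None, :], case_mean[:, None], base[:, None])
    noise = rng.standard_normal((cfg.n_probes, n_samples))
    noise *= sd_logit[:, None] * (cfg.batch_scale ** batch_index)[None, :]
    values = _expit(_logit(mean_mat) + noise)
    values += (cfg.batch_shift * batch_index)[None, :]
    values = np.clip(values, 0.0, 1.0)

    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = np.where(mask, np.nan, values)

    beta = BetaMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        sample_meta=pd.DataFrame({"group": groups, "batch": batches},
                                 index=pd.Index(samples, name="sample_id")),
    )
    return beta, ann, truth


def _simulate_annotation(cfg: MethylSimConfig, rng: np.random.Generator,
                         probes: list[str]) -> pd.DataFrame:
    n = len(probes)
    n_genes = max(1, n // 3)  # ~3 probes per gene
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    gene_of = [genes[i % n_genes] for i in range(n)]
    autosomes = [str(c) for c in range(1, 23)]
    chrom = rng.choice(autosomes, size=n)
    chrom[rng.random(n) < 0.03] = "X"
    chrom[rng.random(n) < 0.01] = "Y"
    region = rng.choice(list(GENIC_REGION_CLASSES), size=n)
    intergenic = rng.random(n) < 0.05
    region = np.where(intergenic, "intergenic", region)
    island = rng.choice(list(ISLAND_RELATIONS), size=n)
    maf = np.full(n, np.nan)
    snp_flag = rng.random(n) < 0.08
    maf[snp_flag] = rng.uniform(0.0, 0.5, size=int(snp_flag.sum()))
    gene_col = np.where(intergenic, "", gene_of).astype(object)
    control = rng.random(n) < 0.02
    blacklist = rng.random(n) < 0.02
    # marker genes get a fixed probe count on clean autosomal probes
    cursor = 0
    for gene, count in cfg.marker_probe_counts:
        taken = 0
        while taken < count and cursor < n:
            i = cursor
            cursor += 1
            if chrom[i] in ("X", "Y") or control[i] or blacklist[i] or (maf[i] > 0.1):
                continue
            gene_col[i] = gene
            if region[i] == "intergenic":
                region[i] = "TSS1500"
                intergenic[i] = False
            taken += 1
    ann = pd.DataFrame(
        {
            "chromosome": chrom,
            "position": rng.integers(10_000, 100_000_000, size=n),
            "gene_symbol": gene_col,
            "region_class": region,
            "island_relation": island,
            "snp_maf": maf,
            "control_probe": control,
            "blacklist": blacklist,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class GwasSimConfig:
    n_snps: int = 1000
    n_risk_genes: int = 20
    frac_exonic: float = 0.15
    cadd_high_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_exonic", "cadd_high_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_risk_genes < 0 or self.n_snps < 0:
            raise ValueError("counts must be nonnegative")


def simulate_gwas(
    cfg: GwasSimConfig,
    gene_universe: list[str],
    risk_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a pre-annotated GWAS summary table.

    Null SNPs get uniform p-values; SNPs in risk genes are enriched below
    0.05, and (when exonic SNPs exist at all) each risk gene is guaranteed
    one associated, deleterious, nonsynonymous-or-stopgain exonic SNP so a
    downstream double-hit search has real targets. Functional class,
    consequence, and CADD columns mimic external variant annotation:
    CADD is present for exonic/splicing SNPs only, above 15 at
    ``cadd_high_rate``. Pass ``risk_genes`` explicitly to control the
    planted truth; otherwise ``n_risk_genes`` are drawn from the universe.
    """
    if not gene_universe:
        raise ValueError("gene_universe must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    universe = [str(g).upper() for g in gene_universe]
    if risk_genes is None:
        k = min(cfg.n_risk_genes, len(universe))
        risk_genes = list(rng.choice(universe, size=k, replace=False))
    risk = {g.upper() for g in risk_genes}

    gene = rng.choice(universe, size=cfg.n_snps)
    is_risk = np.isin(gene, list(risk))
    p = rng.uniform(0.0, 1.0, size=cfg.n_snps)
    p[is_risk] = rng.beta(0.2, 1.0, size=int(is_risk.sum()))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    other_classes = ["intronic", "intergenic", "UTR5", "UTR3", "ncRNA"]
    other_probs = [0.55, 0.25, 0.08, 0.08, 0.04]
    func = np.where(
        rng.random(cfg.n_snps) < cfg.frac_exonic,
        "exonic",
        rng.choice(other_classes, size=cfg.n_snps, p=other_probs),
    )
    consequence = np.full(cfg.n_snps, "none", dtype=object)
    exonic = func == "exonic"
    consequence[exonic] = rng.choice(
        ["nonsynonymous", "synonymous", "stopgain"], size=int(exonic.sum()), p=[0.5, 0.45, 0.05]
    )
    cadd = np.full(cfg.n_snps, np.nan)
    coding = np.isin(func, ["exonic", "splicing"])
    high = rng.random(cfg.n_snps) < cfg.cadd_high_rate
    cadd[coding & high] = rng.uniform(15.01, 45.0, size=int((coding & high).sum()))
    cadd[coding & ~high] = rng.uniform(0.0, 15.0, size=int((coding & ~high).sum()))

    # guarantee one full double-hit-grade SNP per risk gene (unless the
    # configuration forbids exonic SNPs entirely)
    if cfg.frac_exonic > 0:
        for j, g in enumerate(sorted(risk)):
            if j >= cfg.n_snps:
                break
            hits = np.flatnonzero(gene == g)
            i = hits[0] if hits.size else j
            gene[i] = g
            p[i] = rng.uniform(0.001, 0.049)
            func[i] = "exonic"
            consequence[i] = rng.choice(["nonsynonymous", "stopgain"], p=[0.9, 0.1])
            cadd[i] = rng.uniform(16.0, 40.0)

    table = pd.DataFrame(
        {
            "rsid": [f"rs{i + 1:08d}" for i in range(cfg.n_snps)],
            "chromosome": rng.choice([str(c) for c in range(1, 23)], size=cfg.n_snps),
            "position": rng.integers(10_000, 100_000_000, size=cfg.n_snps),
            "gwas_p": p,
            "func_class": func,
            "consequence": consequence,
            "cadd": cadd,
            "gene_symbol": gene,
            "strand": rng.choice(["+", "-"], size=cfg.n_snps),
        }
    )
    return table


# ---------------------------------------------------------------------------
# Expression atlases
# ---------------------------------------------------------------------------

@dataclass
class AtlasSimConfig:
    n_genes: int = 500
    n_tissues: int = 5
    n_specific_per_tissue: int = 20
    log_fold: float = 2.0            # log2 elevation inside the tissue
    n_samples_per_tissue: int = 20
    noise_sd: float = 1.0            # log2-scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues * self.n_specific_per_tissue > self.n_genes:
            raise ValueError("n_tissues * n_specific_per_tissue must not exceed n_genes")
        if self.n_tissues < 2:
            raise ValueError("need >=2 tissues")


def simulate_expression_atlas(
    cfg: AtlasSimConfig,
) -> tuple[pd.DataFrame, pd.Series, dict[str, set[str]]]:
    """Simulate a linear-scale expression atlas with planted specificity.

    Log2 expression is N(5, noise_sd); each tissue's designated specific
    genes are elevated by ``log_fold`` within that tissue. Returns the
    linear-scale matrix (genes x samples), tissue labels, and the truth map
    tissue -> specific genes.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    tissues = [f"tissue{t}" for t in range(cfg.n_tissues)]
    labels = []
    cols = []
    for t in tissues:
        for s in range(cfg.n_samples_per_tissue):
            labels.append(t)
            cols.append(f"{t}_s{s}")
    log2x = rng.normal(5.0, cfg.noise_sd, size=(cfg.n_genes, len(cols)))
    truth: dict[str, set[str]] = {}
    labels_arr = np.array(labels)
    for ti, t in enumerate(tissues):
        start = ti * cfg.n_specific_per_tissue
        members = genes[start:start + cfg.n_specific_per_tissue]
        truth[t] = set(members)
        rows = slice(start, start + cfg.n_specific_per_tissue)
        log2x[rows, labels_arr == t] = log2x[rows, labels_arr == t] + cfg.log_fold
    expr = pd.DataFrame(2.0**log2x, index=genes, columns=cols)
    return expr, pd.Series(labels, index=cols, name="tissue"), truth


def simulate_coexpression_blocks(
    n_genes: int = 50,
    n_samples: int = 100,
    block_size: int = 10,
    n_blocks: int = 1,
    block_r: float = 0.9,
    seed: int = 0,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, list[set[str]]]:
    """Expression with planted equicorrelated gene blocks (for network tests).

    Genes inside a block share a latent factor giving pairwise Pearson
    correlation ``block_r``; remaining genes are independent. Values are
    exponentiated to a nonnegative linear scale (rank correlations are
    unaffected by the monotone transform).
    """
    if genes is not None:
        n_genes = len(genes)
    if block_size * n_blocks > n_genes:
        raise ValueError("blocks exceed gene count")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"GENE{i:05d}" for i in range(n_genes)]
    Z = rng.standard_normal((n_genes, n_samples))
    blocks: list[set[str]] = []
    for b in range(n_blocks):
        rows = slice(b * block_size, (b + 1) * block_size)
        factor = rng.standard_normal(n_samples)
        Z[rows] = np.sqrt(block_r) * factor[None, :] + np.sqrt(1 - block_r) * Z[rows]
        blocks.append(set(genes[rows]))
    expr = pd.DataFrame(2.0 ** (Z + 5.0), index=genes,
                        columns=[f"s{j}" for j in range(n_samples)])
    return expr, blocks


def simulate_validation_sets(
    query_genes: list[str],
    n_sets: int = 4,
    n_genes: int = 400,
    n_per_class: int = 5,
    de_frac_of_query: float = 0.3,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Case/control expression studies with a planted DE subset of the query.

    Each study plants differential expression (log-scale shift ``effect``)
    in an independent random ``de_frac_of_query`` share of the query genes
    plus a background of non-query DE genes. Returns
    (list of (name, expr, labels), truth map study -> DE query genes).
    """
    rng = np.random.default_rng(seed)
    query = [str(g).upper() for g in query_genes]
    background = [f"BG{i:05d}" for i in range(max(0, n_genes - len(query)))]
    genes = query + background
    out = []
    truth: dict[str, set[str]] = {}
    for s in range(n_sets):
        name = f"study{s + 1}"
        cols = [f"{name}_case{i}" for i in range(n_per_class)] + [
            f"{name}_ctrl{i}" for i in range(n_per_class)
        ]
        labels = pd.Series(["case"] * n_per_class + ["control"] * n_per_class, index=cols)
        X = rng.normal(8.0, noise_sd, size=(len(genes), len(cols)))
        n_de_q = int(round(de_frac_of_query * len(query)))
        de_q = set(rng.choice(query, size=n_de_q, replace=False)) if n_de_q else set()
        de_bg = set(rng.choice(background, size=min(30, len(background)), replace=False))
        signs = {g: rng.choice([-1.0, 1.0]) for g in de_q | de_bg}
        for i, g in enumerate(genes):
            if g in signs:
                X[i, :n_per_class] += signs[g] * effect
        out.append((name, pd.DataFrame(X, index=genes, columns=cols), labels))
        truth[name] = de_q
    return out, truth


def simulate_gmt(
    universe: list[str],
    n_sets: int = 10,
    set_size: int = 30,
    planted_query: list[str] | None = None,
    planted_set_name: str = "PLANTED_NEURONAL_SYSTEM",
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene sets over a universe, optionally one planted to overlap
    a query list heavily (for enrichment-recovery tests)."""
    rng = np.random.default_rng(seed)
    universe = [str(g).upper() for g in universe]
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        sets[f"RANDOM_SET_{i:02d}"] = set(rng.choice(universe, size=min(set_size, len(universe)), replace=False))
    if planted_query:
        members = {str(g).upper() for g in planted_query}
        pad = [g for g in universe if g not in members]
        extra = set(rng.choice(pad, size=min(set_size, len(pad)), replace=False))
        sets[planted_set_name] = members | extra
    return sets


# ---------------------------------------------------------------------------
# Packaged published-candidate fixture
# ---------------------------------------------------------------------------

def _fixture_path():
    return resources.files("doublehit") / "data" / "ftdals_candidates.tsv"


def table1_fixture(
    include_distractors: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The published FTD-ALS double-hit candidate list as pipeline inputs.

    Returns (snp_table, dmp_table): the 30 published SNP rows (plus, when
    requested, synthetic distractor rows each violating exactly one filter
    criterion) shaped as a GWAS summary table, and the matching per-probe
    methylation records (probe id, BH-adjusted p, island relation, t).
    Genomic coordinates in the fixture are synthetic placeholders laid out
    so that no SNP coincides with a probe CpG site.
    """
    with _fixture_path().open() as fh:
        raw = pd.read_csv(fh, sep="\t", comment="#")
    raw["distractor_reason"] = raw.get("distractor_reason", pd.Series(dtype=str)).fillna("")
    if not include_distractors:
        raw = raw.loc[raw["distractor_reason"] == ""]
    snps = pd.DataFrame(
        {
            "rsid": raw["rsid"],
            "chromosome": raw["chromosome"],
            "position": raw["snp_position"].astype(int),
            "gwas_p": raw["gwas_p"].astype(float),
            "func_class": raw["func_class"],
            "consequence": raw["consequence"],
            "cadd": raw["cadd"].astype(float),
            "gene_symbol": raw["gene_symbol"],
            "strand": raw["strand"],
            "distractor_reason": raw["distractor_reason"],
        }
    ).reset_index(drop=True)
    dmp = (
        pd.DataFrame(
            {
                "gene": raw["gene_symbol"].astype(str).str.upper(),
                "probe_id": raw["probe_id"],
                "chromosome": raw["chromosome"],
                "position": raw["probe_position"].astype(int),
                "p_bh": raw["dmp_p_bh"].astype(float),
                "island_relation": raw["island_relation"],
                "t_stat": raw["t_stat"].astype(float),
            }
        )
        .drop_duplicates("probe_id")
        .reset_index(drop=True)
    )
    return snps, dmp
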