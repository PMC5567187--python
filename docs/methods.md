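# Methods

This note records the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Preprocessing cascade

The cascade runs in a fixed, logged order: batch adjustment → probe
filtering → imputation → zero-mean normalization. Batch adjustment runs
first, on the full probe set, so that filtering statistics (e.g.
missingness interacting with batch) cannot leak batch structure
downstream.

**Batch adjustment** is a parametric empirical-Bayes location/scale model.
Each probe is standardized against a batch-design fit (weighted grand
mean, pooled residual variance); per-batch, per-probe additive (γ) and
multiplicative (δ²) effects are estimated and shrunk toward batch-level
priors — normal for γ, inverse-gamma for δ², hyperparameters by method of
moments across probes — by the usual iterative conditional scheme, then
the data are back-transformed. Missing cells are tolerated (all moments
use available cells) and stay missing. A single batch is a no-op; a batch
with fewer than two samples is an error naming the batch; a constant probe
is adjusted by location only (scale shrinkage is skipped and logged). The
adjustment operates on the beta scale by default; beta values are bounded,
so a logit-scale variant is a defensible alternative, but location-shift
batch effects on probes away from the bounds are near-additive on both
scales and the beta scale keeps the output directly interpretable.

**Probe filtering** applies six rules in order — missingness > 20 % of
samples, X/Y chromosome, probe-SNP MAF > 0.1, control probe, blacklisted
("spurious") probe, non-genic region (everything outside TSS1500, TSS200,
5'UTR, 1st exon, body, 3'UTR) — with the first failing rule claiming the
probe, so the per-rule removal counts plus the retained count always equal
the input count. Both fraction thresholds are strict: a probe at exactly
20 % missingness or MAF exactly 0.1 is retained. The blacklist and the SNP
flags are consumed from the annotation, never recomputed.

**Imputation** is K-nearest-neighbour with K = 3 over probes. Distances
between partially observed probes are Euclidean over the shared observed
samples rescaled by √(total/shared), making distances computed over
different overlap sizes comparable; no metric is canonical for partially
observed pairs, and this rescaling is the minimal-assumption choice (it
equals the plain Euclidean distance for fully observed pairs). For a
missing cell the K nearest probes *observed at that sample* donate their
unweighted mean; if none qualifies the probe's own mean is used (logged);
a fully missing probe is an error.

**Zero-mean normalization** centers each probe across all samples, cases
and controls together, so that the sign convention holds globally:
values above 0 are relative hypermethylation, below 0 hypomethylation.

## Differential methylation

Per probe, a pooled-variance two-sample Student t (df = nₐ+n_b−2),
two-sided p from the t distribution. Degenerate probes: zero pooled
variance with equal means gives t = 0, p = 1; with unequal means the p is
set to the smallest positive double and flagged. Welch's correction is
available as an option but pooled variance is the default, matching the
plain two-sample design. Correction is Benjamini-Hochberg step-up across
the retained probes (the test count is exposed as `n_tests`); correcting
across probes rather than unique genes is the conservative reading when a
probe can annotate several genes. Direction is the t sign; a probe mapping
to k genes contributes k entries to the significant-gene set, which is why
unique-gene counts can exceed probe counts. Single-gene reports (e.g. for
the known FTD markers GRN, MAPT, C9orf72) are lookups within the
genome-wide result — no re-correction.

## Class discovery

Samples are clustered by average-linkage agglomerative clustering on
Euclidean distances over the significant-probe submatrix (both linkage
and metric configurable; nothing in the analysis constrains them, and
average/Euclidean is the common default for methylation arrays). The tree
is cut at each candidate k (default 2–5) and the Davies-Bouldin index —
mean over clusters of the worst (Sᵢ+Sⱼ)/d(cᵢ,cⱼ) ratio, Sᵢ the mean
member-to-centroid distance — selects k★ (ties to the smaller k;
coincident centroids are an error; a DB curve flat within 1 % of its range
is flagged as structureless). Cluster/diagnosis association is a
two-sided Fisher exact test after collapsing to 2×2: the cluster most
enriched for the target diagnosis versus the rest. The separation
p-value's original derivation is not fully specified upstream; the Fisher
formulation is this package's definition and is validated only against
its own calibration and planted-structure tests.

## Overrepresentation framework

One code path serves tissue specificity, brain regions, pathways, and the
GWAS/DMP overlap: the exact hypergeometric upper tail P(X ≥ x) (log-space
stable), BH-corrected across exactly the sets tested in one call, because
each resource (25 tissues, 26 regions, 22 curated sets, …) was corrected
separately in the reference analysis. The universe size M is always
supplied explicitly (16,115 for a GTEx-style atlas; 25,318 for an
HG19-gene pathway background; configurable), never inferred from the data,
because reported overlap p-values are meaningless without a declared
background. Specificity sets are built per tissue by a tissue-vs-rest
pooled t-test, BH across genes within the tissue, and a two-sided
linear-scale fold rule (FD > 1.5 or FD < 1/1.5, strict): "specific" covers
both enriched and depleted genes, and no exclusivity is imposed across
tissues. Expression must be nonnegative linear-scale; fold differences on
signed or shifted scales are refused rather than silently misinterpreted.

## Double-hit integration

SNPs with unadjusted p < 0.05 (strict) define the GWAS gene set;
blacklisted genes are dropped. The raw GWAS×DMP gene overlap is tested
hypergeometrically against the declared genome universe. The candidate
filter then requires, per SNP: p < 0.05, exonic/splicing, nonsynonymous or
stop-gain, CADD > 15 (all strict), and ≥ 1 significantly differentially
methylated probe in the mapped gene. Each surviving SNP yields one
candidate row carrying the gene's best probe (smallest P_BH), the
direction from the t sign, and min(p) over *all* of the gene's SNPs in the
unfiltered table (intronic/intergenic included — association evidence is
not restricted to the deleterious SNP). Functional class, consequence, and
CADD are input columns: variant annotation is an external-database lookup,
out of scope by design. SNP/probe colocalization checks whether a SNP
falls in a probe's 2-bp CpG site (1-based inclusive; window configurable;
chr-prefix naming normalized).

## Co-expression network

Spearman ρ (average ranks for ties) between candidate genes' expression
profiles; two-sided p from t = ρ√((n−2)/(1−ρ²)). An edge requires |ρ| >
0.6 *and* p < 0.001, both strict and both on unadjusted p (no correction
is applied to pairwise network tests). Constant genes are dropped with a
warning; isolated nodes are removed by default (the network reports only
co-expressed genes) with a flag to keep them. Degree — the incident-edge
count, cross-checked against an independent count before reporting — ranks
genes for prioritization.

## Validation meta-analysis

Each validation study is analysed independently: a per-gene moderated t
with empirical-Bayes variance shrinkage s̃²ᵍ = (d₀s₀²+dᵍs²ᵍ)/(d₀+dᵍ) and
d₀+dᵍ degrees of freedom, the prior (d₀, s₀²) fitted by method of moments
on the log sample variances (digamma/trigamma relations; a spread at or
below pure sampling noise yields the d₀ = ∞ full-pooling limit, logged).
The implementation is authored from the closed-form definition so the
stage is testable standalone; it reproduces the R reference implementation
to machine precision on shared fixtures, and the d₀ = 0 limit equals the
ordinary pooled t. BH runs over each study's own assayed-gene count —
never a global meta-correction — and a query gene is "validated" by a
study when significant there at P_BH < 0.05. Absence from a platform is
recorded as not-assayed, distinct from not-DE. Validation requires
significance only, not direction concordance with methylation; the
stricter rule (hyper ↔ down-regulated, hypo ↔ up-regulated) is available
as the `require_direction` option of `validate_genes` but off by default,
since the reference validation grid imposes none. Genes are ranked by validating-study count,
ties by best P_BH. Duplicate gene symbols within a study collapse to the
max-variance row.

## Synthetic data: what it emulates, and what it does not

Beta values are generated on the logit scale around per-probe baselines
from a bimodal low/high-methylated mixture, inverse-transformed and
clipped — preserving [0, 1] support and the heteroscedasticity
(variance shrinking near the bounds) of real arrays. Planted differential
probes shift the case mean by ±Δβ (default 0.15); batch b adds a beta-scale
location offset (default 0.05) and inflates logit-scale noise
(scale 1.1 per batch); missingness is uniform over cells (the data give
no missingness mechanism, so missing-at-random uniform is the default
assumption). Per-probe noise defaults to SD 0.05 on the beta scale — a
free parameter, not an estimate, since no per-probe variances are
published. The annotation plants targets for every filter rule and gives
the three FTD marker genes their real probe counts (GRN 12, MAPT 1,
C9orf72 4). GWAS tables plant risk genes with association-enriched,
deleterious exonic SNPs; expression atlases plant tissue-specific
elevations; a block variant plants equicorrelated gene cliques for
network tests; validation studies plant DE in a random share of the query.

What passing tests therefore show: the statistics are implemented
correctly (oracle equivalence), calibrated under their own null
(uniform p-values), and powered under the planted conditions. What they do
not show: robustness to cell-composition confounding, probe
cross-hybridization, LD structure among SNPs, correlated probes within
CpG islands, or platform normalization artifacts — none of which the
generators model. Default problem sizes (1,000 probes, 100 samples,
1,000 SNPs, 4 validation studies) are desk-scale choices that keep a full
run in seconds while leaving every stage's statistics in their asymptotic
working range.

## Numerical choices

- Hypergeometric tails and BH run in log/stable space via SciPy and
  statsmodels; BH inputs outside (0, 1] are rejected, not clamped.
- The EB batch iteration stops at relative change < 1e-6 (max 500
  rounds); degenerate scale-spread (no variance across probes) falls back
  to location-only shrinkage.
- The trigamma inverse for the variance-prior fit uses Newton iteration
  from the standard 0.5 + 1/y start, tolerance 1e-10.
- Tie-breaks: linkage follows SciPy's deterministic merge order; DB ties
  select the smaller k; degree ties sort by gene symbol; the best probe
  per gene ties on (P_BH, probe id).
- Zero-variance contrasts produce flagged sentinel results (p = 1 or the
  smallest positive double) rather than NaNs.

## Known limitations

- No covariate adjustment (age, sex, cell composition) in the primary
  contrast; the upstream design this mirrors models none.
- The candidate filter keys on gene symbols; symbol drift between the
  GWAS annotation and the methylation annotation silently reduces
  overlap (a warning reports passing SNPs whose genes lack probes).
- The network stage tests each edge marginally; no graphical-model or
  topology-aware inference.
- Exact discrete tests (hypergeometric, Fisher) are conservative by
  construction; their p-values are super-uniform for coarse table
  margins, which matters when interpreting near-threshold enrichments.
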