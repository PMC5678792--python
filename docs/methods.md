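# Methods

This note records the statistical procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Pathway activity scores

A process's per-sample activity is the first principal component of its
gene-by-sample log2 expression block. Gene rows are centered and, by
default, scaled to unit variance before the SVD so that a single
high-variance gene cannot dominate the component (`scale=False`
restores covariance-PCA). The PCA is fitted jointly on the cancer and
control samples of a cohort: the contribution regression consumes both
groups' scores on one scale, and per-group fitting would break that
comparability. A single-gene process passes through as its centered
(optionally scaled) row with `variance_explained = 1`.

The PC sign is arbitrary, so the returned score is anchored to
correlate non-negatively with the mean expression profile of the genes
used; higher expression of the process's genes therefore always means a
higher activity score, and downstream increased/decreased calls are
orientation-stable. Genes absent from the matrix are dropped with a
logged warning, never imputed; a process with no genes present, or with
a zero-variance gene row, is an error.

Group comparisons of a score use Welch's two-sample t; the *change* of
a process in a cohort is the cancer-mean minus control-mean of its
score. Because scores are centered per cohort, changes are comparable
across cohorts on the standardized scale.

## Differential expression

A gene is called up (down) when its signed linear fold change exceeds
+1.5 (is below −1.5) **and** its two-sided P is at most 0.05. Values
are stored as log2, so group means are averaged after inverse transform
(2^x) and the ratio is reported as r when ≥ 1 and −1/r otherwise,
making the ±1.5 cutoff symmetric. Computing the ratio on the linear
scale is a deliberate reading of the ±1.5 convention; the exact
transform is `mean(2^x_cancer) / mean(2^x_control)`.

The t statistic is the empirical-Bayes moderated t: per-gene residual
variances s²_g (pooled two-group, d = n₁+n₂−2 df) are shrunk toward a
prior s₀² with d₀ df,

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
    t_g = (mean₁ − mean₂) / (s̃_g · sqrt(1/n₁ + 1/n₂)),  df = d₀ + d.

The hyperparameters are estimated by matching the first two moments of
log s²_g using the digamma/trigamma identities for the log of a scaled
chi-square; d₀ comes from a Newton inversion of the trigamma function
and is infinite when the observed spread of log-variances does not
exceed chi-square sampling noise (all genes then share s₀²). This is
the canonical published estimator re-implemented; a frozen fixture in
the test suite pins t and P values, and the prior (d₀, s₀²), to the
reference Bioconductor implementation at 1e-9.

Genes with zero pooled variance are excluded from hyperparameter
estimation and then shrunk like any other gene; a gene with zero
variance *and* zero mean difference gets t = 0, P = 1. No
multiple-testing correction is applied by default — calls threshold the
raw per-gene P at 0.05 — because the fold-change gate already controls
the call set sharply; a Benjamini–Hochberg option exists
(`DEConfig(bh_correction=True)`).

## The contribution regression

For product pathway p with reactant routes r₁…r_M the model is

    yₚ = β₀ + α₀·ID + Σ_m β_m x_m + Σ_m α_m (x_m:ID) + ε,

fitted by OLS with classical SEs and per-term two-sided t tests on
n − (2M+2) residual df. A reactant is classified *increased* when its
interaction P ≤ 0.05 with α̂_m > 0, *decreased* when significant and
negative, otherwise *none*. The 0.05 level is applied per term without
multiplicity correction, matching a per-coefficient reading of the
fitted model; heteroskedasticity-robust (HC3) SEs are available behind
a flag but are not the default.

When driven from expression data (`run_product`), the product score
pools the genes of all product processes, each reactant route pools its
synthesis and uptake processes into one predictor, and all scores are
standardized (unit sample SD) before fitting so coefficients are
comparable across reactants. Standardization is a package choice: it
changes coefficient scale, never t statistics or classifications.

Rank-deficient designs raise an error naming the collinear columns
(located by pivoted QR). One packaged route is *exactly* collinear by
construction: the cytidine-uptake and uridine-uptake transporter sets
are identical as printed in the source table, so the pyrimidine route
cannot be fitted with both salvage reactants present on data where each
route is scored separately; callers must merge or drop one route. This
is encoded as printed rather than silently merged. Similarly, the
thioredoxin/catalase antioxidant group lists CAD among its genes as
printed, although CAD is a pyrimidine-synthesis enzyme elsewhere in the
registry; the row is reproduced verbatim.

## Correlations and conditional co-expression

Cohort-level associations use plain Pearson r with the two-sided P from
t = r·sqrt((n−2)/(1−r²)), requiring ≥ 3 cohorts; subsets of cohorts
(e.g. kidney-cancer subtypes that share one external survival figure)
can be pre-averaged into a single point via `merge_cohorts`. External
per-cohort vectors such as 5-year survival rates are user-supplied
inputs, not package data. The ROS-burden proxy is the per-cohort change
of a seven-gene proteasome set score (PSMB5, PSMD1, PSMD2, PSMD11,
PSMD14, PSME3, PSME4).

Conditional co-expression operationalizes "samples with constant
nucleotide-synthesis level" as the central quantile band (default
[0.4, 0.6]) of the anchors' PC1 composite (default anchors PPAT, CAD);
the band width is configurable, and a full band (0, 1) degenerates to
plain all-sample correlations. Within the band, each anchor gene is
correlated with each target gene; exported cells with P above the
threshold are blank. Conditioning on the anchors necessarily restricts
the anchors' own variance, which attenuates their correlations — this
is the stated procedure, implemented as stated; residualizing targets
on the composite would be the alternative and is deliberately not the
default. A band retaining fewer than 10 samples is an error suggesting
a wider band.

## Synthetic data

The generator mirrors the model the pipeline fits. Latent reactant
activities are z_m = δ_m·ID + N(0,1) (unit within-group variance, so
planted coefficients live on the standardized activity scale); the
product activity is the group-specific linear combination with noise sd
σ; each gene of a process emits loading·latent + baseline + N(0, τ²) on
the log2 scale, with loadings drawn positive (default U(0.8, 1.2)),
baselines U(4, 10), and genes shared by several processes loading on
the mean of their latents. Background genes are baseline plus noise.
Defaults: 30+30 samples (the cohort inclusion rule requires at least
10+10), σ = 1, τ = 0.3, 50 background genes — a deliberately clean
regime in which pathway signal dominates gene noise.

Emission is Gaussian on the log2 scale rather than negative-binomial
counts: the statistics operate on processed continuous expression, and
a counts mode is out of scope. One integer seed drives all draws
through deterministically spawned substreams, so an identical
configuration reproduces a fixture byte for byte; the shipped demo
fixture (two cohorts of 12+12, seed 7) is regenerated and checked
against its on-disk bytes in the tests. The generator accepts τ = 0
and degenerate loading/baseline ranges so noise-free identities are
testable.

What passing recovery tests on this generator does **not** show:
robustness to batch effects, library-size variation, tumor-purity
mixtures, count noise at low expression, or correlated background genes
— none of which are simulated. Results on real tissue cohorts inherit
all of those complications.

## Benchmark sizes and numerical choices

The packaged statistical checks use: 2000 replicate null cohorts
(15+15 samples, two reactants, five genes per process) for the type-I
error of the interaction test; 200 replicates at 200+200 samples for
recovery of a planted α = 0.8 (fitting the emitted latent activities,
where the estimator is unbiased — fitting PCA scores instead attenuates
estimates by the score/latent scale factor but preserves test validity
and classification); 1000-gene cohorts at 30+30 for DE recall (ten
four-fold planted genes) and the null flagged fraction. These sizes
give Monte-Carlo standard errors well inside the asserted bands while
keeping the whole suite and the acceptance script fast.

Other numerics: trigamma inversion by Newton iteration from the 0.5+1/x
start with closed-form guards at the extremes; PC1 via LAPACK SVD
(deterministic); group blocks forced C-contiguous before reduction so
results are bit-identical regardless of how the caller assembled the
frame; ties in the sign anchor (exactly zero correlation) resolve to
orientation +1; identical group distributions short-circuit Welch's t
to t = 0, P = 1 rather than 0/0.
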