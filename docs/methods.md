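# Methods

This note documents the models, rules and numerical choices behind
`crckit`, and what the synthetic validation does and does not show.

## Burden and hypermutation

Variants enter the pipeline pre-annotated (MAF-dialect tables,
1-based fully-closed coordinates). Hard filters keep a record iff
VAF ≥ 0.08 **and** depth ≥ 8 **and** alt reads ≥ 2 — all boundaries
inclusive, matching the wording of the protocol they come from. TMB
counts only the eight coding classes
(`Frame_Shift_Del/Ins`, `In_Frame_Del/Ins`, `Missense_Mutation`,
`Nonsense_Mutation`, `Nonstop_Mutation`, `Splice_Site`; exact,
case-sensitive string match) and excludes variants with 1000 Genomes or
ExAC allele frequency strictly above 0.05. Missing population
frequencies count as 0 — absence from the databases is treated as
evidence of rarity, so such variants are retained.

The TMB denominator is a fixed panel size in Mb (`panel_size_mb`,
default 35, a typical whole-exome target). Per-sample callable
territory is not modelled; set the parameter to the actual panel for
real data. Hypermutation is TMB ≥ 10 muts/Mb (inclusive), and the
MSI-H/POLE attribution is a plain four-way partition of the
hypermutated set. Cohort summary percentages round half-up to one
decimal.

## Signature refitting

Eligible SNVs (missense, nonsense, nonstop, RNA, silent, splice-site,
translation-start classes) are tabulated into the standard 96
pyrimidine-centered substitution classes; purine-reference records are
reverse-complemented. Catalogs from exome capture can be rescaled by a
32-entry genome/exome trinucleotide abundance ratio before fitting
("exome2genome"). The package does not bundle genome-derived abundance
tables; a unit (identity) ratio is the default and users supply
measured ratios for their capture design.

Refitting solves, per sample on its 96-class fraction vector `p`,

    min_{w >= 0}  0.5/96 * ||p - R w||^2 + alpha * ||w||_1

with reference matrix `R` column-normalized to 1. The penalty is chosen
per sample by 5-fold cross-validation over the 96 contexts on a
30-point log-spaced grid spanning 4 decades below the data-derived
`alpha_max`, with the one-standard-error rule (largest penalty within
one SE of the CV minimum) — the refitting approach this follows leaves
penalty selection to the implementation, and 1-SE favours sparse,
stable supports. Weights are rescaled to mutation counts; exposures
below 1e-6 of the sample total are zeroed so "active" is crisp for the
prevalence rule (keep signatures active in **strictly more than** 1 %
of fitted samples). Samples with fewer than 20 SNVs are excluded and
flagged, never silently dropped.

For downstream clustering the exposure matrix is converted to
per-sample contribution fractions (`exposure_fractions`), the
compositional view in which signature activity is conventionally
compared across samples; this removes residual mutation-burden leakage
from the non-hypermutated feature space.

## Consensus-NMF subtyping

Hypermutated samples are assigned to the HM subtype before clustering
so that burden does not dominate the factorization. The feature matrix
concatenates min-max-scaled signature fractions with binary lesion
indicators, drops zero-variance columns, and applies no block
weighting (an optional weight is deliberately not defaulted; the
protocol describes none).

For each K in 2…6, ten NMF runs start from independent random
non-negative initializations. The objective is the generalized
Kullback–Leibler divergence with multiplicative updates (the classic
consensus-NMF algorithm; the commonly used R implementation defaults to
it), 2000 max iterations, 1e-6 tolerance; non-convergent runs are
logged and still used. Each run labels a sample by its **nearest basis
component in cosine similarity** — a deterministic function of the
sample's own profile, so identical samples always co-cluster even when
the factorization is degenerate. The consensus matrix holds
co-clustering fractions over runs (entries are multiples of 1/n_runs);
final labels come from average-linkage hierarchical clustering of
1 − consensus cut at K, and K is chosen as the cophenetic-correlation
argmax (ties to the smaller K) unless overridden — analyses reproducing
the published subtyping fix K = 3.

Cluster naming is unsupervised and permutation-invariant: the cluster
with the lowest mean feature-row sum is genome-stable (GS); of the two
remaining chromosomal-instability clusters the one with the higher
10q11.21-amplification fraction is CIN-HR, the other CIN-LR. Survival
is deliberately not used for naming, so prognostic contrasts between
subtypes remain testable rather than built-in.

## Immunoediting and immunogenicity reduction

Per-context cohort rates use only samples with ≥ 10 non-silent
mutations: `B̄_s` is the fraction of non-silent mutations in context
`s` bearing at least one predicted neoantigen ("immunogenic" counts
mutations, not peptides, to match the per-mutation denominators of the
score), and `N̄_s` is the non-silent/silent count ratio with add-one
smoothing of empty silent bins. A sample's silent mutations give
`N_pred = Σ N̄_s(m)` and `B_pred = Σ N̄_s(m)·B̄_s(m)`, and

    I = (B_obs / N_obs) / (B_pred / N_pred).

Samples with no silent mutations, no non-silent mutations, or zero
predicted quantities are flagged not-assessable rather than scored.
Z-scores use the assessable subpopulation (mean 0, SD 1 by
construction); immunoedited means Z < −1.645, strictly.

HLA-LOH needs calls at all three class-I loci (A/B/C); per locus,
allelic imbalance is p < 0.01 and LOH additionally requires allele copy
number < 0.5 with the CI upper bound strictly below 0.7. The IR
composite is the OR of NPG mutation, HLA-LOH and immunoediting;
not-assessable components contribute "false" rather than excluding the
patient, mirroring how partial-assay denominators coexist with
full-cohort composites. The TNB high/low cut defaults to the cohort
median (no published value exists for it).

## Mitochondrial copy number

`R = (purity·ploidy + (1−purity)·2)/2` and `m = (r_m/r_n)·R`; `R` is 1
for any purity at ploidy 2 and tends to 1 as purity vanishes. MT
variants at rCRS positions 310, 523, 524 and 3107 are removed
(homopolymer/placeholder sites prone to misalignment); the filter is
idempotent and touches nothing else. The mScore-high group is the top
10 % **by rank** with ties broken by sample id (the published split is
the top decile; rank-based splitting makes the group size exact and
deterministic). An explicit best-cutoff scan is available as an option:
decile candidates, log-rank statistic maximized, each group ≥ 10 % of
the cohort. qPCR uses 2^−ΔΔCt with the calibrator defaulting to the
sample with median ΔCt (no calibrator is published); the WES cutoff
transfers to the qPCR scale through OLS on paired samples (≥ 10 pairs
required).

## Clinical statistics

Pathway status per sample is the precedence rollup
oncogenic > VUS > wild-type over member-gene alterations ("unknown"
oncogenicity counts as VUS). Driver-gene consensus keeps genes reported
by ≥ 2 tools, invariant to list order and duplication. Survival uses
lifelines: product-limit curves with the multivariate log-rank test,
and Cox partial likelihood (Efron ties) with categorical covariates
expanded to indicators against their first level; rows with missing
covariates are dropped and counted. Pairwise associations use Yates-
corrected chi-square for 2×2 tables (Fisher's exact when any expected
cell is below 5), plain chi-square for larger tables, two-sided t-tests
for continuous-vs-binary, and report Benjamini–Hochberg adjusted
p-values alongside raw ones. Constant variables are skipped with a
flag.

## Synthetic cohorts: what they emulate and what they do not

`simulate_cohort` draws, per sample: a subtype (default 7 % HM,
31/31/31 across CIN-HR/CIN-LR/GS); a mutation count (log-normal,
medians 600/150/120/80 for HM/CIN-HR/CIN-LR/GS, chosen so the HM gate
at 35 Mb separates cleanly while non-HM burdens overlap); 96-class
contexts from subtype-specific mixtures over a deterministic synthetic
6-signature reference (sparse-Dirichlet profiles, pairwise cosine
< 0.5 — a stand-in, carrying no biological meaning); silent status at
1:3 odds; neoantigen flags Binomial(0.15) on non-silent mutations;
lesions Bernoulli with 10q11.21 amplification at 0.70/0.08/0.05/0.10
across CIN-HR/CIN-LR/GS/HM and each CIN cluster enriched for a distinct
half of ten background lesions (subtype-defining lesion matrices are
differentially altered between clusters); purity Beta(6, 2.5), discrete
ploidy weighted toward 2–3; nuclear reads ~5e7 with a log-normal true
mScore (median 0.01, σ 0.5) inverted through R to read counts; HLA
calls with a 10 % LOH pattern and 5 % missing-locus rate; and
exponential survival with log-hazards −0.69/+0.69/0/0 by subtype,
+0.25 per stage step, log(1.84) for the top mScore decile, independent
exponential censoring (rate 0.01/month) plus administrative censoring
at 120 months — exponential rather than Weibull so closed-form sanity
checks exist. Randomness is hierarchical (one substream per sample), so
growing a cohort never perturbs existing samples.

`fixture_from_counts` is fully deterministic: requested flag counts are
assigned to the earliest samples (overlaps first), TMB is spread
linearly over [10, 50] for hypermutated and [0.5, 9] otherwise and
realized as actual mutation rows, and MT-variant carriers receive one
non-blacklisted plus one blacklisted variant while non-carriers receive
only blacklisted ones.

The simulator does not model read-level noise, germline variation,
linkage between lesions, context-dependent neoantigen rates,
subclonality, or panel coverage gaps. Passing recovery tests therefore
establishes that the pipeline's inference is correct **under its own
assumptions** — well-separated mixtures, independent lesions,
proportional hazards — not that real cohorts satisfy those assumptions.

## Validation sizes

The test suite and acceptance script use problem sizes chosen to make
the statistical assertions sharp while running in minutes on one core:
1000-tuple formula oracles (agreement to 1e-12), 10,000-draw Z-gate
calibration (5 % ± 0.7 pp), 50 replicates of 2000-mutation 60/40
mixtures (±10 pp recovery in ≥ 90 %), a 300-sample cohort for subtype
recovery (ARI ≥ 0.8; observed ≈ 0.9–0.96 across seeds), a planted
hazard ratio of 2 at n = 1000 (estimate within [1.7, 2.3]) and null CI
coverage over a few hundred simulations at n = 250 (≈ 95 % ± 3 pp).
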