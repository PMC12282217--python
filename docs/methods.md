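# Methods

## Data model and transforms

Profiles are samples × features matrices tagged with a unit
(`relative_percent`, `proportion`, `count`, `rpk`) and a feature level
(kingdom … SGB, or pathway). Taxonomic input follows the pipe-delimited
rank-string dialect (`k__…|p__…|…|t__SGB…`); each row is assigned to
exactly one level by the deepest rank its string reaches, so every level is
analysed separately and nothing is double-counted. Pathway tables keep only
unstratified rows; UNMAPPED/UNINTEGRATED are dropped by default.

Because marker-gene profilers report relative abundance, count-requiring
engines receive *approximate counts*: relative abundance × post-QC library
size, rounded half-to-even where an integer requirement exists (half-even
because it is unbiased over many cells). Approximate counts overestimate
per-taxon read numbers; they are a stand-in, and the method-1/method-2
comparison quantifies how much the choice matters.

Shared numerical conventions:

- **Pseudo-counts** are applied on each table's native scale: 0.0001 on
  percent-scale taxa and 1 on RPK pathways, before CLR.
- **Prevalence filter**: keep features with abundance strictly greater
  than a detection floor (0 for counts, 10⁻¹⁵ for proportions — the
  latter so that exact floating-point zeros never count as "present") in
  at least ⌈0.1 n⌉ samples. No renormalisation afterwards; the filter is
  idempotent and applied once per level, shared by all engines.
- **Rarefaction** subsamples without replacement (multivariate
  hypergeometric) to the minimum retained depth; samples below depth are
  dropped with a logged warning. Used only for alpha diversity, where the
  strong depth–richness correlation would otherwise dominate.

## Synthetic cohorts

The generator emulates the study design rather than any particular
dataset: log-baseline abundances are drawn i.i.d. normal with σ = 2, which
gives the strongly uneven, dominance-heavy compositions of real oral
profiles (top share ≫ 10× the median share). Per subject *i* and feature
*f*, the sample's log-abundance is

λ_f + Δ_f·1[case] + β_BMI·(BMI_i − 27)·1[f ∈ B] + u_{i,f} + ε_{s,f},

closed by softmax and realised as multinomial counts at a log-normal
library size (log-sd 0.5 around a mean of ≈375 000 reads, times a
`depth_group_shift` confound on cases). The subject effect u (σ = 0.6) is
shared across a subject's two time points — it is what makes matched
samples more similar than unmatched — and ε (σ = 0.6) is fresh per sample.
The multinomial layer carries sampling noise only; all biological
overdispersion enters through u and ε, keeping the two separable for
oracle checks. These default magnitudes were fixed once as qualitatively
realistic for shotgun oral profiles; the sparsity of real data is matched
only qualitatively (real zero patterns are more structured).

Ground-truth effects are either generative (Δ_f = log2FC·ln 2 on features
drawn from the 55th–90th percentile of baseline abundance, mirroring the
sub-percent abundance of real differential taxa) or implanted post hoc by
multiplying target-group counts of chosen features by a fold change
(spike-in style). Both routes record the signed log2 fold changes as
`SimTruth`. Implantation happens on the count scale before any closure, so
compositional spillover onto other features is real and intended.

The default roster reproduces the study's bookkeeping exactly: 24 paired +
3 early-only + 1 late-only controls and 9 paired + 2 early-only cases,
i.e. 27/25 control samples at the early/late time points.

## Diversity

Shannon is in nats (the index base is a convention; evenness is Pielou's
J = H/ln S, defined as 0 for single-feature samples). Beta diversity is
the Aitchison distance: Euclidean distance between CLR rows. PERMANOVA
uses the standard pseudo-F on squared distances with add-one permutation
p-values (never reports p = 0); group tests permute labels freely, while
time-point tests restrict permutations to within-subject swaps. Every
permutation test has an exhaustive mode that enumerates all label
rearrangements, used as the oracle for n ≤ 8. PERMANOVA is *gated* by a
PERMDISP homogeneity test (distances to group centroids in
principal-coordinate space, permutation F, negative eigenvalues handled
with the usual sign correction): the location test is reported as
trustworthy only when dispersions do not differ at 0.05.

Distance comparisons (matched vs unmatched, stability by group) default to
the two-sided rank-sum test; an omnibus-normality gate can switch the
group comparison to a t-test, and the selection is logged. All-tied inputs
return p = 1 by convention.

## The six engines

These are engine *families* — native implementations of six methodological
archetypes, not re-implementations of the tools that inspired them. Fixed
choices:

- **ast_lm**: OLS per feature; proportions → arcsine-√, counts → CLR with
  a half-count pseudo. Subject pairing enters as fixed effects (the one
  uniform contract tractable across all six engines; true random-effect
  fits are deliberately out of scope and this is an acknowledged
  approximation).
- **clr_lm_bias**: CLR OLS; the median of all raw group effects estimates
  the shared compositional shift and is subtracted before testing, with
  standard errors unchanged. Proportion mode uses half the smallest
  nonzero proportion as pseudo; count mode imputes zeros as
  library-size-scaled half-minima of each feature's nonzero proportions.
- **loglinear_bias**: y = log(count+1); alternate per-feature OLS with a
  per-sample offset equal to the mean residual until convergence (tol
  10⁻⁸, ≤100 iterations), offsets centred each pass. The offsets are only
  identified up to the design projection, so the group contrast of the
  true sample biases appears as one shift shared by every feature's
  coefficient; it is removed by median-recentring (the taxa-specific bias
  step) before the Wald test — without this step the test is provably
  anticonservative. Holm–Bonferroni adjustment. Reported offsets add the
  bias back onto the group indicator, which is what makes them recover
  simulated sampling fractions at r > 0.99.
- **dirichlet_mc**: per instance, proportions ~ Dirichlet(counts + ½) per
  sample (the conventional uninformative half-count prior), CLR, plus
  per-sample scale noise N(0, γ²) with γ = 0.25 stated in log2 units
  (converted to nats internally); Wilcoxon rank-sum per feature — exact
  enumeration for n ≤ 8, mid-rank normal approximation otherwise — and BH
  within instance. Reported p and q are instance averages; the effect is
  the median standardised group difference. Instance-averaged p-values are
  conservative by construction (averaging over fresh scale noise pulls
  the distribution toward 0.5); this is the documented behaviour of
  expected-p aggregation, not a defect.
- **negbin_wald**: positive-counts median-of-ratios size factors
  (normalised to geometric mean 1; only ratios of factors are
  identified). Dispersions by method of moments on design residuals,
  debiased for the χ² sampling bias of the variance estimate, then
  geometric-averaged (weight 0.5) with a log-linear mean trend; the
  retained per-feature noise makes this the least conservative family.
  Wald statistic referred to t(n−p) — at cohort sizes of tens of samples
  the normal reference is measurably anticonservative. Effects are exactly
  invariant to rescaling one sample's counts except through the dispersion
  trend's dependence on the absolute count scale (≈10⁻³ on the log-effect
  scale).
- **reference_perm**: counts → posterior-mean proportions
  (Dirichlet + ½); stage 1 screens √-proportions with a reduced-model
  residual-permutation F test; the weaker-evidence half (largest p) forms
  the reference set — "taxa least likely to be differential". Stage 2
  tests √(proportion / reference total) with the same permutation scheme.
  q-values are the permutation FDR (expected null exceedances over
  observed exceedances at each F), clipped and monotonised along
  decreasing F. Residual permutation of the reduced model is used
  throughout; the permutation scheme the inspiring tool calls by name is
  not precisely published, and this is the closest standard construction.

All engines are equivariant to feature and sample reordering, and a
feature with zero residual variance reports effect 0, p = 1 (flagged
zero-variance policy) rather than an error.

## Consensus and evaluation

The vote counts engines with q < α (α = 0.05) per feature and level;
consensus requires ⌈threshold × engines-that-ran⌉ votes (engines that
errored shrink the denominator and are logged). Direction is the sign of
the summed significant-engine signs; a sign tie yields direction 0 with a
discordance flag — conflicts are reported, not suppressed, and direction
agreement is deliberately *not* required for a consensus call. Features
with 1–2 votes go to a supplementary tier. Method-1/method-2 comparison is
set algebra on consensus calls, stratified by vote count.

Tool metrics per dataset: the share of an engine's calls that are
consensus calls, the share of consensus calls the engine finds, and
min–max-normalised call counts; datasets without consensus calls are
excluded from medians (IQR by linear interpolation). Benchmarking against
implanted truth reports sensitivity, observed FDR (FP / max(1, calls)),
and sign accuracy over true positives.

Cohort summaries follow the clinical-table conventions: a normality gate
(omnibus test by default; a strict mode demands unanimous passes from four
tests) chooses mean±sd + t-test vs median (IQR) + rank-sum; 2×2
categorical tables get the exact hypergeometric test with odds ratio,
larger tables chi-square. Percentages print at one decimal,
rounded half away from zero, with a trailing ".0" stripped (so 14/28
prints as "50").

## Problem sizes and verification

The test suite validates each primitive against an independent oracle:
closed forms (CLR, AST, Shannon, Aitchison), exhaustive enumeration
(Wilcoxon n ≤ 8, 2×2 exact tests, PERMANOVA/PERMDISP n = 6, permutation
p-values), definitional brute force (BH/Holm), statsmodels (NB GLM
coefficients), and scikit-bio (PERMANOVA pseudo-F). Simulation-based
checks run at 60–200 features and 20–50 samples per group over 5–50 seeds
— sizes chosen so each property is measured with comfortable Monte-Carlo
margin while the whole suite stays quick; all are seeded and
deterministic.

Known limitations: subject pairing as fixed effects (no random slopes or
interactions), no phylogenetic diversity metrics, no zero-inflation model
in the count layer, and the generator's independence of features on the
log scale (real taxa co-occur). Null-calibration fine print: pooled
Kolmogorov–Smirnov checks treat features as independent, which
compositional data are not; the three linear-model engines are
KS-uniform under the null at the default conditions, while `dirichlet_mc`
(by the conservatism of instance averaging), `negbin_wald` (mild
mid-range conservatism under log-normal overdispersion), and
`reference_perm` (discrete permutation support at small permutation
counts) deviate conservatively — none inflates the false-positive rate,
as the suite asserts directly.
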