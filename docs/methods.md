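# Methods

`mitoscreen` implements the statistical core of an in-silico pipeline for
characterizing a mitotic kinase inhibitor and finding combination partners:
connectivity-map style matching of a compound's transcriptomic footprint,
kinome selectivity scoring, a per-patient mitotic-activity score, an
expression-stratified synthetic-lethal survival screen, and Chou–Talalay
combination-index analysis. Every analysis has a matching synthetic-data
generator with planted ground truth, so each method's operating
characteristics (recovery, calibration, exactness) are testable end to end.

## Synthetic cohorts

`generate_cohort` simulates paired tumor/normal expression with a single
latent per-patient factor standing for mitotic activity, `a_i ~ N(0, 1)`.

* **Expression.** In the tumor sample, each of the `n_signature_genes`
  signature genes and the anchor gene (GSG2 by default) follows
  `factor_loading * a_i + tumor_shift + N(0, noise_sd)`; all other genes,
  and all genes in the matched normal, are `N(0, noise_sd)`. Values live on
  an arbitrary continuous log-like scale: every downstream statistic is
  rank- or regression-based, so only relative structure matters and no count
  model is needed. Two signature genes therefore share the factor and have
  Pearson correlation `L² / (L² + σ²)` — the closed form the recovery tests
  check against.
* **Survival.** Exponential with hazard
  `λ₀ · exp(hazard_beta · a_i + sl_interaction_beta · I_i)`, where
  `λ₀ = ln2 / 1500 d⁻¹` (≈4-year baseline median, an oncology-cohort scale)
  and `I_i` indicates that the tumor expression of both the anchor and the
  designated partner gene fall below their cohort medians. The exponential
  baseline keeps the proportional-hazards assumption exactly true, so Cox
  recovery is checkable against the planted log-hazard. Censoring is
  independent and administrative: a `censor_rate` fraction of patients (in
  expectation) is censored uniformly before their event time.
* **Defaults** mirror the target application: 681 patients, a 126-gene
  signature, `factor_loading = 1`, `tumor_shift = 1`, `noise_sd = 0.5`,
  `hazard_beta = 0.5`, `censor_rate = 0.3`. Tests and the screens override
  sizes where a specific study condition is stated (e.g. 600 patients and
  `sl_interaction_beta = 0.9` for the SL-screen recovery runs).
* **What it does not emulate:** batch effects, tumor purity, non-gaussian
  expression tails, correlated censoring, clinical covariates, and
  multi-factor co-expression structure. Passing recovery tests show the
  estimators work under their own assumptions, not that real cohorts satisfy
  those assumptions.

Other generators: kinome tables with an exact planted hit count (hits
uniform below the threshold, the rest uniform in `[threshold, 120)` %Ctrl);
median-effect dose–response curves with gaussian noise added on the
`log10(fa/(1−fa))` scale (so noiseless data are exactly log-linear);
fixed-ratio or explicit-grid combinations whose fraction affected solves the
Loewe equation `d1/Dx1(fa) + d2/Dx2(fa) = combo_alpha`, making the planted
interaction multiplier equal to the downstream combination index by
construction; and fingerprint families on disjoint bit blocks whose shared
"core" bit probability is chosen so an expected `family_overlap` fraction of
each molecule's set bits is family-wide.

## Connectivity scoring

`weighted_ks_es` is the weighted Kolmogorov–Smirnov running-sum statistic:
set members at rank i increment by `|score_i|^w` (normalized over members),
non-members decrement by `1/(N−k)`; the enrichment score is the signed
maximum deviation. Because the running sum is piecewise linear between hits,
only the values immediately before and after each hit can be extremal; the
implementation evaluates exactly those candidates (O(k log k)) and is tested
for equality against a full position-by-position enumeration. Equal-magnitude
positive and negative extrema resolve to the positive one (within 1e-12, to
absorb summation-order rounding). If all hit scores are zero at `w > 0`, the
statistic falls back to unweighted steps rather than dividing by zero.

`wtcs` combines the up- and down-set enrichments as `(ES_up − ES_down)/2`
when their signs differ and 0 otherwise. The default weight exponent is 1
(the connectivity-map convention); `w = 0` gives the pure rank statistic,
invariant under monotone score transforms. `preranked_gsea` attaches an
add-one permutation p-value, `p = (1 + #{|ES*| ≥ |ES|})/(1 + n_perm)`, with
gene labels shuffled under the stated seed; p is floored at
`1/(n_perm + 1)` by construction. Candidate ranking reports wtcs and
Tanimoto side by side, sorted by wtcs with a compound-id tie-break, plus a
combined rank (mean of the two ranks) for the two-channel retrieval use
case; compounds lacking fingerprints get a missing Tanimoto, not an error.

## Kinome selectivity

`S(x)` is the fraction of nonmutant kinases with %Ctrl strictly below `x`;
values exactly at the threshold are non-hits, and mutant constructs are
excluded from numerator and denominator alike. The score is carried as an
exact rational plus the conventional 3-decimal rounding. Hit lists sort by
%Ctrl then kinase id so ties are reproducible.

## Mitosis signature and ssGSEA

`derive_signature` keeps candidates that (i) correlate positively with the
anchor across tumor samples — Spearman by default, robust to the unknown
normalization of real cohorts; Pearson selectable — and (ii) are elevated in
tumor versus matched normal by a one-sided paired Wilcoxon signed-rank test,
which respects the paired design without a normality assumption. Each filter
is Benjamini–Hochberg adjusted across candidates at 0.05 by default. The
correlation filter uses tumor samples only (the activity signal lives
there). An empty result raises an error carrying per-filter survivor counts
for diagnosis.

`ssgsea_score` uses the integral (Barbie-style) statistic: with genes
ordered by descending within-sample expression (gene-id tie-break), in-set
positions step an in-set CDF by `rank_weight^tau` normalized over set
members (rank weight `N − i + 1`), out-of-set positions step a uniform CDF,
and the score sums the gap over all N positions — not the max deviation.
Since weights are powers of the rank rather than of raw expression, the
score depends only on within-sample ranks for every `tau`, and `tau = 0.25`
is the default. AMSES is the cohort-wise range normalization of these scores
to [0, 1] (raw scores always retained; a degenerate single-value cohort is
returned raw with a warning). Stage association uses a Jonckheere–Terpstra
ordered-trend statistic — pairwise concordance across ordered groups, ties
half — with a seeded permutation p-value, since no installed library
provides this test directly.

## Survival screen

Kaplan–Meier curves, the log-rank test and univariate Cox fits are delegated
to lifelines (Efron tie handling, Wald intervals); small-sample agreement
with hand product-limit and observed-minus-expected computations is asserted
in tests. `cox_hr` converts non-convergence and monotone-likelihood fits
(detected via lifelines' convergence errors or an implausibly large
coefficient/standard error) into an explicit indeterminate flag instead of
raising.

`stratified_sl_screen` splits patients at the median tumor anchor expression
(ties to low; tertile/quartile cuts available), and within each stratum
dichotomizes each candidate at the within-stratum median, coding **low
expression as 1** — so HR > 1 means low expression of the candidate is
deleterious in that stratum, matching the planted both-low hazard of the
generator. A candidate is called an SL partner when its anchor-low HR is
significantly above 1 (95% CI lower bound > 1) and its anchor-high HR is
not. This CI-based rule is deliberately conservative and testable; under the
null it calls ≈2.4% of candidates (one-sided 2.5% times the probability the
high stratum stays non-significant), which the calibration test bounds at
5%. A continuous covariate mode (sign-flipped expression, same direction
convention) is available. The screen is univariate by design — no clinical
covariate adjustment.

## Synergy

`median_effect_fit` is an unweighted least-squares line of
`log10(fa/(1−fa))` on `log10(D)`; `m` is the slope and `Dm = 10^(−b/m)`.
Measurements with fa outside `[0.01, 0.99]` are excluded from fits (the
logit blows up at the boundary; window configurable) and flagged — never
silently clamped — in Fa-CI tables. A nonpositive slope returns a flagged
fit. `dx(fa) = Dm (fa/(1−fa))^{1/m}` inverts the curve, and the combination
index uses the two-term mutually exclusive (Loewe-type) form
`CI = d1/Dx1(fa) + d2/Dx2(fa)` with the *measured* combination fa, the
CompuSyn convention. The mutually nonexclusive third term, dose-reduction
indices and other synergy models (Bliss/HSA/ZIP) are out of scope. Noiseless
round trips (generate → fit → CI) reproduce `m`, `Dm` and the planted
interaction multiplier to ≥10 significant digits / 1e-6.

## Pipeline

`run_discovery` chains simulate → connect → kinome → amses → slscreen →
synergy on a YAML config with explicit defaults for every tunable named
above, deriving one sub-seed per stage from the global seed, and writes a
manifest of parameters, output sha256 hashes and headline results. Manifest
hashes are a pure function of (config, seed, code version); the shipped
`configs/demo.yaml` completes in well under a minute on one CPU.

## Numerical and testing choices

* All generators and permutation tests consume a single integer seed through
  `numpy.random.default_rng`; equal seeds give bit-identical output.
* Calibration tests use 199 permutations so the 0.05 rejection cutoff is
  exactly attainable (`p ≤ 0.05 ⇔ at most 9 exceedances`), and 400
  replicates per calibration; screen-recovery tests use 100 planted cohorts
  of 600 patients (the stated study condition) plus 30 null cohorts.
  Fixed seeds make these stochastic checks reproducible.
* Degenerate inputs have stated behavior: empty/full gene-set overlap,
  constant covariates and zero-event groups raise; a constant-expression
  sample scores deterministically via the gene-id tie-break; a combination
  row with no root in (0, 1) is flagged, not clamped.

## Limitations

The synthetic cohort's single-factor, gaussian, exponential-survival world
is the simplest one in which every downstream estimator is identifiable;
real tumor cohorts violate it in ways listed above, so planted-truth
recovery rates here are upper bounds on real-data performance. The
connectivity module scores user-supplied profile collections; it does not
ship a reference corpus or its percentile (tau) normalization. The exact
membership of any published signature cannot be reproduced without the
original cohort data and is not attempted.
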