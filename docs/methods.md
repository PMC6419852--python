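# Methods

## Model and assumptions

The package infers miRNA→mRNA regulation from expression measured across
*environments* — sample subgroups such as cancer subtypes, or random
splits. For each target mRNA `Y` with candidate miRNA predictors
`X ∈ ℝ^p`, the working model is linear with environment-invariant noise:

    Y^e = μ + X^e_{S*} γ* + ε^e,    ε^e ~ F_ε for every environment e,

with `ε^e` independent of the causal predictors `X_{S*}`. Environments are
assumed to arise from *noise interventions on the predictors*: between
environments the error distributions of (some of) the miRNAs change, while
the structural equation of the target does not. Under that condition the
parent set is identifiable from invariance: conditioning on exactly `S*`
makes the target's residual distribution look the same everywhere, whereas
omitting a parent whose signal shifts between environments, or relying on
a shifted non-parent, breaks invariance. The hidden-variable extension
`Y^e = X^e γ* + g(H^e, ε^e)` additionally allows unobserved confounders
`H` whose joint distribution with the noise is the same in all
environments.

Subtype labels enter only as a partition of samples; the subtype classifier
itself is an upstream tool whose output the pipeline consumes.

## The invariance test

For a candidate subset `S` one OLS model is fitted on *all pooled samples*
(an intercept-only fit for `S = ∅`), giving residuals `R`. For each
environment `e`, `R` restricted to `e` is compared against `R` on the
complement with two tests:

- Welch two-sample t-test on the means (unequal variances — environments
  differ in size, and equality of variances is exactly what the second
  test examines);
- two-sided variance-ratio F-test on the variances.

The two p-values are combined by Bonferroni, `min(1, 2·min(p_t, p_F))`,
and the per-environment values again by Bonferroni,
`min(1, |ℰ|·min_e p_e)`. The source method lists both tests without a
combination rule; Bonferroni is chosen because it preserves the test level
without any independence assumption, matching the conservative character
of the intersection estimator. A subset is *accepted* iff the combined
p-value is at least `α` (default 0.05).

Degenerate cases: two constant, identical residual groups give p = 1 (no
evidence against invariance); one constant group against a varying one
gives p = 0. Collinear subsets are untestable and treated as rejected with
a logged reason — never silently accepted, so they cannot delete true
parents from the intersection.

## Parent estimation and scores

`icp_parents` enumerates subsets (always including `∅`), accepts or
rejects each, and intersects the accepted collection. If nothing is
accepted the model is flagged rejected and the parent set is empty; if `∅`
is accepted the intersection is empty (no invariant signal). Exhaustive
enumeration is practical to p ≈ 15; for the default 30-miRNA panel the
candidate set is restricted to the first `preselect = 10` predictors to
enter the lasso path and subsets up to `max_set_size = 3`, both
configurable and logged when truncation occurs. Smaller `α` accepts more
subsets, so the intersection can only shrink — the estimate is
conservative in `α`.

Per-predictor confidence information is summarised as the union envelope
of the OLS coefficient confidence intervals (level `1 − α`) over accepted
subsets containing the predictor; predictors outside every accepted subset
get the degenerate interval [0, 0] and score 0. The ranking score of a
predictor is its signed coefficient of largest magnitude across accepted
subsets — the construction detail for the confidence summary is open in
the source method, and the union bound is the reading implemented here.

## Hidden-ICP estimator

With `G_e = X_e'X_e/n_e`, `g_e = X_e'Y_e/n_e` and pooled `G`, `g`, the
estimator solves in least squares the stacked system

    (G_e − G) γ = (g_e − g)   over all environments e.

Under the hidden-variable model the cross-moments contributed by `g(H, ε)`
are environment-invariant and cancel in the differences, so noise
interventions on the predictors make the system identifying;
`E[X_e Y_e] − E[X Y] = (G_e − G) γ*` holds exactly in population. With two
environments the solution reduces to the closed form
`(G₁ − G₂)⁻¹(g₁ − g₂)` whenever the inverse exists (verified to 1e-8 in
the tests). A nearly-zero left side (no intervention contrast) is flagged
as degenerate; a singular stacked system falls back to a ridge-stabilised
solve (`λ = 1e-8` relative to the leading singular value) with a logged
warning. Confidence intervals come from a nonparametric bootstrap that
resamples within each environment (default B = 100, seeded; percentile
2.5/97.5); a predictor is significant when its interval excludes zero.
All-pairs scoring skips the bootstrap (only point estimates feed the
ranking).

## Ranking, ensemble, and baselines

Pearson scores are plain correlations; Lasso scores are per-target
L1-penalised coefficients on standardised predictors mapped back to the
original scale, with the penalty chosen by seeded 10-fold CV at minimum CV
error (the source names no tuning rule; CV-min is the common default and a
fixed-penalty mode exists for exact reproducibility).

Rankings order pairs by decreasing |score| — miRNA regulation is largely
repressive, so strong negative associations must rank first (signed
ordering is available). Exact score ties carry the average of their
positions (`avg_rank`), while the displayed `rank` is the contiguous 1..n
position after a deterministic lexicographic tie-break. Borda aggregation
averages `avg_rank` across methods over the *full shared pair universe*
(whether the source averaged full lists or top lists is unstated;
full-universe averaging is deterministic and uses all information), orders
by increasing mean rank, and errors on universe mismatch instead of
silently intersecting.

## Validation protocol

Predicted pairs are checked against (i) a transfection table — confirmed
iff the pair is present and |log2FC| strictly exceeds the threshold
(default 0.3; "larger than" is read as strict, so a fold-change of exactly
0.3 does not confirm) — and (ii) a confirmed-interaction list. Pairs
absent from the transfection table are counted separately as
*uncheckable*, not as failures, because transfection compendia cover only
some miRNAs; reports surface both restricted and unrestricted counts.
Identifiers match case-insensitively. The null experiment draws
`n_regulators` miRNAs and `k` targets each uniformly without replacement,
applies the same validator, and averages over repetitions (default 100) —
its mean converges to the universe hit-rate times the number of draws,
which the tests verify within binomial error at 2000 repetitions.

## Synergy analysis

For miRNAs `i, j` with predicted target sets of sizes `K`, `M` sharing `n`
mRNAs in a universe of `N`, the p-value is the upper hypergeometric tail
`P(X ≥ n) = 1 − Σ_{x<n} C(K,x)C(N−K,M−x)/C(N,M)`, evaluated through the
log-gamma-based survival function (stable for large arguments; `n = 0`
returns exactly 1). All `C(r,2)` pairs form one BH family and pairs with
adjusted p below the cutoff (default 0.05) are called synergistic. The
universe size `N` defaults to the number of selected mRNAs (the pipeline's
1500-analog) and is configurable, since "mRNAs of interest" admits both
that reading and the union of top lists. Target sets default to the top-k
per-miRNA predictions (k ∈ {50, 100, 150, 200} in the pipeline
configuration).

## Synthetic studies

`simulate_sem` draws, per sample, regulators
`X_j = A_j·H + s_{e,j}·ε` (invariant hidden loadings when `hidden_dim > 0`,
environment-scaled noise otherwise i.i.d.) and targets
`Y = μ + Σ_j γ*_j X_j + b·H + ε_Y` with environment-invariant Gaussian
errors (a variance-matched t₅ option provides heavy tails). Interventions
multiply the noise sd of the intervened regulators by `intervention_scale`
(default 2) in every non-reference environment; the intervened set is a
random half of the regulators by default, or "all", "non_parents", or an
explicit list. Defaults mirror the motivating cohort with the mRNA panel
reduced tenfold: 30 miRNAs, 150 mRNAs, five environments with subtype
sample counts 107/75/147/116/58. True coefficients have magnitudes
`0.5·U(0.5, 1.5)` with random signs: modest effects relative to unit
biological noise, chosen so that no scoring method saturates and the
benchmark can rank them. Everything is a pure function of the parameters
and one seed (bit-identical regeneration).

What the generator deliberately does **not** emulate: count-level
sequencing noise and library-size effects, nonlinear or saturating
regulation, correlated regulator programs, network motifs (shared targets
are slightly *anti*-correlated because parents are drawn without
replacement), or interventions on the targets' own noise (excluded to
match the identifiability condition). Passing tests therefore demonstrate
correctness of the estimators under their stated model, not performance on
real sequencing data.

The toy validation fixtures give true pairs |log2FC| ~ |N(1, 0.2)| with
random sign (confirmed at threshold 0.3 with probability ≈ 0.9998) and
null pairs N(0, 0.15) (confirmed with probability ≈ 0.046); the toy
database is the true pair set plus a configurable fraction of random false
pairs.

## Benchmark designs and problem sizes

The statistical guarantees are exercised at these (seeded) designs, chosen
to finish in minutes on one CPU:

- *Level*: 200 replicates, p = 6, three environments of 150,
  interventions on non-parents, α = 0.05; the parent estimate must be a
  subset of the truth in ≥ 90% of runs. Interventions on non-parents is
  the conservative regime: subsets missing a (non-intervened) parent can
  remain invariant, so the intersection stays small and coverage is the
  binding property.
- *Power*: 100 replicates, unit coefficients, interventions on **all**
  regulators (scale 2), 500 samples per environment; mean Jaccard between
  estimate and truth ≥ 0.7. Power requires intervened parents — without a
  shift in a parent's distribution, its omission is undetectable — so this
  design intervenes everywhere, the regime the subtype argument describes.
- *Oracle equivalence*: 50 random two-environment instances, p ≤ 6,
  exhaustive search versus an independent brute-force enumeration built on
  normal-equation OLS and textbook t/F formulas; exact agreement required.
- *Hidden-ICP consistency*: two environments of 5000, one hidden
  confounder, γ* = (1, 0); mean sup-norm error < 0.15 and closed-form
  agreement to 1e-8.
- *Primitives*: hypergeometric tail versus exact integer summation over
  the full N ≤ 40 grid (1e-12); BH versus an explicit step-up loop; Borda
  versus brute-force mean ranks.
- *End-to-end*: 20 seeds of the default study; precision at the number of
  true pairs for the causal scorer must exceed three times the
  random-draw null baseline.

On the default unconfounded study the Borda ensemble does not dominate its
best member: the data-generating process is exactly the Lasso model, so
L1 regression scores near the precision ceiling and averaging in weaker
rankings can only tie or dilute it. The ensemble earns its keep under
model misspecification — `examples/07_confounded_study.py` shows
correlation losing ~0.35 precision under hidden confounding while the
moment-difference estimator holds — which is the regime heterogeneous real
cohorts occupy.

## Known limitations

- Bonferroni-combined tests are conservative; with many environments the
  accepted collection grows and the intersection shrinks toward ∅
  (abstention, not error).
- Lasso-path preselection can exclude a true parent before subset search
  at p > 15; the truncation is logged.
- The hidden-ICP system needs between-environment second-moment contrast
  for every coefficient it is to identify; non-intervened regulators'
  coefficients are set by the minimum-norm solve and should not be
  over-read.
- The bootstrap intervals are percentile intervals without studentisation;
  at small environment sizes they can undercover.
- Identifier namespaces (miRBase versions, gene symbols vs Ensembl ids)
  are matched case-insensitively but not translated.
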