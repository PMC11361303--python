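# Methods

This note documents the statistical models, default parameters, and numerical
choices behind `commstate`, in the order the pipeline runs.

## 1. Feature tables and preprocessing

All layers are features × samples tables of non-negative values with unique
string identifiers; metadata carries `sample_id`, `subject_id`, `timepoint`,
and an `is_qc_pool` flag, with (subject, timepoint) unique among study
samples.

- **Core-feature filter** (taxa/function): keep features with count
  ≥ `min_count` (default 10) in at least `ceil(prevalence_frac · n_samples)`
  samples (default 30%, inclusive boundary). This removes sparse genera that
  destabilize the mixture fit.
- **Rarefaction**: subsampling without replacement via the multivariate
  hypergeometric distribution (default depth 7 600); samples below depth are
  dropped and logged. Without-replacement draws have exactly the finite-
  population variance, unlike multinomial resampling.
- **CLR**: `log(x_j + c) − mean_j log(x_j + c)` per sample, pseudocount
  `c = 1` by default; zero pseudocount is only accepted on strictly positive
  tables.
- **Metabolome QC filter**: keep features whose coefficient of variation
  across ≥ 2 pooled-QC injections is `< 0.20` (sample SD) **and** whose
  presence among study samples is strictly `> 80%`.
- **Pareto-log**: `log10(x + 1)`, mean-centred per feature, divided by the
  square root of the feature's sample SD — the usual compromise between
  unit-variance autoscaling (inflates noise features) and no scaling
  (dominated by abundant features).

## 2. Dirichlet-multinomial mixture (DMM) community typing

Counts follow `p(x_s) = Σ_k π_k · DM(x_s | α_k)`. The EM algorithm uses exact
responsibilities in the E-step and, in the M-step, `π_k` = mean
responsibility plus a responsibility-weighted Minka fixed-point update for
`α_k`:

```
α_kj ← α_kj · Σ_s r_sk [ψ(x_sj + α_kj) − ψ(α_kj)] / Σ_s r_sk [ψ(N_s + A_k) − ψ(A_k)]
```

This is a generalized EM step: each iteration provably does not increase the
negative log-likelihood, which the tests assert along the whole optimization
path. Defaults: relative tolerance `1e-6`, max 1 000 iterations, 5 restarts
(the first seeded by k-means on CLR profiles, the rest by random
responsibilities). A component whose expected occupancy collapses below one
sample is reinitialized once, then dropped (the fit reports `fitted_K`).

**Model selection.** The marginal likelihood per K is approximated by
Laplace's method around the posterior mode in unconstrained coordinates
(`log α` for all components, plus a logit parameterization of the mixture
weights):

```
−log Z ≈ f(θ̂) − (d/2)·log 2π + ½·log det H(θ̂)
```

with `f` the negative log posterior and `H` its exact analytic Hessian
(mixture identity: `H[log p_s] = Σ_k r_sk H_k + Σ_k r_sk g_k g_kᵀ − ḡ ḡᵀ`,
verified against finite differences). A weak `Normal(0, σ² = 100)` prior on
every unconstrained coordinate makes the integral proper — the pure DM
likelihood plateaus as `α → ∞` (the multinomial limit), so an unpenalized
evidence integral diverges. The prior is broad enough (±20 log-units ≈ 2 SD)
to leave the mode essentially at the MLE. The mode is refined by L-BFGS
before the Hessian is evaluated; if `H` is not positive definite, a `1e-8`
jitter is added before `slogdet`. The selected K minimizes the negative log
evidence; ties within `1e-6` resolve to the smaller K. Accuracy check: on a
3-sample, 2-feature instance the Laplace value matches brute-force 2-D
quadrature to < 0.1 nats, and on simulated 4-state cohorts the generating K
and ≥ 95% of labels are recovered. Assignments are argmax responsibilities,
exact ties broken to the lowest label; labels are 1-based.

Caveat: the Laplace approximation is least accurate when components are
nearly multinomial (very large α), where the likelihood is flat in the
total-concentration direction; for near-boundary fits the evidence can be
off by a few tenths of a nat and occasionally over-selects K by one on small
cohorts.

## 3. Transition null model

For subjects observed at T consecutive timepoints, observed transitions are
tallied over all K² ordered (source → destination) categories (16 for four
states). The default null (`cross_pairing`) is what unlinked subjects would
produce given the observed per-timepoint prevalences:

```
P(A→B) = Σ_t n_A(t) · n_B(t+1) / Σ_t N_t · N_{t+1}
```

A `pooled_marginal` variant (`P(A→B) = f_A · f_B` from pooled frequencies)
is available. The test is a chi-square goodness of fit over all K² cells
with `df = K² − 1`; cells with expected count < 5 are flagged
(`low_expected`) since the asymptotic reference is unreliable there.
Standardized (Pearson) residuals `(O − E)/√E` are reported per cell and
flagged at `|r| > 1.96`. Under an i.i.d. prevalence-matched null the
simulated type-I rate at α = 0.05 stays ≤ 0.08 across 200 replicate cohorts
of the default size.

## 4. Diversity and dissimilarity partitioning

Shannon index uses natural log by default. Distances (Bray-Curtis, Canberra)
delegate to `scipy.spatial.distance.pdist`; Canberra's 0/0 terms are treated
as zero. All `n(n−1)/2` off-diagonal pairs are split exhaustively into
intra-individual (same subject) and inter-individual sets and compared by a
two-sided Mann-Whitney U test; per-subject medians (and their square roots,
a variance-stabilizing scale for downstream regression) summarize temporal
instability per person.

## 5. Variance components and ICC

Per feature, a one-way random-effects decomposition by the method of
moments: with `MSB`/`MSW` the between/within mean squares and
`n0 = (N − Σ n_i²/N)/(I − 1)` the unbalanced-design effective replicate
count, `σ²_w = MSW`, `σ²_b = max(0, (MSB − MSW)/n0)` (truncation logged),
and `ICC = σ²_b/(σ²_b + σ²_w)`. Subjects with a single sample are excluded.
On balanced designs this equals the classical one-way ANOVA estimator
exactly (tested to 1e-10), and designed metabolite ICCs are recovered with
mean absolute error ≤ 0.05 at 500 subjects × 3 timepoints. Layers are
compared on per-feature `total_var`, `intra_var`, and `icc` with
Kruskal-Wallis plus Dunn's post-hoc z-tests (tie-corrected, Bonferroni
over the three pairs).

## 6. Log-ratio associations

The community gradient is summarized as
`log10((num + c)/(den + c))` (default `c = 1`, e.g. Prevotella:Bacteroides).
Associations with metabolite features are covariate-adjusted Spearman
correlations: both the ratio and each feature are residualized by OLS on the
covariate design (default `sex`, `race_ethnicity`, `bmi`, `timepoint`;
categoricals one-hot with first level dropped, constant columns dropped with
a log message, exact rank deficiency raises and names the aliased column),
and the residuals are rank-correlated. P-values are Bonferroni-adjusted
(`p_adj = min(1, p·m)`). Under independence the raw p-value rate at 0.05 is
calibrated (0.05 ± 0.02 at 200 features × 500 samples). Explained-variance
summaries use sequential (type-I) sums of squares over predictor blocks,
expressed as percentages that sum to 100 with the residual.

## 7. Synthetic cohort generator

The generator emulates a three-timepoint, 93-subject cohort with three
molecular layers and known ground truth; all defaults are package choices
made so the estimators above are identifiable at realistic sizes.

- **States**: 4 community states; baseline probabilities 38/93, 21/93,
  22/93, 12/93; first-order Markov chain with stay probability 0.72
  (uniform off-diagonal), overridable by a full transition matrix.
- **Taxa**: 60 genera; per-state Dirichlet concentrations (total 50) give
  each state a distinct dominant marker genus (Bacteroides, Bacteroides_B,
  Blautia, Prevotella; ≥ 3× any non-marker) plus a secondary block; counts
  are Multinomial at lognormal depths (median 5 000, σ = 0.3 — a fast
  default; a study-scale 40 000 preset exists).
- **Function**: 120 pathways = sparse non-negative loadings (10 genera
  each) applied to relative abundances, scaled 1e4, with lognormal
  multiplicative noise — so functional profiles are smoothed mixtures of
  the taxa signal, with intermediate temporal variance by construction.
- **Metabolome**: 200 features on a log10 scale with designed per-feature
  ICC ~ Uniform(0.3, 0.9) at fixed total log-variance 0.04, plus 5 pooled-QC
  injections at CV 0.05.
- **Stabilizer option**: a subject-level scenario in which subjects rich in
  a designated genus (Faecalibacterium) blend later compositions toward
  their baseline, creating a negative association between that genus and
  intra-individual dissimilarity for the regression tests.

What it does **not** emulate: sequencing error/chimeras, compositional
artifacts of bioinformatic pipelines, covariate-driven state membership
(sex/BMI/diet columns are simulated independently of state), batch effects
beyond the QC pools, and dropout/missing visits (every subject is complete).

## 8. Reproducibility

Every stochastic routine takes an explicit integer seed and uses
`numpy.random.Generator`; `scripts/acceptance.py` derives all child seeds
from a single `--seed` via `SeedSequence` (each < 2³¹) and writes its
quantities as JSON. Log messages record dropped samples, truncated variance
components, reinitialized mixture components, and tie conventions
(all-tied rank tests report p = 1; tied Spearman inputs report ρ = 0,
p = 1).
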