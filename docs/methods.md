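# Methods

## The composite light-response model

A trait trajectory over the log light axis `l = ln(PAR)` is modelled as
`y(l) = φ(l) + ω(l)`, with `φ` an S-shaped growth family and
`ω(l) = c·l^d` an allometric environmental disturbance. Seven families are
implemented:

| family | form | parameters |
|---|---|---|
| Gompertz | `K·exp(−a·e^{−bl})` | K, a, b |
| logistic | `K / (1 + a·e^{−bl})` | K, a, b |
| Mitscherlich | `K·(1 − a·e^{−bl})` | K, a, b |
| Bertalanffy | `K·(1 − a·e^{−bl})³` | K, a, b |
| Richards | `K·(1 − a·e^{−bl})^{1/(1−m)}` | K, a, b, m (m ≠ 1) |
| Korf | `K·exp(−a / l^b)` | K, a, b (l > 0) |
| Weibull | `K·(1 − e^{−(l/a)^b})` | K, a, b (l > 0) |

`K` is the upper asymptote in trait units; `b` the intrinsic rate; `c` the
disturbance rate (trait units per `l^d`); `d` a dimensionless scale
exponent. The decreasing qP trait is accommodated by `a < 0`
(Mitscherlich) and a free-signed `c`; the Richards fit is restricted to
`m > 1`, where the curve is monotone and the branch is unambiguous. Group
offsets ε (per-sample mean residual from the global curve, aggregated over
externally supplied structure labels) are a diagnostic only: they are
tested by Kruskal–Wallis and one-way ANOVA and never fed into later
stages.

**Fitting.** Multistart trust-region least squares: one heuristic start
plus (default) 20 Latin-hypercube draws inside data-driven boxes
(`K ≤ 3·max|y|`, `b ∈ (0, 5]`, `d ∈ [−2, 2]`, family-specific `a` ranges),
`xtol/ftol = 1e−14`; the lowest residual sum wins. On noiseless
model-generated data the global optimum is recovered to ~1e−14 relative
error. Model comparison reports AIC, BIC and AICc computed from the
Gaussian profile log-likelihood (`L·ln(rss/L) + penalty`, `k` = number of
curve parameters); BIC is the default selection key. Per-level shares of
the two components use absolute values, `|φ|/(|φ|+|ω|)`, so opposite signs
still give shares in [0, 1]; levels where both terms vanish are reported
missing.

**Identifiability of the composite.** On an 11-point design the two terms
can overlap badly: once a sigmoid saturates, `c·l^d` with small `d` is
nearly (at `d = 0`, exactly) collinear with `K`, and the Fisher
information for `(c, d)` collapses — Cramér–Rao relative standard errors
of several hundred percent at ETR-like parameter points, regardless of
estimator. Recovery of all of `K, b, c, d` is only meaningful where the
components occupy complementary parts of the axis (e.g. a sharp Korf step
with a smooth allometric term, the regime used by the recovery study in
the acceptance tests: CRLB ≈ 2–3% per parameter at 98 samples and 5%
noise). The same ridge is why per-sample parameter tests warm-start every
sample from one pooled fit: per-group starts can park groups in different
ridge basins and manufacture spurious Mann–Whitney significance under the
null.

## Trajectory likelihood and the genome scan

Sample trajectories are multivariate normal around genotype-specific
composites with a shared stationary AR(1) covariance
`Σ_jk = σ²ρ^{|j−k|}`, indexed on level order (levels treated as equally
spaced; a spacing-aware option exists but is off by default). The AR(1)
structure is used analytically throughout: `log det Σ = L·ln σ² +
(L−1)·ln(1−ρ²)`; the precision matrix is tridiagonal; all quadratic forms
reduce to three pooled residual scalars (total square, lag-1 cross
product, interior square). σ² is profiled in closed form and ρ maximised
by bounded scalar search in (−0.99, 0.99); σ² is floored at 1e−8 so
noiseless fixtures cannot blow up the likelihood.

Maximisation alternates a per-genotype curve step with the covariance
step. The curve step is generalised least squares against the group-mean
trajectory (the grouped GLS objective depends on the data only through
group means), solved by Levenberg–Marquardt on innovation-whitened
residuals with analytic Jacobians of all seven families; a Nelder–Mead
step is available via `method="nelder-mead"`. The alternative fit is
warm-started at the null fit and every step is accept-only-if-better, so
`L1 ≥ L0` holds by construction and the scan is deterministic and
invariant to SNP order. Outer iterations stop when the log-likelihood
gains < 1e−6 (max 8).

The LR statistic `−2(log L₀ − log L₁)`, clipped at zero, is referred to
χ² with `(G−1)·p` degrees of freedom (`p` = curve parameters; the
covariance appears under both hypotheses). At the reference design
(98 samples, 11 levels, noise sd 5% of K, ρ = 0.6) the empirical type-I
error at α = 0.05 is 0.03–0.06 over 500 replicates and the null LR's 95th
percentile tracks the χ² reference within ±25%.

Genotype groups smaller than 5 samples cause the SNP to be skipped with a
reason code (optionally the rare heterozygote collapses into the nearer
homozygote); SNPs with missing calls are refit against a null on the same
sample subset so the LR compares like with like. Thresholds follow the
two-stage design: a classical (pure-growth) scan of the full panel ranks
a potential key set (default 10,000, capped at panel size), the
disturbance-augmented model rescans that set, the top 3% (default) of each
ranking intersect into the robust per-trait set, and loci robust for two
or more traits are reported as pleiotropic. Ties always break by scan
order. Supporting diagnostics: per-level one-way ANOVA (static scan),
Kolmogorov–Smirnov normality against a moment-matched normal, and a
kinship matrix of Pearson correlations between centred genotype vectors
with negatives floored at zero (raw values retained).

## Genetic-effect curves

A SNP's effect trajectory is the additive homozygote contrast
`g(l) = (μ_minor-hom(l) − μ_major-hom(l))/2`, falling back to half the
difference of the two observed classes; the applied rule and minor-allele
orientation are recorded on the curve (`definition_tag`). Curves are
closed-form in the fitted parameters, so densification to the 30-point
uniform grid used by the network stage is exact.

## Network inference

For each target, predictors are selected by a two-stage adaptive LASSO on
the empirical derivative (cubic-spline differentiation): ridge regression
with leave-one-out-tuned penalty supplies weights `1/|β_ridge|`, and the
weighted LASSO's penalty is chosen by BIC over a 50-point grid against an
intercept-only baseline, with active-set OLS refits and residual sums
floored at 1e−8 of the derivative's energy (so that once a model fits to
numerical precision BIC prefers the smaller one). The active set is capped
at `d_max = 15`. On a 200-node panel of independent smooth effect curves
this keeps selection density ≈ 2.5%, and on six candidates with a planted
two-predictor truth it matches exhaustive best-subset least squares.

The ODE `dg_p/dl = F_p(g_p) + Σ F_{p←p'}(g_{p'})` uses order-4 Legendre
expansions of each argument curve mapped to [−1, 1] (range padded 5%).
Coefficients minimise the squared distance between the observed curve and
its classical RK4 integral from `g(l_min)`. The split between the self
term and predictor terms has flat directions (both are flexible functions
of curves that co-vary along `l`), so the optimiser is anchored: the warm
start attributes the derivative to the selected predictors first and fits
the self term on the remainder, and a proximal penalty of 1e−7 of the
curve's energy toward that start gives the flat directions curvature.
Five jittered restarts (seeded) plus a joint least-norm start guard
against local minima.

Decomposition integrates the fitted component fields along the full
solution with the same RK4 stages; since RK4 is linear in the stage
derivatives, independent + Σ dependent equals the fitted trajectory to
machine precision. An edge `p′ → p` is retained when the dependent curve's
maximum magnitude exceeds 1% of the target's maximum overall effect; its
sign is the sign of the curve's mean (the signed curve is kept on the edge
for inspection) and its weight the maximum magnitude. Density is
`100·E/(N(N−1))`; hubs are nodes with out-degree strictly above 20% of N.

## The synthetic-study generator

Defaults emulate the reference design: 98 samples, 11 log-spaced light
levels over 7.243–2701.536 μmol·m⁻²·s⁻¹, three traits with baseline
composites ETR = logistic(K=30, a=8, b=1.2) + 1.5·l^0.8,
qP = Mitscherlich(K=0.2, a=−4, b=0.6) + 0.3·l^−0.5 and
qN = Korf(K=0.95, a=30, b=2.5) + 0.1·l^−1.5 (rising ETR, falling qP, a qN
whose disturbance share is ~100% at the lowest light and decays — the
qualitative patterns of the three quenching traits). Residuals are exact
stationary AR(1) draws with sd 5% of each trait's asymptote and ρ = 0.6,
a typical lag-1 correlation for repeated physiological measurements.
Genotypes are Hardy–Weinberg draws at per-SNP allele frequencies uniform
in (0.1, 0.5); three causal SNPs per trait (disjoint across traits, allele
frequency in the upper half of the range so all genotype classes are
testable) multiply K by 1.10 and b by 1.08 per alternate allele — strong,
detectable architecture. Missing genotypes are off by default
(rate ≤ 0.2 available to exercise the filter path).

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent, so ranking-based power results are optimistic relative to
structured genomes), pedigree/kinship structure, genotype-specific
residual covariance, multi-environment designs, and measurement artefacts
such as level-dependent variance. Passing tests therefore demonstrate
correctness of the estimators and the pipeline's statistical calibration
under the stated model, not performance on a real resequencing panel —
the original study's scale (≈5 million SNPs) and its specific loci are
outside desk scale by construction.

## Problem sizes and numerical choices

Test and acceptance studies use 2,000-SNP panels (20 replicate studies for
scan power), 500 null replicates for LR calibration, 200 replicates for
parameter recovery, 30-point dense grids and 5-node planted networks;
the paper-scale sparsity check samples 12 targets against full 199-curve
candidate pools. Tie-breaks are stable by input order everywhere;
degenerate inputs (monomorphic SNPs, zero-variance groups, both-zero
decomposition terms) are skipped or flagged rather than fatal. Dense-grid
resampling of effect curves is exact (closed forms), so no interpolation
error enters the ODE stage.

## Known limitations

- Growth-family selection is per-trait on the mean trajectory; no
  per-sample family heterogeneity.
- The LR null distribution relies on the χ² approximation; no permutation
  thresholds (noted as an option, not implemented).
- The independent/dependent ODE split is identified only up to the
  anchoring convention described above whenever curves are monotone;
  reported decompositions should be read under that convention.
- `F_{p←p'}` depends on the predictor's effect value only (pure coupling);
  a target-modulated alternative is plausible but not implemented.
- Kinship is a descriptive diagnostic; the likelihood contains no
  population-structure or kinship covariance correction.
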