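# photoqtl

Functional mapping of photosynthetic light-response trajectories: decompose
chlorophyll-fluorescence phenotypes into genetic and environmental parts,
scan biallelic SNP panels for QTLs that reshape whole trajectories, and
reconstruct signed, directed regulatory networks among the significant loci.

## Who this is for

Quantitative geneticists and plant physiologists working with
light-response curves — traits such as the electron transport rate (ETR),
photochemical quenching (qP) and nonphotochemical quenching (qN) measured
on each plant across a ladder of actinic light intensities — who want to
map loci controlling the *shape* of the response rather than a single
endpoint, and to ask how those loci influence one another.

## The model

Each trait trajectory over log light intensity `l = ln(PAR)` is written as
an additive gene–environment composite

```
y(l) = φ(l) + c·l^d,
```

where the autogenic term `φ` is one of seven classical growth families
(Gompertz, logistic, Mitscherlich, Bertalanffy, Richards, Korf, Weibull —
selected by information criterion) and the allometric term `c·l^d` captures
the direct environmental disturbance. Per-sample offsets ε from externally
supplied population-structure labels are estimated as a diagnostic
(Kruskal–Wallis / ANOVA across groups) and dropped when non-significant.

For QTL mapping, sample trajectories `y_k ∈ R^L` are multivariate normal
around genotype-specific composites `μ_g(l)` with a shared stationary AR(1)
covariance `Σ_jk = σ²ρ^{|j−k|}`. Each SNP is tested with the likelihood
ratio `LR = −2(log L₀ − log L₁)` between the single-curve null and the
genotype-stratified alternative, referred to χ² with `(G−1)·p` degrees of
freedom. A classical-model genome scan builds a potential key set; a
disturbance-augmented rescan and the intersection of both top fractions
give the robust per-trait loci and, across traits, pleiotropic ones.

Each robust locus yields a genetic-effect curve `g_p(l)` (half the
difference of its homozygote curves). Effects obey a sparse ODE system

```
dg_p/dl = F_p(g_p) + Σ_{p'} F_{p←p'}(g_{p'}),
```

with each component a Legendre-polynomial expansion of its argument curve.
Predictors are chosen by adaptive LASSO (ridge-derived weights, BIC-tuned
penalty), coefficients fitted by least squares against the
fourth-order-Runge–Kutta-integrated trajectory, and the fit decomposed into
an independent curve plus per-predictor dependent curves whose sign and
magnitude define the network's directed edges. Hubs are nodes whose
out-degree exceeds 20% of the node count.

## Worked example

```python
from photoqtl import (SimulationDesign, simulate_study, fit_mean_curve,
                      genome_scan, select_significant)

study = simulate_study(SimulationDesign(n_samples=98, n_snps=500,
                                        n_causal=3, seed=42))
traj = study.trajectories["ETR"]

fit = fit_mean_curve(traj.values.mean(axis=0), traj.grid,
                     family="logistic", with_disturbance=True)
print(fit.summary())

scan = genome_scan(traj, study.genotypes, family="logistic", disturbance=False)
print("top 1% loci:", select_significant(scan, top_fraction=0.01))
print("planted QTLs:", study.truth["causal_snps"]["ETR"])
```

prints

```
Composite light-response fit: logistic + c*l^d
------------------------------------------------
   K   29.8041
   a   11.9245
   b   1.51504
   c   6.15589
   d   0.419772
------------------------------------------------
 rss   0.0771615    se   0.113403    R2   0.999735
 AIC  -44.5572   BIC  -42.5678   AICc  -32.5572
 converged: True
top 1% loci: ['snp000322', 'snp000216', 'snp000380', 'snp000392']
planted QTLs: ['snp000216', 'snp000322', 'snp000380']
```

The fitted asymptote `K ≈ 29.8` recovers the generating value 30 from the
98-sample mean; the R² of 0.9997 says the composite tracks the mean
trajectory almost exactly (the remaining parameters sit on the flat
K–c·l^d ridge discussed in `docs/methods.md`). All three planted QTLs rank
in the scan's top 1%; the one extra locus is a false positive at this
panel size.

The full pipeline (filtering → curve fitting → classical scan → key set →
composite rescan → intersections → effect curves → networks) runs from a
YAML config:

```bash
photoqtl simulate --n-samples 98 --n-snps 2000 --seed 1 --out study/
photoqtl run --config config.yaml
```

writing per-stage CSV/JSON artifacts, GraphML networks and a reproducible
run manifest.

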