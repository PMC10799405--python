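"""Functional mapping of trajectory phenotypes to SNP genotypes.

Each sample's trajectory y_k = (y_k(1), …, y_k(L)) is modelled as
multivariate normal around a genotype-specific composite curve μ_g(l) with
a shared AR(1) residual covariance Σ_jk = σ²ρ^{|j−k|}.  A SNP is tested by
the likelihood ratio between a single-curve null (all genotypes share one
curve) and the genotype-stratified alternative; −2ΔlogL is referred to a
χ² distribution whose degrees of freedom equal the extra curve parameters,
(G−1) × p.

Genotypes are observed, so the likelihood factorises over genotype groups
and the maximisation alternates a per-genotype curve step (generalised
least squares against the group-mean trajectory, exploiting that the GLS
objective depends on the data only through the group means) with a
closed-form-profiled covariance step (σ² profiled out; ρ by scalar
maximisation).  Both steps ascend the likelihood from a warm start at the
null fit, which guarantees L1 ≥ L0.

The AR(1) structure is used throughout in its analytic form: the precision
matrix is tridiagonal, log det Σ = L·log σ² + (L−1)·log(1−ρ²), and all
quadratic forms reduce to three scalar residual statistics, making the
genome scan a few milliseconds per SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import MISSING, GenotypeMatrix, TraitTrajectories
from .growth import HDEEParams, eval_hdee, hdee_jacobian, n_growth_params
from .hdee import HDEECurveModel, _parameter_bounds
from .light import LightGrid

__all__ = [
    "CovarianceParams",
    "GenotypeModelFit",
    "ar1_covariance",
    "mvn_loglik",
    "fit_null_model",
    "fit_genotype_model",
    "lr_test",
    "genome_scan",
    "build_potential_key_set",
    "select_significant",
    "intersect_models",
    "detect_pleiotropy",
    "static_scan",
    "ks_normality",
    "kinship_matrix",
]

_SIGMA2_FLOOR = 1e-8
_RHO_BOUND = 0.99


@dataclass(frozen=True)
class CovarianceParams:
    """Stationary AR(1) residual covariance: variance σ² and lag-1 correlation ρ."""

    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")


def ar1_covariance(cov: CovarianceParams, L: int) -> np.ndarray:
    """Dense L × L matrix Σ_jk = σ²ρ^|j−k| (symmetric positive definite)."""
    j = np.arange(L)
    return cov.sigma2 * cov.rho ** np.abs(j[:, None] - j[None, :])


def mvn_loglik(y, mu, cov_matrix) -> float:
    """Exact multivariate-normal log density via Cholesky factorisation."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    S = np.asarray(cov_matrix, dtype=float)
    if y.shape != mu.shape or S.shape != (y.size, y.size):
        raise ValueError("dimension mismatch")
    try:
        chol = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    z = np.linalg.solve(chol, y - mu)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (y.size * np.log(2 * np.pi) + logdet + z @ z))


# ---------------------------------------------------------------------------
# AR(1) sufficient statistics and profiled covariance step
# ---------------------------------------------------------------------------

def _ar1_suffstats(resid: np.ndarray) -> tuple[float, float, float]:
    """(S0, S1, Smid): total square, lag-1 cross product, interior square."""
    s0 = float(np.sum(resid**2))
    s1 = float(np.sum(resid[:, :-1] * resid[:, 1:]))
    smid = float(np.sum(resid[:, 1:-1] ** 2))
    return s0, s1, smid


def _ar1_loglik_from_stats(s0: float, s1: float, smid: float, n: int, L: int,
                           sigma2: float, rho: float) -> float:
    q = s0 - 2.0 * rho * s1 + rho**2 * smid
    return -0.5 * (
        n * L * math.log(2 * math.pi * sigma2)
        + n * (L - 1) * math.log(1.0 - rho**2)
        + q / (sigma2 * (1.0 - rho**2))
    )


def _ar1_mle(resid: np.ndarray) -> tuple[CovarianceParams, float]:
    """Maximum-likelihood (σ², ρ) for pooled residual rows, with σ² profiled."""
    n, L = resid.shape
    s0, s1, smid = _ar1_suffstats(resid)

    def neg_profile(rho: float) -> float:
        q = s0 - 2.0 * rho * s1 + rho**2 * smid
        sigma2 = max(q / (n * L * (1.0 - rho**2)), _SIGMA2_FLOOR)
        return -_ar1_loglik_from_stats(s0, s1, smid, n, L, sigma2, rho)

    sol = optimize.minimize_scalar(neg_profile, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(sol.x)
    q = s0 - 2.0 * rho * s1 + rho**2 * smid
    sigma2 = max(q / (n * L * (1.0 - rho**2)), _SIGMA2_FLOOR)
    cov = CovarianceParams(sigma2=sigma2, rho=rho)
    return cov, _ar1_loglik_from_stats(s0, s1, smid, n, L, sigma2, rho)


def _whiten(r: np.ndarray, rho: float) -> np.ndarray:
    """Innovation transform: r'M r = Σ whitened² for the AR(1) precision M."""
    out = np.empty_like(r)
    out[0] = math.sqrt(1.0 - rho**2) * r[0]
    out[1:] = r[1:] - rho * r[:-1]
    return out


# ---------------------------------------------------------------------------
# Grouped-likelihood fits
# ---------------------------------------------------------------------------

@dataclass
class GenotypeModelFit:
    """Maximised genotype-stratified (or pooled, G=1) trajectory likelihood."""

    trait: str
    family: str
    disturbance: bool
    genotype_params: dict
    group_sizes: dict
    cov: CovarianceParams
    loglik: float
    grid: LightGrid
    converged: bool = True

    @property
    def G(self) -> int:
        return len(self.genotype_params)

    @property
    def n(self) -> int:
        return int(sum(self.group_sizes.values()))

    @property
    def n_curve_params(self) -> int:
        return n_growth_params(self.family) + (2 if self.disturbance else 0)

    def mean_curves(self, l=None) -> dict:
        l = self.grid.log_levels if l is None else np.asarray(l, dtype=float)
        return {g: eval_hdee(self.family, p, l) for g, p in self.genotype_params.items()}

    def summary(self) -> str:
        rows = [f"Trajectory likelihood fit: trait={self.trait} family={self.family}"
                f"{' + c*l^d' if self.disturbance else ''}"]
        rows.append(f" groups={self.G}  n={self.n}  loglik={self.loglik:.4f}")
        rows.append(f" sigma2={self.cov.sigma2:.5g}  rho={self.cov.rho:.4f}")
        for g, p in self.genotype_params.items():
            rows.append(f" genotype {g} (n={self.group_sizes[g]}): K={p.K:.4g} a={p.a:.4g} "
                        f"b={p.b:.4g}" + (f" m={p.m:.4g}" if p.m is not None else "")
                        + (f" c={p.c:.4g} d={p.d:.4g}" if self.disturbance else ""))
        return "\n".join(rows)


def _whiten_matrix(J: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(J)
    out[0] = math.sqrt(1.0 - rho**2) * J[0]
    out[1:] = J[1:] - rho * J[:-1]
    return out


def _curve_step(ybar: np.ndarray, grid: LightGrid, family: str, disturbance: bool,
                rho: float, x0: np.ndarray, method: str = "ls") -> np.ndarray:
    """GLS curve update against one group-mean trajectory under fixed ρ."""
    l = grid.log_levels

    def resid_w(x):
        p = HDEEParams.from_vector(x, family, disturbance)
        with np.errstate(over="ignore", invalid="ignore"):
            pred = eval_hdee(family, p, l)
        pred = np.where(np.isfinite(pred), pred, 1e6)
        return _whiten(pred - ybar, rho)

    def jac_w(x):
        p = HDEEParams.from_vector(x, family, disturbance)
        J = hdee_jacobian(family, p, l, disturbance)
        J = np.where(np.isfinite(J), J, 0.0)
        return _whiten_matrix(J, rho)

    if method == "nelder-mead":
        sol = optimize.minimize(lambda x: float(np.sum(resid_w(x) ** 2)), x0,
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        x_new = sol.x
    else:
        try:
            sol = optimize.least_squares(resid_w, x0, jac=jac_w, method="lm",
                                         xtol=1e-12, ftol=1e-12, max_nfev=300)
            x_new = sol.x
        except Exception:
            lo, hi = _parameter_bounds(family, disturbance, ybar)
            sol = optimize.least_squares(resid_w, np.clip(x0, lo, hi), bounds=(lo, hi),
                                         method="trf", xtol=1e-12, ftol=1e-12,
                                         gtol=1e-12, max_nfev=400)
            x_new = sol.x
    # Accept only if the GLS objective did not get worse (warm-start guard).
    if np.sum(resid_w(x_new) ** 2) <= np.sum(resid_w(x0) ** 2):
        return x_new
    return x0


def _fit_grouped(Y: np.ndarray, grid: LightGrid, family: str, disturbance: bool,
                 groups: Sequence[np.ndarray], x0s: Sequence[np.ndarray],
                 cov0: Optional[CovarianceParams] = None, max_outer: int = 8,
                 tol: float = 1e-6, method: str = "ls") -> tuple[list, CovarianceParams, float, bool]:
    """Alternating maximisation of the grouped AR(1) trajectory likelihood."""
    n, L = Y.shape
    ybars = [Y[idx].mean(axis=0) for idx in groups]
    xs = [np.asarray(x, dtype=float).copy() for x in x0s]

    def residuals(xs_):
        R = np.empty_like(Y)
        for idx, x in zip(groups, xs_):
            p = HDEEParams.from_vector(x, family, disturbance)
            R[idx] = Y[idx] - eval_hdee(family, p, grid.log_levels)[None, :]
        return R

    if cov0 is None:
        cov, ll = _ar1_mle(residuals(xs))
    else:
        cov = cov0
        ll = _ar1_loglik_from_stats(*_ar1_suffstats(residuals(xs)), n, L, cov.sigma2, cov.rho)

    converged = False
    for _ in range(max_outer):
        for gi, ybar in enumerate(ybars):
            xs[gi] = _curve_step(ybar, grid, family, disturbance, cov.rho, xs[gi], method)
        R = residuals(xs)
        cov_new, ll_new = _ar1_mle(R)
        if ll_new < ll:  # never step downhill in covariance
            ll_new = _ar1_loglik_from_stats(*_ar1_suffstats(R), n, L, cov.sigma2, cov.rho)
            cov_new = cov
        if ll_new < ll - 1e-9:
            break
        improved = ll_new - ll
        cov, ll = cov_new, ll_new
        if improved < tol:
            converged = True
            break
    return xs, cov, ll, converged


def fit_null_model(traj: TraitTrajectories, family: str = "logistic",
                   disturbance: bool = True, x0: Optional[np.ndarray] = None,
                   n_restarts: int = 10, seed: int = 0, method: str = "ls") -> GenotypeModelFit:
    """Single shared mean curve + AR(1) covariance, maximising the pooled likelihood."""
    Y = traj.values
    if x0 is None:
        ols = HDEECurveModel(Y.mean(axis=0), traj.grid, family, disturbance).fit(
            n_restarts=n_restarts, seed=seed)
        x0 = ols.params.as_vector(family, disturbance)
    xs, cov, ll, conv = _fit_grouped(Y, traj.grid, family, disturbance,
                                     [np.arange(Y.shape[0])], [x0], method=method)
    return GenotypeModelFit(
        trait=traj.trait, family=family, disturbance=disturbance,
        genotype_params={None: HDEEParams.from_vector(xs[0], family, disturbance)},
        group_sizes={None: Y.shape[0]}, cov=cov, loglik=ll, grid=traj.grid, converged=conv,
    )


class SNPSkipped(ValueError):
    """Raised when a SNP cannot be tested (with a reason code)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def fit_genotype_model(traj: TraitTrajectories, genotype_column, family: str = "logistic",
                       disturbance: bool = True, min_group_size: int = 5,
                       null_fit: Optional[GenotypeModelFit] = None,
                       collapse_rare: bool = False, method: str = "ls") -> GenotypeModelFit:
    """Genotype-stratified curve fit with one shared AR(1) covariance.

    Samples with missing genotype are dropped.  Genotype groups smaller than
    ``min_group_size`` cause the SNP to be skipped unless ``collapse_rare``
    merges the rare heterozygote class into the nearer homozygote.
    """
    codes = np.asarray(genotype_column)
    if codes.size != traj.n_samples:
        raise ValueError("genotype column length must match sample count")
    bad = ~np.isin(codes, [0, 1, 2, MISSING])
    if bad.any():
        raise ValueError(f"unknown genotype codes: {np.unique(codes[bad])}")
    keep = codes != MISSING
    Y = traj.values[keep]
    codes = codes[keep].astype(int)
    if Y.shape[0] == 0:
        raise SNPSkipped("all_missing")

    uniq, counts = np.unique(codes, return_counts=True)
    if collapse_rare:
        for g, c in zip(list(uniq), list(counts)):
            if c < min_group_size and g == 1 and uniq.size > 1:
                others = uniq[uniq != 1]
                target = others[np.argmax([np.sum(codes == o) for o in others])]
                codes[codes == 1] = target
        uniq, counts = np.unique(codes, return_counts=True)
    if np.any(counts < min_group_size) and uniq.size > 1:
        raise SNPSkipped("group_below_min_size")

    if null_fit is None or null_fit.n != Y.shape[0]:
        sub = TraitTrajectories(traj.trait, Y, traj.grid)
        x0 = None
        if null_fit is not None:
            x0 = next(iter(null_fit.genotype_params.values())).as_vector(family, disturbance)
        null_fit = fit_null_model(sub, family, disturbance, x0=x0, method=method)

    if uniq.size == 1:
        return GenotypeModelFit(
            trait=traj.trait, family=family, disturbance=disturbance,
            genotype_params={int(uniq[0]): next(iter(null_fit.genotype_params.values()))},
            group_sizes={int(uniq[0]): int(counts[0])}, cov=null_fit.cov,
            loglik=null_fit.loglik, grid=traj.grid, converged=null_fit.converged,
        )

    x_null = next(iter(null_fit.genotype_params.values())).as_vector(family, disturbance)
    groups = [np.flatnonzero(codes == g) for g in uniq]
    xs, cov, ll, conv = _fit_grouped(Y, traj.grid, family, disturbance, groups,
                                     [x_null.copy() for _ in uniq], cov0=null_fit.cov,
                                     method=method)
    return GenotypeModelFit(
        trait=traj.trait, family=family, disturbance=disturbance,
        genotype_params={int(g): HDEEParams.from_vector(x, family, disturbance)
                         for g, x in zip(uniq, xs)},
        group_sizes={int(g): int(c) for g, c in zip(uniq, counts)},
        cov=cov, loglik=ll, grid=traj.grid, converged=conv,
    )


def lr_test(L0: float, L1: float, df: int) -> tuple[float, float]:
    """LR = −2(logL0 − logL1), clipped at zero, referred to χ²_df."""
    if df < 1:
        raise ValueError("df must be >= 1")
    lr = max(0.0, -2.0 * (L0 - L1))
    return lr, float(stats.chi2.sf(lr, df))


def genome_scan(traj: TraitTrajectories, gm: GenotypeMatrix, family: str = "logistic",
                disturbance: bool = True, min_group_size: int = 5,
                collapse_rare: bool = False, method: str = "ls") -> pd.DataFrame:
    """Likelihood-ratio scan over every SNP; one record per SNP.

    Deterministic: the per-SNP alternative fits are warm-started from the
    (deterministic) null fit, so rescanning the same data, in any SNP
    order, reproduces identical LR values.
    """
    if not np.array_equal(traj.sample_ids, gm.sample_ids):
        raise ValueError("sample ids must be aligned between phenotypes and genotypes")
    if gm.n_snps == 0:
        raise ValueError("no SNPs to scan")
    p_curve = n_growth_params(family) + (2 if disturbance else 0)
    null_all = fit_null_model(traj, family, disturbance, method=method)
    rows = []
    for i in range(gm.n_snps):
        snp = gm.snp_ids[i]
        snp = snp.item() if hasattr(snp, "item") else snp
        col = gm.codes[i]
        has_missing = np.any(col == MISSING)
        null_i = null_all
        if has_missing:
            keep = col != MISSING
            sub = TraitTrajectories(traj.trait, traj.values[keep], traj.grid)
            x0 = next(iter(null_all.genotype_params.values())).as_vector(family, disturbance)
            null_i = fit_null_model(sub, family, disturbance, x0=x0, method=method)
        base = {"snp_id": snp, "chrom": np.asarray(gm.chrom)[i], "pos": np.asarray(gm.pos)[i]}
        try:
            alt = fit_genotype_model(traj, col, family, disturbance, min_group_size,
                                     null_fit=null_i, collapse_rare=collapse_rare, method=method)
        except SNPSkipped as exc:
            rows.append({**base, "L0": np.nan, "L1": np.nan, "lr": np.nan, "df": 0,
                         "pvalue": np.nan, "G": 0, "counts": "", "status": exc.reason})
            continue
        df_ = (alt.G - 1) * p_curve
        if df_ == 0:
            rows.append({**base, "L0": null_i.loglik, "L1": alt.loglik, "lr": 0.0, "df": 0,
                         "pvalue": np.nan, "G": alt.G,
                         "counts": _counts_str(alt.group_sizes), "status": "monomorphic"})
            continue
        lr, p = lr_test(null_i.loglik, alt.loglik, df_)
        rows.append({**base, "L0": null_i.loglik, "L1": alt.loglik, "lr": lr, "df": df_,
                     "pvalue": p, "G": alt.G, "counts": _counts_str(alt.group_sizes),
                     "status": "ok"})
    return pd.DataFrame(rows)


def _counts_str(group_sizes: Mapping) -> str:
    return ";".join(f"{g}:{n}" for g, n in sorted(group_sizes.items()))


# ---------------------------------------------------------------------------
# Significance sets
# ---------------------------------------------------------------------------

def _ranked_ids(scan: pd.DataFrame) -> list:
    ok = scan[scan["status"] == "ok"].reset_index(drop=True)
    ids = ok["snp_id"].tolist()
    lrs = ok["lr"].tolist()
    order = sorted(range(len(ids)), key=lambda i: (-lrs[i], i))
    return [ids[i] for i in order]


def build_potential_key_set(scan: pd.DataFrame, k: int = 10000) -> list:
    """Top-k SNP ids by LR (stable tie-break by scan order); all if k ≥ #SNPs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = _ranked_ids(scan)
    return ranked[: min(k, len(ranked))]


def select_significant(scan: pd.DataFrame, top_fraction: float = 0.03) -> list:
    """ceil(top_fraction × #tested) highest-LR SNP ids."""
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    ranked = _ranked_ids(scan)
    k = math.ceil(top_fraction * len(ranked))
    return ranked[:k]


def intersect_models(classical_set: Sequence, hdee_set: Sequence) -> list:
    """Loci significant under both curve models, in classical-set order."""
    h = set(hdee_set)
    return [s for s in classical_set if s in h]


def detect_pleiotropy(robust_sets: Mapping[str, Sequence]) -> pd.DataFrame:
    """SNPs present in the robust sets of two or more traits."""
    if len(robust_sets) < 2:
        raise ValueError("pleiotropy detection needs at least two traits")
    membership: dict = {}
    for trait, ids in robust_sets.items():
        for s in ids:
            membership.setdefault(s, []).append(trait)
    rows = [{"snp_id": s, "traits": tuple(ts), "n_traits": len(ts)}
            for s, ts in membership.items() if len(ts) >= 2]
    return pd.DataFrame(rows, columns=["snp_id", "traits", "n_traits"])


# ---------------------------------------------------------------------------
# Static per-level scan and data diagnostics
# ---------------------------------------------------------------------------

def static_scan(traj: TraitTrajectories, gm: GenotypeMatrix, level_index: int,
                min_group_size: int = 2) -> pd.DataFrame:
    """One-way ANOVA of the phenotype at a single light level per SNP."""
    if not 0 <= level_index < traj.grid.L:
        raise ValueError("invalid light-level index")
    y = traj.values[:, level_index]
    rows = []
    for i in range(gm.n_snps):
        col = gm.codes[i]
        keep = col != MISSING
        groups = [y[keep][col[keep] == g] for g in np.unique(col[keep])]
        groups = [g for g in groups if g.size >= min_group_size]
        if len(groups) < 2 or all(np.ptp(g) == 0 for g in groups):
            rows.append({"snp_id": gm.snp_ids[i], "F": np.nan, "pvalue": np.nan,
                         "status": "degenerate"})
            continue
        res = stats.f_oneway(*groups)
        rows.append({"snp_id": gm.snp_ids[i], "F": float(res.statistic),
                     "pvalue": float(res.pvalue), "status": "ok"})
    return pd.DataFrame(rows)


def ks_normality(values) -> tuple[float, float]:
    """Kolmogorov–Smirnov test against a moment-matched normal."""
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input")
    res = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def kinship_matrix(gm: GenotypeMatrix, threshold: float = 0.3) -> tuple[np.ndarray, dict]:
    """Pearson correlation of centered genotype vectors between samples.

    Negative correlations are floored at zero in the reported matrix (raw
    values are returned in the summary); the summary gives the off-diagonal
    range and the fraction of pairs below ``threshold``.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = gm.codes.astype(float)
    X[gm.codes == MISSING] = np.nan
    mean = np.nanmean(X, axis=1, keepdims=True)
    Xc = np.where(np.isnan(X), 0.0, X - mean)
    sd = Xc.std(axis=1)
    poly = sd > 0
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    Xc = Xc[poly]
    with np.errstate(invalid="ignore"):
        raw = np.corrcoef(Xc.T)
    floored = np.clip(raw, 0.0, None)
    np.fill_diagonal(floored, 1.0)
    off = floored[~np.eye(gm.n_samples, dtype=bool)]
    summary = {
        "min": float(off.min()), "max": float(off.max()),
        "fraction_below_threshold": float(np.mean(off < threshold)),
        "threshold": threshold, "raw": raw,
    }
    return floored, summary
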