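"""Genetic-effect trajectories derived from per-SNP genotype model fits.

The disparity between genotype mean curves is the SNP's genetic effect on
the trait.  The default contrast is the additive homozygote contrast
a(l) = (μ_minor-hom(l) − μ_major-hom(l)) / 2; when only two genotype
classes were observed, half their mean difference in the minor-allele
direction is used instead.  The applied rule is recorded on the curve as
``definition_tag`` so downstream consumers can audit it.

Because genotype curves are closed-form, effect curves can be re-evaluated
exactly on arbitrarily dense light grids — the form the ODE network stage
requires.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .growth import HDEEParams, eval_disturbance, eval_growth, eval_hdee
from .hdee import HDEECurveModel
from .mapping import GenotypeModelFit
from .data import MISSING, TraitTrajectories

__all__ = [
    "GeneticEffectCurve",
    "genotype_mean_curves",
    "overall_genetic_effect",
    "resample_effect_grid",
    "fit_per_sample_params",
    "genotype_param_tests",
]


@dataclass
class GeneticEffectCurve:
    """Per-SNP effect trajectory g(l) with its generating contrast."""

    snp_id: object
    trait: str
    grid: np.ndarray
    values: np.ndarray
    family: str
    genotype_params: Mapping[int, HDEEParams]
    contrast: tuple  # ((code_hi, sign_hi), (code_lo, sign_lo), scale)
    definition_tag: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("effect grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("effect values must be finite")

    def evaluate(self, l) -> np.ndarray:
        """Exact closed-form re-evaluation of the contrast at new abscissae."""
        l = np.asarray(l, dtype=float)
        (hi, lo), scale = self.contrast[:2], self.contrast[2]
        mu_hi = eval_hdee(self.family, self.genotype_params[hi], l)
        mu_lo = eval_hdee(self.family, self.genotype_params[lo], l)
        return scale * (mu_hi - mu_lo)


def genotype_mean_curves(fit: GenotypeModelFit, n_points: int = 30) -> dict:
    """Per-genotype φ, ω, composite curves and disturbance share on a dense grid."""
    dense = fit.grid.dense(n_points)
    out = {}
    for g, p in fit.genotype_params.items():
        phi = eval_growth(fit.family, p, dense)
        omega = eval_disturbance(p.c, p.d, dense) if fit.disturbance else np.zeros_like(dense)
        total = np.abs(phi) + np.abs(omega)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(total > 0, np.abs(omega) / total, np.nan)
        out[g] = pd.DataFrame({"l": dense, "autogenic": phi, "disturbance": omega,
                               "composite": phi + omega, "disturbance_share": share})
    return out


def overall_genetic_effect(fit: GenotypeModelFit, snp_id=None, n_points: int = 30,
                           minor_is_alt: Optional[bool] = None) -> GeneticEffectCurve:
    """Additive genetic-effect trajectory of one SNP.

    ``minor_is_alt`` overrides the minor-allele call; by default it is
    inferred from the fitted group sizes (alternate-allele frequency < 0.5).
    """
    codes = sorted(k for k in fit.genotype_params if k is not None)
    if len(codes) < 2:
        raise ValueError("genetic effect needs at least two genotype classes")
    if minor_is_alt is None:
        n = fit.n
        alt_freq = sum(g * fit.group_sizes[g] for g in codes) / (2.0 * n)
        minor_is_alt = alt_freq <= 0.5
    if 0 in codes and 2 in codes:
        hi, lo, tag = 2, 0, "additive_homozygote_contrast"
    else:
        hi, lo = max(codes), min(codes),
        tag = "half_difference_two_genotypes"
    if not minor_is_alt:
        hi, lo = lo, hi
        tag += "|minor=ref"
    else:
        tag += "|minor=alt"
    dense = fit.grid.dense(n_points)
    mu_hi = eval_hdee(fit.family, fit.genotype_params[hi], dense)
    mu_lo = eval_hdee(fit.family, fit.genotype_params[lo], dense)
    return GeneticEffectCurve(
        snp_id=snp_id, trait=fit.trait, grid=dense, values=0.5 * (mu_hi - mu_lo),
        family=fit.family, genotype_params=dict(fit.genotype_params),
        contrast=(hi, lo, 0.5), definition_tag=tag,
    )


def resample_effect_grid(curve: GeneticEffectCurve, n_points: int) -> GeneticEffectCurve:
    """Re-evaluate the closed-form contrast on a uniform dense grid (no
    interpolation error)."""
    if n_points < curve.grid.size:
        raise ValueError("n_points must be at least the current grid size")
    dense = np.linspace(curve.grid[0], curve.grid[-1], n_points)
    return replace(curve, grid=dense, values=curve.evaluate(dense))


def fit_per_sample_params(traj: TraitTrajectories, fit: GenotypeModelFit,
                          genotype_column, start: str = "pooled") -> pd.DataFrame:
    """Fit the composite curve to each sample individually.

    Every sample is warm-started from the same pooled-mean fit (no
    restarts).  A shared start matters: the composite curve has a weakly
    identified ridge between K and c·l^d, and starting each genotype group
    from its own group fit can park the groups in different ridge basins,
    manufacturing spurious parameter differences under the null.
    ``start="group"`` restores per-group warm starts for comparison.
    """
    codes = np.asarray(genotype_column)
    if start == "pooled":
        pooled = HDEECurveModel.from_trajectories(
            traj.values, traj.grid, family=fit.family, disturbance=fit.disturbance
        ).fit(n_restarts=10)
        start_of = {g: pooled.params for g in fit.genotype_params}
    else:
        start_of = dict(fit.genotype_params)
    fallback = next(iter(start_of.values()))
    rows = []
    for k in range(traj.n_samples):
        g = int(codes[k]) if codes[k] != MISSING else None
        start_p = start_of.get(g, fallback)
        model = HDEECurveModel(traj.values[k], traj.grid, fit.family, fit.disturbance)
        res = model.fit(n_restarts=0, x0=start_p.as_vector(fit.family, fit.disturbance))
        p = res.params
        rows.append({"sample": traj.sample_ids[k], "genotype": codes[k],
                     "K": p.K, "a": p.a, "b": p.b,
                     **({"m": p.m} if p.m is not None else {}),
                     "c": p.c, "d": p.d, "rss": res.rss})
    return pd.DataFrame(rows)


def genotype_param_tests(per_sample_params: pd.DataFrame,
                         params: Sequence[str] = ("K", "a", "b", "c", "d"),
                         min_group_size: int = 3) -> dict:
    """Two-sided Mann–Whitney U per curve parameter between two genotype groups."""
    present = [g for g in sorted(per_sample_params["genotype"].unique()) if g != MISSING]
    if len(present) != 2:
        raise ValueError("parameter tests compare exactly two genotype groups")
    g1 = per_sample_params[per_sample_params["genotype"] == present[0]]
    g2 = per_sample_params[per_sample_params["genotype"] == present[1]]
    if len(g1) < min_group_size or len(g2) < min_group_size:
        raise ValueError("both genotype groups need at least min_group_size samples")
    out = {}
    for name in params:
        if name not in per_sample_params.columns:
            continue
        x, y = g1[name].to_numpy(), g2[name].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            continue  # degenerate: identical constant values
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        out[name] = {"U": float(res.statistic), "pvalue": float(res.pvalue)}
    return out
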