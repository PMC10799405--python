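"""Synthetic study generator.

Emulates the study design the pipeline targets: ~100 clonally propagated
poplar samples phenotyped for three chlorophyll-fluorescence traits (ETR,
qP, qN) under an 11-step actinic light ladder, genotyped at thousands of
biallelic SNPs.  Trajectories follow trait-specific composite curves
(logistic / Mitscherlich / Korf plus an allometric disturbance c·l^d) with
stationary AR(1) residuals; a small number of planted causal SNPs shift the
asymptote K and rate b of the autogenic term per copy of the alternate
allele, while all remaining SNPs are phenotypically null.

Defaults are the study conditions used throughout the tests: 98 samples,
11 log-spaced light levels from 7.243 to 2701.536 μmol·m⁻²·s⁻¹, residual
standard deviation 5% of each trait's asymptote, lag-1 correlation 0.6,
and three causal SNPs per trait with 10%/8% per-allele shifts on K/b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .data import MISSING, GenotypeMatrix, TraitTrajectories
from .growth import HDEEParams, TRAIT_FORMS, eval_hdee
from .light import LightGrid, default_light_grid

__all__ = [
    "SimulationDesign",
    "SyntheticStudy",
    "DEFAULT_TRAIT_PARAMS",
    "simulate_genotypes",
    "simulate_trajectories",
    "simulate_study",
]

#: Baseline composite-curve parameters per trait (shared by all null SNPs).
DEFAULT_TRAIT_PARAMS: dict[str, HDEEParams] = {
    "ETR": HDEEParams(K=30.0, a=8.0, b=1.2, c=1.5, d=0.8),
    "qP": HDEEParams(K=0.2, a=-4.0, b=0.6, c=0.3, d=-0.5),
    "qN": HDEEParams(K=0.95, a=30.0, b=2.5, c=0.1, d=-1.5),
}

#: Residual standard deviation as a fraction of the trait asymptote K.
NOISE_CV = 0.05


@dataclass
class SimulationDesign:
    """Dials of the synthetic study (defaults are the reference conditions)."""

    n_samples: int = 98
    n_snps: int = 2000
    n_causal: int = 3
    maf_range: tuple = (0.1, 0.5)
    genotype_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"K": 0.10, "b": 0.08})
    residual_sigma2: Optional[Mapping[str, float]] = None
    residual_rho: float = 0.6
    group_count: int = 6
    missing_rate: float = 0.0
    L: int = 11
    traits: tuple = ("ETR", "qP", "qN")
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.05 < lo < hi <= 0.5):
            raise ValueError("maf_range must lie within (0.05, 0.5]")
        if self.n_causal < 0 or self.n_causal * len(self.traits) > self.n_snps:
            raise ValueError("n_causal per trait must fit within n_snps")
        if not abs(self.residual_rho) < 1:
            raise ValueError("|residual_rho| must be < 1")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")

    def sigma2_for(self, trait: str) -> float:
        if self.residual_sigma2 is not None:
            return float(self.residual_sigma2[trait])
        return (NOISE_CV * DEFAULT_TRAIT_PARAMS[trait].K) ** 2


@dataclass
class SyntheticStudy:
    """Genotypes, per-trait trajectories, and the generating truth record."""

    genotypes: GenotypeMatrix
    trajectories: dict
    truth: dict
    grid: LightGrid

    def write(self, outdir) -> None:
        from .io import write_coded_matrix, write_phenotypes, write_truth, write_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(self.genotypes, outdir / "genotypes.vcf")
        write_coded_matrix(self.genotypes, outdir / "genotypes.csv")
        write_phenotypes(self.trajectories, outdir / "phenotypes.csv")
        write_truth(self.truth, outdir / "truth.json")


def simulate_genotypes(n_samples: int, n_snps: int, maf_range=(0.1, 0.5),
                       seed: int = 0, missing_rate: float = 0.0) -> GenotypeMatrix:
    """Hardy–Weinberg genotypes at per-SNP allele frequencies drawn uniformly.

    The alternate-allele frequency is drawn from ``maf_range`` (⊆ (0.05, 0.5]),
    so the alternate allele is the minor one; codes count its copies.
    """
    lo, hi = maf_range
    if not (0.05 < lo < hi <= 0.5):
        raise ValueError("maf_range must lie within (0.05, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    codes = rng.binomial(2, p[:, None], size=(n_snps, n_samples)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = MISSING
    snp_ids = np.array([f"snp{i:06d}" for i in range(n_snps)])
    sample_ids = np.array([f"S{i:03d}" for i in range(n_samples)])
    chrom = np.array([str(1 + (i % 19)) for i in range(n_snps)], dtype=object)
    pos = np.arange(1, n_snps + 1) * 100
    return GenotypeMatrix(snp_ids, sample_ids, codes, chrom=chrom, pos=pos)


def _ar1_noise(rng: np.random.Generator, n: int, L: int, sigma2: float, rho: float) -> np.ndarray:
    """Stationary AR(1) rows: cov(e_j, e_k) = σ²ρ^|j−k| exactly."""
    if sigma2 == 0:
        return np.zeros((n, L))
    sigma = np.sqrt(sigma2)
    e = np.empty((n, L))
    e[:, 0] = rng.normal(0.0, sigma, size=n)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for j in range(1, L):
        e[:, j] = rho * e[:, j - 1] + rng.normal(0.0, innov_sd, size=n)
    return e


def simulate_trajectories(grid: LightGrid, genotype_column, per_genotype_params: Mapping,
                          sigma2: float, rho: float, seed: int = 0,
                          family: str = "logistic") -> np.ndarray:
    """Genotype-specific mean curves plus one AR(1) residual draw per sample."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    codes = np.asarray(genotype_column)
    unknown = set(np.unique(codes)) - set(per_genotype_params)
    if unknown:
        raise ValueError(f"unknown genotype codes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    l = grid.log_levels
    curves = {g: eval_hdee(family, p, l) for g, p in per_genotype_params.items()}
    mu = np.stack([curves[g] for g in codes])
    return mu + _ar1_noise(rng, codes.size, grid.L, sigma2, rho)


def _shifted_params(base: HDEEParams, dosage_total: Mapping[str, float]) -> HDEEParams:
    kw = {}
    for name, shift in dosage_total.items():
        kw[name] = getattr(base, name) * (1.0 + shift)
    return base.with_(**kw)


def simulate_study(design: SimulationDesign, grid: Optional[LightGrid] = None) -> SyntheticStudy:
    """Full synthetic study: genotypes, planted architecture, trajectories, truth.

    Causal SNPs are drawn with allele frequency in the upper half of
    ``maf_range`` so that every genotype class is large enough to test, and
    each copy of the alternate allele multiplies the affected curve
    parameters by (1 + effect).  Causal sets are disjoint across traits.
    """
    rng = np.random.default_rng(design.seed)
    if grid is None:
        grid = default_light_grid(design.L)
    gm = simulate_genotypes(design.n_samples, design.n_snps, design.maf_range,
                            seed=int(rng.integers(2**31 - 1)),
                            missing_rate=design.missing_rate)

    n_causal_total = design.n_causal * len(design.traits)
    causal_idx = rng.choice(design.n_snps, size=n_causal_total, replace=False) \
        if n_causal_total else np.array([], dtype=int)
    # redraw causal genotype rows at common frequencies
    lo, hi = design.maf_range
    mid = max(lo, 0.5 * (lo + hi))
    for i in causal_idx:
        p = rng.uniform(mid, hi)
        gm.codes[i] = rng.binomial(2, p, size=design.n_samples).astype(np.int8)

    causal_by_trait = {
        trait: sorted(gm.snp_ids[causal_idx[t * design.n_causal:(t + 1) * design.n_causal]].tolist())
        for t, trait in enumerate(design.traits)
    }
    id_to_row = {s: i for i, s in enumerate(gm.snp_ids)}

    trajectories: dict[str, TraitTrajectories] = {}
    genotype_params_truth: dict = {}
    for trait in design.traits:
        base = DEFAULT_TRAIT_PARAMS[trait]
        family = TRAIT_FORMS[trait]
        dosage = np.zeros(design.n_samples)
        for s in causal_by_trait[trait]:
            col = np.clip(gm.codes[id_to_row[s]], 0, 2)  # missing treated as 0 dosage
            dosage = dosage + col
        # per-sample parameter shifts accumulate additively over causal alleles
        mu = np.empty((design.n_samples, grid.L))
        for k in range(design.n_samples):
            shifts = {name: eff * dosage[k] for name, eff in design.genotype_effect_sizes.items()}
            mu[k] = eval_hdee(family, _shifted_params(base, shifts), grid.log_levels)
        sigma2 = design.sigma2_for(trait)
        noise = _ar1_noise(np.random.default_rng(int(rng.integers(2**31 - 1))),
                           design.n_samples, grid.L, sigma2, design.residual_rho)
        trajectories[trait] = TraitTrajectories(trait, mu + noise, grid,
                                                sample_ids=gm.sample_ids)
        genotype_params_truth[trait] = {
            "family": family,
            "baseline": vars(base).copy(),
            "per_allele_effects": dict(design.genotype_effect_sizes),
            "sigma2": sigma2,
            "rho": design.residual_rho,
        }

    groups = rng.integers(design.group_count, size=design.n_samples)
    truth = {
        "causal_snps": causal_by_trait,
        "trait_models": genotype_params_truth,
        "group_labels": groups.tolist(),
        "seed": design.seed,
        "design": {
            "n_samples": design.n_samples, "n_snps": design.n_snps,
            "n_causal": design.n_causal, "maf_range": list(design.maf_range),
            "group_count": design.group_count, "missing_rate": design.missing_rate,
            "L": design.L, "traits": list(design.traits),
        },
    }
    return SyntheticStudy(genotypes=gm, trajectories=trajectories, truth=truth, grid=grid)
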