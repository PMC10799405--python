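"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .light import LightGrid

MISSING = -1  # genotype code for a missing call


@dataclass
class GenotypeMatrix:
    """Coded biallelic SNP genotypes.

    ``codes`` is an (n_snps × n_samples) integer matrix counting copies of
    the alternate allele (0/1/2), with :data:`MISSING` (−1) for no-calls.
    """

    snp_ids: np.ndarray
    sample_ids: np.ndarray
    codes: np.ndarray
    chrom: np.ndarray = None  # type: ignore[assignment]
    pos: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (self.snp_ids.size, self.sample_ids.size):
            raise ValueError("codes must be n_snps x n_samples")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or missing (-1)")
        if self.chrom is None:
            self.chrom = np.full(self.snp_ids.size, "1", dtype=object)
        if self.pos is None:
            self.pos = np.arange(1, self.snp_ids.size + 1)

    @property
    def n_snps(self) -> int:
        return self.snp_ids.size

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @property
    def missing_rate(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=1)

    @property
    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        obs = self.codes != MISSING
        with np.errstate(invalid="ignore"):
            alt = np.where(obs, self.codes, 0).sum(axis=1) / (2.0 * obs.sum(axis=1))
        return np.minimum(alt, 1.0 - alt)

    def subset(self, snp_index=None, sample_index=None) -> "GenotypeMatrix":
        si = np.arange(self.n_snps) if snp_index is None else np.asarray(snp_index)
        ki = np.arange(self.n_samples) if sample_index is None else np.asarray(sample_index)
        return GenotypeMatrix(
            snp_ids=self.snp_ids[si], sample_ids=self.sample_ids[ki],
            codes=self.codes[np.ix_(si, ki)], chrom=np.asarray(self.chrom)[si],
            pos=np.asarray(self.pos)[si],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, index=self.snp_ids, columns=self.sample_ids)
        df.index.name = "snp_id"
        return df


@dataclass
class TraitTrajectories:
    """Per-sample phenotype trajectories of one trait over a shared grid."""

    trait: str
    values: np.ndarray
    grid: LightGrid
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.L:
            raise ValueError("values must be an n_samples x L matrix on the grid")
        if np.any(np.all(np.isnan(self.values), axis=1)):
            raise ValueError("trajectories contain an entirely-missing row")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i:03d}" for i in range(self.values.shape[0])])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
        if self.sample_ids.size != self.values.shape[0]:
            raise ValueError("sample_ids length must match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, sample_index) -> "TraitTrajectories":
        idx = np.asarray(sample_index)
        return TraitTrajectories(self.trait, self.values[idx], self.grid, self.sample_ids[idx])

    def to_tidy(self) -> pd.DataFrame:
        n, L = self.values.shape
        return pd.DataFrame(
            {
                "sample": np.repeat(self.sample_ids, L),
                "trait": self.trait,
                "light_level": np.tile(self.grid.raw_levels, n),
                "value": self.values.ravel(),
            }
        )


def align_samples(traj: TraitTrajectories, gm: GenotypeMatrix) -> tuple[TraitTrajectories, GenotypeMatrix, list]:
    """Intersect phenotype and genotype sample sets, preserving genotype order."""
    common = [s for s in gm.sample_ids if s in set(traj.sample_ids)]
    dropped = [s for s in traj.sample_ids if s not in set(gm.sample_ids)]
    dropped += [s for s in gm.sample_ids if s not in set(traj.sample_ids)]
    t_idx = {s: i for i, s in enumerate(traj.sample_ids)}
    g_idx = {s: i for i, s in enumerate(gm.sample_ids)}
    traj2 = traj.subset([t_idx[s] for s in common])
    gm2 = gm.subset(sample_index=[g_idx[s] for s in common])
    return traj2, gm2, dropped
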