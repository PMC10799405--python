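"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (GT field only) or as a coded-matrix CSV
(snp_id × sample, values 0/1/2, empty for missing); phenotypes as tidy CSV
(sample, trait, light_level, value) or wide per-trait CSV (sample column +
one column per light level); truth records and significance sets as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .data import MISSING, GenotypeMatrix, TraitTrajectories
from .light import make_light_grid

log = logging.getLogger("photoqtl")

__all__ = [
    "read_vcf_genotypes",
    "write_vcf",
    "read_coded_matrix",
    "write_coded_matrix",
    "filter_snps",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "read_truth",
]


def read_vcf_genotypes(path, multiallelic: str = "reject") -> GenotypeMatrix:
    """Read biallelic GT calls from a VCF into a coded matrix.

    ``multiallelic='reject'`` drops records with more than one ALT allele
    (logged); any other policy raises, since splitting is out of scope.
    """
    if multiallelic != "reject":
        raise ValueError("only the 'reject' multi-allelic policy is supported")
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snp_ids, chroms, poss, rows = [], [], [], []
    n_multi = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        codes = np.empty(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                codes[j] = MISSING
            else:
                codes[j] = int(sum(1 for a in gt if a != 0))
        snp_ids.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}")
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        rows.append(codes)
    vf.close()
    if n_multi:
        log.info("dropped %d multi-allelic records", n_multi)
    if not rows:
        raise ValueError(f"no biallelic records found in {path}")
    return GenotypeMatrix(np.array(snp_ids), np.array(samples),
                          np.vstack(rows), chrom=np.array(chroms, dtype=object),
                          pos=np.array(poss))


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the coded matrix as a minimal GT-only VCF."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in sorted(set(map(str, gm.chrom)), key=str):
        header.add_line(f"##contig=<ID={c}>")
    for s in gm.sample_ids:
        header.add_sample(str(s))
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(gm.n_snps):
            rec = out.new_record(contig=str(gm.chrom[i]), start=int(gm.pos[i]) - 1,
                                 stop=int(gm.pos[i]), alleles=("A", "G"),
                                 id=str(gm.snp_ids[i]))
            for j, s in enumerate(gm.sample_ids):
                rec.samples[str(s)]["GT"] = gt_of[int(gm.codes[i, j])]
            out.write(rec)


def write_coded_matrix(gm: GenotypeMatrix, path) -> None:
    df = gm.to_frame().astype("object")
    df[gm.codes == MISSING] = ""
    df.insert(0, "chrom", gm.chrom)
    df.insert(1, "pos", gm.pos)
    df.to_csv(path)


def read_coded_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype={0: str})
    chrom = df.pop("chrom").to_numpy(dtype=object) if "chrom" in df else None
    pos = df.pop("pos").to_numpy() if "pos" in df else None
    codes = df.apply(pd.to_numeric, errors="coerce").fillna(MISSING).to_numpy()
    return GenotypeMatrix(df.index.to_numpy(), df.columns.to_numpy(),
                          codes.astype(np.int8), chrom=chrom, pos=pos)


def filter_snps(gm: GenotypeMatrix, maf_min: float = 0.05,
                missing_max: float = 0.2) -> tuple[GenotypeMatrix, dict]:
    """Keep SNPs with MAF strictly > maf_min, missing rate ≤ missing_max,
    and exactly two observed alleles.

    Each removed SNP is counted under the first rule it violates
    (biallelic → missing → MAF), so rule counts plus survivors add up to
    the input count.
    """
    obs = gm.codes != MISSING
    # a site is biallelic in coded form when both alleles are observed:
    alt_count = np.where(obs, gm.codes, 0).sum(axis=1)
    total = 2 * obs.sum(axis=1)
    has_both = (alt_count > 0) & (alt_count < total)
    miss = gm.missing_rate
    maf = gm.maf
    fail_biallelic = ~has_both
    fail_missing = ~fail_biallelic & (miss > missing_max)
    fail_maf = ~fail_biallelic & ~fail_missing & ~(maf > maf_min)
    keep = ~(fail_biallelic | fail_missing | fail_maf)
    if not keep.any():
        raise ValueError("no SNPs survive filtering")
    report = {
        "input": int(gm.n_snps),
        "removed_not_biallelic": int(fail_biallelic.sum()),
        "removed_missing_rate": int(fail_missing.sum()),
        "removed_maf": int(fail_maf.sum()),
        "kept": int(keep.sum()),
        "maf_min": maf_min,
        "missing_max": missing_max,
    }
    return gm.subset(snp_index=np.flatnonzero(keep)), report


def write_phenotypes(trajectories: Mapping[str, TraitTrajectories], path) -> None:
    pd.concat([t.to_tidy() for t in trajectories.values()]).to_csv(path, index=False)


def read_phenotypes(path) -> dict:
    """Read tidy (sample, trait, light_level, value) or wide phenotype CSV.

    Wide files need columns ``sample`` and ``trait`` plus one numeric-named
    column per raw light level.  All samples must share the light grid;
    duplicate (sample, trait, level) rows are an error.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"sample", "trait", "light_level", "value"} <= cols:
        tidy = df
    elif {"sample", "trait"} <= cols:
        levels = [c for c in df.columns if c not in ("sample", "trait")]
        tidy = df.melt(id_vars=["sample", "trait"], value_vars=levels,
                       var_name="light_level", value_name="value")
        tidy["light_level"] = tidy["light_level"].astype(float)
    else:
        raise ValueError("phenotype file must be tidy or wide with sample/trait columns")
    if tidy.duplicated(["sample", "trait", "light_level"]).any():
        raise ValueError("duplicate (sample, trait, light_level) rows")
    out = {}
    for trait, sub in tidy.groupby("trait", sort=False):
        wide = sub.pivot(index="sample", columns="light_level", values="value")
        if wide.isna().any().any():
            raise ValueError(f"inconsistent light grids across samples for trait {trait}")
        wide = wide.reindex(sorted(wide.columns), axis=1)
        grid = make_light_grid(np.asarray(wide.columns, dtype=float))
        out[str(trait)] = TraitTrajectories(str(trait), wide.to_numpy(), grid,
                                            sample_ids=wide.index.to_numpy())
    return out


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
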