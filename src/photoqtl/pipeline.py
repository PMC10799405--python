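"""End-to-end pipeline orchestration.

Stages run in the fixed order: SNP filtering → composite-curve fitting and
growth-family selection per trait → classical-model genome scan → potential
key set → composite-model (disturbance-augmented) rescan → per-trait
significant sets and their intersection → pleiotropy table → effect curves
for the robust loci → ODE network per trait.  Every stage writes its
outputs under the configured directory and is recorded in a machine-readable
run manifest (seeds, thresholds, stage outputs), so a rerun with the same
configuration and seed reproduces the same artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .data import align_samples
from .effects import overall_genetic_effect
from .growth import TRAIT_FORMS
from .hdee import estimate_group_perturbations, select_growth_model
from .mapping import (build_potential_key_set, detect_pleiotropy, fit_genotype_model,
                      genome_scan, intersect_models, select_significant, SNPSkipped)
from .network import QTLNetworkModel

log = logging.getLogger("photoqtl")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds steering one pipeline run."""

    genotypes: str
    phenotypes: str
    outdir: str
    groups: Optional[str] = None
    curve_families: dict = field(default_factory=lambda: dict(TRAIT_FORMS))
    maf_min: float = 0.05
    missing_max: float = 0.2
    key_set_size: int = 10000
    top_fraction: float = 0.03
    min_group_size: int = 5
    d_max: int = 15
    lop_order: int = 4
    tau_fraction: float = 0.01
    dense_points: int = 30
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("top_fraction", "tau_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate_paths(self) -> None:
        for name in ("genotypes", "phenotypes"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.groups is not None and not Path(self.groups).exists():
            raise FileNotFoundError(f"groups path does not exist: {self.groups}")


def _read_genotypes(path):
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return pio.read_vcf_genotypes(path)
    return pio.read_coded_matrix(path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    A stage failure halts the run with the stage name; outputs of completed
    stages stay on disk.
    """
    config.validate_paths()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "started": time.time()}
    stage = "load"
    try:
        gm = _read_genotypes(config.genotypes)
        trajectories = pio.read_phenotypes(config.phenotypes)

        stage = "filter"
        gm, report = pio.filter_snps(gm, config.maf_min, config.missing_max)
        (out / "filter_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"]["filter"] = {"output": "filter_report.json", **report}

        stage = "hdee_fit"
        fit_rows = []
        selected_family = {}
        for trait, traj in trajectories.items():
            traj, gm_t, dropped = align_samples(traj, gm)
            trajectories[trait] = traj
            if dropped:
                log.warning("trait %s: dropped unmatched samples %s", trait, dropped)
            fam = config.curve_families.get(trait, "logistic")
            best, table = select_growth_model(traj.values.mean(axis=0), traj.grid,
                                              with_disturbance=True, seed=config.seed)
            table.to_csv(out / f"hdee_selection_{trait}.csv")
            selected_family[trait] = fam  # configured form used downstream
            fit_rows.append({"trait": trait, "configured_family": fam,
                             "ic_best_family": table["bic"].idxmin(),
                             "rss": best.rss, "r2": best.r2})
            if config.groups is not None:
                labels = pd.read_csv(config.groups, index_col=0).iloc[:, 0]
                labels = labels.reindex(traj.sample_ids).to_numpy()
                from .hdee import fit_mean_curve
                gfit = fit_mean_curve(traj.values.mean(axis=0), traj.grid, fam,
                                      True, seed=config.seed)
                pert = estimate_group_perturbations(traj.values, traj.grid, gfit, labels)
                (out / f"group_perturbation_{trait}.json").write_text(json.dumps({
                    "kw_pvalue": pert.kw_pvalue, "anova_pvalue": pert.anova_pvalue,
                    "group_epsilon": {str(k): v for k, v in pert.group_epsilon.items()},
                }, indent=2))
        pd.DataFrame(fit_rows).to_csv(out / "hdee_fits.csv", index=False)
        manifest["stages"]["hdee_fit"] = {"output": "hdee_fits.csv"}

        gm = align_samples(next(iter(trajectories.values())), gm)[1]

        stage = "classical_scan"
        classical = {}
        for trait, traj in trajectories.items():
            scan = genome_scan(traj, gm, family=selected_family[trait],
                               disturbance=False, min_group_size=config.min_group_size)
            scan.to_csv(out / f"scan_classical_{trait}.csv", index=False)
            classical[trait] = scan
        manifest["stages"]["classical_scan"] = {
            "output": [f"scan_classical_{t}.csv" for t in trajectories]}

        stage = "potential_key_set"
        key_sets = {t: build_potential_key_set(classical[t], config.key_set_size)
                    for t in trajectories}
        (out / "potential_key_sets.json").write_text(
            json.dumps({t: list(map(str, s)) for t, s in key_sets.items()}, indent=2))
        manifest["stages"]["potential_key_set"] = {"output": "potential_key_sets.json",
                                                   "k": config.key_set_size}

        stage = "hdee_scan"
        hdee_scans = {}
        for trait, traj in trajectories.items():
            idx = [int(np.flatnonzero(gm.snp_ids == s)[0]) for s in key_sets[trait]]
            sub = gm.subset(snp_index=idx)
            scan = genome_scan(traj, sub, family=selected_family[trait],
                               disturbance=True, min_group_size=config.min_group_size)
            scan.to_csv(out / f"scan_hdee_{trait}.csv", index=False)
            hdee_scans[trait] = scan
        manifest["stages"]["hdee_scan"] = {
            "output": [f"scan_hdee_{t}.csv" for t in trajectories]}

        stage = "significance"
        robust = {}
        sig = {}
        for trait in trajectories:
            sc = select_significant(classical[trait], config.top_fraction)
            sh = select_significant(hdee_scans[trait], config.top_fraction)
            robust[trait] = intersect_models(sc, sh)
            sig[trait] = {"classical": list(map(str, sc)), "hdee": list(map(str, sh)),
                          "robust": list(map(str, robust[trait]))}
        pleio = detect_pleiotropy(robust) if len(robust) >= 2 else pd.DataFrame()
        (out / "significant_sets.json").write_text(json.dumps(sig, indent=2))
        pleio.to_csv(out / "pleiotropy.csv", index=False)
        manifest["stages"]["significance"] = {"output": ["significant_sets.json",
                                                         "pleiotropy.csv"],
                                              "top_fraction": config.top_fraction}

        stage = "effect_curves"
        effect_curves = {}
        for trait, traj in trajectories.items():
            curves = {}
            rows = []
            for snp in robust[trait]:
                i = int(np.flatnonzero(gm.snp_ids == snp)[0])
                try:
                    fit = fit_genotype_model(traj, gm.codes[i],
                                             family=selected_family[trait],
                                             disturbance=True,
                                             min_group_size=config.min_group_size)
                except SNPSkipped:
                    continue
                if fit.G < 2:
                    continue
                curve = overall_genetic_effect(fit, snp_id=snp,
                                               n_points=config.dense_points)
                curves[snp] = curve
                for l, v in zip(curve.grid, curve.values):
                    rows.append({"snp": snp, "trait": trait, "l": l, "value": v})
            pd.DataFrame(rows).to_csv(out / f"effect_curves_{trait}.csv", index=False)
            effect_curves[trait] = curves
        manifest["stages"]["effect_curves"] = {
            "output": [f"effect_curves_{t}.csv" for t in trajectories]}

        stage = "network"
        net_summaries = {}
        for trait, curves in effect_curves.items():
            if len(curves) < 2:
                net_summaries[trait] = {"skipped": "fewer than 2 effect curves"}
                continue
            grid = next(iter(curves.values())).grid
            model = QTLNetworkModel({k: c.values for k, c in curves.items()}, grid,
                                    trait=trait, lop_order=config.lop_order,
                                    d_max=config.d_max,
                                    tau_fraction=config.tau_fraction,
                                    seed=config.seed)
            res = model.fit()
            res.network.to_graphml(out / f"network_{trait}.graphml")
            res.network.edge_list().to_csv(out / f"network_{trait}_edges.csv", index=False)
            s = res.stats()
            net_summaries[trait] = {k: s[k] for k in
                                    ("n_nodes", "n_edges", "density_pct",
                                     "positive_pct", "negative_pct")}
            net_summaries[trait]["hubs"] = list(map(str, res.hubs()))
        (out / "network_summary.json").write_text(json.dumps(net_summaries, indent=2))
        manifest["stages"]["network"] = {"output": "network_summary.json",
                                         **{t: s for t, s in net_summaries.items()}}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["finished"] = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
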