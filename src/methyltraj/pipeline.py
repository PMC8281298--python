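"""End-to-end pipeline: simulate -> QC -> clocks -> trajectory -> association
-> enrichment -> network, with a JSON + Markdown run report.

The report carries the quantities a study of this design summarizes: samples
retained after QC, loci tested, signature size and its hypo/hyper split,
per-module counts, per-stage clock ages with the ANOVA/Tukey table,
enrichment tables, and the SCC size with its top hub genes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from methyltraj import _io
from methyltraj.association import (
    assign_modules,
    bonferroni_select,
    fit_gam_matrix,
    round_pseudotime,
    signature_to_table,
)
from methyltraj.clocks import apply_clock, predictions_to_frame, stage_anova_tukey
from methyltraj.datasets import SimulationConfig, simulate_study
from methyltraj.enrichment import feature_enrichment, results_to_frame
from methyltraj.network import (
    build_network,
    extract_scc,
    rank_hub_genes,
    topology_metrics,
)
from methyltraj.preprocess import IntensityPair, qc_pipeline
from methyltraj.trajectory import (
    infer_trajectory,
    orient_pseudotime,
    pca_reduce,
    select_top_mad,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full run; every threshold is overridable."""

    out_dir: str = "methyltraj_run"
    seed: int = 0
    simulate: Dict = field(default_factory=lambda: {"enabled": True, "n_probes": 10_000})
    qc: Dict = field(default_factory=lambda: {"enabled": True, "detp_thresh": 0.05,
                                              "sample_frac": 0.01, "probe_frac": 0.01})
    clock: Dict = field(default_factory=lambda: {"enabled": True})
    trajectory: Dict = field(default_factory=lambda: {"enabled": True, "fraction": 0.05,
                                                       "n_components": 2, "k": 4})
    associate: Dict = field(default_factory=lambda: {"enabled": True, "alpha": 0.05,
                                                      "n_modules": 9})
    enrichment: Dict = field(default_factory=lambda: {"enabled": True})
    network: Dict = field(default_factory=lambda: {"enabled": True})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise PipelineError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(val, dict):
                current.update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the enabled stages in order; returns (and writes) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"seed": config.seed, "stages": []}
    stage = "simulate"
    try:
        sim_opts = {k: v for k, v in config.simulate.items() if k != "enabled"}
        sim_cfg = SimulationConfig(seed=config.seed, **sim_opts)
        study = simulate_study(sim_cfg)
        _io.write_study(study, out / "inputs")
        report["stages"].append(stage)
        report["n_probes_simulated"] = sim_cfg.n_probes
        report["n_samples_simulated"] = sim_cfg.n_samples

        # ---- QC + normalization -------------------------------------------
        stage = "qc"
        if config.qc.get("enabled", True):
            intensities = IntensityPair(
                methylated=study.meth, unmethylated=study.unmeth,
                detection_p=study.detp, beadcount=study.beadcount,
                probe_type=study.annotation["probe_type"],
            )
            min_median = config.qc.get("min_median",
                                       0.25 * sim_cfg.mean_total_intensity)
            beta, qc_report = qc_pipeline(
                intensities, annotation=study.annotation, min_median=min_median,
                detp_thresh=config.qc.get("detp_thresh", 0.05),
                sample_frac=config.qc.get("sample_frac", 0.01),
                probe_frac=config.qc.get("probe_frac", 0.01),
            )
            qc_report.to_json(out / "qc_report.json")
            report["stages"].append(stage)
            report["failed_samples"] = sorted(qc_report.failed_samples)
            report["n_samples_retained"] = qc_report.n_samples_after
            report["n_probes_retained"] = qc_report.n_probes_after
        else:
            beta = study.beta
            report["n_samples_retained"] = beta.shape[1]
            report["n_probes_retained"] = beta.shape[0]
        samples = study.samples.loc[beta.columns]
        _io.write_matrix(beta, out / "beta_normalized.tsv")

        # ---- clocks --------------------------------------------------------
        stage = "clock"
        if config.clock.get("enabled", True):
            preds = apply_clock(beta, study.clock)
            ages = predictions_to_frame(preds)
            ages["stage"] = samples.loc[ages.index, "stage"]
            ages.to_csv(out / "ages.csv")
            comp = stage_anova_tukey(ages["age"].to_numpy(), ages["stage"].to_numpy())
            comp.to_frame().to_csv(out / "age_tukey.csv", index=False)
            report["stages"].append(stage)
            report["clock"] = {
                "name": study.clock.name,
                "unit": study.clock.output_unit,
                "mean_age_by_stage": {
                    str(s): float(v) for s, v in ages.groupby("stage")["age"].mean().items()
                },
                "anova_p": comp.anova_p,
            }

        # ---- trajectory ----------------------------------------------------
        stage = "trajectory"
        traj_cfg = config.trajectory
        selection = select_top_mad(beta, fraction=traj_cfg.get("fraction", 0.05))
        beta_sel = beta.loc[selection.selected_probes]
        space = pca_reduce(beta_sel, n_components=traj_cfg.get("n_components", 2))
        traj = infer_trajectory(space, k=traj_cfg.get("k", 4), seed=config.seed)
        anchor = traj_cfg.get("anchor_stage", samples["stage"].iloc[0])
        traj = orient_pseudotime(traj, samples, anchor)
        traj.pseudotime.to_csv(out / "pseudotime.csv")
        report["stages"].append(stage)
        report["n_loci_tested"] = len(selection.selected_probes)
        report["explained_variance_pc1_pc2"] = float(
            space.explained_variance_fraction[:2].sum()
        )

        # ---- association ---------------------------------------------------
        stage = "associate"
        t = round_pseudotime(traj.pseudotime.to_numpy())
        results, fitted = fit_gam_matrix(beta_sel, t)
        signature = bonferroni_select(results, alpha=config.associate.get("alpha", 0.05))
        n_modules = config.associate.get("n_modules", 9)
        fitted_df = pd.DataFrame(fitted, index=beta_sel.index)
        if len(signature) >= n_modules:
            signature = assign_modules(signature, fitted_df, n_modules=n_modules,
                                       seed=config.seed)
        table = signature_to_table(signature, annotation=study.annotation)
        table.to_csv(out / "signature.tsv", sep="\t")
        report["stages"].append(stage)
        report["signature_size"] = len(signature)
        report["n_hypo"] = signature.n_hypo
        report["n_hyper"] = signature.n_hyper
        if "module" in signature.table.columns:
            report["module_counts"] = {
                str(int(k)): int(v)
                for k, v in signature.table["module"].value_counts().sort_index().items()
            }

        # ---- enrichment ----------------------------------------------------
        stage = "enrichment"
        if config.enrichment.get("enabled", True) and len(signature) > 0:
            enr = {}
            for fld in ("region_group", "cgi_relation"):
                res = feature_enrichment(signature.probes, selection.selected_probes,
                                         study.annotation, fld)
                frame = results_to_frame(res)
                frame.to_csv(out / f"enrichment_{fld}.tsv", sep="\t", index=False)
                enr[fld] = frame.to_dict(orient="records")
            report["stages"].append(stage)
            report["enrichment"] = enr

        # ---- network -------------------------------------------------------
        stage = "network"
        if config.network.get("enabled", True):
            net = build_network(study.network_edges)
            scc = extract_scc(net)
            report["stages"].append(stage)
            if scc is None:
                report["scc"] = None
            else:
                metrics = topology_metrics(scc)
                metrics.to_csv(out / "scc_metrics.tsv", sep="\t")
                hubs = rank_hub_genes(metrics)
                report["scc"] = {
                    "n_genes": len(scc.nodes),
                    "n_interactions": scc.n_edges,
                    "top_hubs": hubs[:5],
                }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _write_markdown(report, out / "report.md")
    return report


def _write_markdown(report: Dict, path) -> None:
    lines = ["# methyltraj run report", ""]
    lines.append(f"- seed: {report['seed']}")
    for key in ("n_samples_retained", "n_probes_retained", "n_loci_tested",
                "signature_size", "n_hypo", "n_hyper"):
        if key in report:
            lines.append(f"- {key.replace('_', ' ')}: {report[key]}")
    if "module_counts" in report:
        lines.append("- module counts: " + ", ".join(
            f"M{k}={v}" for k, v in report["module_counts"].items()))
    if report.get("clock"):
        lines.append(f"- clock ({report['clock']['name']}, {report['clock']['unit']}), "
                     f"ANOVA p = {report['clock']['anova_p']:.3g}")
        for s, v in report["clock"]["mean_age_by_stage"].items():
            lines.append(f"    - {s}: {v:.1f}")
    if report.get("scc"):
        scc = report["scc"]
        lines.append(f"- SCC: {scc['n_genes']} genes, {scc['n_interactions']} interactions; "
                     f"top hubs: {', '.join(scc['top_hubs'])}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
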