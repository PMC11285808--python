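"""End-to-end orchestration: simulate -> estimate -> fit -> summarize.

Stages communicate only through files (CSVs plus JSON sidecars) so any
stage can be re-run in isolation and outputs are language-agnostic.  A
run is driven by a YAML configuration holding the global seed, the chain
profile and either a generator request or paths to user-supplied tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fecundity, lifespan, prevalence, synth
from .data import (ExperimentTable, RunConfig, config_hash, read_experiment,
                   write_experiment)
from .power import analytic_required_n, power_grid

__all__ = ["PipelineError", "RunReport", "run_pipeline", "PROFILES"]

log = logging.getLogger("flyvir")

#: chain profiles: smoke completes in minutes; full mirrors a production
#: run (1e6 steps, 10k recorded) and is meant for real analyses only.
PROFILES = {
    "smoke": {"chain_total": 4000, "burn_in": 1000, "chain_recorded": 1000},
    "full": {"chain_total": 1_000_000, "burn_in": 100_000, "chain_recorded": 10_000},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    out_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None

    def check_outputs(self) -> None:
        missing = [str(p) for p in self.outputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline outputs: {missing}")


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text())
    else:
        raw = dict(config)
    raw.setdefault("seed", 0)
    raw.setdefault("profile", "smoke")
    raw.setdefault("generator", "paper_like")
    return raw


def _run_cfg(raw: dict) -> RunConfig:
    prof = dict(PROFILES[raw.get("profile", "smoke")])
    prof.update(raw.get("chains", {}))
    return RunConfig(seed=int(raw["seed"]), **prof)


def _stage(name: str, fn, report: RunReport):
    log.info("[%s] running", name)
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise PipelineError(name, exc) from exc


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> RunReport:
    """Execute all stages on synthetic or user-provided tables."""
    raw = _load_config(config)
    out = Path(out_dir or raw.get("out_dir", "flyvir_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(raw["seed"])
    cfg = _run_cfg(raw)
    report = RunReport(out_dir=out, config=raw)

    def capture(wlist):
        report.warnings.extend(str(w.message) for w in wlist)

    # ---- stage: data (simulate or load) ---------------------------------
    def data_stage() -> ExperimentTable:
        gen = raw.get("generator")
        if "inputs" in raw:
            paths = raw["inputs"]
            return read_experiment(paths["recipients"], paths["detections"],
                                   paths["donors"], paths.get("meta"))
        if gen == "paper_like":
            gcfg = synth.paper_like_config()
        elif isinstance(gen, dict):
            gcfg = synth.GeneratorConfig(**gen)
        else:
            raise ValueError(f"unknown generator spec {gen!r}")
        table = synth.generate_experiment(gcfg, seed)
        paths = write_experiment(table, out / "data")
        report.outputs.update({f"data_{k}": v for k, v in paths.items()})
        return table

    table = _stage("simulate", data_stage, report)

    # ---- stage: prevalence ----------------------------------------------
    def prevalence_stage():
        prev = prevalence.prevalence_by_group(table.donors)
        p = out / "prevalence.csv"
        prev.to_csv(p, index=False)
        report.outputs["prevalence"] = p
        return prev

    _stage("prevalence", prevalence_stage, report)

    # ---- stage: transmission --------------------------------------------
    def transmission_stage():
        tr = prevalence.transmission_by_virus(table.detections)
        p = out / "transmission.csv"
        tr.to_csv(p, index=False)
        report.outputs["transmission"] = p
        # donor-group comparison: per wild group, how many of the viruses
        # present in its pools transmitted to at least one recipient
        don = table.donors
        det = table.detections
        vial_group = don.drop_duplicates("vial_id").set_index("vial_id")["species_group"]
        fly_vial = table.recipients.set_index("fly_id")["vial_id"]
        det = det.assign(group=det["fly_id"].map(fly_vial).map(vial_group))
        counts = {}
        for group, sub in don[don["assay_positive"]].groupby("species_group"):
            if group == "LabControl":
                continue
            present = set(sub["virus"])
            dd = det[(det["group"] == group) & det["detected"]]
            transmitted = set(dd["virus"]) & present
            counts[group] = (len(transmitted), len(present))
        fisher = {"groups": counts, "p_value": None}
        if len(counts) >= 2 and all(n > 0 for _, n in counts.values()):
            t = prevalence.donor_group_transmission_table(counts)
            if t.sum(axis=0).min() > 0:
                fisher["p_value"] = prevalence.fisher_exact_rxc(t)
        p = out / "transmission_fisher.json"
        p.write_text(json.dumps(fisher, indent=2, default=str))
        report.outputs["transmission_fisher"] = p
        return tr

    trans = _stage("transmission", transmission_stage, report)

    # ---- stage: lifespan models -----------------------------------------
    def lifespan_stage():
        with warnings.catch_warnings(record=True) as wl:
            warnings.simplefilter("always")
            fa = lifespan.fit_lifespan_A(table, cfg, seed=seed + 1)
            fb = lifespan.fit_lifespan_B(table, cfg, seed=seed + 2)
        capture(wl)
        fa.summaries.to_csv(out / "lifespan_A_summary.csv", index=False)
        fb.summaries.to_csv(out / "lifespan_B_summary.csv", index=False)
        fa.chain.to_frame().to_csv(out / "lifespan_A_chain.csv", index=False)
        rows = []
        for v in fa.viruses:
            s = lifespan.percent_reduction(fa, v)
            rows.append({"virus": v, "pct_reduction": s.mean,
                         "hpd_low": s.hpd_low, "hpd_high": s.hpd_high,
                         "pmcmc": s.pmcmc, "ess": s.ess})
        pd.DataFrame(rows).to_csv(out / "lifespan_effects.csv", index=False)
        for k in ("lifespan_A_summary", "lifespan_B_summary",
                  "lifespan_A_chain", "lifespan_effects"):
            report.outputs[k] = out / f"{k}.csv"
        return fa, fb

    fa, fb = _stage("lifespan", lifespan_stage, report)

    # ---- stage: fecundity ------------------------------------------------
    def fecundity_stage():
        with warnings.catch_warnings(record=True) as wl:
            warnings.simplefilter("always")
            ff = fecundity.fit_fecundity(table, cfg, "lifetime", seed=seed + 3)
        capture(wl)
        ff.summaries.to_csv(out / "fecundity_summary.csv", index=False)
        rows = []
        for v in ff.count_viruses:
            s = fecundity.percent_offspring_reduction(ff, v)
            row = {"virus": v, "pct_reduction": s.mean, "hpd_low": s.hpd_low,
                   "hpd_high": s.hpd_high, "pmcmc": s.pmcmc}
            if v in ff.zero_viruses:
                pz = ff.p_zero(v)
                row.update(p_zero=pz.mean, p_zero_low=pz.hpd_low,
                           p_zero_high=pz.hpd_high)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "offspring_effects.csv", index=False)
        ppc = fecundity.posterior_predictive_zeros(ff, n_draws=200, seed=seed + 4)
        (out / "ppc_zeros.json").write_text(json.dumps({
            "observed_zeros": ppc.observed_zeros,
            "band_low": ppc.band_low, "band_high": ppc.band_high,
            "inside_band": ppc.inside_band}, indent=2))
        corr = fecundity.early_late_correlation(table)
        (out / "early_late_correlation.json").write_text(json.dumps(corr, indent=2))
        report.outputs.update({
            "fecundity_summary": out / "fecundity_summary.csv",
            "offspring_effects": out / "offspring_effects.csv",
            "ppc_zeros": out / "ppc_zeros.json",
            "early_late_correlation": out / "early_late_correlation.json"})
        return ff

    ff = _stage("fecundity", fecundity_stage, report)

    # ---- stage: power ----------------------------------------------------
    def power_stage():
        mu = float(fa.intercept().mean())
        sd_e = float(np.sqrt(fa.chain.col("var_residual").mean()))
        sd_v = float(np.sqrt(fa.chain.col("var_vial").mean()))
        pw = raw.get("power", {})
        grid = power_grid(pw.get("ns", [25, 50, 100, 200]),
                          pw.get("effects", [5.0, 10.0, 20.0]),
                          mu, sd_v, sd_e,
                          reps=int(pw.get("reps", 400)), seed=seed + 5)
        grid.frame.to_csv(out / "power.csv", index=False)
        req = analytic_required_n(0.8, 1.0, mu, float(np.hypot(sd_v, sd_e)))
        (out / "required_n.json").write_text(json.dumps({
            "target_power": 0.8, "pct_reduction": 1.0, "mu": mu,
            "sd_total": float(np.hypot(sd_v, sd_e)),
            "required_n_per_group": req}, indent=2))
        report.outputs["power"] = out / "power.csv"
        report.outputs["required_n"] = out / "required_n.json"

    _stage("power", power_stage, report)

    # ---- stage: report ----------------------------------------------------
    def report_stage():
        tr_map = trans.set_index("virus")
        rows = []
        for v in table.virus_panel:
            row = {"virus": v}
            if v in tr_map.index:
                row["transmission_rate"] = float(tr_map.loc[v, "rate"])
                row["n_infected"] = int(tr_map.loc[v, "n_infected"])
                row["n_exposed"] = int(tr_map.loc[v, "n_exposed"])
            if v in fa.viruses:
                s = lifespan.percent_reduction(fa, v)
                row["lifespan_pct_reduction"] = s.mean
                row["lifespan_pmcmc"] = s.pmcmc
            if v in ff.count_viruses:
                s = fecundity.percent_offspring_reduction(ff, v)
                row["offspring_pct_reduction"] = s.mean
                row["offspring_pmcmc"] = s.pmcmc
            if v in ff.zero_viruses:
                row["p_zero"] = ff.p_zero(v).mean
            rows.append(row)
        summary = pd.DataFrame(rows)
        summary.to_csv(out / "report.csv", index=False)
        meta = {"seed": seed, "profile": raw.get("profile"),
                "config_hash": config_hash(
                    {k: v for k, v in raw.items() if k != "out_dir"}),
                "warnings": report.warnings,
                "dropped_viruses": fa.dropped,
                "zero_part_excluded": ff.excluded_zero}
        (out / "report.json").write_text(json.dumps(meta, indent=2, default=str))
        report.outputs["report"] = out / "report.csv"
        report.outputs["report_meta"] = out / "report.json"
        return summary

    report.summary = _stage("report", report_stage, report)
    report.check_outputs()
    return report
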