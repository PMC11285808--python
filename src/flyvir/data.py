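"""Domain tables, CSV schemas, configuration and validation.

The experiment is represented by three tidy tables:

``recipients``
    one row per exposed laboratory female: ``fly_id, vial_id,
    lifespan_days, censored, offspring_early, offspring_total,
    excluded_early``.
``detections``
    long format, one row per (fly, virus) pair the fly was exposed to:
    ``fly_id, virus, exposed, detected``.  A fly's exposure panel is the
    set of viruses that tested positive in its co-housing vial's donor
    pool; infection status is the end-of-life assay result.
``donors``
    long format, one row per (vial, virus) pooled assay: ``vial_id,
    species_group, pool_size, virus, assay_positive``.

CSV dialect: comma-separated, UTF-8, header row, "." decimal, booleans
written as ``true``/``false``, missing values as the empty string.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .mcmc import PriorSpec

__all__ = [
    "SPECIES_GROUPS",
    "RunConfig",
    "ExperimentTable",
    "read_experiment",
    "write_experiment",
    "apply_reclassification",
    "stage_rng",
    "load_run_config",
    "save_run_config",
]

SPECIES_GROUPS = ("Dmel", "Dimm", "DobsGroup", "LabControl")

RECIPIENT_COLUMNS = ["fly_id", "vial_id", "lifespan_days", "censored",
                     "offspring_early", "offspring_total", "excluded_early"]
DETECTION_COLUMNS = ["fly_id", "virus", "exposed", "detected"]
DONOR_COLUMNS = ["vial_id", "species_group", "pool_size", "virus", "assay_positive"]

_BOOL_MAP = {"true": True, "false": False, True: True, False: False}


@dataclass(frozen=True)
class RunConfig:
    """Chain lengths, significance settings and priors for one analysis run."""

    seed: int = 0
    chain_total: int = 20000
    chain_recorded: int = 2000
    burn_in: int = 2000
    alpha: float = 0.05
    hpd_mass: float = 0.95
    priors: PriorSpec = field(default_factory=PriorSpec)
    followup_days: float = 72.0
    ess_floor: float = 200.0
    include_censored: bool = True

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.chain_total <= 0 or self.chain_recorded <= 0:
            raise ValueError("chain settings must be positive")
        if self.chain_recorded > self.chain_total - self.burn_in:
            raise ValueError("chain_recorded must be <= chain_total - burn_in")
        if not 0.0 < self.hpd_mass < 1.0:
            raise ValueError("hpd_mass must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for a named pipeline stage."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, h]))


@dataclass
class ExperimentTable:
    """Validated in-memory experiment: recipients, detections, donor pools."""

    recipients: pd.DataFrame
    detections: pd.DataFrame
    donors: pd.DataFrame
    virus_panel: list[str]
    meta: dict = field(default_factory=dict)

    # -- accessors used by the models -------------------------------------
    def detection_wide(self) -> pd.DataFrame:
        """Fly x virus boolean infection matrix (False where unexposed)."""
        wide = pd.DataFrame(False, index=self.recipients["fly_id"],
                            columns=list(self.virus_panel))
        det = self.detections
        pos = det[det["detected"].astype(bool)]
        for fly, virus in zip(pos["fly_id"], pos["virus"]):
            wide.at[fly, virus] = True
        return wide

    def n_infections(self) -> pd.Series:
        return self.detection_wide().sum(axis=1)

    def validate(self, max_followup: float | None = None) -> None:
        r, d, dn = self.recipients, self.detections, self.donors
        for name, df, cols in (("recipients", r, RECIPIENT_COLUMNS),
                               ("detections", d, DETECTION_COLUMNS),
                               ("donors", dn, DONOR_COLUMNS)):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table missing columns: {missing}")
        if r["fly_id"].duplicated().any():
            dup = r.loc[r["fly_id"].duplicated(), "fly_id"].iloc[0]
            raise ValueError(f"duplicate fly_id {dup!r} in recipients")
        if (r["lifespan_days"] <= 0).any():
            bad = r.loc[r["lifespan_days"] <= 0, "fly_id"].iloc[0]
            raise ValueError(f"non-positive lifespan for fly {bad!r}")
        if max_followup is not None and (r["lifespan_days"] > max_followup).any():
            bad = r.loc[r["lifespan_days"] > max_followup, "fly_id"].iloc[0]
            raise ValueError(
                f"lifespan beyond follow-up limit {max_followup} for fly {bad!r}")
        if (r["offspring_early"] > r["offspring_total"]).any():
            bad = r.loc[r["offspring_early"] > r["offspring_total"], "fly_id"].iloc[0]
            raise ValueError(f"offspring_early exceeds offspring_total for fly {bad!r}")
        if (r["offspring_total"] < 0).any() or (r["offspring_early"] < 0).any():
            raise ValueError("negative offspring counts")
        known_vials = set(dn["vial_id"])
        orphan = set(r["vial_id"]) - known_vials
        if orphan:
            raise ValueError(f"recipient vials without a donor pool: {sorted(orphan)}")
        if (dn["pool_size"] < 1).any():
            bad = dn.loc[dn["pool_size"] < 1, "vial_id"].iloc[0]
            raise ValueError(f"pool_size < 1 for vial {bad!r}")
        panel = set(self.virus_panel)
        if not panel or any(not v for v in panel):
            raise ValueError("virus panel must be non-empty strings")
        if len(panel) != len(self.virus_panel):
            raise ValueError("duplicate virus in panel")
        stray = (set(d["virus"]) | set(dn["virus"])) - panel
        if stray:
            raise ValueError(f"viruses outside the panel: {sorted(stray)}")
        known_flies = set(r["fly_id"])
        orphan_fly = set(d["fly_id"]) - known_flies
        if orphan_fly:
            raise ValueError(f"detections for unknown flies: {sorted(orphan_fly)}")
        bad = d[d["detected"].astype(bool) & ~d["exposed"].astype(bool)]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"fly {row['fly_id']!r} has a detection for virus "
                f"{row['virus']!r} outside its exposure panel")
        if d.duplicated(["fly_id", "virus"]).any():
            row = d[d.duplicated(["fly_id", "virus"])].iloc[0]
            raise ValueError(
                f"duplicate detection row for fly {row['fly_id']!r} / "
                f"virus {row['virus']!r}")


def _write_bools(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype == bool:
            out[c] = out[c].map({True: "true", False: "false"})
    return out


def _read_bools(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        if c in df.columns:
            vals = df[c]
            if vals.dtype != bool:
                parsed = vals.astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False})
                if parsed.isna().any():
                    bad = vals[parsed.isna()].iloc[0]
                    raise ValueError(f"column {c!r}: unparseable boolean {bad!r}")
                df[c] = parsed
    return df


def write_experiment(table: ExperimentTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the three experiment CSVs plus a JSON provenance sidecar."""
    table.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "recipients": out / "recipients.csv",
        "detections": out / "detections.csv",
        "donors": out / "donors.csv",
        "meta": out / "run_meta.json",
    }
    _write_bools(table.recipients[RECIPIENT_COLUMNS]).to_csv(paths["recipients"], index=False)
    _write_bools(table.detections[DETECTION_COLUMNS]).to_csv(paths["detections"], index=False)
    _write_bools(table.donors[DONOR_COLUMNS]).to_csv(paths["donors"], index=False)
    meta = dict(table.meta)
    meta.setdefault("written_at", time.strftime("%Y-%m-%dT%H:%M:%S"))
    meta["virus_panel"] = list(table.virus_panel)
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return paths


def read_experiment(
    recipients_path: str | Path,
    detections_path: str | Path,
    donors_path: str | Path,
    meta_path: str | Path | None = None,
) -> ExperimentTable:
    """Load and validate an experiment from its three CSV files."""
    for p in (recipients_path, detections_path, donors_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input file: {p}")
    rec = pd.read_csv(recipients_path, dtype={"fly_id": str, "vial_id": str})
    det = pd.read_csv(detections_path, dtype={"fly_id": str, "virus": str})
    don = pd.read_csv(donors_path, dtype={"vial_id": str, "virus": str,
                                          "species_group": str})
    rec = _read_bools(rec, ["censored", "excluded_early"])
    det = _read_bools(det, ["exposed", "detected"])
    don = _read_bools(don, ["assay_positive"])
    meta: dict = {}
    if meta_path is not None and Path(meta_path).exists():
        meta = json.loads(Path(meta_path).read_text())
    panel = meta.get("virus_panel") or sorted(set(det["virus"]) | set(don["virus"]))
    table = ExperimentTable(recipients=rec, detections=det, donors=don,
                            virus_panel=list(panel), meta=meta)
    table.validate()
    return table


def apply_reclassification(
    table: ExperimentTable,
    overrides: Mapping[str, tuple[str, bool]],
) -> ExperimentTable:
    """Return a copy with per-fly infection statuses overridden.

    ``overrides`` maps fly_id to ``(virus, new_detected_status)``.  Used to
    re-analyse the data after reclassifying flies whose infections were
    detected indirectly (e.g. via partner or offspring assays) or presumed
    cleared.  The original table is untouched and the override is recorded
    in the new table's provenance.
    """
    det = table.detections.copy()
    known_flies = set(table.recipients["fly_id"])
    for fly, (virus, status) in overrides.items():
        if fly not in known_flies:
            raise KeyError(f"unknown fly_id {fly!r}")
        if virus not in table.virus_panel:
            raise KeyError(f"unknown virus {virus!r}")
        mask = (det["fly_id"] == fly) & (det["virus"] == virus)
        if not mask.any():
            raise KeyError(f"fly {fly!r} was not exposed to virus {virus!r}")
        det.loc[mask, "detected"] = bool(status)
    meta = dict(table.meta)
    log = list(meta.get("reclassifications", []))
    log.extend([fly, virus, bool(status)]
               for fly, (virus, status) in sorted(overrides.items()))
    meta["reclassifications"] = log
    new = ExperimentTable(recipients=table.recipients.copy(),
                          detections=det, donors=table.donors.copy(),
                          virus_panel=list(table.virus_panel), meta=meta)
    new.validate()
    return new


# ---------------------------------------------------------------------------
# Config files


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    d = {
        "seed": cfg.seed, "chain_total": cfg.chain_total,
        "chain_recorded": cfg.chain_recorded, "burn_in": cfg.burn_in,
        "alpha": cfg.alpha, "hpd_mass": cfg.hpd_mass,
        "followup_days": cfg.followup_days, "ess_floor": cfg.ess_floor,
        "include_censored": cfg.include_censored,
        "priors": {"fixed_effect_var": cfg.priors.fixed_effect_var,
                   "variance_v": cfg.priors.variance_v,
                   "variance_nu": cfg.priors.variance_nu},
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_run_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    priors = PriorSpec(**d.pop("priors", {}))
    return RunConfig(priors=priors, **d)


def config_hash(obj) -> str:
    """Stable short hash of any YAML-serializable configuration object."""
    text = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
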