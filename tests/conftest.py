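import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from flyvir.data import ExperimentTable, RunConfig
from flyvir.synth import GeneratorConfig, generate_experiment, paper_like_config

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def fast_cfg():
    """Reduced-chain settings so model fits finish in well under a second."""
    return RunConfig(seed=0, chain_total=1200, burn_in=300, chain_recorded=450)


@pytest.fixture(scope="session")
def small_gen_cfg():
    """Tiny two-group experiment used by IO and plumbing tests."""
    return GeneratorConfig(
        n_vials={"Dmel": 3, "Dimm": 2, "LabControl": 1},
        recipients_per_vial=8,
        carriage={"virA": {"Dmel": 0.5}, "virB": {"Dmel": 0.2, "Dimm": 0.4}},
        transmission={"virA": 0.5, "virB": 0.3},
        lifespan_effects={"virA": -10.0, "virB": -4.0},
        count_effects={"virA": -0.5},
    )


@pytest.fixture(scope="session")
def small_table(small_gen_cfg):
    return generate_experiment(small_gen_cfg, 3)


@pytest.fixture(scope="session")
def paper_table():
    return generate_experiment(paper_like_config(), 7)


def build_table(lifespans, infections, vials, offspring_total=None,
                offspring_early=None, censored=None, excluded_early=None,
                exposed=None):
    """Hand-rolled ExperimentTable for targeted model tests.

    ``infections`` maps virus -> boolean array; every fly is treated as
    exposed to every virus in the panel unless ``exposed`` (virus ->
    boolean array) narrows it.
    """
    n = len(lifespans)
    fly_ids = [f"f{i:04d}" for i in range(n)]
    vials = np.asarray(vials)
    vial_ids = [f"v{int(v):03d}" for v in vials]
    total = (np.zeros(n, dtype=int) if offspring_total is None
             else np.asarray(offspring_total, dtype=int))
    early = (np.minimum(total, 0) if offspring_early is None
             else np.asarray(offspring_early, dtype=int))
    rec = pd.DataFrame({
        "fly_id": fly_ids, "vial_id": vial_ids,
        "lifespan_days": np.asarray(lifespans, dtype=float),
        "censored": np.zeros(n, bool) if censored is None else np.asarray(censored),
        "offspring_early": early, "offspring_total": total,
        "excluded_early": (np.zeros(n, bool) if excluded_early is None
                           else np.asarray(excluded_early)),
    })
    det_rows = []
    for virus, flags in infections.items():
        exp_flags = (np.ones(n, bool) if exposed is None or virus not in exposed
                     else np.asarray(exposed[virus]))
        for i in range(n):
            if exp_flags[i]:
                det_rows.append({"fly_id": fly_ids[i], "virus": virus,
                                 "exposed": True,
                                 "detected": bool(flags[i])})
    don = pd.DataFrame([
        {"vial_id": v, "species_group": "Dmel", "pool_size": 10,
         "virus": virus, "assay_positive": True}
        for v in sorted(set(vial_ids)) for virus in infections])
    table = ExperimentTable(recipients=rec, detections=pd.DataFrame(det_rows),
                            donors=don, virus_panel=sorted(infections))
    table.validate()
    return table
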