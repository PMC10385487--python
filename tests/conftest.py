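"""Shared fixtures: one small synthetic study reused across test modules.

The dataset is deliberately tiny (50 parents, 80 hybrids, 4 trials of
12 x 10 plots) so the full two-stage pipeline runs in a couple of seconds;
session scope keeps it to a single simulation + fit per test run.
"""

import numpy as np
import pytest

from hybridgp.markers import grm_vanraden, dominance_matrix
from hybridgp.simulate import (SimConfig, TrialLayout, simulate_dataset,
                               hybrid_dosages)

TINY_TRIALS = (
    TrialLayout("Est", 2019, 12, 10),
    TrialLayout("Hee", 2019, 12, 10),
    TrialLayout("Est", 2020, 12, 10),
    TrialLayout("Hee", 2020, 12, 10),
)


@pytest.fixture(scope="session")
def tiny_cfg():
    return SimConfig.desk_scale(
        seed=3, n_parents=50, n_hybrids=80, n_snps=120, trials=TINY_TRIALS,
        var_sca=0.0, var_gxt=1.0, var_delta=1.0)


@pytest.fixture(scope="session")
def tiny_ds(tiny_cfg):
    return simulate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_kernels(tiny_ds):
    Xh = hybrid_dosages(tiny_ds["parents"], tiny_ds["crossplan"])
    Gp = grm_vanraden(tiny_ds["parents"])
    Gh = grm_vanraden(Xh)
    D = dominance_matrix(Xh)
    return {"Gp": Gp, "Gh": Gh, "D": D, "Xh": Xh}


@pytest.fixture(scope="session")
def tiny_blues(tiny_ds):
    from hybridgp.stage1 import run_stage1
    return run_stage1(tiny_ds["plots"], ["TY"])["TY"]


@pytest.fixture(scope="session")
def tiny_multitrial(tiny_ds):
    from hybridgp.multitrial import fit_multitrial
    return fit_multitrial(tiny_ds["plots"], "TY")


@pytest.fixture(scope="session")
def tiny_gca(tiny_ds, tiny_kernels, tiny_blues):
    from hybridgp.stage2 import fit_gca
    return fit_gca(tiny_blues.table, tiny_ds["crossplan"],
                   tiny_kernels["Gp"], tiny_kernels["Gh"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231407)
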