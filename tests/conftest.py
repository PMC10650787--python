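"""Shared fixtures: the two standard frame schedules, calibrated blood
curves and published wild-type rate constants, all generated at test time."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from petkin import (
    KineticParams2TC,
    make_frame_schedule,
    simulate_tissue_tac,
)
from petkin.cohort import default_input_spec, make_input_function
from petkin.reported_values import FRAME_SCHEDULE_SPECS, RATE_CONSTANTS


@pytest.fixture(scope="session")
def sched_2fa():
    return make_frame_schedule(FRAME_SCHEDULE_SPECS["2-FA"])


@pytest.fixture(scope="session")
def sched_nifene():
    return make_frame_schedule(FRAME_SCHEDULE_SPECS["Nifene"])


@pytest.fixture(scope="session")
def blood_2fa(sched_2fa):
    return make_input_function(default_input_spec("2-FA"), sched_2fa,
                               subject="sim", ligand="2-FA", group="WT")


@pytest.fixture(scope="session")
def blood_nifene(sched_nifene):
    return make_input_function(default_input_spec("Nifene"), sched_nifene,
                               subject="sim", ligand="Nifene", group="WT")


def params_from_table(ligand: str, group: str, region: str, vp: float = 0.05):
    t = RATE_CONSTANTS[ligand][group][region]
    return KineticParams2TC(K1=t["K1"][0], k2=t["k2"][0], k3=t["k3"][0],
                            k4=t["k4"][0], vp=vp)


@pytest.fixture(scope="session")
def wt_thalamus_2fa_params():
    return params_from_table("2-FA", "WT", "thalamus")


@pytest.fixture(scope="session")
def wt_thalamus_2fa_tac(wt_thalamus_2fa_params, blood_2fa, sched_2fa):
    return simulate_tissue_tac(wt_thalamus_2fa_params, blood_2fa, sched_2fa,
                               region="thalamus")
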