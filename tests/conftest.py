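import numpy as np
import pytest

from taktclinic.clinic_model import (ClinicConfig, Department, Pathway,
                                     ServiceModel)
from taktclinic.demand import ArrivalProfile, ArrivalStream
from taktclinic.experiments import make_benchmark_clinic
from taktclinic.takt_planner import build_static_plan


@pytest.fixture(scope="session")
def small_bundle():
    return make_benchmark_clinic("small")


@pytest.fixture(scope="session")
def full_bundle():
    return make_benchmark_clinic("full")


def single_department_clinic(day_length: float, c: int,
                             service: ServiceModel) -> ClinicConfig:
    """One-department clinic whose whole day is a single planning slot."""
    dept = Department("Q", service, min_resources=0, max_resources=max(c, 1))
    return ClinicConfig(departments=(dept,),
                        pathways=(Pathway("p", ("Q",), 1.0),),
                        open_time=0.0, close_time=day_length,
                        slot_length=day_length)


@pytest.fixture
def lindley_setup():
    """Deterministic single-server toy: service 5 min, arrivals at 0, 2, 4.

    The Lindley recursion W_{n+1} = max(0, W_n + S - A) gives waits
    (0, 3, 6) and cycles (5, 8, 11).
    """
    clinic = single_department_clinic(30.0, 1,
                                      ServiceModel("deterministic", 5.0))
    stream = ArrivalStream(((0.0, "p"), (2.0, "p"), (4.0, "p")))
    plan = build_static_plan(clinic, {"Q": 1})
    return clinic, stream, plan
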