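import pytest

from lhxpop import reference as ref
from lhxpop import response as rsp


@pytest.fixture(scope="session")
def schedules():
    """Calibrated reference schedules (solved once per session)."""
    return ref.calibrated()


@pytest.fixture(scope="session")
def mass_schedules():
    return {s: ref.mass_schedule(s) for s in rsp.SEXES}


@pytest.fixture(scope="session")
def anchors(schedules):
    return rsp.anchors_from_schedules(schedules.lhx_egoa, schedules.hfys_pre)


@pytest.fixture(scope="session")
def sigmoid_model(anchors, mass_schedules):
    params = rsp.calibrate_sigmoid(anchors, mass_schedules)
    return rsp.ResponseModel(
        kind="sigmoid", anchors=anchors, mass_schedule=mass_schedules, sigmoid=params
    )


@pytest.fixture(scope="session")
def sigmoid_sweep(sigmoid_model):
    return rsp.sweep(sigmoid_model)


@pytest.fixture(scope="session")
def study_ledger():
    return ref.build_study_ledger()
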