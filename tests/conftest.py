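import numpy as np
import pytest

import ventsim as v
from ventsim import protocol as P


@pytest.fixture
def three_unit_pig():
    """Hand-enumerable 3-unit lung: opening {10,20,30}, closing {5,15,25}."""
    units = [
        v.AlveolarUnit(10.0, 5.0, state=1),
        v.AlveolarUnit(20.0, 15.0, state=1),
        v.AlveolarUnit(30.0, 25.0, state=1),
    ]
    return v.make_pig_from_units(units, injury=_no_injury())


def _no_injury():
    return v.InjuryParams(
        cyclic_consolidation_prob=0.0,
        overdistension_consolidation_prob=0.0,
        cyclic_pressure_shift=0.0,
    )


@pytest.fixture
def no_injury():
    return _no_injury()


@pytest.fixture
def healthy_pig():
    return v.make_pig(46.0, seed=7)


@pytest.fixture(scope="session")
def lavaged_pig():
    """One pig through baseline + lavage (shared across read-only tests)."""
    pig = v.make_pig(46.0, seed=11)
    t, rr = P.run_baseline(pig, 60)
    log = P.ExperimentLog(arm="x")
    t, bg = P.run_lavage(pig, rr=rr, log=log, t0=t)
    return pig, bg, log, t, rr
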