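import numpy as np
import pytest

from spinefem import fe_solver, fixtures, mesher
from spinefem.parameterization import VertebraParams


@pytest.fixture(scope="session")
def fixture18():
    """Default 18-level synthetic Lenke-5-like spine (zero noise)."""
    spec = fixtures.SyntheticSpineSpec(seed=1)
    return fixtures.generate_spine(spec)


@pytest.fixture(scope="session")
def params18(fixture18):
    return fixture18[1].params_per_vertebra


def _stack_params(n, lz=22.0, gap=8.0, lx=40.0, ly=30.0):
    labels = ["L5", "L4", "L3", "L2", "L1"][:n]
    return [
        VertebraParams(labels[i], (0.0, 0.0, lz + i * (lz + gap)), (lx, ly, lz))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def two_level_params():
    return _stack_params(2)


@pytest.fixture(scope="session")
def spine2(two_level_params):
    return mesher.assemble_spine(
        two_level_params, mesher.SpineConfig(resolution=(4, 4, 3))
    )


@pytest.fixture(scope="session")
def solve2(spine2):
    return fe_solver.solve(spine2, None, fe_solver.LoadCase(magnitude=2.0))


@pytest.fixture(scope="session")
def spine3():
    return mesher.assemble_spine(
        _stack_params(3), mesher.SpineConfig(resolution=(4, 4, 3))
    )


@pytest.fixture(scope="session")
def solve3(spine3):
    return fe_solver.solve(spine3, None, fe_solver.LoadCase(magnitude=2.0))
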