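import numpy as np
import pytest

from pmapdose import (
    BinaryMask,
    CohortGeneratorSpec,
    DoseGrid,
    FractionationScheme,
    GridGeometry,
    PhantomSpec,
    PlanPainterSpec,
    generate_cohort,
    generate_phantom,
    paint_plan_pair,
)


@pytest.fixture
def geo16():
    return GridGeometry((16, 16, 16), (2.0, 2.0, 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dose_mask(rng, shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0), max_dose=70.0):
    """A random (DoseGrid, non-empty BinaryMask) pair on one lattice."""
    geo = GridGeometry(shape, spacing)
    dose = DoseGrid(geo, rng.uniform(0.0, max_dose, shape))
    mask = rng.random(shape) < 0.3
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    return dose, BinaryMask(geo, mask)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def fx():
    return FractionationScheme(66.0, 33)


@pytest.fixture(scope="session")
def plan_pair(phantom):
    return paint_plan_pair(phantom, PlanPainterSpec(seed=7))


@pytest.fixture(scope="session")
def cohort100():
    """The default 100-patient synthetic study, shared across tests."""
    return generate_cohort(CohortGeneratorSpec(n=100, seed=3))
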