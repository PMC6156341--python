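import numpy as np
import pytest

from qqfit.objective import make_objective
from qqfit.optimize import SearchSpace
from qqfit.raf import GROUND_TRUTH, RafEquilibriumAdapter, derive_constants
from qqfit.synth import gen_raf_qual, gen_raf_quant, raf_constraints_from_labels


@pytest.fixture(scope="session")
def truth_constants():
    return derive_constants(**GROUND_TRUTH)


@pytest.fixture(scope="session")
def raf_adapter():
    return RafEquilibriumAdapter()


@pytest.fixture(scope="session")
def raf_space():
    return SearchSpace({"K3": (1e-4, 1e4), "K5": (1e-4, 1e4)})


@pytest.fixture(scope="session")
def raf_constraints(truth_constants):
    return raf_constraints_from_labels(gen_raf_qual(truth_constants))


@pytest.fixture(scope="session")
def raf_quant_seeded(truth_constants):
    return gen_raf_quant(truth_constants, seed=1)


@pytest.fixture(scope="session")
def raf_total_objective(raf_adapter, raf_quant_seeded, raf_constraints):
    return make_objective(raf_adapter, raf_quant_seeded, raf_constraints, "total")
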