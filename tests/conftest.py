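import numpy as np
import pytest

from vdwcomb import PotentialModel, generate_synthetic_curve
from vdwcomb.potentials import tt_well_consistent
from vdwcomb.workbench import default_truth

#: one representative, physically plausible model per family (argon-like well)
REFERENCE_MODELS = {
    "LJ12-6": PotentialModel("LJ12-6", {"sigma": 3.35, "epsilon": 1.19}),
    "LJ8-6": PotentialModel("LJ8-6", {"sigma": 3.76, "epsilon": 1.19}),
    "WBH": PotentialModel("WBH", {"sigma": 3.76, "epsilon": 1.19, "gamma": 12.0}),
    "MBH": PotentialModel("MBH", {"sigma": 3.76, "epsilon": 1.19, "gamma": 13.0}),
    "MRS": PotentialModel("MRS", {"sigma": 3.76, "epsilon": 1.19, "gamma": 6.5}),
    "BHA": PotentialModel("BHA", {"A": 390000.0, "b": 3.45, "C6": 6200.0}),
    "GBH": PotentialModel(
        "GBH", {"sigma": 3.76, "epsilon": 1.19, "gamma": 12.5, "delta": 6.0}
    ),
    "LJ14-7": PotentialModel(
        "LJ14-7", {"sigma": 3.76, "epsilon": 1.19, "gamma": 0.12, "delta": 0.07}
    ),
    "TT": tt_well_consistent(1.2, 0.4, 0.2, Re=3.76, De=1.19),
}


@pytest.fixture(scope="session")
def reference_models():
    return REFERENCE_MODELS


@pytest.fixture(scope="session")
def ar_lj():
    """Argon-like Lennard-Jones 12-6 (ε/k ≈ 120 K, σ = 3.4 Å)."""
    return PotentialModel("LJ12-6", {"sigma": 3.4, "epsilon": 0.99774})


@pytest.fixture(scope="session")
def gbh_truth():
    return default_truth("GBH", 3.8, 1.19)


@pytest.fixture()
def make_curve():
    def _make(model, r_start=1.8, r_stop=30.0, step=0.1, noise=0.0, seed=0, a="X", b="X"):
        return generate_synthetic_curve(
            model, r_start, r_stop, step, noise_sd=noise, seed=seed,
            element_a=a, element_b=b,
        )

    return _make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231114)
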