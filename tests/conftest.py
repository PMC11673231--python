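import numpy as np
import pytest

from mtlrank import HyperParams, train
from mtlrank.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def one_module_data():
    """A 600-subject cohort with one planted 25-gene risk module."""
    cfg = SimulationConfig(n=600, seed=11)
    cohort, membership, factors, eta = simulate_cohort(cfg)
    return {"cohort": cohort, "membership": membership, "factors": factors,
            "eta": eta, "config": cfg}


@pytest.fixture(scope="session")
def fitted_model(one_module_data):
    """An early-stopped composite-loss model fitted on 300 training subjects."""
    cohort = one_module_data["cohort"]
    rng = np.random.default_rng(7)
    idx = rng.permutation(400)
    tr = cohort.subset(idx[100:400])
    val = cohort.subset(idx[:100])
    hp = HyperParams(epochs=512, width=32, seed=7)
    model = train(tr, hp, "nmtlr_rank", val=val)
    return {"model": model, "train": tr, "val": val,
            "test": cohort.subset(np.arange(400, 600))}
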