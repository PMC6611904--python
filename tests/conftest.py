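import numpy as np
import pytest

import cismark as cm


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic small simulated dataset shared across read-only tests."""
    cfg = cm.SimConfig(n_genes=120, chrom_len=700_000, seed=11)
    annotation, genome, chip, inp, deg, truth = cm.simulate_dataset(cfg)
    return {
        "cfg": cfg,
        "annotation": annotation,
        "genome": genome,
        "chip": chip,
        "input": inp,
        "deg": deg,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
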