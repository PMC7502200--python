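import numpy as np
import pytest

import devnoise as dn
from devnoise import preprocess as pp


@pytest.fixture(scope="session")
def hourglass_sim():
    """Default (hourglass) synthetic study at moderate size, preprocessed."""
    cfg = dn.SimConfig(n_genes=1500, embryos_per_stage=12, seed=0)
    counts, meta, truth = dn.simulate_counts(cfg)
    expr = pp.correct_batch(pp.normalize(counts), meta, zero_mask=counts == 0)
    return {"config": cfg, "counts": counts, "meta": meta, "truth": truth, "expr": expr}


@pytest.fixture(scope="session")
def genome_sim():
    """Small simulation with its genome bundle (single mark for speed)."""
    cfg = dn.SimConfig(n_genes=600, embryos_per_stage=8, marks=("H3K4me3",), seed=1)
    counts, meta, truth = dn.simulate_counts(cfg)
    bundle = dn.simulate_genome(cfg, truth)
    return {"config": cfg, "counts": counts, "meta": meta, "truth": truth, "bundle": bundle}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
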