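import numpy as np
import pandas as pd
import pytest

import coldseq as cs


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-treatment simulation reused by read-only tests."""
    cfg = cs.SimConfig(
        n_genes=2000,
        conditions=("22C", "0C", "4C"),
        de_fraction_per_condition=0.2,
        lib_size_mean=1e6,
        seed=7,
    )
    cm, truth = cs.generate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def de_0c(small_sim):
    _, cm, _ = small_sim
    return cs.nb_exact_test(cm, "22C", "0C")


@pytest.fixture()
def toy_counts():
    """Six-sample Poisson-ish toy matrix with two conditions."""
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.poisson(60, size=(40, 6)),
        index=[f"g{i:02d}" for i in range(40)],
        columns=[f"s{j}" for j in range(6)],
    )
    cond = {f"s{j}": ("ctrl" if j < 3 else "cold") for j in range(6)}
    return cs.CountMatrix(counts, cond)


@pytest.fixture()
def toy_de_frame():
    """Hand-written DE table for ranking tests."""
    frame = pd.DataFrame(
        {
            "logFC": [5.0, 5.0, 3.0, -2.0, 4.0, 1.0],
            "logCPM": [6.0, 6.0, 6.0, 6.0, 3.0, 6.0],
            "PValue": [1e-5, 2e-5, 1e-4, 1e-4, 1e-5, 0.5],
            "FDR": [1e-4, 5e-5, 1e-3, 1e-3, 1e-4, 0.9],
        },
        index=["gB", "gA", "gC", "gD", "gE", "gF"],
    )
    return cs.DEResults(frame, control="ctrl", treatment="cold", dispersion=0.1)
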