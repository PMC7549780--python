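import numpy as np
import pandas as pd
import pytest

from hybridase import dualmap, simdata


@pytest.fixture(scope="session")
def small_refs():
    """Ten diverged 600 nt genes, the shared mapping fixture."""
    return simdata.simulate_references(
        10, 600, divergence_rate=0.07, seed=101, min_length=350
    )


@pytest.fixture(scope="session")
def small_index(small_refs):
    return dualmap.DualIndex(small_refs, k=31)


def make_de_frame(directions, log2fcs=None, genes=None) -> pd.DataFrame:
    """Minimal gene-indexed DE frame for patterns-level tests."""
    n = len(directions)
    if genes is None:
        genes = [f"g{i}" for i in range(n)]
    if log2fcs is None:
        lfc_of = {"up": 2.0, "down": -2.0, "unaltered": 0.0}
        log2fcs = [lfc_of[d] for d in directions]
    return pd.DataFrame(
        {"direction": list(directions), "log2fc": np.asarray(log2fcs, dtype=float)},
        index=genes,
    )
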