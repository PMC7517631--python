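import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from irsom.io import CountMatrix
from irsom.simulate import default_classes, simulate_counts, simulate_genesets, write_simulation


@pytest.fixture(scope="session")
def small_sim():
    """A small planted dataset: 4 x 120 class transcripts + 500 flat."""
    classes = default_classes(n_per_class=120, n_flat=500)
    matrix, design, truth = simulate_counts(classes, seed=101)
    return matrix, design, truth


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, small_sim):
    """The small dataset written out in the on-disk formats."""
    matrix, design, truth = small_sim
    sets = simulate_genesets(truth, n_decoy_sets=10, seed=102)
    outdir = tmp_path_factory.mktemp("simdata")
    write_simulation(outdir, matrix, design, truth, sets)
    return outdir


@pytest.fixture()
def tiny_counts():
    """Two-condition, 2x2-sample count matrix for unit arithmetic."""
    return CountMatrix(
        feature_ids=["T1", "T2", "T3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        counts=np.array([[10.0, 12, 50, 55], [5, 6, 5, 6], [100, 90, 100, 110]]),
        effective_lengths=np.array([100.0, 200.0, 1000.0]),
    )


@pytest.fixture()
def paired_design():
    rows = []
    for p in range(1, 6):
        for cond in ("pre_ischemia", "ischemia", "reperfusion"):
            rows.append((f"P{p}_{cond}", f"P{p}", cond))
    return pd.DataFrame(rows, columns=["sample", "patient", "condition"])
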