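import numpy as np
import pandas as pd
import pytest

from agesplit import synthetic


@pytest.fixture(scope="session")
def small_design():
    """A fast three-group design with every effect class planted."""
    return synthetic.StudyDesign(
        n_genes=600,
        group_sizes={"YH": 6, "YP": 5, "OP": 8},
        class_fractions={
            "null": 0.8,
            "pathology_up": 0.05,
            "pathology_down": 0.05,
            "primary_up": 0.05,
            "primary_down": 0.05,
        },
        seed=123,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    cm, truth = synthetic.simulate_counts(small_design)
    pm = synthetic.simulate_proteome(small_design, cm, truth)
    return cm, truth, pm


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by explicit sort-and-cummin."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
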