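import numpy as np
import pandas as pd
import pytest

from camrisk.synthetic import (
    simulate_expression,
    simulate_fractions,
    simulate_reference,
)


@pytest.fixture(scope="session")
def noiseless_mixture():
    """Small noiseless convex mixture with K_true = 3 and known ground truth."""
    S, markers = simulate_reference(3, 300, markers_per_subclone=20, marker_fold=5.0, seed=1)
    A, labels = simulate_fractions([80], [[1.0, 1.0, 1.0]], seed=2)
    X = simulate_expression(A, S, noise_sd=0.0, seed=3)
    return {"X": X, "A": A, "S": S, "markers": markers}


@pytest.fixture(scope="session")
def pure_marker_mixture():
    """Noiseless mixture whose markers have zero off-subclone expression."""
    S, markers = simulate_reference(
        3, 300, markers_per_subclone=20, marker_fold=5.0, seed=11, marker_background=0.0
    )
    A, _ = simulate_fractions([60], [[1.0, 1.0, 1.0]], seed=12)
    X = simulate_expression(A, S, noise_sd=0.0, seed=13)
    return {"X": X, "A": A, "S": S, "markers": markers}


@pytest.fixture(scope="session")
def two_group_labels():
    ids = [f"s{i:04d}" for i in range(120)]
    return pd.Series(["low"] * 80 + ["high"] * 40, index=ids, name="group")


@pytest.fixture(scope="session")
def survival_vectors():
    """Seeded two-group exponential survival arrays (no censoring)."""
    rng = np.random.default_rng(42)
    g = rng.integers(0, 2, 400)
    times = rng.exponential(1.0 / (0.05 * np.exp(0.8 * g)))
    events = np.ones(400, dtype=int)
    return times, events, g
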