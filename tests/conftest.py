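import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dopasig import simulate
from dopasig.io import CountMatrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Study-shaped cohort with planted mutation and batch effects."""
    design = simulate.default_design(800, n_lrrk2_deg=30, n_parkin_deg=30,
                                     n_shared_deg=20, seed=42)
    counts, meta, truth = simulate.simulate_counts(design)
    return counts, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_count_matrix(rng, n_genes=20, n_samples=5):
    counts = rng.negative_binomial(5, 0.3, size=(n_genes, n_samples))
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{j}" for j in range(n_samples)]
    return CountMatrix(genes, samples, counts)


@pytest.fixture
def two_group_meta():
    """Minimal two-group, two-place metadata for 16 samples (8 per group)."""
    rows = []
    for i in range(16):
        mut = "LRRK2" if i < 8 else "healthy"
        rows.append({
            "sample_id": f"S{i:02d}",
            "condition": "PD" if mut != "healthy" else "healthy",
            "mutation": mut,
            "place": "A" if i % 2 == 0 else "B",
            "replicate": str(i % 2 + 1),
            "gender": "M",
            "reprogramming": "sendai",
        })
    return pd.DataFrame(rows)
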