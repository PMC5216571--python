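import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from triploidexpr.io import ExpressionMatrix, GeneRecord


def make_matrix(counts, lengths=None, library_size=None):
    """Small 3-group ExpressionMatrix from a (genes x samples) count array."""
    counts = np.asarray(counts, dtype=np.int64)
    n_genes, n_samples = counts.shape
    if n_samples % 3:
        raise ValueError("samples must split evenly over the three groups")
    reps = n_samples // 3
    samples, group_of = [], {}
    for group in ("paternal", "maternal", "hybrid"):
        for r in range(1, reps + 1):
            name = f"{group}_{r}"
            samples.append(name)
            group_of[name] = group
    lengths = lengths if lengths is not None else [1000] * n_genes
    genes = [GeneRecord(f"g{i + 1}", int(L)) for i, L in enumerate(lengths)]
    if library_size is not None:
        library_size = np.full(n_samples, library_size, dtype=np.int64)
    return ExpressionMatrix(genes=genes, samples=samples, group_of=group_of,
                            counts=counts, library_size=library_size)


@pytest.fixture
def small_matrix():
    """3 genes x 9 samples with simple structured counts."""
    rng = np.random.default_rng(42)
    counts = rng.integers(5, 50, size=(3, 9))
    return make_matrix(counts)
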