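import numpy as np
import pytest

from mirhubnet import ExpressionMatrix, SyntheticConfig, generate_dual_dataset


@pytest.fixture
def labeled_matrix():
    """8 features x 20 samples, 10/10 classes; feature f0 separates them."""
    rng = np.random.default_rng(42)
    values = rng.standard_normal((8, 20))
    values[0, :10] -= 4.0
    values[0, 10:] += 4.0
    sample_ids = [f"S{i:02d}" for i in range(20)]
    labels = {s: ("alpha" if i < 10 else "beta") for i, s in enumerate(sample_ids)}
    return ExpressionMatrix([f"f{i}" for i in range(8)], sample_ids, values, labels)


@pytest.fixture
def tiny_dataset():
    """Small dual dataset for pipeline tests (fast to generate and analyse)."""
    config = SyntheticConfig(
        n_class_a=40, n_class_b=60, n_mirna=40, n_hubs=3, module_size=4,
        n_genes=300, targets_per_mirna=5, seed=11,
    )
    return generate_dual_dataset(config)


def null_labeled_matrix(n_features, n_per_class, seed, class_names=("alpha", "beta")):
    """Pure-noise two-class matrix for type-I checks."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    sample_ids = [f"S{i:03d}" for i in range(n)]
    labels = {
        s: (class_names[0] if i < n_per_class else class_names[1])
        for i, s in enumerate(sample_ids)
    }
    return ExpressionMatrix(
        [f"f{i}" for i in range(n_features)],
        sample_ids,
        rng.standard_normal((n_features, n)),
        labels,
    )
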