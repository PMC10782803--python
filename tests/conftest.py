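import numpy as np
import pytest

import methylens as ml
from methylens.core import BetaMatrix, LabelVector


@pytest.fixture(scope="session")
def small_dataset():
    """Separable 3-class beta matrix, 60 x 120."""
    spec = ml.SynthSpec(
        n_samples=60, n_features=120, n_classes=3, n_informative=10, delta=0.3, seed=1
    )
    return ml.gen_methyl_dataset(spec)


@pytest.fixture(scope="session")
def two_cluster_matrix():
    """Two clusters, 10 separating + 90 noise probes, with ground truth."""
    spec = ml.SynthSpec(
        n_samples=120, n_features=100, n_classes=2, n_informative=5, delta=0.35, seed=3
    )
    X, y = ml.gen_methyl_dataset(spec)
    return X, y, set(X.feature_ids[:10])


def planted_feature_dataset(seed, n=90, p=200, K=3, n_inf=10, delta=0.3):
    """K classes, ``n_inf`` informative probes total (feature j shifts
    class j mod K), the rest Beta(2,2) noise."""
    rng = np.random.default_rng(seed)
    X = rng.beta(2, 2, size=(n, p))
    lab = np.arange(n) % K
    lab = lab[rng.permutation(n)]
    signs = np.where(rng.random(n_inf) < 0.5, -1.0, 1.0)
    for j in range(n_inf):
        X[lab == j % K, j] += delta * signs[j]
    X = np.clip(X, 0.01, 0.99)
    ids = [f"S{i:03d}" for i in range(n)]
    fids = [f"cg{j:03d}" for j in range(p)]
    return (
        BetaMatrix(ids, fids, X),
        LabelVector(ids, [f"C{k + 1}" for k in lab]),
        set(fids[:n_inf]),
    )
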