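import numpy as np
import pandas as pd
import pytest

from iegdecode import schema as S
from iegdecode.normalization import FeatureMatrix
from iegdecode.synthetic_data import (
    default_config,
    generate_ct_dataset,
    generate_feature_matrix,
    null_config,
    sparse_signature_config,
)


@pytest.fixture(scope="session")
def default_fm():
    fm, truth = generate_feature_matrix(default_config(seed=7))
    return fm, truth


@pytest.fixture(scope="session")
def sparse_fm():
    fm, truth = generate_feature_matrix(sparse_signature_config(seed=11))
    return fm, truth


@pytest.fixture(scope="session")
def null_fm():
    fm, truth = generate_feature_matrix(null_config(seed=13))
    return fm, truth


@pytest.fixture(scope="session")
def ct_dataset():
    cfg = default_config(seed=3)
    return cfg, *generate_ct_dataset(cfg)


def make_feature_matrix(X, y, prefix="f"):
    """Wrap plain arrays as a FeatureMatrix for decoder-level tests."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = [f"m{i}" for i in range(len(X))]
    values = pd.DataFrame(
        X,
        index=pd.Index(ids, name=S.MOUSE),
        columns=[f"{prefix}{j}" for j in range(X.shape[1])],
    )
    return FeatureMatrix(values=values, labels=pd.Series(list(y), index=ids), transform="log2")


@pytest.fixture
def fm_factory():
    return make_feature_matrix


def brute_force_loo_predict(X, y, k=1):
    """Independent O(n^2) oracle: explicit distance loop, sorted
    candidate list, plurality vote with nearest-member tie-break."""
    import math

    X = np.asarray(X, dtype=float)
    preds = []
    for i in range(len(X)):
        dists = sorted(
            (math.dist(X[i], X[j]), j) for j in range(len(X)) if j != i
        )
        neighbors = [y[j] for _, j in dists[:k]]
        counts = {}
        for lab in neighbors:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        preds.append(next(lab for lab in neighbors if counts[lab] == best))
    return np.array(preds)


@pytest.fixture(scope="session")
def brute_force_loo():
    return brute_force_loo_predict
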