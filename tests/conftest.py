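import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rtcp.synthetic import SyntheticSpec, generate_dataset
from rtcp.features import rtcp_vector, feature_matrix


@pytest.fixture(scope="session")
def signal_dataset():
    """Synthetic dataset at the study conditions: 200 per class,
    reduced-alphabet signal 0.5, PSSM column shift 1.0, ST_SS alphabet."""
    ds = generate_dataset(SyntheticSpec(seed=11))
    vecs = [
        rtcp_vector(s, p, ds.spec.alphabet, i)
        for i, s, p in zip(ds.ids, ds.sequences, ds.pssms)
    ]
    X, ids, schema = feature_matrix(vecs)
    return ds, X, ids


@pytest.fixture(scope="session")
def separable_features():
    """Two well-separated 80-dim Gaussians, 200 samples each."""
    rng = np.random.default_rng(0)
    X = np.vstack(
        [rng.normal(-1.0, 1.0, size=(200, 80)), rng.normal(1.0, 1.0, size=(200, 80))]
    )
    y = np.array([0] * 200 + [1] * 200)
    return X, y
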