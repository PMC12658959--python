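import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from depthfd.traits import TraitSpace, default_trait_scheme

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return default_trait_scheme()


def make_space(points, labels=None, m=None):
    """Build a TraitSpace directly from raw coordinates (for metric tests)."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if labels is None:
        labels = [f"sp{i}" for i in range(points.shape[0])]
    coords = pd.DataFrame(
        points, index=labels,
        columns=[f"PCo{i+1}" for i in range(points.shape[1])],
    )
    return TraitSpace(
        coordinates=coords,
        eigenvalues=np.ones(points.shape[1]),
        m_selected=m or points.shape[1],
    )


@pytest.fixture
def space_factory():
    return make_space
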