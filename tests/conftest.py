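import numpy as np
import pytest
from hypothesis import settings

from nnct import Atlas, Connectome, GeneratorParams, validate_connectome

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def two_node() -> Connectome:
    """The analytic workhorse: coupling 0.5 between two nodes."""
    return validate_connectome(["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]]))


@pytest.fixture
def small_atlas() -> Atlas:
    return Atlas(
        node_ids=("v1", "v2", "m1"),
        labels=("Vis1", "Vis2", "Mot1"),
        lobes=("occipital", "occipital", "frontal"),
        networks=("visual", "visual", "somatomotor"),
    )


@pytest.fixture
def params() -> GeneratorParams:
    return GeneratorParams()


def random_symmetric_normalized(n: int, rng) -> np.ndarray:
    """A random symmetric matrix scaled to spectral radius < 1."""
    M = rng.standard_normal((n, n))
    M = (M + M.T) / 2
    return M / (1 + np.linalg.norm(M, 2))
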