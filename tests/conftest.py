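import numpy as np
import pytest

from geomix.hmm import AncestryModel, TransitionModel
from geomix.simulate import make_synthetic_gradients


def random_instance(seed, L=8, M=3, extent=((0.0, 10.0), (0.0, 10.0)),
                    steepness=0.5, missing_frac=0.0):
    """A small random haploid HMM instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    grad = make_synthetic_gradients(L, extent, steepness=steepness, seed=seed)
    h = rng.integers(0, 2, L).astype(float)
    if missing_frac:
        h[rng.random(L) < missing_frac] = np.nan
    X = rng.uniform(extent[0][0], extent[0][1], (M, 2))
    Pi = rng.dirichlet(np.ones(M))
    model = AncestryModel(X=X, Pi=Pi)
    trans = TransitionModel(tau=rng.uniform(0.0, 1.0, L - 1))
    return h, grad, model, trans


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
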