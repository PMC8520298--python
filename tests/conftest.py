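import numpy as np
import pytest

from msaunet import ModelConfig, build_model
from msaunet.phantom import PhantomSpec, generate_case
from msaunet.preprocessing import apply_clahe, window_ct


@pytest.fixture(scope="session")
def phantom_batch():
    """8 preprocessed 64x64 phantom slices with masks (one case)."""
    spec = PhantomSpec(size=(64, 64), n_cases=1, slices_per_case=8, rng_seed=123)
    slices = generate_case(spec, 0)
    imgs = np.stack([apply_clahe(window_ct(s.hu)) for s in slices])
    masks = np.stack([s.mask for s in slices])
    return imgs, masks


@pytest.fixture()
def tiny_model():
    """Smallest full configuration that satisfies the divisibility rules."""
    return build_model(ModelConfig(depth=2, base_filters=4, input_size=(32, 32),
                                   seed=0))


def finite_difference_grad(fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar-valued ``fn`` at ``x``."""
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        grad[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return grad
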