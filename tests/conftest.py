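import numpy as np
import pytest

from kiwidet.autograd import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(20240725)


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of a scalar-valued fn at x (float64)."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(x)
        flat[i] = orig - eps
        fm = fn(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g


def check_grad(op, x_shape, rng, eps=1e-3, rtol=5e-2, atol=5e-3, scale=1.0):
    """Compare autograd gradient of sum(op(x)) with finite differences."""
    x0 = (rng.standard_normal(x_shape) * scale).astype(np.float32)

    def f(arr):
        t = Tensor(arr.astype(np.float32))
        return float(op(t).sum().data)

    t = Tensor(x0.copy(), requires_grad=True)
    out = op(t).sum()
    out.backward()
    num = numeric_grad(f, x0.astype(np.float64), eps=eps)
    np.testing.assert_allclose(t.grad, num, rtol=rtol, atol=atol)
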