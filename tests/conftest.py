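import numpy as np
import pytest

from lmtb import nn
from lmtb.tensor import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def zero_biases(model):
    """Zero every additive parameter (conv/linear biases, norm shifts, DyT gamma)."""
    for name, p in model.named_parameters():
        if name.rsplit(".", 1)[-1] in ("bias", "gamma"):
            p.data[:] = 0.0
    return model


def numeric_grad(fn, arr, eps=1e-5):
    """Central finite differences of scalar fn w.r.t. a float64 array."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        f1 = fn()
        arr[i] = orig - eps
        f2 = fn()
        arr[i] = orig
        g[i] = (f1 - f2) / (2 * eps)
        it.iternext()
    return g


def check_grad(op, *arrays, atol=1e-6, rtol=1e-4):
    """Compare autograd gradients of sum(op(*tensors)) with finite differences."""
    tensors = [Tensor(a.astype(np.float64), requires_grad=True) for a in arrays]
    out = op(*tensors)
    out.sum().backward()
    for t, a in zip(tensors, arrays):
        ref = numeric_grad(lambda: op(*[Tensor(x.data) for x in tensors]).sum().item(), t.data)
        np.testing.assert_allclose(t.grad, ref, atol=atol, rtol=rtol)


@pytest.fixture(autouse=True)
def _seed_weight_init():
    nn.manual_seed(0)
    yield
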