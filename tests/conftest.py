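import numpy as np
import pytest

from seednet.network_builder import NetworkPlan


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_plan():
    """A miniature stage layout for fast training/plumbing tests."""
    return NetworkPlan(stem_channels=8, block_counts=(2, 2),
                       mid_channels=(4, 8), early_stages=1)


def numeric_grad(fn, x, eps=1e-5):
    """Central-difference gradient of a scalar-valued fn at x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        f1 = fn(x)
        x[i] = orig - eps
        f0 = fn(x)
        x[i] = orig
        g[i] = (f1 - f0) / (2 * eps)
        it.iternext()
    return g


def promote_to_float64(module):
    """Cast a module's parameters/state to float64 for tight grad checks."""
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
        p.grad = np.zeros_like(p.data)
    for m in module.modules():
        for attr in ("running_mean", "running_var"):
            if hasattr(m, attr):
                setattr(m, attr, getattr(m, attr).astype(np.float64))
    return module


def check_module_gradients(module, x, rtol=1e-6, atol=1e-8, seed=0):
    """Compare analytic backward() against central differences.

    Checks the input gradient and every parameter gradient of the module
    for the scalar objective sum(forward(x) * R) with a fixed random R.
    """
    promote_to_float64(module)
    x = np.asarray(x, dtype=np.float64)
    r = np.random.default_rng(seed).normal(size=module.forward(x).shape)

    def objective_x(xv):
        return float((module.forward(xv) * r).sum())

    module.forward(x)
    module.zero_grad()
    dx = module.backward(r)
    dx_num = numeric_grad(objective_x, x.copy())
    np.testing.assert_allclose(dx, dx_num, rtol=rtol, atol=atol,
                               err_msg="input gradient mismatch")

    for name, p in module.named_parameters():
        analytic = p.grad.copy()

        def objective_p(pv, p=p):
            old = p.data
            p.data = pv
            val = float((module.forward(x) * r).sum())
            p.data = old
            return val

        numeric = numeric_grad(objective_p, p.data.copy())
        np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol,
                                   err_msg=f"parameter gradient mismatch: {name}")
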