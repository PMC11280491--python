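import numpy as np
import pytest

from dentseg.deformable_pathway import StageConfig
from dentseg.runtime import ModelConfig
from dentseg.semantic_enhance import SEMConfig
from dentseg.ssm_pathway import SSMConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Smallest structurally-complete model; used where only wiring matters."""
    return ModelConfig(
        stages=StageConfig(depths=(1, 1, 1, 1), channels=(4, 8, 8, 8),
                           groups=2, droppath_rate=0.0, mlp_ratio=1.0),
        ssm=SSMConfig(stem_channels=2, state_dim=2, mlp_ratio=1.0),
        sem=SEMConfig(fused_channels=8, codewords=4, mlp_ratio=1.0),
        attention_ratio=2, seed=7)


def numerical_gradcheck(f, tensors, eps=1e-6, tol=1e-5, seed=0):
    """Compare autodiff gradients of scalar-projected f against central
    finite differences, for every input tensor."""
    out = f(*tensors)
    proj = np.random.default_rng(seed).standard_normal(out.shape)
    out.backward(proj)
    for t in tensors:
        num = np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = t.data[i]
            t.data[i] = orig + eps
            f_plus = f(*tensors).data
            t.data[i] = orig - eps
            f_minus = f(*tensors).data
            t.data[i] = orig
            num[i] = ((f_plus - f_minus) / (2 * eps) * proj).sum()
        err = np.abs(num - t.grad).max()
        assert err < tol, f"gradcheck failed: max abs err {err} on shape {t.shape}"
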