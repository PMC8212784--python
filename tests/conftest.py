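import numpy as np
import pytest

from mtseg.mtvnet import MultiTaskVNet, NetworkConfig
from mtseg.phantom import PhantomSpec, generate_case, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(volume_shape=(48, 48, 48), subregion_radii=(10.0, 7.0, 4.0), seed=7)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_case(small_spec)


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory, small_spec):
    root = tmp_path_factory.mktemp("phantoms") / "ds"
    manifest = generate_dataset(3, root, spec=small_spec, seed=11)
    return root, manifest


@pytest.fixture(scope="session")
def tiny_net() -> MultiTaskVNet:
    return MultiTaskVNet(NetworkConfig(encoder_levels=2, base_filters=2, seed=5))


def cast_params_float64(obj, _seen=None):
    """Recursively promote every layer's parameters to float64 (for
    finite-difference gradient checks)."""
    from mtseg.nn.layers import Layer

    _seen = _seen if _seen is not None else set()
    if id(obj) in _seen:
        return obj
    _seen.add(id(obj))
    if isinstance(obj, Layer):
        for k in obj.params:
            obj.params[k] = obj.params[k].astype(np.float64)
        if hasattr(obj, "running_mean"):
            obj.running_mean = obj.running_mean.astype(np.float64)
            obj.running_var = obj.running_var.astype(np.float64)
    if hasattr(obj, "__dict__"):
        for attr in vars(obj).values():
            if isinstance(attr, list):
                for item in attr:
                    if item is not None and hasattr(item, "__dict__"):
                        cast_params_float64(item, _seen)
            elif hasattr(attr, "__dict__") and not isinstance(attr, np.ndarray):
                cast_params_float64(attr, _seen)
    return obj
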