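import numpy as np
import pytest

from sddliver.config import RunConfig
from sddliver.phantom import PhantomSpec, generate_slice


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def stomach_phantom():
    """One canonical stomach-case phantom slice with ground truth."""
    return generate_slice(PhantomSpec(case="stomach", seed=7))


@pytest.fixture(scope="session")
def phantom_suite():
    """Small multi-case phantom set (image, masks, case) for pipeline tests."""
    out = []
    for case in ("stomach", "kidney", "heart"):
        for seed in (0, 1):
            img, masks = generate_slice(PhantomSpec(case=case, seed=seed))
            out.append((img, masks, case))
    return out


def circle_contour(radius: float, n: int = 200, center=(100.0, 100.0)) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)]
    )
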