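import numpy as np
import pytest

from dnqsm.phantom import PhantomSpec, make_dentate_phantom


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Compact 40³ phantom used where full default resolution is unnecessary."""
    kw = dict(
        grid_shape=(40, 40, 40),
        brain_radii_mm=(8.5, 8.5, 8.0),
        shell_center_mm=(4.0, 0.0, 0.0),
        shell_radii_mm=(3.0, 4.0, 3.5),
        wall_thickness_mm=0.8,
        corrugation_amplitude_mm=0.4,
        csf_pocket_radius_mm=1.0,
        external_source_positions_mm=((9.0, 8.5, 7.5), (-8.5, -8.0, -7.0)),
        external_source_strengths=(1.5e3, -1.0e3),
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth of the default dentate phantom (96³, 0.5 mm)."""
    return make_dentate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_truth():
    return make_dentate_phantom(small_phantom_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
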