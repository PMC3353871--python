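import numpy as np
import pytest

import voxmark as vm


@pytest.fixture(scope="session")
def sphere32():
    """Solid sphere, radius 10, centered in a 32^3 unit-spacing grid."""
    spec = vm.PhantomSpec(kind="solid_sphere", dims=(32, 32, 32), radius=10.0)
    return vm.generate(spec)


@pytest.fixture(scope="session")
def two_shell32():
    """Nested bone shells (outer r=12, inner r=6) around soft interior."""
    spec = vm.PhantomSpec(
        kind="two_shell", dims=(32, 32, 32), radius=12.0, inner_radius=6.0, shell_thickness=2.0
    )
    return vm.generate(spec)


@pytest.fixture(scope="session")
def two_shell32_aa():
    """Anti-aliased variant of the two-shell phantom for renderer tests."""
    spec = vm.PhantomSpec(
        kind="two_shell", dims=(32, 32, 32), radius=12.0, inner_radius=6.0,
        shell_thickness=2.0, antialias=True,
    )
    return vm.generate(spec)


@pytest.fixture(scope="session")
def mirror_blobs():
    """Two bone spheres exactly mirrored about the x midplane of a 48x32x32 grid."""
    spec = vm.PhantomSpec(
        kind="mirror_blobs", dims=(48, 32, 32), radius=6.0, blob_offset=12.0
    )
    return vm.generate(spec)


@pytest.fixture
def random_volume():
    def make(dims=(8, 8, 8), seed=0, spacing=(1.0, 1.0, 1.0)):
        rng = np.random.default_rng(seed)
        return vm.Volume(data=rng.uniform(0, 100, size=dims), spacing=spacing)

    return make
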