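import numpy as np
import pytest

from octenamel import LayerSpec, PhantomSpec, VoxelGeometry


@pytest.fixture
def geometry():
    return VoxelGeometry()  # 12, 12, 7 um, n = 1.63


@pytest.fixture
def slab_spec_factory():
    """Single uniform enamel slab occupying exactly ``enamel_rows`` image
    rows (attenuation 0, no surface line), on a dark background."""

    def make(
        enamel_rows=100,
        rows=160,
        cols=50,
        frames=6,
        speckle_shape=None,
        seed=0,
        geometry=None,
    ):
        g = geometry or VoxelGeometry()
        # same float expression as the generator's depth axis, so the band
        # covers exactly enamel_rows image rows
        thickness = enamel_rows * (g.ly_um / g.n_tissue)
        return PhantomSpec(
            rows=rows,
            cols=cols,
            frames=frames,
            geometry=g,
            layers=[LayerSpec("enamel", 0.0, thickness, 200.0, 0.0)],
            surface_offset_px=10,
            surface_reflectivity=0.0,
            speckle_shape=speckle_shape,
            noise_floor=8.0,
            seed=seed,
        )

    return make
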