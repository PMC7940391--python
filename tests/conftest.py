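import numpy as np
import pytest

from parcstd import Parcellation, SynthSpec, voronoi_parcellation


def parc(labels, voxel_size=(1.0, 1.0, 1.0), name="test", space="testspace"):
    """Wrap an integer array as a Parcellation on a diagonal-affine grid."""
    labels = np.asarray(labels)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return Parcellation(labels=labels, affine=aff, name=name, space=space)


@pytest.fixture
def small_voronoi():
    """A 24^3 Voronoi parcellation with 12 regions (deterministic)."""
    spec = SynthSpec(
        shape=(24, 24, 24), n_regions=12, seed=42, semi_axes=(10.5, 10.5, 10.5)
    )
    return voronoi_parcellation(spec)


@pytest.fixture
def flat_volume():
    """2x2x2 volume: half label 1, half label 2."""
    labels = np.array([[[1, 1], [1, 1]], [[2, 2], [2, 2]]])
    return parc(labels)
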