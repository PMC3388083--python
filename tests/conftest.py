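import numpy as np
import pytest

from voxtrace.transfer import TransferFunction1D
from voxtrace.transport import Medium
from voxtrace.volume import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def constant_tf(opacity=1.0, emission=(0.0, 0.0, 0.0), diffuse=(0.8, 0.8, 0.8)):
    return TransferFunction1D(
        {
            "opacity": ([0.0, 1.0], [opacity, opacity]),
            "emission": ([0.0, 1.0], [emission, emission]),
            "diffuse": ([0.0, 1.0], [diffuse, diffuse]),
        }
    )


def homogeneous_medium(sigma_t, extent=1000.0, dims=4):
    """Homogeneous medium with extinction sigma_t filling a large box.

    The stored field is the full-range constant 65535, so normalized
    intensity is 1 everywhere and sigma_t = density_scale exactly.
    """
    spacing = extent / (dims - 1)
    v = Volume(
        np.full((dims, dims, dims), 65535, dtype=np.uint16),
        (spacing, spacing, spacing),
        (-extent / 2, -extent / 2, -extent / 2),
        (0.0, 65535.0),
    )
    if sigma_t == 0.0:
        return Medium(v, constant_tf(opacity=0.0), 1.0)
    return Medium(v, constant_tf(opacity=1.0), float(sigma_t))


def two_layer_medium(sigma_lo, sigma_hi, boundary_voxel=32, extent=1000.0, dims=64):
    """Two-layer slab along z: sigma_lo then sigma_hi (both must be <= 1).

    The stored field steps between two values at voxel ``boundary_voxel``
    and the opacity map steps at the midpoint intensity, so the effective
    extinction boundary sits exactly at ``z_eff = (boundary_voxel - 0.5) *
    spacing`` (where trilinear interpolation crosses the midpoint). Returns
    ``(medium, z_eff)``.
    """
    spacing = extent / (dims - 1)
    layer = np.where(np.arange(dims) < boundary_voxel, 16384, 49152).astype(np.uint16)
    data = np.broadcast_to(layer[None, None, :], (dims, dims, dims)).copy()
    v = Volume(data, (spacing,) * 3, (0.0, 0.0, 0.0), (0.0, 65535.0))
    lo_u, hi_u = 16384 / 65535, 49152 / 65535
    mid = (lo_u + hi_u) / 2
    tf = TransferFunction1D(
        {
            "opacity": (
                [0.0, mid - 1e-9, mid + 1e-9, 1.0],
                [sigma_lo, sigma_lo, sigma_hi, sigma_hi],
            )
        }
    )
    return Medium(v, tf, 1.0), (boundary_voxel - 0.5) * spacing
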