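"""Small vector-math helpers shared by the rendering modules.

Everything here is vectorized: points and directions are arrays of shape
``(..., 3)`` and scalar quantities broadcast along the leading axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "orthonormal_basis",
    "concentric_disk",
    "uniform_sphere",
    "cosine_hemisphere",
    "cosine_hemisphere_pdf",
]


def normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Return ``v`` scaled to unit length along ``axis`` (zero maps to zero)."""
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, v / n, 0.0)
    return out


def orthonormal_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Build tangent vectors (t, b) so that (t, b, n) is right-handed.

    Branchless construction (Duff et al.); ``n`` must be unit length,
    shape ``(..., 3)``.
    """
    n = np.asarray(n, dtype=np.float64)
    sign = np.where(n[..., 2] >= 0.0, 1.0, -1.0)
    a = -1.0 / (sign + n[..., 2])
    b = n[..., 0] * n[..., 1] * a
    t = np.stack(
        [1.0 + sign * n[..., 0] ** 2 * a, sign * b, -sign * n[..., 0]], axis=-1
    )
    bt = np.stack([b, sign + n[..., 1] ** 2 * a, -n[..., 1]], axis=-1)
    return t, bt


def concentric_disk(u1: np.ndarray, u2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shirley–Chiu concentric mapping from the unit square to the unit disk.

    Low-distortion and area preserving, so uniform square samples become
    uniform disk samples.
    """
    ox = 2.0 * np.asarray(u1, dtype=np.float64) - 1.0
    oy = 2.0 * np.asarray(u2, dtype=np.float64) - 1.0
    use_x = np.abs(ox) > np.abs(oy)
    r = np.where(use_x, ox, oy)  # signed radius covers both half-planes
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(
            use_x,
            (np.pi / 4.0) * (oy / np.where(ox == 0, 1.0, ox)),
            (np.pi / 2.0) - (np.pi / 4.0) * (ox / np.where(oy == 0, 1.0, oy)),
        )
    theta = np.where((ox == 0) & (oy == 0), 0.0, theta)
    r = np.where((ox == 0) & (oy == 0), 0.0, r)
    return r * np.cos(theta), r * np.sin(theta)


def uniform_sphere(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """Uniform direction on the unit sphere; pdf is 1/(4*pi) per steradian."""
    z = 1.0 - 2.0 * np.asarray(u1, dtype=np.float64)
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = 2.0 * np.pi * np.asarray(u2, dtype=np.float64)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)


def cosine_hemisphere(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """Cosine-weighted direction about +z; pdf is cos(theta)/pi."""
    dx, dy = concentric_disk(u1, u2)
    z = np.sqrt(np.clip(1.0 - dx * dx - dy * dy, 0.0, None))
    return np.stack([dx, dy, z], axis=-1)


def cosine_hemisphere_pdf(cos_theta: np.ndarray) -> np.ndarray:
    return np.where(cos_theta > 0.0, cos_theta / np.pi, 0.0)
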