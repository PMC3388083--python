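"""Thin-lens camera: primary-ray generation with stratified pixel sampling.

Conventions (used everywhere):

* right-handed camera basis ``(right, up, forward)`` with ``forward`` from
  eye to target;
* the film plane sits at ``focal_distance`` in front of the lens with
  physical height ``2 * focal_distance * tan(vertical_fov / 2)`` — so every
  film point is its own focal point and a zero-radius aperture reduces
  exactly to a pinhole camera;
* pixel ``(0, 0)`` is top-left, y down; world units mm.

Lens points are drawn with the Shirley–Chiu concentric disk mapping, scaled
by ``aperture_radius``; the aperture size controls depth of field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mathutils import concentric_disk, normalize

__all__ = ["Ray", "ThinLensCamera", "generate_ray", "generate_rays", "stratified_jitter"]


@dataclass
class Ray:
    """Ray batch: ``origin``/``direction`` have shape ``(..., 3)``.

    ``direction`` is unit length; the parametric range is ``[tmin, tmax]``.
    """

    origin: np.ndarray
    direction: np.ndarray
    tmin: np.ndarray = 0.0
    tmax: np.ndarray = np.inf

    def at(self, t) -> np.ndarray:
        return self.origin + np.asarray(t)[..., None] * self.direction


@dataclass
class ThinLensCamera:
    eye: np.ndarray
    target: np.ndarray
    up: np.ndarray
    vertical_fov: float  # degrees
    film_resolution: tuple[int, int]  # (width, height) pixels
    aperture_radius: float = 0.0  # mm; 0 = pinhole
    focal_distance: float | None = None  # mm; default |target - eye|

    forward: np.ndarray = field(init=False)
    right: np.ndarray = field(init=False)
    up_cam: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.eye = np.asarray(self.eye, dtype=np.float64)
        self.target = np.asarray(self.target, dtype=np.float64)
        self.up = np.asarray(self.up, dtype=np.float64)
        view = self.target - self.eye
        vn = np.linalg.norm(view)
        if vn == 0:
            raise ValueError("eye and target coincide")
        if not 0.0 < self.vertical_fov < 180.0:
            raise ValueError("vertical_fov must be in (0, 180) degrees")
        if self.aperture_radius < 0:
            raise ValueError("aperture_radius must be nonnegative")
        self.forward = view / vn
        r = np.cross(normalize(self.up), self.forward)
        rn = np.linalg.norm(r)
        if rn < 1e-12:
            raise ValueError("view direction parallel to up")
        self.right = r / rn  # right x up_cam = forward (right-handed)
        self.up_cam = np.cross(self.forward, self.right)
        if self.focal_distance is None:
            self.focal_distance = float(vn)
        if self.focal_distance <= 0:
            raise ValueError("focal_distance must be positive")

    @property
    def film_height_mm(self) -> float:
        return 2.0 * self.focal_distance * np.tan(np.radians(self.vertical_fov) / 2.0)

    @property
    def film_width_mm(self) -> float:
        w, h = self.film_resolution
        return self.film_height_mm * w / h


def stratified_jitter(sample_index: int, strata: tuple[int, int], rng, n: int | None = None):
    """One uniform point inside the current stratum of an ``sx x sy`` grid.

    Successive ``sample_index`` values rotate row-major through the strata,
    so ``sx * sy`` consecutive frame estimates cover every stratum once.
    With ``n`` given, returns ``n`` independent points (shape ``(n, 2)``),
    all inside the same stratum — the per-frame batch case.
    """
    sx, sy = strata
    if sx < 1 or sy < 1:
        raise ValueError("strata must be >= (1, 1)")
    k = int(sample_index) % (sx * sy)
    ix, iy = k % sx, k // sx
    u = rng.random((n, 2) if n is not None else 2)
    u[..., 0] = (ix + u[..., 0]) / sx
    u[..., 1] = (iy + u[..., 1]) / sy
    return u


def generate_rays(
    cam: ThinLensCamera,
    pixels: np.ndarray,
    rng,
    frame_index: int = 0,
    strata: tuple[int, int] = (2, 2),
    film_uv: np.ndarray | None = None,
    lens_uv: np.ndarray | None = None,
) -> Ray:
    """Primary rays for integer pixel coordinates ``pixels`` (shape (n, 2)).

    The film point is the pixel corner plus a stratified jitter in the pixel
    square (``film_uv`` overrides the jitter — handy for tests); the lens
    point is a concentric-disk sample scaled by the aperture radius
    (``lens_uv`` overrides the pre-warp square sample). Every lens ray
    passes through the focal-plane point of its pinhole counterpart.
    """
    pixels = np.atleast_2d(np.asarray(pixels))
    n = pixels.shape[0]
    w, h = cam.film_resolution
    if np.any(pixels < 0) or np.any(pixels[:, 0] >= w) or np.any(pixels[:, 1] >= h):
        raise ValueError("pixel outside film resolution")
    if film_uv is None:
        film_uv = stratified_jitter(frame_index, strata, rng, n)
    film_uv = np.atleast_2d(np.asarray(film_uv, dtype=np.float64))

    # film-plane point (= focal point) in world space
    sx = (pixels[:, 0] + film_uv[:, 0]) / w  # 0..1 left->right
    sy = (pixels[:, 1] + film_uv[:, 1]) / h  # 0..1 top->bottom
    fw, fh = cam.film_width_mm, cam.film_height_mm
    focal_pt = (
        cam.eye
        + cam.focal_distance * cam.forward
        + ((sx - 0.5) * fw)[:, None] * cam.right
        + ((0.5 - sy) * fh)[:, None] * cam.up_cam
    )

    if cam.aperture_radius > 0.0:
        if lens_uv is None:
            lens_uv = rng.random((n, 2))
        lens_uv = np.atleast_2d(np.asarray(lens_uv, dtype=np.float64))
        lx, ly = concentric_disk(lens_uv[:, 0], lens_uv[:, 1])
        origin = (
            cam.eye
            + (cam.aperture_radius * lx)[:, None] * cam.right
            + (cam.aperture_radius * ly)[:, None] * cam.up_cam
        )
    else:
        origin = np.broadcast_to(cam.eye, (n, 3)).copy()
    direction = normalize(focal_pt - origin)
    return Ray(origin, direction, np.zeros(n), np.full(n, np.inf))


def generate_ray(cam: ThinLensCamera, pixel, rng, **kw) -> Ray:
    """Single-pixel convenience wrapper around :func:`generate_rays`."""
    r = generate_rays(cam, np.asarray(pixel)[None, :], rng, **kw)
    return Ray(r.origin[0], r.direction[0], float(r.tmin[0]), float(r.tmax[0]))
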