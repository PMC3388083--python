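"""Area and background (environment) lights: sampling, evaluation, intersection.

Two light shapes cover every configuration the renderer supports: textured
planar rectangles (``AreaLight``) and an all-enclosing background sphere at
infinity (``BackgroundLight``). Both expose the pair of operations the MIS
estimator needs:

* ``sample_light`` — draw a direction toward the light from a shading point,
  with its solid-angle pdf and the light's exitant radiance;
* ``intersect_light`` — given a scattering-sampled ray, find the light hit
  and report the *same* pdf that ``sample_light`` would have assigned to
  that direction (the consistency MIS relies on).

Area-light sampling is uniform over the rectangle; the area-measure pdf
``1/A`` converts to solid angle as ``pdf = d^2 / (A * |cos(theta_l)|)``.
The background is sampled uniformly over the sphere, pdf ``1/(4*pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mathutils import normalize, uniform_sphere

__all__ = ["AreaLight", "BackgroundLight", "LightSample", "sample_light", "intersect_light"]

_EPS = 1e-12


def _texture_lookup(tex: np.ndarray, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Bilinear lookup of an (H, W, 3) texture at coordinates in [0, 1]^2."""
    h, w = tex.shape[:2]
    x = np.clip(s, 0.0, 1.0) * (w - 1)
    y = np.clip(t, 0.0, 1.0) * (h - 1)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (x - x0)[..., None]
    fy = (y - y0)[..., None]
    return (
        tex[y0, x0] * (1 - fx) * (1 - fy)
        + tex[y0, x1] * fx * (1 - fy)
        + tex[y1, x0] * (1 - fx) * fy
        + tex[y1, x1] * fx * fy
    )


@dataclass
class AreaLight:
    """Planar rectangular light with an orthonormal frame.

    ``normal`` faces the emitting side when ``one_sided``; ``up_hint`` fixes
    the in-plane orientation. ``radiance`` is a constant RGB triple or an
    (H, W, 3) texture mapped over the rectangle.
    """

    center: np.ndarray
    normal: np.ndarray
    half_extents: tuple[float, float]  # mm
    radiance: np.ndarray  # (3,) or (H, W, 3)
    up_hint: np.ndarray = (0.0, 0.0, 1.0)
    one_sided: bool = True

    u_axis: np.ndarray = field(init=False)
    v_axis: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.normal = np.asarray(normalize(self.normal), dtype=np.float64)
        self.radiance = np.asarray(self.radiance, dtype=np.float64)
        hx, hy = self.half_extents
        if hx <= 0 or hy <= 0:
            raise ValueError("half_extents must be positive")
        u = np.cross(np.asarray(self.up_hint, dtype=np.float64), self.normal)
        if np.linalg.norm(u) < 1e-9:
            u = np.cross(np.array([1.0, 0.0, 0.0]), self.normal)
        self.u_axis = normalize(u)
        self.v_axis = np.cross(self.normal, self.u_axis)

    @property
    def area(self) -> float:
        return 4.0 * self.half_extents[0] * self.half_extents[1]

    def exitant_radiance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Radiance at local rectangle coordinates (a, b) in [-1, 1]^2."""
        if self.radiance.ndim == 1:
            return np.broadcast_to(self.radiance, np.shape(a) + (3,)).copy()
        return _texture_lookup(self.radiance, (a + 1) / 2, (b + 1) / 2)


@dataclass
class BackgroundLight:
    """Environment light at infinity: constant RGB or lat-long texture."""

    radiance: np.ndarray

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=np.float64)

    def radiance_along(self, direction: np.ndarray) -> np.ndarray:
        direction = np.asarray(direction, dtype=np.float64)
        if self.radiance.ndim == 1:
            return np.broadcast_to(self.radiance, direction.shape).copy()
        s = np.arctan2(direction[..., 1], direction[..., 0]) / (2 * np.pi) + 0.5
        t = np.arccos(np.clip(direction[..., 2], -1.0, 1.0)) / np.pi
        return _texture_lookup(self.radiance, s, t)


@dataclass
class LightSample:
    """Batched light sample toward the light from each shading point."""

    direction: np.ndarray  # unit, shading point -> light
    distance: np.ndarray  # mm; inf for background
    pdf_solid_angle: np.ndarray  # 1/sr; <= 0 flags an invalid/degenerate sample
    exitant_radiance: np.ndarray


def sample_light(light, from_point: np.ndarray, rng) -> LightSample:
    """Draw one stochastic sample on ``light`` per shading point (vectorized)."""
    p = np.atleast_2d(np.asarray(from_point, dtype=np.float64))
    n = p.shape[0]
    if isinstance(light, BackgroundLight):
        u = rng.random((n, 2))
        wi = uniform_sphere(u[:, 0], u[:, 1])
        pdf = np.full(n, 1.0 / (4.0 * np.pi))
        return LightSample(wi, np.full(n, np.inf), pdf, light.radiance_along(wi))

    ab = 2.0 * rng.random((n, 2)) - 1.0
    pt = (
        light.center
        + (ab[:, 0] * light.half_extents[0])[:, None] * light.u_axis
        + (ab[:, 1] * light.half_extents[1])[:, None] * light.v_axis
    )
    d = pt - p
    dist = np.linalg.norm(d, axis=-1)
    ok = dist > _EPS
    wi = np.where(ok[:, None], d / np.where(ok, dist, 1.0)[:, None], 0.0)
    cos_l = -np.einsum("ij,j->i", wi, light.normal)
    rad = light.exitant_radiance(ab[:, 0], ab[:, 1])
    if light.one_sided:
        rad = np.where((cos_l > 0.0)[:, None], rad, 0.0)
    degenerate = (np.abs(cos_l) <= _EPS) | ~ok
    pdf = np.where(
        degenerate, 0.0, dist**2 / (light.area * np.abs(np.where(degenerate, 1.0, cos_l)))
    )
    rad = np.where(degenerate[:, None], 0.0, rad)
    return LightSample(wi, dist, pdf, rad)


def intersect_light(light, ray):
    """Intersect ``ray`` with ``light``.

    Returns ``(hit, distance, exitant_radiance, pdf_solid_angle)`` where the
    pdf is exactly the density :func:`sample_light` assigns to the hit
    direction from the ray origin — required by the power heuristic.
    Background lights are hit at infinite distance by any ray.
    """
    o = np.atleast_2d(np.asarray(ray.origin, dtype=np.float64))
    d = np.atleast_2d(np.asarray(ray.direction, dtype=np.float64))
    n = o.shape[0]
    if isinstance(light, BackgroundLight):
        return (
            np.ones(n, dtype=bool),
            np.full(n, np.inf),
            light.radiance_along(d),
            np.full(n, 1.0 / (4.0 * np.pi)),
        )

    denom = np.einsum("ij,j->i", d, light.normal)
    # plane intersection
    num = np.einsum("ij,j->i", light.center - o, light.normal)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    tmin = np.broadcast_to(np.asarray(ray.tmin, dtype=np.float64), (n,))
    tmax = np.broadcast_to(np.asarray(ray.tmax, dtype=np.float64), (n,))
    valid = (np.abs(denom) > _EPS) & (t > np.maximum(tmin, _EPS)) & (t <= tmax)
    hit_pt = o + np.where(np.isfinite(t), t, 0.0)[:, None] * d
    rel = hit_pt - light.center
    a = np.einsum("ij,j->i", rel, light.u_axis) / light.half_extents[0]
    b = np.einsum("ij,j->i", rel, light.v_axis) / light.half_extents[1]
    valid &= (np.abs(a) <= 1.0) & (np.abs(b) <= 1.0)
    cos_l = -denom  # cos between light normal and direction toward the origin
    rad = light.exitant_radiance(np.clip(a, -1, 1), np.clip(b, -1, 1))
    if light.one_sided:
        rad = np.where((cos_l > 0.0)[:, None], rad, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pdf = np.where(valid, t**2 / (light.area * np.abs(cos_l)), 0.0)
    rad = np.where(valid[:, None], rad, 0.0)
    dist = np.where(valid, t, np.inf)
    return valid, dist, rad, pdf
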