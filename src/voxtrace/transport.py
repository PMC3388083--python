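"""The core estimator: Woodcock tracking and MIS single-scatter direct lighting.

One frame estimate per pixel follows the stochastic ray-casting recipe:

1. a thin-lens camera ray is clipped against the volume's bounding box
   (misses return the background radiance);
2. **Woodcock tracking** samples a free path through the heterogeneous
   medium: tentative collisions are generated with the majorant extinction
   ``sigma_max`` (``t <- t - ln(1-u)/sigma_max``) and accepted with
   probability ``sigma_t(x)/sigma_max``. The method is unbiased and yields
   exactly one scattering point per ray;
3. at the accepted point a scattering mode (BRDF or phase) is chosen by the
   hybrid rule, the transfer function's emission is deposited, and direct
   lighting is estimated with **multiple importance sampling**: one light
   sample and one scattering-function sample, combined with the power
   heuristic (beta = 2). Shadow rays are single binary Woodcock queries —
   blocked or unblocked — whose expectation is the transmittance.

Everything is vectorized over ray/event batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import scattering as sc
from . import transfer, volume as vol
from .camera import Ray, generate_rays
from .lights import BackgroundLight, intersect_light, sample_light

__all__ = [
    "Medium",
    "TrackingResult",
    "woodcock_track",
    "shadow_visible",
    "power_heuristic",
    "make_scatter_event",
    "scatter_eval",
    "scatter_sample",
    "estimate_direct",
    "render_frame",
    "render_sample",
]


@dataclass
class Medium:
    """A volume tied to its transfer function and global density scale."""

    volume: vol.Volume
    tf: transfer.TransferFunction1D
    density_scale: float  # 1/mm

    @cached_property
    def sigma_max(self) -> float:
        return transfer.sigma_max(self.tf, self.density_scale)

    def sigma_t(self, intensity: np.ndarray) -> np.ndarray:
        return self.density_scale * transfer.eval_channel(self.tf, "opacity", intensity)


@dataclass
class TrackingResult:
    """Outcome of Woodcock tracking for a ray batch."""

    scattered: np.ndarray  # (n,) bool
    t_scatter: np.ndarray  # (n,) mm, nan where not scattered
    position: np.ndarray  # (n, 3) mm, valid where scattered
    intensity: np.ndarray  # (n,) normalized intensity at the accepted point


def woodcock_track(ray: Ray, t_near, t_far, medium: Medium, rng, sigma_max=None) -> TrackingResult:
    """Sample one free path per ray between ``t_near`` and ``t_far``.

    Unbiased for any ``sigma_max >= sigma_t`` along the ray; a nonpositive
    majorant means vacuum and never scatters.
    """
    o = np.atleast_2d(np.asarray(ray.origin, dtype=np.float64))
    d = np.atleast_2d(np.asarray(ray.direction, dtype=np.float64))
    n = o.shape[0]
    t_near = np.broadcast_to(np.asarray(t_near, dtype=np.float64), (n,))
    t_far = np.broadcast_to(np.asarray(t_far, dtype=np.float64), (n,))
    if sigma_max is None:
        sigma_max = medium.sigma_max

    scattered = np.zeros(n, dtype=bool)
    t = t_near.copy()
    t_scat = np.full(n, np.nan)
    pos = np.zeros((n, 3))
    inten = np.zeros(n)
    if sigma_max <= 0.0:
        return TrackingResult(scattered, t_scat, pos, inten)

    active = t_near < t_far
    idx = np.flatnonzero(active)
    while idx.size:
        u = rng.random(idx.size)
        t[idx] = t[idx] - np.log1p(-u) / sigma_max
        alive = t[idx] <= t_far[idx]
        idx = idx[alive]
        if not idx.size:
            break
        p = o[idx] + t[idx, None] * d[idx]
        f = vol.sample_intensity(medium.volume, p)
        accept = rng.random(idx.size) < medium.sigma_t(f) / sigma_max
        acc = idx[accept]
        scattered[acc] = True
        t_scat[acc] = t[acc]
        pos[acc] = p[accept]
        inten[acc] = f[accept]
        idx = idx[~accept]
    return TrackingResult(scattered, t_scat, pos, inten)


def shadow_visible(point, direction, distance, medium: Medium, rng, sigma_max=None) -> np.ndarray:
    """Binary visibility from ``point`` toward a light along ``direction``.

    One Woodcock query on the shadow ray clipped to the light distance (and
    the volume's box): visible iff the sampled collision lies beyond the
    light. The indicator's expectation equals the transmittance, so the
    estimator is unbiased.
    """
    p = np.atleast_2d(np.asarray(point, dtype=np.float64))
    d = np.atleast_2d(np.asarray(direction, dtype=np.float64))
    n = p.shape[0]
    dist = np.broadcast_to(np.asarray(distance, dtype=np.float64), (n,))
    ray = Ray(p, d, np.zeros(n), dist)
    hit, t0, t1 = vol.intersect_box(medium.volume, ray)
    t1 = np.minimum(t1, dist)
    res = woodcock_track(ray, np.where(hit, t0, 0.0), np.where(hit, t1, -1.0), medium, rng, sigma_max)
    return ~res.scattered


def power_heuristic(pdf_a, pdf_b) -> np.ndarray:
    """Veach power heuristic with beta = 2; 0 when both densities vanish."""
    pa = np.asarray(pdf_a, dtype=np.float64) ** 2
    pb = np.asarray(pdf_b, dtype=np.float64) ** 2
    s = pa + pb
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(s > 0.0, pa / np.where(s > 0, s, 1.0), 0.0)
    return w


def make_scatter_event(
    medium: Medium,
    params: sc.HybridParams,
    position: np.ndarray,
    intensity: np.ndarray,
    wo_world: np.ndarray,
    rng,
) -> sc.ScatterEvent:
    """Assemble the full scattering record at accepted collision points.

    Looks up the material, evaluates the gradient, applies the hybrid rule
    and builds the shading frame (normal = gradient direction, flipped to
    face the outgoing direction). Zero-gradient events are always phase.
    """
    position = np.atleast_2d(position)
    intensity = np.atleast_1d(intensity)
    mat = transfer.optical_properties(medium.tf, intensity, medium.density_scale)
    grad = vol.sample_gradient(medium.volume, position)
    opacity = transfer.eval_channel(medium.tf, "opacity", intensity)
    p_brdf = sc.brdf_probability(opacity, grad.normalized_magnitude, params)
    p_brdf = np.where(grad.magnitude > 0.0, p_brdf, 0.0)
    mode = sc.choose_mode(p_brdf, rng)
    nrm, tan, bit = sc.make_shading_frame(grad.vector, wo_world)
    return sc.ScatterEvent(
        position=position,
        intensity=intensity,
        opacity=opacity,
        gradient=grad,
        mode=np.atleast_1d(mode),
        normal=nrm,
        tangent=tan,
        bitangent=bit,
        material=mat,
        wo_world=np.atleast_2d(wo_world),
    )


def scatter_eval(event: sc.ScatterEvent, wi_world: np.ndarray):
    """Evaluate the event's scattering model toward ``wi_world``.

    Returns ``(f, pdf, cos_factor)``: RGB value, the density under which
    :func:`scatter_sample` draws directions, and the geometric cosine
    (1 for phase events, ``max(n . wi, 0)`` for BRDF events).
    """
    n = event.position.shape[0]
    wi_world = np.atleast_2d(wi_world)
    f = np.zeros((n, 3))
    pdf = np.zeros(n)
    cosf = np.ones(n)
    is_b = event.mode == sc.MODE_BRDF
    if np.any(~is_b):
        f[~is_b] = sc.INV_4PI
        pdf[~is_b] = sc.INV_4PI
    if np.any(is_b):
        ev_wo = event.to_local(event.wo_world)[is_b]
        ev_wi = event.to_local(wi_world)[is_b]
        mat = event.material.take(is_b)
        f[is_b] = sc.brdf_eval(ev_wi, ev_wo, mat)
        pdf[is_b] = sc.brdf_pdf(ev_wi, ev_wo, mat)
        cosf[is_b] = np.clip(ev_wi[..., 2], 0.0, None)
    return f, pdf, cosf


def scatter_sample(event: sc.ScatterEvent, rng):
    """Importance-sample a direction from the event's scattering model."""
    n = event.position.shape[0]
    wi = np.zeros((n, 3))
    pdf = np.zeros(n)
    is_b = event.mode == sc.MODE_BRDF
    if np.any(~is_b):
        wi[~is_b] = sc.phase_sample(rng, int((~is_b).sum()))
        pdf[~is_b] = sc.INV_4PI
    if np.any(is_b):
        wo_l = event.to_local(event.wo_world)[is_b]
        wi_l, p = sc.brdf_sample(wo_l, event.material.take(is_b), rng)
        sub = sc.ScatterEvent(
            event.position[is_b], event.intensity[is_b], event.opacity[is_b],
            event.gradient, event.mode[is_b], event.normal[is_b],
            event.tangent[is_b], event.bitangent[is_b],
            event.material.take(is_b), event.wo_world[is_b],
        )
        wi[is_b] = sub.to_world(wi_l)
        pdf[is_b] = p
    return wi, pdf


def estimate_direct(event: sc.ScatterEvent, scene, rng, strategy: str = "mis") -> np.ndarray:
    """Single-scatter direct lighting at the event batch (RGB per event).

    Per event one light is chosen uniformly; two estimators for that light
    are combined with the power heuristic:

    * **light sampling** — a stochastic point on the light, one binary
      shadow query, the scattering model evaluated toward it;
    * **scattering sampling** — a direction from the scattering model,
      intersected with the chosen light, shadow-tested to the hit.

    ``strategy`` restricts the estimator to ``"light"`` or ``"scatter"``
    alone (weight 1) for variance studies; ``"mis"`` is the renderer's path.
    Zero-pdf branches contribute zero, never NaN.
    """
    lights = scene.all_lights
    n = event.position.shape[0]
    out = np.zeros((n, 3))
    if not lights:
        return out
    k = len(lights)
    p_sel = 1.0 / k
    choice = rng.integers(k, size=n)
    medium = scene.medium

    for li, light in enumerate(lights):
        m = choice == li
        if not np.any(m):
            continue
        sub = _take_event(event, m)
        pts = sub.position

        if strategy in ("mis", "light"):
            ls = sample_light(light, pts, rng)
            f, pdf_s, cosf = scatter_eval(sub, ls.direction)
            pdf_a = p_sel * ls.pdf_solid_angle
            usable = (pdf_a > 0.0) & np.any(ls.exitant_radiance > 0.0, axis=-1) & (
                np.any(f > 0.0, axis=-1)
            )
            contrib = np.zeros((pts.shape[0], 3))
            if np.any(usable):
                vis = shadow_visible(
                    pts[usable], ls.direction[usable], ls.distance[usable], medium, rng
                )
                w = (
                    power_heuristic(pdf_a[usable], pdf_s[usable])
                    if strategy == "mis"
                    else 1.0
                )
                contrib[usable] = (
                    f[usable]
                    * ls.exitant_radiance[usable]
                    * (cosf[usable] * vis * w / pdf_a[usable])[:, None]
                )
            out[m] += contrib

        if strategy in ("mis", "scatter"):
            wi, pdf_s = scatter_sample(sub, rng)
            f, _, cosf = scatter_eval(sub, wi)
            ray = Ray(pts, wi, np.zeros(pts.shape[0]), np.full(pts.shape[0], np.inf))
            hit, dist, rad, pdf_l = intersect_light(light, ray)
            usable = hit & (pdf_s > 0.0) & np.any(rad > 0.0, axis=-1) & np.any(
                f > 0.0, axis=-1
            )
            contrib = np.zeros((pts.shape[0], 3))
            if np.any(usable):
                vis = shadow_visible(pts[usable], wi[usable], dist[usable], medium, rng)
                w = (
                    power_heuristic(pdf_s[usable], p_sel * pdf_l[usable])
                    if strategy == "mis"
                    else 1.0
                )
                contrib[usable] = (
                    f[usable]
                    * rad[usable]
                    * (cosf[usable] * vis * w / (p_sel * pdf_s[usable]))[:, None]
                )
            out[m] += contrib
    return out


def _take_event(event: sc.ScatterEvent, m) -> sc.ScatterEvent:
    g = event.gradient
    return sc.ScatterEvent(
        position=event.position[m],
        intensity=event.intensity[m],
        opacity=event.opacity[m],
        gradient=vol.GradientSample(g.vector[m], g.magnitude[m], g.normalized_magnitude[m]),
        mode=event.mode[m],
        normal=event.normal[m],
        tangent=event.tangent[m],
        bitangent=event.bitangent[m],
        material=event.material.take(m),
        wo_world=event.wo_world[m],
    )


def render_pixels(pixels: np.ndarray, scene, rng, frame_index: int = 0) -> np.ndarray:
    """One frame-estimate radiance sample for each pixel in ``pixels``."""
    medium = scene.medium
    ray = generate_rays(scene.camera, pixels, rng, frame_index=frame_index)
    n = ray.origin.shape[0]
    L = np.zeros((n, 3))
    hit, t0, t1 = vol.intersect_box(medium.volume, ray)

    background = getattr(scene, "background", None)

    res = woodcock_track(
        ray, np.where(hit, t0, 0.0), np.where(hit, t1, -1.0), medium, rng
    )
    escaped = ~res.scattered
    if background is not None and np.any(escaped):
        L[escaped] = background.radiance_along(ray.direction[escaped])

    if np.any(res.scattered):
        s = res.scattered
        event = make_scatter_event(
            medium,
            scene.hybrid,
            res.position[s],
            res.intensity[s],
            -ray.direction[s],
            rng,
        )
        contrib = np.atleast_2d(event.material.emission).copy()
        contrib += estimate_direct(event, scene, rng)
        L[s] = contrib
    return L


def render_frame(scene, frame_index: int, rng) -> np.ndarray:
    """Render one full frame estimate; returns an (H, W, 3) radiance image."""
    w, h = scene.camera.film_resolution
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    pixels = np.stack([xs.ravel(), ys.ravel()], axis=-1)
    L = render_pixels(pixels, scene, rng, frame_index=frame_index)
    return L.reshape(h, w, 3)


def render_sample(pixel, scene, rng, frame_index: int = 0) -> np.ndarray:
    """One radiance sample for a single pixel (RGB)."""
    return render_pixels(np.asarray(pixel)[None, :], scene, rng, frame_index)[0]
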