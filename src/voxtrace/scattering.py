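"""Hybrid surface/volumetric scattering: isotropic phase and Fresnel-blend BRDF.

Volumetric media have no explicit boundary surface, so the renderer switches
stochastically per scattering event between

* a **BRDF** (surface-like scattering about the local gradient direction),
  used where the gradient is well defined, and
* an **isotropic phase function** (value = pdf = ``1/(4*pi)``) elsewhere.

The switch probability grows with the normalized gradient magnitude ``Gn``
and a user *gradient factor* ``g_f`` in [0, 1]:

    P_brdf = 1 - exp(-s * g_f * Gn)

with sharpness ``s`` (default 8). It is zero when either control is zero and
strictly increasing in both, so flat regions always scatter volumetrically.

The surface model is the Ashikhmin–Shirley Fresnel blend: a Lambert-based
diffuse term coupled to a glossy microfacet Blinn lobe via Schlick's Fresnel
approximation, reciprocal and energy conserving for physically plausible
materials. ``F0`` derives from the transfer function's index of reflection
as ``((ior - 1) / (ior + 1))**2``; the specular colour scales the glossy
lobe. All directions here live in the local shading frame with the normal
along +z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mathutils import (
    cosine_hemisphere,
    normalize,
    orthonormal_basis,
    uniform_sphere,
)
from .transfer import OpticalProperties
from .volume import GradientSample

__all__ = [
    "MODE_PHASE",
    "MODE_BRDF",
    "HybridParams",
    "ScatterEvent",
    "brdf_probability",
    "choose_mode",
    "phase_value",
    "phase_sample",
    "phase_eval_sample",
    "brdf_eval",
    "brdf_pdf",
    "brdf_sample",
    "make_shading_frame",
]

MODE_PHASE = 0
MODE_BRDF = 1

INV_4PI = 1.0 / (4.0 * np.pi)


@dataclass
class HybridParams:
    """Controls of the stochastic surface/volume switch."""

    gradient_factor: float = 0.5  # in [0, 1]
    sharpness: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gradient_factor <= 1.0:
            raise ValueError("gradient_factor must lie in [0, 1]")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")


@dataclass
class ScatterEvent:
    """Accepted scattering point(s) with everything shading needs (batched)."""

    position: np.ndarray  # (n, 3) mm
    intensity: np.ndarray  # (n,) normalized
    opacity: np.ndarray  # (n,)
    gradient: GradientSample
    mode: np.ndarray  # (n,) MODE_PHASE / MODE_BRDF
    normal: np.ndarray  # (n, 3) shading normal (brdf entries)
    tangent: np.ndarray  # (n, 3)
    bitangent: np.ndarray  # (n, 3)
    material: OpticalProperties
    wo_world: np.ndarray  # (n, 3) outgoing direction (toward the camera)

    def to_local(self, w_world: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                np.einsum("ij,ij->i", w_world, self.tangent),
                np.einsum("ij,ij->i", w_world, self.bitangent),
                np.einsum("ij,ij->i", w_world, self.normal),
            ],
            axis=-1,
        )

    def to_world(self, w_local: np.ndarray) -> np.ndarray:
        return (
            w_local[..., 0:1] * self.tangent
            + w_local[..., 1:2] * self.bitangent
            + w_local[..., 2:3] * self.normal
        )


def make_shading_frame(gradient_vector: np.ndarray, wo_world: np.ndarray):
    """Shading basis with normal along the gradient, flipped to face ``wo``.

    Degenerate (zero) gradients fall back to +z; those events are phase-mode
    anyway, where the frame is unused.
    """
    g = np.atleast_2d(np.asarray(gradient_vector, dtype=np.float64))
    wo = np.atleast_2d(np.asarray(wo_world, dtype=np.float64))
    n = normalize(g)
    degenerate = np.linalg.norm(g, axis=-1) < 1e-30
    n = np.where(degenerate[:, None], np.array([0.0, 0.0, 1.0]), n)
    flip = np.einsum("ij,ij->i", n, wo) < 0.0
    n = np.where(flip[:, None], -n, n)
    t, b = orthonormal_basis(n)
    return n, t, b


def brdf_probability(opacity, Gn, params: HybridParams) -> np.ndarray:
    """Probability of surface (BRDF) scattering at an accepted event.

    ``P = 1 - exp(-s * g_f * Gn)``: zero when the gradient factor or the
    normalized gradient magnitude is zero, strictly increasing in both.
    Opacity enters implicitly — events are only generated where the medium
    is dense enough for Woodcock tracking to accept a collision.
    """
    del opacity  # part of the operation contract; see docstring
    Gn = np.asarray(Gn, dtype=np.float64)
    return 1.0 - np.exp(-params.sharpness * params.gradient_factor * Gn)


def choose_mode(p_brdf, rng) -> np.ndarray:
    """Bernoulli draw per event: MODE_BRDF with probability ``p_brdf``.

    The renderer treats the choice as sampling a stochastic mixture
    scattering model, so the chosen mode's full estimate is used as-is; its
    expectation is the P-weighted mixture of the two models.
    """
    p = np.asarray(p_brdf, dtype=np.float64)
    u = rng.random(p.shape) if p.shape else rng.random()
    return np.where(u < p, MODE_BRDF, MODE_PHASE)


# --- isotropic phase function -------------------------------------------------


def phase_value(n: int | None = None) -> np.ndarray:
    """Isotropic phase function value (= pdf) per steradian."""
    return np.full(n, INV_4PI) if n is not None else np.float64(INV_4PI)


def phase_sample(rng, n: int) -> np.ndarray:
    u = rng.random((n, 2))
    return uniform_sphere(u[:, 0], u[:, 1])


def phase_eval_sample(direction_out: np.ndarray, rng):
    """Sample an incoming direction for the isotropic phase function.

    Returns ``(direction_in, value, pdf)`` with value = pdf = 1/(4*pi)
    independent of ``direction_out``.
    """
    d = np.atleast_2d(np.asarray(direction_out, dtype=np.float64))
    wi = phase_sample(rng, d.shape[0])
    val = phase_value(d.shape[0])
    if np.asarray(direction_out).ndim == 1:
        return wi[0], float(val[0]), float(val[0])
    return wi, val, val.copy()


# --- Fresnel-blend BRDF -------------------------------------------------------


def _f0_from_ior(ior: np.ndarray) -> np.ndarray:
    ior = np.asarray(ior, dtype=np.float64)
    return ((ior - 1.0) / (ior + 1.0)) ** 2


def _schlick(f0: np.ndarray, cos_x: np.ndarray) -> np.ndarray:
    return f0 + (1.0 - f0) * (1.0 - cos_x) ** 5


def brdf_eval(wi: np.ndarray, wo: np.ndarray, material: OpticalProperties) -> np.ndarray:
    """Fresnel-blend BRDF value (per steradian, RGB) in the shading frame.

    Zero whenever either direction lies below the surface. Diffuse part:
    ``28 rho / (23 pi) * (1 - F0) * (1 - (1 - cos_i/2)^5)(1 - (1 - cos_o/2)^5)``;
    glossy part: normalized Blinn lobe ``(e+1)/(8 pi) * (n.h)^e /
    (h.wi * max(cos_i, cos_o))`` times Schlick Fresnel and the specular colour.
    """
    wi = np.atleast_2d(np.asarray(wi, dtype=np.float64))
    wo = np.atleast_2d(np.asarray(wo, dtype=np.float64))
    cos_i = wi[..., 2]
    cos_o = wo[..., 2]
    up = (cos_i > 0.0) & (cos_o > 0.0)

    f0 = np.atleast_1d(_f0_from_ior(material.ior))[..., None]
    rho_d = np.atleast_2d(np.asarray(material.diffuse, dtype=np.float64))
    rho_s = np.atleast_2d(np.asarray(material.specular, dtype=np.float64))
    e = np.atleast_1d(np.asarray(material.blinn_exponent, dtype=np.float64))

    diff = (
        (28.0 / (23.0 * np.pi))
        * rho_d
        * (1.0 - f0)
        * (1.0 - (1.0 - np.clip(cos_i, 0, 1)[..., None] / 2.0) ** 5)
        * (1.0 - (1.0 - np.clip(cos_o, 0, 1)[..., None] / 2.0) ** 5)
    )

    h = wi + wo
    hn = np.linalg.norm(h, axis=-1)
    ok = up & (hn > 1e-12)
    h = np.where(ok[..., None], h / np.where(hn > 1e-12, hn, 1.0)[..., None], 0.0)
    nh = np.clip(h[..., 2], 0.0, 1.0)
    hwi = np.abs(np.einsum("...j,...j->...", h, wi))
    denom = hwi * np.maximum(cos_i, cos_o)
    with np.errstate(divide="ignore", invalid="ignore"):
        blinn = (e + 1.0) / (8.0 * np.pi) * nh**e / np.where(denom > 0, denom, 1.0)
    spec = rho_s * blinn[..., None] * _schlick(f0, hwi[..., None])
    spec = np.where(ok[..., None] & (denom > 0)[..., None], spec, 0.0)

    out = np.where(up[..., None], diff + spec, 0.0)
    return out


def brdf_pdf(wi: np.ndarray, wo: np.ndarray, material: OpticalProperties) -> np.ndarray:
    """Sampling density of :func:`brdf_sample` at ``wi`` (per steradian).

    Equal-weight mixture of the cosine-hemisphere pdf and the Blinn
    half-vector pdf pushed forward through the mirror reflection:
    ``pdf_blinn(wi) = (e+1)/(2 pi) * (n.h)^e / (4 |wo.h|)``.
    """
    wi = np.atleast_2d(np.asarray(wi, dtype=np.float64))
    wo = np.atleast_2d(np.asarray(wo, dtype=np.float64))
    e = np.atleast_1d(np.asarray(material.blinn_exponent, dtype=np.float64))
    cos_i = wi[..., 2]
    pdf_cos = np.where(cos_i > 0.0, cos_i / np.pi, 0.0)

    h = wi + wo
    hn = np.linalg.norm(h, axis=-1)
    ok = hn > 1e-12
    h = h / np.where(ok, hn, 1.0)[..., None]
    # normalize(wi + wo) equals the sampled half-vector up to sign; recover
    # the sampled one (upper hemisphere) so the density is exact
    nh = np.clip(np.abs(h[..., 2]), 0.0, 1.0)
    woh = np.abs(np.einsum("...j,...j->...", h, wo))
    with np.errstate(divide="ignore", invalid="ignore"):
        pdf_blinn = (e + 1.0) / (2.0 * np.pi) * nh**e / (4.0 * np.where(woh > 0, woh, 1.0))
    pdf_blinn = np.where(ok & (woh > 1e-12) & (nh > 0.0), pdf_blinn, 0.0)
    return 0.5 * pdf_cos + 0.5 * pdf_blinn


def brdf_sample(wo: np.ndarray, material: OpticalProperties, rng):
    """Importance-sample an incoming direction for the Fresnel blend.

    Mixture sampling: with probability 1/2 a cosine-weighted hemisphere
    direction (diffuse lobe), otherwise a Blinn half-vector
    (``cos(theta_h) = u^(1/(e+1))``) reflected about ``wo``. Returns
    ``(wi, pdf)`` with the mixture pdf; ``wi`` may land below the surface
    (glossy branch), in which case the BRDF value — not the pdf — is zero.
    """
    wo = np.atleast_2d(np.asarray(wo, dtype=np.float64))
    n = wo.shape[0]
    e = np.broadcast_to(
        np.atleast_1d(np.asarray(material.blinn_exponent, dtype=np.float64)), (n,)
    )
    pick_glossy = rng.random(n) < 0.5
    u = rng.random((n, 2))

    wi_cos = cosine_hemisphere(u[:, 0], u[:, 1])

    cos_th = u[:, 0] ** (1.0 / (e + 1.0))
    sin_th = np.sqrt(np.clip(1.0 - cos_th**2, 0.0, None))
    phi = 2.0 * np.pi * u[:, 1]
    h = np.stack([sin_th * np.cos(phi), sin_th * np.sin(phi), cos_th], axis=-1)
    woh = np.einsum("ij,ij->i", wo, h)
    wi_blinn = 2.0 * woh[:, None] * h - wo

    wi = np.where(pick_glossy[:, None], wi_blinn, wi_cos)
    pdf = brdf_pdf(wi, wo, material)
    return wi, pdf
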