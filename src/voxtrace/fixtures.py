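"""Deterministic procedural volumes and reference scenes for tests and demos.

Real CT volumes are large binary downloads; every test and example in this
package instead runs on procedural scalar fields quantized to the same
unsigned 16-bit storage real datasets use. Identical ``FixtureSpec`` inputs
regenerate bit-identical volumes (seeded), so the whole suite runs offline.

All fixture volumes normalize intensity over the full 16-bit range
``(0, 65535)`` rather than the stored min/max, which makes the mapping from
procedural field value to transfer-function coordinate predictable.

The named scenes cover the configurations the estimator's analytic checks
need: a homogeneous emissive cube (closed-form per-pixel radiance), a quad
light over a Lambertian-style event in vacuum (quadrature oracle for MIS), a
soft-shadow scene with a dense occluder slab, and an environment light plus
two area lights over nested shells — the benchmark-style lighting rig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import ThinLensCamera, generate_rays
from .film import prefilter_estimate
from .lights import AreaLight, BackgroundLight
from .scattering import HybridParams
from .scene import Scene
from .transfer import TransferFunction1D, eval_channel
from .volume import Volume, intersect_box, save_volume_nrrd

__all__ = [
    "FixtureSpec",
    "make_volume",
    "make_scene",
    "emissive_cube_reference",
    "SCENE_NAMES",
]

FULL_RANGE = (0.0, 65535.0)

KINDS = ("homogeneous_cube", "two_layer_slab", "nested_shells", "occluder_slab_scene", "noise")


@dataclass
class FixtureSpec:
    kind: str
    dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def make_volume(spec: FixtureSpec, path=None) -> Volume:
    """Generate the procedural volume for ``spec`` (optionally saved as NRRD)."""
    nx, ny, nz = spec.dims
    p = spec.params
    if spec.kind == "homogeneous_cube":
        data = np.full(spec.dims, int(p.get("value", 40000)), dtype=np.uint16)
    elif spec.kind == "two_layer_slab":
        axis = int(p.get("axis", 2))
        frac = float(p.get("frac", 0.5))
        lo, hi = int(p.get("value_lo", 20000)), int(p.get("value_hi", 50000))
        idx = np.arange(spec.dims[axis])
        layer = np.where(idx < frac * spec.dims[axis], lo, hi).astype(np.uint16)
        shape = [1, 1, 1]
        shape[axis] = spec.dims[axis]
        data = np.broadcast_to(layer.reshape(shape), spec.dims).astype(np.uint16)
    elif spec.kind == "nested_shells":
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        c = (np.array(spec.dims) - 1) / 2.0
        r = np.sqrt((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2)
        r1 = float(p.get("r1", 0.25 * min(spec.dims)))
        r2 = float(p.get("r2", 0.42 * min(spec.dims)))
        w = float(p.get("width", 2.5))
        v1 = float(p.get("v1", 30000))
        v2 = float(p.get("v2", 55000))
        f = v1 * np.exp(-0.5 * ((r - r1) / w) ** 2) + v2 * np.exp(
            -0.5 * ((r - r2) / w) ** 2
        )
        data = np.clip(f, 0, 65535).astype(np.uint16)
    elif spec.kind == "occluder_slab_scene":
        # emissive/scattering block in the lower half, dense slab above it
        data = np.zeros(spec.dims, dtype=np.uint16)
        body = int(p.get("body_value", 20000))
        slab = int(p.get("slab_value", 60000))
        z_body = int(p.get("body_top", nz // 2))
        z0, z1 = int(p.get("slab_lo", int(0.65 * nz))), int(p.get("slab_hi", int(0.75 * nz)))
        x_half = int(p.get("slab_half_width", nx // 6))
        data[:, :, :z_body] = body
        cx = nx // 2
        data[max(cx - x_half, 0) : min(cx + x_half, nx), :, z0:z1] = slab
    elif spec.kind == "noise":
        rng = np.random.default_rng(spec.seed)
        data = rng.integers(0, 65536, size=spec.dims, dtype=np.uint16)
    else:  # pragma: no cover - guarded in FixtureSpec
        raise ValueError(spec.kind)
    v = Volume(data, spec.spacing, (0.0, 0.0, 0.0), FULL_RANGE)
    if path is not None:
        save_volume_nrrd(v, path)
    return v


def _constant_tf(opacity, emission=(0, 0, 0), diffuse=(0.8, 0.8, 0.8)) -> TransferFunction1D:
    return TransferFunction1D(
        {
            "opacity": ([0.0, 1.0], [opacity, opacity]),
            "emission": ([0.0, 1.0], [emission, emission]),
            "diffuse": ([0.0, 1.0], [diffuse, diffuse]),
        }
    )


SCENE_NAMES = ("emissive_cube", "quad_lambert_mis", "quad_shadow", "env_plus_two_area")


def make_scene(name: str, film: tuple[int, int] = (64, 64)) -> Scene:
    """Build one of the named reference scenes (deterministic)."""
    if name == "emissive_cube":
        # Homogeneous emissive medium filling the box [0, 31]^3 mm.
        # sigma_t = 0.08/mm so optical depth across the cube is ~2.5; the
        # narrow fov keeps every camera ray crossing the full depth, which
        # makes the per-pixel radiance closed-form: (1 - exp(-sigma_t d)) E.
        volume = make_volume(FixtureSpec("homogeneous_cube", dims=(32, 32, 32)))
        tf = _constant_tf(opacity=1.0, emission=(1.0, 1.0, 1.0))
        cam = ThinLensCamera(
            eye=(15.5, 15.5, -40.0),
            target=(15.5, 15.5, 15.5),
            up=(0.0, 1.0, 0.0),
            vertical_fov=16.0,
            film_resolution=film,
        )
        return Scene(volume, tf, cam, density_scale=0.08,
                     hybrid=HybridParams(gradient_factor=0.0))

    if name == "quad_lambert_mis":
        # Vacuum medium, a single quad light of moderate solid angle: the
        # regime where neither light- nor scattering-sampling dominates.
        volume = make_volume(
            FixtureSpec("homogeneous_cube", dims=(8, 8, 8), spacing=(4, 4, 4), params={"value": 0})
        )
        tf = _constant_tf(opacity=0.0, diffuse=(0.7, 0.7, 0.7))
        cam = ThinLensCamera(
            eye=(14.0, 14.0, -20.0),
            target=(14.0, 14.0, 14.0),
            up=(0.0, 1.0, 0.0),
            vertical_fov=30.0,
            film_resolution=film,
        )
        light = AreaLight(
            center=(14.0, 14.0, 2.0),
            normal=(0.0, 0.0, 1.0),
            half_extents=(24.0, 24.0),
            radiance=(3.0, 3.0, 3.0),
            up_hint=(0.0, 1.0, 0.0),
        )
        return Scene(volume, tf, cam, lights=[light], density_scale=1.0,
                     hybrid=HybridParams(gradient_factor=0.0))

    if name == "quad_shadow":
        volume = make_volume(FixtureSpec("occluder_slab_scene", dims=(64, 64, 64)))
        tf = TransferFunction1D(
            {
                "opacity": ([0.0, 0.2, 0.31, 0.6, 0.92, 1.0], [0.0, 0.0, 0.35, 0.35, 1.0, 1.0]),
                "diffuse": (
                    [0.0, 1.0],
                    [(0.75, 0.72, 0.68), (0.75, 0.72, 0.68)],
                ),
            }
        )
        cam = ThinLensCamera(
            eye=(31.5, -90.0, 40.0),
            target=(31.5, 31.5, 25.0),
            up=(0.0, 0.0, 1.0),
            vertical_fov=40.0,
            film_resolution=film,
        )
        light = AreaLight(
            center=(31.5, 31.5, 120.0),
            normal=(0.0, 0.0, -1.0),
            half_extents=(10.0, 10.0),
            radiance=(200.0, 200.0, 200.0),
            up_hint=(0.0, 1.0, 0.0),
        )
        return Scene(volume, tf, cam, lights=[light], density_scale=0.35,
                     hybrid=HybridParams(gradient_factor=0.5))

    if name == "env_plus_two_area":
        # Benchmark-style lighting rig: an environment light and two
        # additional area lights around a nested-shell phantom.
        volume = make_volume(FixtureSpec("nested_shells", dims=(64, 64, 64)))
        tf = TransferFunction1D(
            {
                "opacity": ([0.0, 0.25, 0.45, 0.7, 0.9, 1.0], [0.0, 0.0, 0.4, 0.1, 0.9, 0.9]),
                "diffuse": ([0.0, 1.0], [(0.8, 0.6, 0.5), (0.8, 0.6, 0.5)]),
                "specular": ([0.0, 1.0], [(0.2, 0.2, 0.2), (0.2, 0.2, 0.2)]),
                "roughness": ([0.0, 1.0], [0.3, 0.3]),
                "ior": ([0.0, 1.0], [1.4, 1.4]),
            }
        )
        cam = ThinLensCamera(
            eye=(31.5, -80.0, 50.0),
            target=(31.5, 31.5, 31.5),
            up=(0.0, 0.0, 1.0),
            vertical_fov=35.0,
            film_resolution=film,
            aperture_radius=0.0,
        )
        lights = [
            AreaLight((90.0, -40.0, 80.0), (-0.6, 0.55, -0.55), (12.0, 12.0), (25.0, 24.0, 22.0)),
            AreaLight((-30.0, -40.0, 60.0), (0.6, 0.55, -0.45), (8.0, 8.0), (10.0, 11.0, 13.0)),
        ]
        bg = BackgroundLight((0.15, 0.17, 0.2))
        return Scene(volume, tf, cam, lights=lights, background=bg,
                     density_scale=0.4, hybrid=HybridParams(gradient_factor=0.8))

    raise ValueError(f"unknown scene {name!r}; known: {SCENE_NAMES}")


def emissive_cube_reference(scene: Scene, prefiltered: bool = True) -> np.ndarray:
    """Closed-form converged image of a homogeneous emissive scene.

    Per pixel-center ray: ``(1 - exp(-sigma_t * chord)) * E`` with the chord
    from box clipping. With ``prefiltered`` the Gaussian pre-filter is
    applied, matching the expectation of the accumulated pipeline output
    (the pre-filter is linear, so filtering commutes with taking the mean).
    """
    cam = scene.camera
    w, h = cam.film_resolution
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    pixels = np.stack([xs.ravel(), ys.ravel()], axis=-1)
    rng = np.random.default_rng(0)  # unused: jitter is overridden
    ray = generate_rays(cam, pixels, rng, film_uv=np.full((pixels.shape[0], 2), 0.5))
    hit, t0, t1 = intersect_box(scene.volume, ray)
    chord = np.where(hit, t1 - t0, 0.0)
    u = 40000.0 / 65535.0  # homogeneous cube stored value, normalized
    sigma_t = scene.density_scale * float(eval_channel(scene.tf, "opacity", u))
    emission = np.asarray(eval_channel(scene.tf, "emission", u), dtype=np.float64)
    img = (1.0 - np.exp(-sigma_t * chord))[:, None] * emission
    img = img.reshape(h, w, 3)
    return prefilter_estimate(img) if prefiltered else img
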