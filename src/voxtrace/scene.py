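"""Scene description: volume + transfer function + camera + lights.

A scene bundles everything one progressive render needs. Scenes can be
built programmatically (see :mod:`voxtrace.fixtures`) or loaded from a JSON
config whose blocks mirror the dataclass fields:

.. code-block:: json

    {
      "volume": "volume.nrrd",
      "transfer_function": "tf.json",
      "density_scale": 100.0,
      "gradient_factor": 0.5,
      "camera": {"eye": [0,0,-5], "target": [0,0,0], "up": [0,1,0],
                 "vertical_fov": 30, "film_resolution": [256, 256],
                 "aperture_radius": 0.0, "focal_distance": 5.0},
      "lights": [{"type": "area", "center": [0,3,0], "normal": [0,-1,0],
                  "half_extents": [1,1], "radiance": [5,5,5]}],
      "background": {"radiance": [0.1, 0.1, 0.1]}
    }

Area-light ``radiance`` may instead name a PNG texture path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import ThinLensCamera
from .lights import AreaLight, BackgroundLight
from .scattering import HybridParams
from .transfer import TransferFunction1D, load_tf_preset
from .transport import Medium
from .volume import Volume, load_volume

__all__ = ["Scene", "load_scene"]


@dataclass
class Scene:
    volume: Volume
    tf: TransferFunction1D
    camera: ThinLensCamera
    lights: list = field(default_factory=list)
    background: BackgroundLight | None = None
    density_scale: float = 100.0  # 1/mm for a unit-scale scene
    hybrid: HybridParams = field(default_factory=HybridParams)

    @property
    def medium(self) -> Medium:
        return Medium(self.volume, self.tf, self.density_scale)

    @property
    def all_lights(self) -> list:
        return list(self.lights) + ([self.background] if self.background else [])


def _load_texture(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(str(path)), dtype=np.float64)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    return img[..., :3] / 255.0


def load_scene(path) -> Scene:
    """Read a scene config (JSON); relative paths resolve next to the file."""
    path = Path(path)
    with open(path) as f:
        cfg = json.load(f)
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    vol = load_volume(resolve(cfg["volume"]))
    tf = load_tf_preset(resolve(cfg["transfer_function"]))
    cam_cfg = dict(cfg["camera"])
    cam_cfg["film_resolution"] = tuple(cam_cfg["film_resolution"])
    cam = ThinLensCamera(**cam_cfg)

    lights = []
    for lc in cfg.get("lights", []):
        lc = dict(lc)
        if lc.pop("type", "area") != "area":
            raise ValueError("light blocks must have type 'area'")
        rad = lc["radiance"]
        if isinstance(rad, str):
            lc["radiance"] = _load_texture(resolve(rad))
        lc["half_extents"] = tuple(lc["half_extents"])
        lights.append(AreaLight(**lc))

    background = None
    if "background" in cfg:
        rad = cfg["background"]["radiance"]
        background = BackgroundLight(
            _load_texture(resolve(rad)) if isinstance(rad, str) else rad
        )

    return Scene(
        volume=vol,
        tf=tf,
        camera=cam,
        lights=lights,
        background=background,
        density_scale=float(cfg.get("density_scale", 100.0)),
        hybrid=HybridParams(
            gradient_factor=float(cfg.get("gradient_factor", 0.5)),
            sharpness=float(cfg.get("hybrid_sharpness", 8.0)),
        ),
    )
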