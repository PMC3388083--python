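"""1-D multi-channel transfer functions mapping intensity to optical properties.

The transfer function turns normalized intensity ``u in [0, 1]`` into the
quantities the renderer needs per sample: opacity (which, scaled by a global
``density_scale`` in 1/mm, becomes the extinction coefficient sigma_t used by
Woodcock tracking), emission radiance, diffuse and specular colour, specular
roughness and index of reflection. Each channel is a piecewise-linear curve
over sorted node positions; the first node sits at 0 and the last at 1.

The roughness channel maps to a Blinn exponent through the standard bridge
``exponent = 2 / r**2 - 2``, clamped to ``[1, 1e4]``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TransferFunction1D",
    "OpticalProperties",
    "eval_channel",
    "optical_properties",
    "sigma_max",
    "roughness_to_blinn_exponent",
    "load_tf_preset",
    "save_tf_preset",
]

logger = logging.getLogger(__name__)

CHANNELS = ("opacity", "emission", "diffuse", "specular", "roughness", "ior")
_VECTOR_CHANNELS = {"emission", "diffuse", "specular"}
_CHANNEL_DEFAULTS = {
    "opacity": 0.0,
    "emission": (0.0, 0.0, 0.0),
    "diffuse": (0.8, 0.8, 0.8),
    "specular": (0.0, 0.0, 0.0),
    "roughness": 1.0,
    "ior": 1.0,
}


@dataclass
class TransferFunction1D:
    """Piecewise-linear transfer function.

    ``channels`` maps channel name to ``(positions, values)`` where positions
    is a strictly increasing 1-D array starting at 0 and ending at 1, and
    values has shape ``(m,)`` for scalar channels or ``(m, 3)`` for colour
    channels (emission, diffuse, specular).
    """

    channels: dict

    def __post_init__(self) -> None:
        out = {}
        for name in CHANNELS:
            if name in self.channels:
                pos, val = self.channels[name]
                pos = np.asarray(pos, dtype=np.float64)
                val = np.asarray(val, dtype=np.float64)
            else:
                pos = np.array([0.0, 1.0])
                d = _CHANNEL_DEFAULTS[name]
                val = np.array([d, d], dtype=np.float64)
            if pos.ndim != 1 or pos.size < 2:
                raise ValueError(f"channel {name!r}: need at least two nodes")
            if pos[0] != 0.0 or pos[-1] != 1.0:
                raise ValueError(f"channel {name!r}: first node at 0, last at 1")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"channel {name!r}: positions strictly increasing")
            if name in _VECTOR_CHANNELS:
                val = np.broadcast_to(
                    val[:, None] if val.ndim == 1 else val, (pos.size, 3)
                ).astype(np.float64)
            if name == "opacity" and (np.any(val < 0) or np.any(val > 1)):
                raise ValueError("opacity node values must lie in [0, 1]")
            if name in ("diffuse", "specular") and (np.any(val < 0) or np.any(val > 1)):
                raise ValueError(f"{name} node values must lie in [0, 1]")
            if name == "ior" and np.any(val < 1):
                raise ValueError("index of reflection must be >= 1")
            out[name] = (pos, val)
        self.channels = out

    @property
    def max_opacity(self) -> float:
        return float(self.channels["opacity"][1].max())


_clamp_warned = False


def eval_channel(tf: TransferFunction1D, channel: str, u) -> np.ndarray:
    """Evaluate one channel at normalized intensity ``u`` (vectorized).

    Piecewise-linear between bracketing nodes, exact at node positions.
    Out-of-range ``u`` clamps to [0, 1] (warned once per process).
    """
    global _clamp_warned
    u = np.asarray(u, dtype=np.float64)
    if np.any(u < 0) or np.any(u > 1):
        if not _clamp_warned:
            logger.warning("transfer-function lookup outside [0,1]; clamping")
            _clamp_warned = True
        u = np.clip(u, 0.0, 1.0)
    pos, val = tf.channels[channel]
    if val.ndim == 1:
        return np.interp(u, pos, val)
    return np.stack([np.interp(u, pos, val[:, c]) for c in range(3)], axis=-1)


def roughness_to_blinn_exponent(r) -> np.ndarray:
    r = np.asarray(r, dtype=np.float64)
    with np.errstate(divide="ignore"):
        e = 2.0 / (r * r) - 2.0
    return np.clip(e, 1.0, 1.0e4)


@dataclass
class OpticalProperties:
    """Per-sample optical and material record (batched arrays)."""

    sigma_t: np.ndarray  # 1/mm
    diffuse: np.ndarray
    specular: np.ndarray
    blinn_exponent: np.ndarray
    ior: np.ndarray
    emission: np.ndarray

    def take(self, idx) -> "OpticalProperties":
        """Subset the batch (fancy index or boolean mask along axis 0)."""
        return OpticalProperties(
            sigma_t=np.atleast_1d(self.sigma_t)[idx],
            diffuse=np.atleast_2d(self.diffuse)[idx],
            specular=np.atleast_2d(self.specular)[idx],
            blinn_exponent=np.atleast_1d(self.blinn_exponent)[idx],
            ior=np.atleast_1d(self.ior)[idx],
            emission=np.atleast_2d(self.emission)[idx],
        )


def optical_properties(tf: TransferFunction1D, u, density_scale: float) -> OpticalProperties:
    """Bundle all channel lookups at ``u``; sigma_t = density_scale * opacity."""
    if density_scale <= 0:
        raise ValueError("density_scale must be positive")
    return OpticalProperties(
        sigma_t=density_scale * eval_channel(tf, "opacity", u),
        diffuse=eval_channel(tf, "diffuse", u),
        specular=eval_channel(tf, "specular", u),
        blinn_exponent=roughness_to_blinn_exponent(eval_channel(tf, "roughness", u)),
        ior=eval_channel(tf, "ior", u),
        emission=eval_channel(tf, "emission", u),
    )


def sigma_max(tf: TransferFunction1D, density_scale: float) -> float:
    """Majorant extinction for Woodcock tracking.

    ``density_scale * max(opacity node values)``: conservative (piecewise-
    linear curves are bounded by their node extrema) and independent of the
    volume's occupancy, so it never under-estimates sigma_t anywhere.
    """
    return density_scale * tf.max_opacity


def tf_to_dict(tf: TransferFunction1D) -> dict:
    return {
        name: {"positions": pos.tolist(), "values": val.tolist()}
        for name, (pos, val) in tf.channels.items()
    }


def tf_from_dict(d: dict) -> TransferFunction1D:
    return TransferFunction1D(
        {name: (spec["positions"], spec["values"]) for name, spec in d.items()}
    )


def load_tf_preset(path) -> TransferFunction1D:
    """Read a JSON transfer-function preset (see docs for the schema)."""
    with open(Path(path)) as f:
        return tf_from_dict(json.load(f))


def save_tf_preset(tf: TransferFunction1D, path) -> None:
    with open(Path(path), "w") as f:
        json.dump(tf_to_dict(tf), f, indent=2)
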