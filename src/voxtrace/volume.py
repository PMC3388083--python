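"""Scalar volumes: loading, trilinear sampling, gradients and ray clipping.

A :class:`Volume` is a node-centered scalar grid: voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * spacing`` (all world units mm) and the bounding box
spans the outermost nodes, so its extent per axis is ``(dims - 1) * spacing``.
Stored scalars are unsigned 8- or 16-bit; sampling returns intensity
normalized to ``[0, 1]`` over the volume's dynamic range (``intensity_range``,
by default the stored min/max, overridable at load time).

Out-of-box sample positions clamp to the boundary value, which keeps central
differences well defined on the faces.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Volume",
    "GradientSample",
    "VolumeFormatError",
    "UnsupportedElementTypeError",
    "load_volume",
    "save_volume_nrrd",
    "sample_intensity",
    "sample_gradient",
    "intersect_box",
]


class VolumeFormatError(ValueError):
    """Missing or contradictory volume metadata."""


class UnsupportedElementTypeError(VolumeFormatError):
    """Element type other than unsigned 8/16-bit."""


@dataclass
class GradientSample:
    """Finite-difference gradient of the normalized intensity field.

    ``vector`` has units of normalized intensity per mm; ``magnitude`` is its
    Euclidean norm, and ``normalized_magnitude`` is the magnitude divided by
    the volume's precomputed maximum gradient magnitude, clamped to [0, 1].
    """

    vector: np.ndarray
    magnitude: np.ndarray
    normalized_magnitude: np.ndarray


@dataclass
class Volume:
    """Node-centered scalar grid with world-space placement.

    ``data`` is indexed ``data[i, j, k]`` with ``i`` along world x.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    intensity_range: tuple[float, float]
    _norm: np.ndarray = field(init=False, repr=False)
    grad_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError("volume data must be a 3-D array")
        if any(d < 2 for d in self.data.shape):
            raise VolumeFormatError("all dims must be >= 2")
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if np.any(self.spacing <= 0):
            raise VolumeFormatError("spacing components must be positive")
        lo, hi = self.intensity_range
        if hi > lo:
            self._norm = (self.data.astype(np.float64) - lo) / (hi - lo)
        else:
            # degenerate constant volume: normalized field is identically 0
            self._norm = np.zeros(self.data.shape, dtype=np.float64)
        gx, gy, gz = np.gradient(self._norm, *self.spacing)
        gm = float(np.sqrt(gx * gx + gy * gy + gz * gz).max())
        self.grad_max = gm if gm > 0 else 1.0

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def bbox_min(self) -> np.ndarray:
        return self.origin

    @property
    def bbox_max(self) -> np.ndarray:
        return self.origin + (np.array(self.data.shape) - 1) * self.spacing


def load_volume(path, format_hint: str | None = None, intensity_range=None) -> Volume:
    """Read a volume from NRRD, MHD/MHA, or RAW with an INI sidecar.

    ``format_hint`` is one of ``{"raw+meta", "mhd", "nrrd"}``; by default it
    is inferred from the file extension. ``intensity_range`` overrides the
    normalization range (default: stored min/max).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint is None:
        ext = path.suffix.lower()
        format_hint = {
            ".nrrd": "nrrd",
            ".nhdr": "nrrd",
            ".mhd": "mhd",
            ".mha": "mhd",
            ".raw": "raw+meta",
            ".ini": "raw+meta",
        }.get(ext)
        if format_hint is None:
            raise VolumeFormatError(f"cannot infer volume format from {path.name!r}")
    if format_hint == "raw+meta":
        data, spacing, origin = _read_raw_with_sidecar(path)
    elif format_hint in ("nrrd", "mhd"):
        data, spacing, origin = _read_itk(path)
    else:
        raise VolumeFormatError(f"unknown format hint {format_hint!r}")
    if data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise UnsupportedElementTypeError(
            f"element type {data.dtype} not supported (need uint8/uint16)"
        )
    if intensity_range is None:
        intensity_range = (float(data.min()), float(data.max()))
    return Volume(data, spacing, origin, intensity_range)


def _read_itk(path: Path):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing = np.array(img.GetSpacing(), dtype=np.float64)
    origin = np.array(img.GetOrigin(), dtype=np.float64)
    return data, spacing, origin


def _read_raw_with_sidecar(path: Path):
    """RAW volume next to an INI sidecar (same stem, .ini extension).

    Sidecar section ``[volume]`` keys: dims (x y z), spacing, element_type
    (uint8|uint16), byte_order (little|big), origin (optional). The raw file
    is x-fastest (C order as z, y, x).
    """
    if path.suffix.lower() == ".ini":
        meta_path, raw_path = path, path.with_suffix(".raw")
    else:
        meta_path, raw_path = path.with_suffix(".ini"), path
    if not meta_path.exists() or not raw_path.exists():
        raise VolumeFormatError(f"missing RAW/sidecar pair for {path.name!r}")
    cp = configparser.ConfigParser()
    cp.read(meta_path)
    if "volume" not in cp:
        raise VolumeFormatError("sidecar missing [volume] section")
    sec = cp["volume"]
    try:
        dims = tuple(int(x) for x in sec["dims"].split())
        spacing = np.array([float(x) for x in sec["spacing"].split()])
        elem = sec["element_type"].strip().lower()
    except KeyError as e:
        raise VolumeFormatError(f"sidecar missing key: {e}") from e
    if len(dims) != 3 or len(spacing) != 3:
        raise VolumeFormatError("dims and spacing must have three components")
    origin = np.array(
        [float(x) for x in sec.get("origin", "0 0 0").split()], dtype=np.float64
    )
    byte_order = sec.get("byte_order", "little").strip().lower()
    if elem not in ("uint8", "uint16"):
        raise UnsupportedElementTypeError(f"element type {elem!r} not supported")
    dtype = np.dtype(elem).newbyteorder("<" if byte_order == "little" else ">")
    raw = np.fromfile(raw_path, dtype=dtype)
    expected = dims[0] * dims[1] * dims[2]
    if raw.size != expected:
        raise VolumeFormatError(
            f"raw length {raw.size} != dims product {expected}"
        )
    data = raw.astype(elem).reshape(dims[::-1]).transpose(2, 1, 0)
    return np.ascontiguousarray(data), spacing, origin


def save_volume_nrrd(v: Volume, path) -> None:
    """Write ``v`` to NRRD, preserving dims/spacing/origin bit-exactly."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    sitk.WriteImage(img, str(path))


def sample_intensity(v: Volume, p: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated normalized intensity at world points ``p``.

    ``p`` has shape ``(..., 3)``; positions outside the bounding box clamp
    to the boundary value.
    """
    p = np.asarray(p, dtype=np.float64)
    idx = (p - v.origin) / v.spacing
    flat = idx.reshape(-1, 3).T
    vals = map_coordinates(v._norm, flat, order=1, mode="nearest", prefilter=False)
    return vals.reshape(p.shape[:-1])


def sample_gradient(v: Volume, p: np.ndarray) -> GradientSample:
    """Central-difference gradient of the normalized intensity at ``p``.

    Step per axis is one voxel spacing; face positions rely on the clamped
    sampler, which makes the one-sided limit well defined.
    """
    p = np.asarray(p, dtype=np.float64)
    comps = []
    for ax in range(3):
        h = np.zeros(3)
        h[ax] = v.spacing[ax]
        comps.append(
            (sample_intensity(v, p + h) - sample_intensity(v, p - h))
            / (2.0 * v.spacing[ax])
        )
    vec = np.stack(comps, axis=-1)
    mag = np.linalg.norm(vec, axis=-1)
    return GradientSample(vec, mag, np.clip(mag / v.grad_max, 0.0, 1.0))


def intersect_box(v: Volume, ray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clip ``ray`` against the volume's bounding box (slab method).

    Returns ``(hit, t_near, t_far)``; the interval is already intersected
    with ``[ray.tmin, ray.tmax]``. Rays that miss carry ``hit = False`` and
    are discarded by callers. Vectorized over ray batches.
    """
    o = np.asarray(ray.origin, dtype=np.float64)
    d = np.asarray(ray.direction, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
        t0 = (v.bbox_min - o) * inv
        t1 = (v.bbox_max - o) * inv
    # 0 * inf -> nan when the origin sits exactly on a slab plane of a
    # perpendicular axis; treat that slab as non-constraining (nan propagates
    # through minimum/maximum, then is replaced below)
    lo = np.minimum(t0, t1)
    hi = np.maximum(t0, t1)
    lo = np.where(np.isnan(lo), -np.inf, lo)
    hi = np.where(np.isnan(hi), np.inf, hi)
    t_near = np.maximum(lo.max(axis=-1), np.asarray(ray.tmin, dtype=np.float64))
    t_far = np.minimum(hi.min(axis=-1), np.asarray(ray.tmax, dtype=np.float64))
    # reject rays whose perpendicular origin lies outside a slab
    parallel_miss = np.any((d == 0.0) & ((o < v.bbox_min) | (o > v.bbox_max)), axis=-1)
    hit = (t_near <= t_far) & ~parallel_miss
    return hit, t_near, t_far
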