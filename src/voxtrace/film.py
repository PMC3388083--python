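"""Progressive film: accumulation, post-processing chain, and convergence metric.

Each frame estimate flows through a fixed pipeline:

    raw estimate -> Gaussian pre-filter -> cumulative moving average (HDR)
                 -> tone map -> gamma    -> variance-driven KNN denoise (LDR)

The cumulative moving average implements progressive Monte Carlo
integration: after N frames the HDR buffer equals the arithmetic mean of the
N estimates. The per-pixel mean/second-moment aggregates of the LDR image
are maintained with Welford's numerically stable single-pass update; their
mean over all pixels (the *mean running sample variance*) steers how much
the KNN filter blends into the output — strong while the estimate is noisy,
vanishing as it converges.

Convergence is measured with the NRMS: the root-mean-square difference
between the running estimate and a converged reference, normalized by the
reference's value range.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "Film",
    "prefilter_estimate",
    "tonemap_gamma",
    "knn_denoise",
    "nrms",
    "write_png",
    "write_hdr_tiff",
]

# Post-processing defaults; each knob is a plain keyword on its function.
GAUSS_SIGMA = 0.66  # px, 3x3 window
KNN_WINDOW = 7
KNN_BANDWIDTH = 0.2  # colour-similarity bandwidth h on LDR values
KNN_LERP_SCALE = 100.0  # k in lerpC = exp(-k * mean_variance)


def prefilter_estimate(frame: np.ndarray, sigma: float = GAUSS_SIGMA, radius: int = 1) -> np.ndarray:
    """Separable Gaussian pre-filter of a raw frame estimate (anti-aliasing).

    Default sigma 0.66 px over a 3x3 window; the kernel is normalized so a
    constant image passes through unchanged, and edges replicate.
    """
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    out = convolve1d(np.asarray(frame, dtype=np.float64), k, axis=0, mode="nearest")
    return convolve1d(out, k, axis=1, mode="nearest")


def tonemap_gamma(hdr: np.ndarray, exposure: float = 1.0, gamma: float = 2.2) -> np.ndarray:
    """Exponential exposure tone map then gamma correction, into [0, 1].

    ``L' = 1 - exp(-L / exposure)`` per channel, followed by ``L'**(1/gamma)``;
    monotone, maps 0 to 0 and compresses arbitrary dynamic range.
    """
    if exposure <= 0 or gamma <= 0:
        raise ValueError("exposure and gamma must be positive")
    ldr = 1.0 - np.exp(-np.asarray(hdr, dtype=np.float64) / exposure)
    return np.clip(ldr, 0.0, 1.0) ** (1.0 / gamma)


def knn_denoise(
    ldr: np.ndarray,
    mean_variance: float,
    window: int = KNN_WINDOW,
    bandwidth: float = KNN_BANDWIDTH,
    lerp_scale: float = KNN_LERP_SCALE,
    spatial_sigma: float | None = None,
    variance_boost: float = 8.0,
) -> np.ndarray:
    """Variance-driven K-nearest-neighbour noise reduction on an LDR image.

    A Gaussian blur whose per-pixel weights are attenuated by colour
    similarity, ``exp(-||c_i - c_0||^2 / h_eff^2)``, over a ``window x
    window`` neighbourhood. The similarity bandwidth widens with the running
    sample variance (``h_eff^2 = bandwidth^2 + variance_boost *
    mean_variance``): while the estimate is noisy, large colour differences
    are expected and should not block smoothing; as it converges, the filter
    becomes strictly edge-preserving. The filtered image is blended with the
    input through ``lerpC = exp(-lerp_scale * mean_variance)`` (weight of
    the *original*), so the filter's influence decays to zero with the
    variance; ``mean_variance = 0`` returns the input exactly, and a uniform
    image is a fixed point for any parameters.
    """
    img = np.asarray(ldr, dtype=np.float64)
    mv = max(float(mean_variance), 0.0)
    lerp_c = float(np.exp(-lerp_scale * mv))
    if lerp_c >= 1.0:
        return img.copy()
    r = window // 2
    if spatial_sigma is None:
        spatial_sigma = window / 4.0
    h2 = bandwidth**2 + variance_boost * mv
    pad = np.pad(img, ((r, r), (r, r), (0, 0)), mode="edge")
    h, w = img.shape[:2]
    acc = np.zeros_like(img)
    wsum = np.zeros(img.shape[:2])
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            nb = pad[r + dy : r + dy + h, r + dx : r + dx + w]
            d2 = ((nb - img) ** 2).sum(axis=-1)
            with np.errstate(over="ignore"):
                wgt = np.exp(-(dx * dx + dy * dy) / (2.0 * spatial_sigma**2)) * (
                    np.exp(-d2 / h2) if np.isfinite(h2) else 1.0
                )
            acc += wgt[..., None] * nb
            wsum += wgt
    filtered = acc / wsum[..., None]
    return lerp_c * img + (1.0 - lerp_c) * filtered


def nrms(running: np.ndarray, reference: np.ndarray) -> float:
    """Normalized RMS error between a running estimate and a reference.

    RMS of the per-pixel difference divided by the reference's value range;
    a constant reference has no range and raises ``ValueError``.
    """
    a = np.asarray(running, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("resolution mismatch")
    rng_ = float(b.max() - b.min())
    if rng_ == 0.0:
        raise ValueError("reference has zero value range; NRMS undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)) / rng_)


class Film:
    """HDR accumulation buffer with running LDR variance and final output.

    ``hdr_accum`` holds the cumulative moving average of the (pre-filtered)
    frame estimates; ``frame_count`` is N. ``ldr_mean``/``ldr_m2`` are the
    Welford aggregates of the tone-mapped image, from which
    ``mean_variance`` derives. ``reset()`` implements restart-on-edit: any
    scene change clears every aggregate and N returns to 0.
    """

    def __init__(self, resolution: tuple[int, int]):
        self.resolution = tuple(int(x) for x in resolution)  # (width, height)
        w, h = self.resolution
        self.hdr_accum = np.zeros((h, w, 3))
        self.frame_count = 0
        self.ldr_mean = np.zeros((h, w, 3))
        self.ldr_m2 = np.zeros((h, w, 3))
        self.ldr_count = 0
        self.ldr_output = np.zeros((h, w, 3))

    def reset(self) -> None:
        self.hdr_accum[:] = 0.0
        self.frame_count = 0
        self.ldr_mean[:] = 0.0
        self.ldr_m2[:] = 0.0
        self.ldr_count = 0
        self.ldr_output[:] = 0.0

    def accumulate(self, frame: np.ndarray) -> None:
        """Cumulative moving average update: mean <- mean + (x - mean)/(N+1)."""
        frame = np.asarray(frame, dtype=np.float64)
        if frame.shape != self.hdr_accum.shape:
            raise ValueError("frame resolution mismatch")
        self.frame_count += 1
        self.hdr_accum += (frame - self.hdr_accum) / self.frame_count

    def update_variance(self, ldr_frame: np.ndarray) -> None:
        """Welford single-pass update of the LDR mean/M2 aggregates."""
        x = np.asarray(ldr_frame, dtype=np.float64)
        if x.shape != self.ldr_mean.shape:
            raise ValueError("frame resolution mismatch")
        self.ldr_count += 1
        delta = x - self.ldr_mean
        self.ldr_mean += delta / self.ldr_count
        self.ldr_m2 += delta * (x - self.ldr_mean)

    @property
    def per_pixel_variance(self) -> np.ndarray:
        if self.ldr_count < 2:
            return np.full_like(self.ldr_m2, np.inf)
        return self.ldr_m2 / (self.ldr_count - 1)

    @property
    def mean_variance(self) -> float:
        """Mean running sample variance of the LDR estimate over all pixels.

        Undefined (infinite) before two frames exist, which drives the KNN
        filter to maximal influence during the earliest iterations.
        """
        if self.ldr_count < 2:
            return np.inf
        return float(np.mean(self.ldr_m2) / (self.ldr_count - 1))


def write_png(path, ldr: np.ndarray) -> None:
    """8-bit PNG from an LDR image in [0, 1]."""
    import imageio.v3 as iio

    img = np.clip(np.asarray(ldr), 0.0, 1.0)
    iio.imwrite(str(path), (img * 255.0 + 0.5).astype(np.uint8))


def write_hdr_tiff(path, hdr: np.ndarray) -> None:
    """Float32 TIFF of the HDR accumulation buffer."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(hdr, dtype=np.float32))
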