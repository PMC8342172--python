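"""Edge-probability maps and the edge stop function g.

The evolution is gated by a stop function g ∈ (0, 1] that is small where edge
evidence is strong. Edge evidence comes either from an externally supplied
per-pixel boundary-probability image (e.g. the output of a learned edge
detector, loaded from file), or from a classical fallback: the magnitude of
the Gaussian-smoothed image gradient, rescaled to [0, 1].

Because probabilities live in [0, 1], g = 1/(1+E²) alone gives only g = 0.5 at
a perfect edge — not enough of a barrier. A multiplicative gain (default 4)
is applied to the evidence before squaring, so E ≈ 1 drives g ≈ 0.06 while
the transition g = 0.5 sits at E = 1/gain = 0.25: evidence below ~25 %
probability barely slows the contour (it must keep moving through the broad
low-probability skirt of a band-limited edge ridge), evidence near 1 stops it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import raster_core
from .exceptions import InputError, ParameterError

#: default multiplicative gain on edge evidence before squaring in g = 1/(1+E²)
DEFAULT_EDGE_GAIN = 4.0

_LUMA = np.array([0.299, 0.587, 0.114])

SOURCES = ("external-file", "gradient-fallback", "ground-truth-synthetic")


@dataclass(frozen=True)
class EdgeProbabilityMap:
    """Per-pixel boundary likelihood in [0, 1] plus its provenance."""

    values: np.ndarray
    source: str

    def __post_init__(self):
        values = raster_core.validate_field(self.values, "edge map")
        if values.min() < 0.0 or values.max() > 1.0:
            raise ParameterError("edge probabilities must lie in [0, 1]")
        if self.source not in SOURCES:
            raise ParameterError(f"unknown edge-map source {self.source!r}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def to_gray(image: np.ndarray) -> np.ndarray:
    """Collapse an (h, w, 3|4) array to luma; pass 2-D arrays through."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return arr


def _rescale_integer(arr: np.ndarray) -> np.ndarray:
    """Linearly map stored integer ranges (8/16-bit) to [0, 1]."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a [0, 1] grayscale field (RGB -> luma)."""
    try:
        raw = iio.imread(Path(path))
    except Exception as exc:  # plugins raise a zoo of error types
        raise InputError(f"cannot read image {path}: {exc}") from exc
    return to_gray(_rescale_integer(np.asarray(raw)))


def edge_probability_from_gradient(image, sigma: float) -> EdgeProbabilityMap:
    """Classical edge evidence |∇(G_σ ∗ I)| rescaled to [0, 1] by its maximum.

    Stands in for a learned boundary-probability map when none is supplied.
    A constant image yields the all-zero map.
    """
    image = to_gray(image)
    smoothed = raster_core.gaussian_smooth(image, sigma)
    gx, gy = raster_core.gradient(smoothed)
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return EdgeProbabilityMap(mag, "gradient-fallback")


def load_edge_map(path, target_shape: tuple[int, int]) -> EdgeProbabilityMap:
    """Load an 8/16-bit grayscale edge-probability image, rescaled to [0, 1].

    The stored shape must equal *target_shape* (the image being segmented);
    resampling a probability map silently would corrupt its calibration.
    """
    values = load_image(path)
    if values.shape != tuple(target_shape):
        raise InputError(
            f"edge map shape {values.shape} does not match image shape {tuple(target_shape)}"
        )
    return EdgeProbabilityMap(np.clip(values, 0.0, 1.0), "external-file")


def stop_function(
    edges: EdgeProbabilityMap,
    gain: float = DEFAULT_EDGE_GAIN,
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Edge stop function g = 1 / (1 + (gain·E)²) ∈ (0, 1].

    *smooth_sigma* > 0 applies Gaussian smoothing to the evidence first (used
    for externally loaded maps, matching the smoothing of the fallback path).
    g is strictly decreasing in the evidence and equals 1 where E = 0.
    """
    if gain < 0:
        raise ParameterError(f"gain must be nonnegative, got {gain}")
    evidence = edges.values
    if smooth_sigma > 0:
        evidence = raster_core.gaussian_smooth(evidence, smooth_sigma)
    scaled = gain * evidence
    return 1.0 / (1.0 + scaled * scaled)
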