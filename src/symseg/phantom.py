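"""Seeded synthetic tongue-like phantoms with ground truth.

Each phantom is a bilaterally symmetric blob on a plain background: a wide
rounded top (elliptical cap) tapering monotonically to a single pointed pole
(the apex), mirroring the geometry the segmenter exploits. The generator also
reproduces the conditions that make real tongue images hard:

* ``low-contrast`` — foreground/background intensity gap of only ~0.08;
* ``speckle``      — bright/dark spot noise scattered on the blob surface;
* ``crack``        — a dark median streak along the symmetry axis;
* ``weak-side``    — the ground-truth edge probability attenuated on one
  side of the axis, emulating a locally unreliable edge detector.

Every phantom carries its ground-truth mask, apex location, symmetry axis and
edge-probability map, so the whole pipeline is testable without external
data. All randomness flows from one :class:`numpy.random.Generator` per
phantom; a fixed seed reproduces the phantom bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from . import raster_core, symmetry
from .edge_prior import EdgeProbabilityMap
from .exceptions import ParameterError
from .symmetry import SymmetryAxis

PRESETS = ("clean", "low-contrast", "speckle", "crack", "weak-side")

#: Gaussian sigma of the soft intensity edge and of the edge-map feathering
EDGE_SOFTNESS = 1.0
FEATHER_SIGMA = 1.0
SPECKLE_SIGMA = 0.8


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; seeded, hence bit-reproducible.

    The blob's half-width profile is a parabola rising from 0 at the apex to
    ``half_width`` over ``taper_length`` pixels along the axis (a genuine
    wedge corner at the apex), closed above by a half-ellipse of height
    ``cap_height``. ``axis_angle`` tilts the axis away from vertical.
    """

    shape: tuple[int, int] = (128, 128)
    apex: tuple[float, float] = (63.5, 100.0)
    axis_angle: float = 0.0
    half_width: float = 33.0
    taper_length: float = 46.0
    cap_height: float = 18.0
    fg_level: float = 0.8
    bg_level: float = 0.2
    speckle_density: float = 0.0
    speckle_amplitude: float = 0.3
    crack_width: float = 0.0
    weak_side_attenuation: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.shape
        ax, ay = self.apex
        if not (0 <= ax <= w - 1 and 0 <= ay <= h - 1):
            raise ParameterError(f"apex {self.apex} outside image of shape {self.shape}")
        if not (0.0 <= self.fg_level <= 1.0 and 0.0 <= self.bg_level <= 1.0):
            raise ParameterError("fg_level and bg_level must lie in [0, 1]")
        if not 0.0 <= self.speckle_density <= 0.2:
            raise ParameterError("speckle_density must lie in [0, 0.2]")
        if not 0.0 < self.weak_side_attenuation <= 1.0:
            raise ParameterError("weak_side_attenuation must lie in (0, 1]")

    @property
    def contrast_gap(self) -> float:
        return self.fg_level - self.bg_level


@dataclass(frozen=True)
class Phantom:
    """One generated phantom with its complete ground truth."""

    image: np.ndarray
    mask: np.ndarray
    apex: tuple[float, float]
    edges: EdgeProbabilityMap
    axis: SymmetryAxis
    spec: PhantomSpec


def _blob_geometry(spec: PhantomSpec):
    """Axis-aligned coordinates (s along axis from apex, t across) per pixel."""
    h, w = spec.shape
    a = np.deg2rad(spec.axis_angle)
    ex, ey = np.sin(a), -np.cos(a)  # unit vector apex -> cap (up the image)
    px, py = np.cos(a), np.sin(a)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    rx, ry = xx - spec.apex[0], yy - spec.apex[1]
    s = rx * ex + ry * ey
    t = rx * px + ry * py
    return s, t


def _half_width(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """Half-width of the blob at axial position s (−1 outside the blob span)."""
    L, W, Hc = spec.taper_length, spec.half_width, spec.cap_height
    u = s / L
    taper = W * (2.0 * u - u * u)  # parabola: 0 at apex, W with zero slope at s=L
    v = (s - L) / Hc
    cap = W * np.sqrt(np.clip(1.0 - v * v, 0.0, None))
    hw = np.where(s <= L, taper, cap)
    return np.where((s >= 0) & (s <= L + Hc), hw, -1.0)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom: image, mask, apex, ground-truth edges and axis."""
    rng = np.random.default_rng(spec.seed)
    s, t = _blob_geometry(spec)
    hw = _half_width(spec, s)
    mask = np.abs(t) <= hw

    soft = raster_core.gaussian_smooth(mask.astype(np.float64), EDGE_SOFTNESS)
    image = spec.bg_level + spec.contrast_gap * soft

    if spec.speckle_density > 0:
        interior = ndimage.binary_erosion(mask, iterations=3)
        idx = np.flatnonzero(interior)
        n_dots = int(round(spec.speckle_density * idx.size))
        if n_dots > 0:
            chosen = rng.choice(idx, size=n_dots, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_dots)
            dots = np.zeros(mask.size)
            dots[chosen] = signs
            dots = raster_core.gaussian_smooth(dots.reshape(mask.shape), SPECKLE_SIGMA)
            peak = np.abs(dots).max()
            if peak > 0:
                image = image + spec.speckle_amplitude * dots / peak

    if spec.crack_width > 0:
        depth = 0.5 * spec.contrast_gap
        along = (s > 0.15 * spec.taper_length) & (s < spec.taper_length + 0.3 * spec.cap_height)
        profile = np.exp(-((t / (spec.crack_width / 2.0)) ** 2))
        image = image - depth * profile * along * soft

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    # edge ridge = gradient magnitude of the soft mask: peaks ON the true
    # boundary (between the last inside and first outside pixel), unlike a
    # feathered inner-boundary ring, which would bias the ridge 0.5 px inward
    egx, egy = raster_core.gradient(soft)
    edges = np.hypot(egx, egy)
    peak = edges.max()
    if peak > 0:
        edges = edges / peak
    if spec.weak_side_attenuation < 1.0:
        edges = np.where(t > 0, edges * spec.weak_side_attenuation, edges)
    edge_map = EdgeProbabilityMap(np.clip(edges, 0.0, 1.0), "ground-truth-synthetic")

    a = np.deg2rad(spec.axis_angle)
    top = (
        spec.apex[0] + spec.taper_length * np.sin(a),
        spec.apex[1] - spec.taper_length * np.cos(a),
    )
    axis = symmetry.axis_from_points(top, spec.apex, spec.shape)
    return Phantom(image=image, mask=mask, apex=spec.apex, edges=edge_map, axis=axis, spec=spec)


def generate_disk(
    shape: tuple[int, int] = (128, 128),
    center: tuple[float, float] = (63.5, 63.5),
    radius: float = 40.0,
    fg_level: float = 0.8,
    bg_level: float = 0.2,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """High-contrast disk phantom: the canonical easy target for the flow."""
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r = np.hypot(xx - center[0], yy - center[1])
    mask = r <= radius
    soft = raster_core.gaussian_smooth(mask.astype(np.float64), EDGE_SOFTNESS)
    image = bg_level + (fg_level - bg_level) * soft
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    egx, egy = raster_core.gradient(soft)
    edges = np.hypot(egx, egy)
    if edges.max() > 0:
        edges = edges / edges.max()
    edge_map = EdgeProbabilityMap(edges, "ground-truth-synthetic")
    axis = symmetry.axis_from_points(center, (center[0], center[1] + radius), shape)
    spec = PhantomSpec(shape=shape, apex=(center[0], min(center[1] + radius, h - 1)), seed=seed)
    return Phantom(image=image, mask=mask, apex=spec.apex, edges=edge_map, axis=axis, spec=spec)


_PRESET_OVERRIDES: dict[str, dict] = {
    "clean": {},
    "low-contrast": {"fg_level": 0.54, "bg_level": 0.46, "noise_sigma": 0.01},
    "speckle": {"speckle_density": 0.05, "speckle_amplitude": 0.3},
    "crack": {"crack_width": 3.0},
    "weak-side": {"weak_side_attenuation": 0.2},
}


def _random_spec(preset: str, seed: int, shape: tuple[int, int]) -> PhantomSpec:
    """Draw the per-item geometry for a preset from realistic ranges."""
    rng = np.random.default_rng(seed)
    h, w = shape
    scale = min(h, w) / 128.0
    apex = (
        (w - 1) / 2.0 + rng.uniform(-4.0, 4.0) * scale,
        0.78 * h + rng.uniform(-5.0, 5.0) * scale,
    )
    base = PhantomSpec(
        shape=shape,
        apex=apex,
        axis_angle=rng.uniform(-6.0, 6.0),
        half_width=rng.uniform(30.0, 36.0) * scale,
        taper_length=rng.uniform(42.0, 50.0) * scale,
        cap_height=rng.uniform(16.0, 20.0) * scale,
        noise_sigma=0.005,
        seed=seed,
    )
    return replace(base, **_PRESET_OVERRIDES[preset])


def phantom_suite(
    preset: str, n: int, seed: int, shape: tuple[int, int] = (128, 128)
) -> list[Phantom]:
    """Generate *n* phantoms of a preset with per-item derived seeds."""
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    return [generate_phantom(_random_spec(preset, int(s), shape)) for s in child_seeds]


def save_phantom(ph: Phantom, outdir, stem: str) -> dict:
    """Write image/mask/edge PNGs plus a lossless float sidecar; return manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    to8 = lambda f: np.clip(np.round(f * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(outdir / f"{stem}_image.png", to8(ph.image))
    iio.imwrite(outdir / f"{stem}_mask.png", np.where(ph.mask, 255, 0).astype(np.uint8))
    iio.imwrite(outdir / f"{stem}_edges.png", to8(ph.edges.values))
    np.save(outdir / f"{stem}_image.npy", ph.image)
    manifest = {
        "stem": stem,
        "spec": asdict(ph.spec),
        "apex": list(ph.apex),
        "axis": {"A": ph.axis.A, "B": ph.axis.B, "C": ph.axis.C},
    }
    return manifest


def save_suite(phantoms: list[Phantom], outdir, preset: str) -> Path:
    """Save a suite plus a JSON manifest; file stems embed the per-item seed."""
    outdir = Path(outdir)
    entries = [
        save_phantom(ph, outdir, f"phantom_{preset}_{i:03d}_seed{ph.spec.seed}")
        for i, ph in enumerate(phantoms)
    ]
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps({"preset": preset, "items": entries}, indent=2))
    return manifest_path
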