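"""Symmetry-axis detection, reflection transforms, and the symmetry energy.

The target (a tongue-like blob) is assumed bilaterally symmetric about an
axis running from the blob's mass centre to its single pointed pole ("tip").
The axis is found automatically: the centre of gravity of the edge-probability
map fixes a point on the axis, a Harris-corner search in a band around the
image mid-column locates the tip, and the line through both is the axis.

Reflection across the axis Ax + By + C = 0 is the homogeneous matrix

    M = 1/(A²+B²) · [[B²−A², −2AB, −2AC],
                     [−2AB,  A²−B², −2BC],
                     [0,     0,     A²+B²]],

an involution whose fixed line is the axis. Scalar fields are reflected by
bilinear resampling at M·q.

The symmetry detection constraint (SCT) energy penalises asymmetry of the
edge-weighted inside indicator w = H_ε(−φ)·g:

    S(φ) = η · Σ (w − ŵ)²,     ŵ = reflection of w across the axis.

S vanishes when the contour (as weighted by the edge evidence) is mirror
symmetric, and grows when one side lags the other — e.g. at a weak edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor
from skimage.morphology import skeletonize

from . import raster_core
from .exceptions import DegenerateInputError, ParameterError, TipNotFoundError
from .edge_prior import EdgeProbabilityMap
from .raster_core import smoothed_heaviside, validate_field


@dataclass(frozen=True)
class SymmetryAxis:
    """A line A·x + B·y + C = 0 with the two points that defined it.

    ``centroid`` is the mass centre of the edge map, ``tip`` the detected
    pole; ``midpoint`` is the midpoint O of the axis's two intersections with
    the image rectangle, used as the centre of the initial contour.
    """

    A: float
    B: float
    C: float
    centroid: tuple[float, float]
    tip: tuple[float, float]
    midpoint: tuple[float, float]

    def __post_init__(self):
        if self.A == 0.0 and self.B == 0.0:
            raise ParameterError("axis coefficients (A, B) must not both be zero")
        for p in (self.centroid, self.tip):
            if abs(self.signed_distance(*p)) > 1e-6:
                raise ParameterError(f"point {p} does not lie on the axis")

    def signed_distance(self, x: float, y: float) -> float:
        """Perpendicular signed distance from (x, y) to the axis."""
        return (self.A * x + self.B * y + self.C) / math.hypot(self.A, self.B)

    def angle_deg(self) -> float:
        """Axis tilt in degrees from the image vertical, in (−90, 90].

        Positive values tilt the upward axis direction toward +x (image
        coordinates, y pointing down); a vertical axis reads 0° regardless
        of the line's orientation.
        """
        # line direction (dx, dy) = (B, −A); signed angle of the upward
        # direction vs vertical is atan2(dx, −dy), folded to (−90, 90]
        ang = math.degrees(math.atan2(self.B, self.A))
        ang = (ang + 90.0) % 180.0 - 90.0
        return ang


@dataclass(frozen=True)
class HarrisParams:
    """Controls for corner-based tip detection.

    ``search_halfwidth_k`` is the half-width in pixels of the vertical strip
    around the image mid-column searched for tip candidates; ``None`` resolves
    to 10 % of the image width at use. ``y_band`` restricts candidates to the
    lower fraction of the image (the pole of a tongue sits low-centre).
    """

    window_sigma: float = 2.0
    sensitivity: float = 0.05
    response_threshold: float = 0.1
    search_halfwidth_k: float | None = None
    y_band: float = 0.4

    def __post_init__(self):
        if not 0.01 <= self.sensitivity <= 0.25:
            raise ParameterError("Harris sensitivity must lie in [0.01, 0.25]")
        if self.search_halfwidth_k is not None and self.search_halfwidth_k < 1:
            raise ParameterError("search_halfwidth_k must be >= 1 pixel")
        if not 0.0 < self.y_band <= 1.0:
            raise ParameterError("y_band must lie in (0, 1]")

    def halfwidth(self, width: int) -> float:
        return self.search_halfwidth_k if self.search_halfwidth_k is not None else 0.1 * width


@dataclass
class ReflectionMap:
    """Homogeneous reflection matrix plus the resampling rule for fields.

    ``oob`` selects what reflected samples that fall outside the image see:
    ``"replicate"`` (nearest edge value, default) or ``"background"``
    (constant fill, appropriate when outside means "not object").
    """

    M: np.ndarray
    axis: SymmetryAxis
    oob: str = "replicate"
    _coords: dict = field(default_factory=dict, repr=False, compare=False)

    def transform_points(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map points (x, y) to their mirror images across the axis."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        M = self.M
        xr = M[0, 0] * x + M[0, 1] * y + M[0, 2]
        yr = M[1, 0] * x + M[1, 1] * y + M[1, 2]
        return xr, yr

    def sample_coords(self, shape: tuple[int, int]) -> np.ndarray:
        """(2, h, w) array of (row, col) sample positions, cached per shape."""
        key = tuple(shape)
        if key not in self._coords:
            h, w = key
            yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
            xr, yr = self.transform_points(xx, yy)
            self._coords[key] = np.stack([yr, xr])
        return self._coords[key]


def gradient_centroid(edges: EdgeProbabilityMap) -> tuple[float, float]:
    """Centre of gravity (x̄, ȳ) of the edge map, weights = pixel values.

    The centroid of an axisymmetric figure lies on its symmetry axis, which is
    what makes this a usable axis anchor.
    """
    p = edges.values
    total = p.sum()
    if total <= 0:
        raise DegenerateInputError("edge map has no positive pixels")
    h, w = p.shape
    yy, xx = np.mgrid[0:h, 0:w]
    return float((p * xx).sum() / total), float((p * yy).sum() / total)


def harris_response(image, params: HarrisParams = HarrisParams()) -> np.ndarray:
    """Harris corner response det(S) − k·trace(S)² of the structure tensor S.

    S is the Gaussian-windowed (sigma = ``window_sigma``) outer product of the
    image gradients, computed with replicate boundary handling so a constant
    image yields an identically flat response. Flat regions give ≈ 0,
    straight edges ≤ 0, corners > 0.
    """
    image = validate_field(image, "image")
    arr, arc, acc = structure_tensor(
        image, sigma=params.window_sigma, mode="nearest", order="rc"
    )
    det = arr * acc - arc * arc
    trace = arr + acc
    return det - params.sensitivity * trace * trace


def detect_tip(
    edges: EdgeProbabilityMap,
    response: np.ndarray,
    params: HarrisParams = HarrisParams(),
) -> tuple[float, float]:
    """Mean coordinate of corner candidates in the low-centre search band.

    Candidates are pixels whose Harris response exceeds
    ``response_threshold × max(response)`` and that lie within ``±k`` pixels of
    the image mid-column and within the lower ``y_band`` fraction of rows.
    Raises :class:`TipNotFoundError` if no candidate survives.
    """
    response = np.asarray(response, dtype=np.float64)
    h, w = response.shape
    mid = (w - 1) / 2.0
    k = params.halfwidth(w)
    y_min = (1.0 - params.y_band) * (h - 1)
    yy, xx = np.mgrid[0:h, 0:w]
    band = (np.abs(xx - mid) <= k) & (yy >= y_min)
    thresh = params.response_threshold * response.max()
    cand = band & (response > thresh) & (response > 0)
    if not cand.any():
        raise TipNotFoundError("no Harris corner candidate in the tip search band")
    return float(xx[cand].mean()), float(yy[cand].mean())


def tip_fallback(
    edges: EdgeProbabilityMap, params: HarrisParams = HarrisParams()
) -> tuple[float, float]:
    """Lowest strong-edge pixel in the mid-column strip.

    Used when no Harris corner survives (smooth, corner-free poles): among
    strip pixels with edge probability above half the strip maximum, take the
    lowest row; ties resolve to their mean column.
    """
    p = edges.values
    h, w = p.shape
    mid = (w - 1) / 2.0
    k = params.halfwidth(w)
    yy, xx = np.mgrid[0:h, 0:w]
    strip = np.abs(xx - mid) <= k
    strip_max = p[strip].max() if strip.any() else 0.0
    if strip_max <= 0:
        raise TipNotFoundError("no edge evidence in the mid-column strip")
    strong = strip & (p > 0.5 * strip_max)
    y2 = yy[strong].max()
    x2 = xx[strong & (yy == y2)].mean()
    return float(x2), float(y2)


def axis_from_points(
    p1: tuple[float, float], p2: tuple[float, float], shape: tuple[int, int]
) -> SymmetryAxis:
    """Axis through centroid *p1* and tip *p2* on an image of the given shape.

    Line coefficients: A = y1−y2, B = x2−x1, C = x1·y2 − x2·y1. The axis
    midpoint O is the midpoint of the line's two intersections with the image
    rectangle [0, w−1] × [0, h−1].
    """
    (x1, y1), (x2, y2) = p1, p2
    if x1 == x2 and y1 == y2:
        raise DegenerateInputError("centroid and tip coincide; axis undefined")
    A = y1 - y2
    B = x2 - x1
    C = x1 * y2 - x2 * y1
    h, w = shape
    (xa, ya), (xb, yb) = _clip_line_to_rect(p1, p2, w - 1.0, h - 1.0)
    midpoint = ((xa + xb) / 2.0, (ya + yb) / 2.0)
    return SymmetryAxis(A, B, C, centroid=tuple(map(float, p1)), tip=tuple(map(float, p2)), midpoint=midpoint)


def _clip_line_to_rect(p1, p2, xmax: float, ymax: float):
    """Liang–Barsky clip of the infinite line through p1, p2 to [0,xmax]x[0,ymax]."""
    x1, y1 = p1
    dx, dy = p2[0] - x1, p2[1] - y1
    t_lo, t_hi = -np.inf, np.inf
    for delta, lo, hi, start in ((dx, 0.0, xmax, x1), (dy, 0.0, ymax, y1)):
        if delta == 0.0:
            if start < lo or start > hi:
                raise DegenerateInputError("axis does not intersect the image rectangle")
            continue
        ta, tb = (lo - start) / delta, (hi - start) / delta
        if ta > tb:
            ta, tb = tb, ta
        t_lo, t_hi = max(t_lo, ta), min(t_hi, tb)
    if t_lo > t_hi:
        raise DegenerateInputError("axis does not intersect the image rectangle")
    return (
        (x1 + t_lo * dx, y1 + t_lo * dy),
        (x1 + t_hi * dx, y1 + t_hi * dy),
    )


def reflection_matrix(axis: SymmetryAxis, oob: str = "replicate") -> ReflectionMap:
    """Homogeneous reflection matrix across the axis; M·M = I."""
    A, B, C = axis.A, axis.B, axis.C
    n = A * A + B * B
    M = (
        np.array(
            [
                [B * B - A * A, -2 * A * B, -2 * A * C],
                [-2 * A * B, A * A - B * B, -2 * B * C],
                [0.0, 0.0, n],
            ]
        )
        / n
    )
    return ReflectionMap(M=M, axis=axis, oob=oob)


def reflect_field(
    f, m: ReflectionMap, background: float | None = None
) -> np.ndarray:
    """Resample *f* at its mirror coordinates: f̂(q) = f(M·q), bilinear.

    Out-of-bounds samples replicate the nearest edge value unless the map's
    policy is ``"background"``, in which case they take *background* (default
    0, i.e. "not object").
    """
    f = np.asarray(f, dtype=np.float64)
    coords = m.sample_coords(f.shape)
    if m.oob == "background":
        cval = 0.0 if background is None else background
        return ndimage.map_coordinates(f, coords, order=1, mode="constant", cval=cval)
    return ndimage.map_coordinates(f, coords, order=1, mode="nearest")


def sct_energy(
    phi, g, m: ReflectionMap, eta: float, epsilon: float
) -> float:
    """Symmetry detection constraint energy η·Σ(w − ŵ)², w = H_ε(−φ)·g.

    Zero (up to resampling error) when the edge-weighted inside indicator is
    mirror symmetric about the axis; linear in η.
    """
    if eta < 0:
        raise ParameterError(f"eta must be nonnegative, got {eta}")
    if eta == 0:
        return 0.0
    phi = np.asarray(phi, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    w = smoothed_heaviside(-phi, epsilon) * g
    w_hat = reflect_field(w, m)
    diff = w - w_hat
    return float(eta * np.sum(diff * diff))


#: edge pixels above this fraction of the map maximum anchor the axis centroid
CENTROID_SUPPORT_FRACTION = 0.1


def detect_axis(
    image,
    edges: EdgeProbabilityMap,
    params: HarrisParams = HarrisParams(),
) -> SymmetryAxis:
    """Full automatic axis detection: edge centroid + Harris/fallback tip.

    The centroid is taken over the *skeleton* of the edge support (pixels
    above 10 % of the map maximum, thinned to one-pixel ridge lines and
    equally weighted) rather than value-weighted: the axis anchor should
    reflect the boundary's geometry, and both a value-weighted mean and a
    raw-support mean are dragged off-axis whenever the edge detector is
    locally less confident on one side — exactly the condition the symmetry
    constraint is meant to rescue. Thinning removes the residual bias from
    the support band being wider where the evidence is stronger.
    """
    support = edges.values > CENTROID_SUPPORT_FRACTION * edges.values.max()
    ridge = skeletonize(support)
    if not ridge.any():
        ridge = support
    centroid = gradient_centroid(
        EdgeProbabilityMap(ridge.astype(float), edges.source)
    )
    try:
        resp = harris_response(image, params)
        tip = detect_tip(edges, resp, params)
    except TipNotFoundError:
        tip = tip_fallback(edges, params)
    return axis_from_points(centroid, tip, edges.shape)
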