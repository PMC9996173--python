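"""Minimum luminal diameter from a segmentation mask.

The measurement chain is: select the largest connected lumen component,
collect every boundary pixel of its contour, locate the geometric centre
from the first-order image moments

    M_pq = sum_x sum_y x^p y^q f(x, y),      (xbar, ybar) = (M10/M00, M01/M00),

translate the contour so the centre is the origin, classify each point to
a quadrant (or an axis class when a translated coordinate is essentially
zero), convert to polar form (rho, theta), and build centre-passing
diameters: two points on the same axis, or a point in quadrant 1 (resp. 2)
paired with a point in quadrant 3 (resp. 4) whose coordinate slopes --
tangents of the polar angle -- agree within an absolute tolerance.  The
length of each candidate diameter is rho1 + rho2; the minimum over all
candidates, scaled by the pixel spacing, is the minimum luminal diameter.

Pixel coordinates are 0-based with the origin at the top-left corner, x
rightward and y downward; quadrants are defined on the raw translated
signs, which leaves diameter lengths unaffected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .errors import NoDiameterFound, NoLumenFound
from .segmentation import RED_RANGES, HsvRange, segment_lumen

__all__ = [
    "Contour",
    "ImageMoments",
    "Centroid",
    "PolarContourPoint",
    "DiameterSearchParams",
    "ScaleCalibration",
    "extract_contour",
    "moments",
    "centroid_of",
    "to_polar_quadrants",
    "find_min_diameter",
    "DiameterResult",
    "calibrate",
    "measure",
    "measure_mask",
    "Measurement",
]

#: Components smaller than this many pixels are never accepted as the lumen.
MIN_LUMEN_AREA = 9


class Centroid(NamedTuple):
    x: float
    y: float


@dataclass(frozen=True)
class ImageMoments:
    """Raw moments of a binary region: M00 (area), M10 and M01."""

    m00: float
    m10: float
    m01: float


@dataclass(frozen=True)
class DiameterSearchParams:
    """Tuning of the slope-matched diameter search.

    slope_abs_tol
        Absolute tolerance when comparing the tangent values of candidate
        point pairs (default 0.0256).  Exact slope equality almost never
        occurs on integer pixel grids, so a tolerance is required to build
        enough diameters.
    steep_tangent
        Above this |tangent|, pairs are additionally compared by polar
        angle (tolerance atan(slope_abs_tol)); an absolute tolerance on the
        tangent is meaningless for near-vertical chords.
    zero_tol
        A translated coordinate with magnitude below this is treated as
        exactly zero, routing the point to an axis class.
    pixel_extent_px
        Added to the raw rho1 + rho2 when reporting a measurement: the two
        boundary pixel *centers* each sit half a pixel inside the true
        lumen edge, so the physical diameter extends 0.5 px beyond each
        endpoint.  Set to 0 to report the raw polar sum.
    """

    slope_abs_tol: float = 0.0256
    steep_tangent: float = 40.0
    zero_tol: float = 0.5
    pixel_extent_px: float = 1.0

    def __post_init__(self) -> None:
        if self.slope_abs_tol < 0:
            raise ValueError("slope_abs_tol must be >= 0")


@dataclass(frozen=True)
class ScaleCalibration:
    """Physical pixel spacing in millimetres per pixel."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if not (self.mm_per_px > 0 and math.isfinite(self.mm_per_px)):
            raise ValueError("mm_per_px must be positive and finite")


class PolarContourPoint(NamedTuple):
    """A contour point in centred polar form.

    ``quadrant`` is one of Q1..Q4 or an axis class +x/-x/+y/-y; ``rho`` is
    the Euclidean distance from the centroid and ``theta`` the polar angle
    of the translated point (atan2 convention, y down).
    """

    quadrant: str
    rho: float
    theta: float


Contour = np.ndarray  # (N, 2) array of (x, y) boundary pixel coordinates


def extract_contour(mask: np.ndarray, min_area: int = MIN_LUMEN_AREA) -> Contour:
    """All boundary pixels of the largest connected component of ``mask``.

    Any nonzero mask value is foreground.  Components are 8-connected; the
    largest one is selected, components below ``min_area`` pixels are
    rejected.  A boundary pixel is a foreground pixel with at least one
    4-neighbour outside the component.  Points are returned as (x, y)
    rows ordered by polar angle about the component's pixel mean, so the
    sequence traces the closed outline once.

    Raises
    ------
    NoLumenFound
        Empty mask, all components below the area floor, or fewer than
        three boundary points (a lumen must enclose area to be measured).
    """
    fg = np.asarray(mask) != 0
    if not fg.any():
        raise NoLumenFound("empty mask")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise NoLumenFound(
            f"largest component has {sizes[best - 1]} px, below the {min_area} px floor"
        )
    comp = labels == best
    boundary = comp & ~ndimage.binary_erosion(comp)
    ys, xs = np.nonzero(boundary)
    if xs.size < 3:
        raise NoLumenFound(f"contour has only {xs.size} boundary point(s)")
    cx, cy = xs.mean(), ys.mean()
    order = np.argsort(np.arctan2(ys - cy, xs - cx), kind="stable")
    return np.column_stack([xs, ys])[order].astype(float)


def moments(region: np.ndarray) -> ImageMoments:
    """Raw moments M00, M10, M01 of a binary region (nonzero = foreground)."""
    fg = np.asarray(region) != 0
    m00 = float(fg.sum())
    if m00 == 0:
        raise NoLumenFound("empty region has no moments")
    ys, xs = np.nonzero(fg)
    return ImageMoments(m00=m00, m10=float(xs.sum()), m01=float(ys.sum()))


def centroid_of(region: np.ndarray) -> Centroid:
    """Geometric centre (M10/M00, M01/M00) of the filled foreground region."""
    m = moments(region)
    return Centroid(m.m10 / m.m00, m.m01 / m.m00)


def to_polar_quadrants(
    contour: Contour,
    c: Centroid,
    zero_tol: float = 0.5,
) -> list[PolarContourPoint]:
    """Translate contour points to the centroid frame and classify them.

    Each point is shifted by -c; a coordinate with magnitude < ``zero_tol``
    counts as zero and routes the point to an axis class (+x, -x, +y, -y);
    otherwise the sign pattern selects Q1..Q4.  Points essentially
    coincident with the centroid are excluded (a warning reports how many).
    """
    pts = np.asarray(contour, dtype=float)
    dx = pts[:, 0] - c.x
    dy = pts[:, 1] - c.y
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    out: list[PolarContourPoint] = []
    excluded = 0
    for i in range(pts.shape[0]):
        x0 = abs(dx[i]) < zero_tol
        y0 = abs(dy[i]) < zero_tol
        if x0 and y0:
            excluded += 1
            continue
        if x0:
            klass = "+y" if dy[i] > 0 else "-y"
        elif y0:
            klass = "+x" if dx[i] > 0 else "-x"
        elif dx[i] > 0:
            klass = "Q1" if dy[i] > 0 else "Q4"
        else:
            klass = "Q2" if dy[i] > 0 else "Q3"
        out.append(PolarContourPoint(klass, float(rho[i]), float(theta[i])))
    if excluded:
        warnings.warn(
            f"{excluded} contour point(s) coincident with the centroid were excluded",
            stacklevel=2,
        )
    return out


@dataclass
class DiameterResult:
    """Minimum diameter in pixels plus search diagnostics."""

    px: float
    n_candidates: int
    pair: tuple[PolarContourPoint, PolarContourPoint]

    def __float__(self) -> float:
        return self.px


def _pair_search(
    a: list[PolarContourPoint],
    b: list[PolarContourPoint],
    params: DiameterSearchParams,
) -> tuple[float, int, tuple | None]:
    """Best slope-matched diameter between opposite quadrants a and b."""
    if not a or not b:
        return math.inf, 0, None
    ta = np.tan([p.theta for p in a])
    tb = np.tan([p.theta for p in b])
    ra = np.array([p.rho for p in a])
    rb = np.array([p.rho for p in b])

    diff = np.abs(ta[:, None] - tb[None, :])
    # math.isclose semantics: abs_tol plus the default relative term.
    tol = np.maximum(1e-9 * np.maximum(np.abs(ta)[:, None], np.abs(tb)[None, :]), params.slope_abs_tol)
    matched = diff <= tol

    steep = (np.abs(ta)[:, None] > params.steep_tangent) & (np.abs(tb)[None, :] > params.steep_tangent)
    if steep.any():
        th_a = np.array([p.theta for p in a])
        th_b = np.array([p.theta for p in b])
        d = np.abs(th_a[:, None] - th_b[None, :]) % math.pi
        ang = np.minimum(d, math.pi - d)
        matched |= steep & (ang <= math.atan(params.slope_abs_tol))

    if not matched.any():
        return math.inf, 0, None
    lengths = np.where(matched, ra[:, None] + rb[None, :], math.inf)
    i, j = np.unravel_index(np.argmin(lengths), lengths.shape)
    return float(lengths[i, j]), int(matched.sum()), (a[int(i)], b[int(j)])


def find_min_diameter(
    points: Sequence[PolarContourPoint],
    params: DiameterSearchParams | None = None,
) -> DiameterResult:
    """Minimum centre-passing diameter over all candidate point pairs.

    Candidates are (a) axis pairs -- one point on +x with one on -x, and
    likewise for +-y -- and (b) slope-matched pairs between quadrants 1/3
    and 2/4.  Each candidate's length is rho1 + rho2.

    Raises
    ------
    NoDiameterFound
        If no pair satisfies the axis or slope-matching conditions; the
        caller may retry with a larger ``slope_abs_tol``.
    """
    params = params or DiameterSearchParams()
    groups: dict[str, list[PolarContourPoint]] = {
        k: [] for k in ("Q1", "Q2", "Q3", "Q4", "+x", "-x", "+y", "-y")
    }
    for p in points:
        if p.quadrant not in groups:
            raise ValueError(f"unknown quadrant class {p.quadrant!r}")
        groups[p.quadrant].append(p)

    best = math.inf
    best_pair: tuple | None = None
    n_candidates = 0

    for pos, neg in (("+x", "-x"), ("+y", "-y")):
        for p in groups[pos]:
            for q in groups[neg]:
                n_candidates += 1
                length = p.rho + q.rho
                if length < best:
                    best, best_pair = length, (p, q)

    for qa, qb in (("Q1", "Q3"), ("Q2", "Q4")):
        length, count, pair = _pair_search(groups[qa], groups[qb], params)
        n_candidates += count
        if length < best:
            best, best_pair = length, pair

    if best_pair is None:
        raise NoDiameterFound(
            f"no diameter candidate at slope_abs_tol={params.slope_abs_tol}"
        )
    return DiameterResult(px=best, n_candidates=n_candidates, pair=best_pair)


def calibrate(length_mm: float, length_px: float) -> ScaleCalibration:
    """Pixel spacing from a scale bar of known physical length.

    A 10 mm bar spanning 379 px gives 0.026 mm per pixel (3 dp).
    """
    if not (length_mm > 0 and length_px > 0):
        raise ValueError("scale lengths must be positive")
    return ScaleCalibration(mm_per_px=length_mm / length_px)


@dataclass
class Measurement:
    """End-to-end measurement of one cross-section image."""

    diameter_px: float
    diameter_mm: float
    centroid: Centroid
    n_candidates: int
    n_boundary_points: int
    warnings: list[str] = field(default_factory=list)


def measure_mask(
    mask: np.ndarray,
    cal: ScaleCalibration,
    params: DiameterSearchParams | None = None,
) -> Measurement:
    """Measure the minimum luminal diameter of an already-segmented mask."""
    params = params or DiameterSearchParams()
    contour = extract_contour(mask)
    # Centroid of the filled selected component, not of the contour polyline.
    labels, _ = ndimage.label(np.asarray(mask) != 0, structure=np.ones((3, 3), dtype=bool))
    comp_label = labels[int(contour[0, 1]), int(contour[0, 0])]
    c = centroid_of(labels == comp_label)

    msgs: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        polar = to_polar_quadrants(contour, c, zero_tol=params.zero_tol)
        msgs.extend(str(w.message) for w in caught)

    result = find_min_diameter(polar, params)
    diameter_px = result.px + params.pixel_extent_px
    return Measurement(
        diameter_px=diameter_px,
        diameter_mm=diameter_px * cal.mm_per_px,
        centroid=c,
        n_candidates=result.n_candidates,
        n_boundary_points=len(contour),
        warnings=msgs,
    )


def measure(
    img: np.ndarray,
    cal: ScaleCalibration,
    params: DiameterSearchParams | None = None,
    ranges: Sequence[HsvRange] = RED_RANGES,
) -> Measurement:
    """Segment a colour cross-section image and measure its minimum diameter.

    Composition of the whole chain: HSV segmentation, contour extraction,
    moment centroid, polar quadrant decomposition, slope-matched diameter
    search, and physical calibration (mm = px * mm_per_px).  Propagates
    :class:`NoLumenFound` / :class:`NoDiameterFound`.
    """
    seg = segment_lumen(img, ranges)
    return measure_mask(seg.mask, cal, params)
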