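"""Contour-pair annotations, 3-class label masks, and the plausibility check.

The annotation currency of the pipeline is a pair of closed polylines in
patch millimetre coordinates: the *inner* contour (lumen-wall interface) and
the *outer* contour (wall-background interface).  For network training and
evaluation these are rasterized into label masks with the encoding
``{0: background, 1: vessel wall, 2: lumen}``, and predicted masks are
converted back to sub-pixel contours for distance metrics and wall-thickness
quantification.

The plausibility check mirrors the rule used to flag implausible automatic
segmentations: a segmentation is rejected if the lumen is not completely
surrounded by wall tissue, or if the vessel (wall plus lumen) consists of
more than one connected component.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

logger = logging.getLogger(__name__)

BACKGROUND, WALL, LUMEN = 0, 1, 2


@dataclass
class ContourPair:
    """Closed inner (lumen) and outer (wall) polylines in patch mm coordinates.

    Polylines are stored as ``(N, 2)`` vertex arrays without a repeated end
    vertex; closure is implicit.  Both must be simple polygons with at least
    8 vertices, and the inner contour must lie strictly inside the outer one.
    """

    inner: np.ndarray
    outer: np.ndarray

    def __post_init__(self) -> None:
        self.inner = _as_closed_polyline(self.inner, "inner")
        self.outer = _as_closed_polyline(self.outer, "outer")
        outer_poly = Polygon(self.outer)
        if not outer_poly.is_valid:
            raise ValueError("outer contour is self-intersecting")
        if not Polygon(self.inner).is_valid:
            raise ValueError("inner contour is self-intersecting")
        if not np.all(shapely.contains_xy(outer_poly, self.inner[:, 0], self.inner[:, 1])):
            raise ValueError("inner contour must lie strictly inside the outer contour")

    def to_json(self) -> str:
        return json.dumps(
            {
                "inner": self.inner.tolist(),
                "outer": self.outer.tolist(),
                "units": "mm",
                "frame": "patch",
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ContourPair":
        d = json.loads(text)
        return cls(np.asarray(d["inner"], dtype=float), np.asarray(d["outer"], dtype=float))


def _as_closed_polyline(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError(f"{name} contour must be an (N, 2) array")
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 8:
        raise ValueError(f"{name} contour needs at least 8 distinct vertices")
    return v


@dataclass
class LabelMask:
    """A 2D integer patch over ``{0 background, 1 wall, 2 lumen}``."""

    labels: np.ndarray
    pixel_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.isin(self.labels, [BACKGROUND, WALL, LUMEN]).all():
            raise ValueError("label mask values must be in {0, 1, 2}")
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_px(self) -> int:
        return self.labels.shape[0]

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of pixel-center coordinates in the centered patch frame."""
        n0, n1 = self.labels.shape
        x = (np.arange(n0) - (n0 - 1) / 2.0) * self.pixel_mm
        y = (np.arange(n1) - (n1 - 1) / 2.0) * self.pixel_mm
        return np.meshgrid(x, y, indexing="ij")


@dataclass
class PlausibilityResult:
    """Outcome of the segmentation plausibility check."""

    plausible: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        allowed = {"lumen_not_enclosed", "multiple_components"}
        if not set(self.reasons) <= allowed:
            raise ValueError(f"unknown reasons: {set(self.reasons) - allowed}")
        if self.plausible != (len(self.reasons) == 0):
            raise ValueError("plausible flag must match empty reasons")


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def contours_to_mask(cp: ContourPair, n_px: int, pixel_mm: float) -> LabelMask:
    """Rasterize a contour pair into a 3-class label mask.

    A pixel whose center lies inside the inner polygon is lumen; inside the
    outer polygon but not the inner is wall; otherwise background.  Pixel
    centers exactly on a contour count as inside (ties go to the enclosed
    region), which makes the rasterization deterministic.
    """
    half = (n_px - 1) / 2.0
    coords = (np.arange(n_px) - half) * pixel_mm
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    inner_poly = Polygon(cp.inner)
    outer_poly = Polygon(cp.outer)
    in_inner = shapely.intersects_xy(inner_poly, xx.ravel(), yy.ravel()).reshape(n_px, n_px)
    in_outer = shapely.intersects_xy(outer_poly, xx.ravel(), yy.ravel()).reshape(n_px, n_px)
    labels = np.where(in_inner, LUMEN, np.where(in_outer, WALL, BACKGROUND))
    return LabelMask(labels.astype(np.uint8), pixel_mm)


def _largest_closed_contour(binary: np.ndarray, pixel_mm: float, name: str) -> np.ndarray:
    """Sub-pixel 0.5-level iso-contour of a binary image, in patch mm.

    Returns the largest (by enclosed area) closed contour; smaller secondary
    components are reported in the log.
    """
    padded = np.pad(binary.astype(float), 1)  # guarantee closed contours at the border
    contours = measure.find_contours(padded, 0.5)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if not closed:
        raise ValueError(f"no closed {name} contour found")
    areas = []
    for c in closed:
        x, y = c[:, 0], c[:, 1]
        areas.append(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    order = np.argsort(areas)[::-1]
    if len(closed) > 1:
        logger.info(
            "%s region has %d closed boundary components; keeping the largest", name, len(closed)
        )
    c = closed[order[0]][:-1]  # drop duplicated end vertex
    n0, n1 = binary.shape
    # padded index -> patch mm (pixel centers at half-integer offsets from center)
    x_mm = (c[:, 0] - 1 - (n0 - 1) / 2.0) * pixel_mm
    y_mm = (c[:, 1] - 1 - (n1 - 1) / 2.0) * pixel_mm
    return np.column_stack([x_mm, y_mm])


def mask_to_contours(mask: LabelMask) -> ContourPair:
    """Extract sub-pixel inner/outer contours from a 3-class label mask.

    The inner contour is the 0.5 iso-contour of the binary lumen image and
    the outer contour that of the binary vessel (wall or lumen) image; if a
    label splits into several components the largest closed contour is kept.
    """
    labels = mask.labels
    for value, name in ((WALL, "wall"), (LUMEN, "lumen")):
        if not np.any(labels == value):
            raise ValueError(f"mask contains no {name} (label {value}) pixels")
    lumen = labels == LUMEN
    vessel = labels >= WALL
    # restrict to the component structure actually used for the boundary
    inner = _largest_closed_contour(lumen, mask.pixel_mm, "lumen")
    outer = _largest_closed_contour(vessel, mask.pixel_mm, "vessel")
    return ContourPair(inner, outer)


# ---------------------------------------------------------------------------
# plausibility and centroids
# ---------------------------------------------------------------------------

_STRUCT_8 = np.ones((3, 3), dtype=bool)


def plausibility_check(mask: LabelMask) -> PlausibilityResult:
    """Flag implausible segmentations.

    ``lumen_not_enclosed``: some lumen pixel is 4-adjacent to background or
    touches the patch border (the wall cannot be verified outside the field
    of view).  ``multiple_components``: the union of wall and lumen has more
    than one 8-connected component.  An empty lumen or wall is implausible
    with both reasons.
    """
    labels = mask.labels
    lumen = labels == LUMEN
    vessel = labels >= WALL
    reasons: list[str] = []

    if not lumen.any() or not (labels == WALL).any():
        return PlausibilityResult(False, ["lumen_not_enclosed", "multiple_components"])

    background = labels == BACKGROUND
    touches_bg = False
    for shift_axis in (0, 1):
        for direction in (1, -1):
            shifted = np.roll(background, direction, axis=shift_axis)
            # rolled-in edge is not a real neighbour; border contact is
            # handled separately below
            if shift_axis == 0:
                shifted[0 if direction == 1 else -1, :] = False
            else:
                shifted[:, 0 if direction == 1 else -1] = False
            touches_bg |= bool(np.any(lumen & shifted))
    on_border = (
        lumen[0, :].any() or lumen[-1, :].any() or lumen[:, 0].any() or lumen[:, -1].any()
    )
    if touches_bg or on_border:
        reasons.append("lumen_not_enclosed")

    n_components = ndimage.label(vessel, structure=_STRUCT_8)[1]
    if n_components > 1:
        reasons.append("multiple_components")

    return PlausibilityResult(len(reasons) == 0, reasons)


def lumen_mass_center(mask_or_contour: LabelMask | ContourPair | np.ndarray) -> np.ndarray:
    """Mass center of the lumen, in patch mm coordinates.

    Accepts a label mask (pixel centroid of label 2), a contour pair, or a
    bare closed polyline (polygon centroid).  This is the centerpoint used
    when no centerline is available for a cross-section.
    """
    if isinstance(mask_or_contour, LabelMask):
        lumen = mask_or_contour.labels == LUMEN
        if not lumen.any():
            raise ValueError("mask has an empty lumen")
        xx, yy = mask_or_contour.pixel_centers_mm()
        return np.array([xx[lumen].mean(), yy[lumen].mean()])
    if isinstance(mask_or_contour, ContourPair):
        poly = Polygon(mask_or_contour.inner)
    else:
        poly = Polygon(np.asarray(mask_or_contour, dtype=float))
    if poly.area <= 0:
        raise ValueError("degenerate lumen contour")
    c = poly.centroid
    return np.array([c.x, c.y])
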