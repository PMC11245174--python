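"""Clinical quantification: wall thickness profiles, bull's-eye summaries
and agreement statistics.

Vessel wall thickness (VWT) is measured by radial ray casting from the
centerline point: for each angle, a ray is intersected with the inner and
outer wall contour, giving the centerline-to-inner-wall distance and the
inner-to-outer wall thickness along the same ray.  The angular origin is
anatomically anchored (0 deg = anterior, increasing clockwise when viewed
from proximal to distal), so profiles can be labelled A/P/R/L.

Profiles are summarized in a 12-segment bull's-eye (mean per 30 deg sector)
together with the maximal VWT over all rays -- the clinically reported
quantity.  Agreement between two raters/methods is assessed with ICC(3,1)
(two-way mixed effects, single rater, consistency definition) and
Bland-Altman limits of agreement (mean difference +/- 1.96 sd).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation import ContourPair

logger = logging.getLogger(__name__)

N_SEGMENTS = 12


@dataclass
class RayProfile:
    """Per-angle inner radius and wall thickness around a centerpoint.

    ``angles_deg`` cover [0, 360); ``inner_r_mm`` is the distance from the
    centerpoint to the first inner-contour crossing and ``vwt_mm`` the
    distance from that crossing to the outer-contour crossing along the same
    ray.  ``valid`` flags rays where both crossings exist and the inner
    crossing was unique (non-star-shaped lumens are flagged).
    """

    angles_deg: np.ndarray
    inner_r_mm: np.ndarray
    vwt_mm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        for a in ("angles_deg", "inner_r_mm", "vwt_mm", "valid"):
            setattr(self, a, np.asarray(getattr(self, a)))
        if np.any(self.vwt_mm[self.valid] <= 0):
            raise ValueError("wall thickness must be positive on valid rays")


@dataclass
class BullsEye:
    """12-segment summary of a ray profile plus the maximal VWT over rays."""

    segment_vwt_mm: np.ndarray
    segment_inner_mm: np.ndarray
    max_vwt_mm: float
    segment_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.segment_vwt_mm = np.asarray(self.segment_vwt_mm, dtype=float)
        self.segment_inner_mm = np.asarray(self.segment_inner_mm, dtype=float)
        if self.segment_valid is None:
            self.segment_valid = np.ones(N_SEGMENTS, dtype=bool)
        if self.segment_vwt_mm.shape != (N_SEGMENTS,):
            raise ValueError(f"bull's-eye needs exactly {N_SEGMENTS} segments")
        finite = self.segment_vwt_mm[self.segment_valid]
        if finite.size and self.max_vwt_mm < np.nanmax(finite) - 1e-9:
            raise ValueError("max VWT cannot be below any sector mean")


@dataclass
class AgreementStats:
    """ICC and Bland-Altman agreement between paired measurements."""

    icc31: float
    mean_diff: float
    loa_low: float
    loa_high: float

    def __post_init__(self) -> None:
        if not (self.loa_low - 1e-12 <= self.mean_diff <= self.loa_high + 1e-12):
            raise ValueError("limits of agreement must bracket the mean difference")


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


def _ray_crossings(center: np.ndarray, direction: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Sorted positive ray parameters where the ray crosses a closed polyline."""
    p = np.asarray(polyline, dtype=float)
    a = p
    b = np.roll(p, -1, axis=0)
    d = b - a
    # solve center + r*dir = a + t*d for each segment
    denom = direction[0] * (-d[:, 1]) - direction[1] * (-d[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        rhs = a - center[None, :]
        r = (rhs[:, 0] * (-d[:, 1]) - rhs[:, 1] * (-d[:, 0])) / denom
        t = (direction[0] * rhs[:, 1] - direction[1] * rhs[:, 0]) / denom
    # t tolerance: a ray through a shared vertex must not fall between the
    # two incident segments' half-open ranges (duplicates are collapsed below)
    ok = np.isfinite(r) & np.isfinite(t) & (r > 1e-12) & (t >= -1e-9) & (t < 1.0)
    crossings = np.sort(r[ok])
    if crossings.size > 1:
        # a ray through a shared polygon vertex reports the hit once per
        # incident segment; collapse near-identical parameters
        keep = np.concatenate([[True], np.diff(crossings) > 1e-9])
        crossings = crossings[keep]
    return crossings


def ray_profile(cp: ContourPair, center: np.ndarray, n_rays: int = 360) -> RayProfile:
    """Cast ``n_rays`` equiangular rays from ``center`` through both contours.

    The centerpoint must lie inside the inner contour.  For each ray the
    nearest inner crossing gives the inner radius; the first outer crossing
    beyond it gives the wall thickness.  Rays with multiple inner crossings
    (non-star-shaped lumen) use the nearest one and are flagged invalid, as
    are rays without an outer crossing.
    """
    if n_rays < 72:
        raise ValueError("need at least 72 rays for a stable profile")
    center = np.asarray(center, dtype=float)
    import shapely
    from shapely.geometry import Polygon

    if not shapely.contains_xy(Polygon(cp.inner), center[0], center[1]):
        raise ValueError("centerpoint lies outside the inner contour")

    angles = np.arange(n_rays) * 360.0 / n_rays
    inner_r = np.full(n_rays, np.nan)
    vwt = np.full(n_rays, np.nan)
    valid = np.zeros(n_rays, dtype=bool)
    for i, ang in enumerate(angles):
        th = np.deg2rad(ang)
        # 0 deg = anterior (+u), clockwise viewed from proximal to distal
        direction = np.array([np.cos(th), -np.sin(th)])
        ri = _ray_crossings(center, direction, cp.inner)
        ro = _ray_crossings(center, direction, cp.outer)
        if ri.size == 0:
            continue
        inner_r[i] = ri[0]
        beyond = ro[ro > ri[0] + 1e-12]
        if beyond.size == 0:
            continue
        vwt[i] = beyond[0] - ri[0]
        valid[i] = ri.size == 1
    n_flagged = int(np.sum(~valid))
    if n_flagged:
        logger.info("%d of %d rays flagged (no crossing or non-star-shaped lumen)", n_flagged, n_rays)
    return RayProfile(angles, inner_r, vwt, valid)


def bullseye(rp: RayProfile) -> BullsEye:
    """Aggregate a ray profile into 12 sectors of 30 degrees.

    Sector values are means over the sector's valid rays; a sector whose
    rays are all flagged is marked invalid (NaN value).  The maximal VWT is
    taken over individual rays, not sector means.
    """
    seg_vwt = np.full(N_SEGMENTS, np.nan)
    seg_inner = np.full(N_SEGMENTS, np.nan)
    seg_valid = np.zeros(N_SEGMENTS, dtype=bool)
    sector = (rp.angles_deg // 30.0).astype(int) % N_SEGMENTS
    for k in range(N_SEGMENTS):
        m = (sector == k) & rp.valid & np.isfinite(rp.vwt_mm)
        if np.any(m):
            seg_vwt[k] = rp.vwt_mm[m].mean()
            seg_inner[k] = rp.inner_r_mm[m].mean()
            seg_valid[k] = True
        else:
            logger.warning("bull's-eye sector %d has no valid rays", k + 1)
    usable = np.isfinite(rp.vwt_mm)
    max_vwt = float(np.max(rp.vwt_mm[usable])) if usable.any() else float("nan")
    return BullsEye(seg_vwt, seg_inner, max_vwt, seg_valid)


def max_vwt(cp: ContourPair, center: np.ndarray, n_rays: int = 360, method: str = "ray") -> float:
    """Maximal vessel wall thickness of a cross-section, in mm.

    ``method="ray"`` (default) takes the maximum over radial rays from the
    centerpoint, matching the bull's-eye construction.  ``method="nearest"``
    instead takes, for each dense inner-contour sample, the distance to the
    nearest point of the outer contour, and returns the maximum.
    """
    if method == "ray":
        return bullseye(ray_profile(cp, center, n_rays)).max_vwt_mm
    if method == "nearest":
        from .metrics import _point_segment_distances, densify

        pts = densify(cp.inner)
        return float(_point_segment_distances(pts, cp.outer).max())
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------


def icc31(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(3,1): two-way mixed effects, single rater, consistency definition.

    ``x`` and ``y`` are paired measurements of the same n targets by two
    fixed raters (k = 2).  From the two-way ANOVA decomposition,
    ``ICC(3,1) = (MS_rows - MS_error) / (MS_rows + (k-1) MS_error)``.
    Consistency ignores a constant offset between the raters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1D measurement vectors")
    n = len(x)
    if n < 3:
        raise ValueError("ICC needs at least 3 paired measurements")
    data = np.column_stack([x, y])  # n targets x k raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows < 1e-300:
        raise ValueError("zero between-target variance; ICC undefined")
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def bland_altman(x: np.ndarray, y: np.ndarray, icc: float | None = None) -> AgreementStats:
    """Bland-Altman agreement: mean difference and mean +/- 1.96 sd limits.

    The differences are ``x - y``; the standard deviation is the sample sd
    (n - 1 denominator).  If ``icc`` is not supplied it is computed via
    :func:`icc31` when n >= 3, else recorded as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if icc is None:
        try:
            icc = icc31(x, y)
        except ValueError:
            icc = float("nan")
    return AgreementStats(icc, mean, mean - 1.96 * sd, mean + 1.96 * sd)
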