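"""Centerline handling, standardized plane placement and multiplanar reconstruction.

The vessel-wall analysis operates on 2D cross-sections extracted perpendicular
to the carotid centerline.  This module provides the geometric backbone:

* :class:`Centerline` -- an arc-length parametrized 3D polyline with unit
  tangents, branch labels (CCA / ICA / ECA) and named markers (the flow
  diverter ``FD`` at the bifurcation, and an ``ICA`` marker distal to it).
* :class:`PlaneSpec` -- an oriented 2D sampling grid embedded in 3D space.
* :func:`place_planes` -- the standardized 8-plane scheme: two planes in the
  common carotid, five in the internal and one in the external carotid.
* :func:`extract_mpr` -- trilinear multiplanar reconstruction of a 2D patch
  (default 25 mm field of view, 0.195 mm isotropic pixels) from a 3D volume.

Coordinate conventions: world coordinates are in millimetres; patch pixel
``(i, j)`` sits at ``center + (i-(n-1)/2)*pixel_mm*axis_u
+ (j-(n-1)/2)*pixel_mm*axis_v``, i.e. the patch is centered on the centerline
point.  ``axis_u`` is anatomically anchored (projection of the subject's
anterior axis onto the plane) so that angular quantification can be labelled
anterior/posterior/right/left.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

logger = logging.getLogger(__name__)

BRANCHES = ("CCA", "ICA", "ECA")

DEFAULT_FOV_MM = 25.0
DEFAULT_PIXEL_MM = 0.195
# 25 mm / 0.195 mm = 128.2; the grid is 128 px (effective FOV 24.96 mm) so that
# five stride-2 halvings of the segmentation network land on integer sizes.
DEFAULT_N_PX = 128

# Anatomical anchor: +y of the volume frame is treated as the anterior axis.
ANTERIOR_AXIS = np.array([0.0, 1.0, 0.0])


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3D scalar image with isotropic spacing and a world-space origin.

    ``data[i, j, k]`` lies at world position ``origin + spacing * (i, j, k)``
    (axis order x, y, z in mm).
    """

    data: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(points_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing_mm + self.origin_mm

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.eye(4)
        affine[:3, :3] *= self.spacing_mm
        affine[:3, 3] = self.origin_mm
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path) -> "Volume":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        affine = img.affine
        scales = np.linalg.norm(affine[:3, :3], axis=0)
        if not np.allclose(scales, scales[0], rtol=1e-3):
            raise ValueError("only isotropic volumes are supported")
        return cls(np.asarray(img.dataobj, dtype=float), float(scales[0]), affine[:3, 3].copy())


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------


@dataclass
class Centerline:
    """Arc-length parametrized centerline of a bifurcating carotid artery.

    Points are stored as one ordered array (all CCA points, then ICA, then
    ECA); ``branch`` labels each point and ``bifurcation_index`` is the index
    of the first post-bifurcation point.  ``arclength`` is the path distance
    from the proximal CCA origin, monotone within each branch (ICA and ECA
    both restart from the CCA's terminal arc length, so the two daughter
    branches share the bifurcation parameter).  ``markers`` maps names such as
    ``"FD"`` (flow diverter, the bifurcation landmark anchoring the eight
    standardized planes) and ``"ICA"`` to arc lengths.
    """

    points: np.ndarray
    tangents: np.ndarray
    arclength: np.ndarray
    branch: np.ndarray
    bifurcation_index: int
    markers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.branch = np.asarray(self.branch)
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("tangents must be unit-norm")
        for b in self.present_branches():
            s = self.arclength[self.branch == b]
            if np.any(np.diff(s) <= 0):
                raise ValueError(f"arclength not strictly increasing on branch {b}")

    def present_branches(self) -> list[str]:
        return [b for b in BRANCHES if np.any(self.branch == b)]

    def branch_arrays(self, branch: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = self.branch == branch
        if not np.any(m):
            raise KeyError(f"branch {branch!r} not present")
        return self.points[m], self.tangents[m], self.arclength[m]

    def branch_range(self, branch: str) -> tuple[float, float]:
        _, _, s = self.branch_arrays(branch)
        return float(s[0]), float(s[-1])

    def _interp(self, branch: str, s: float, values: np.ndarray, arclen: np.ndarray) -> np.ndarray:
        lo, hi = arclen[0], arclen[-1]
        if s < lo - 1e-9 or s > hi + 1e-9:
            raise ValueError(
                f"arc length {s:.3f} mm outside branch {branch} range [{lo:.3f}, {hi:.3f}]"
            )
        s = float(np.clip(s, lo, hi))
        out = np.empty(values.shape[1])
        for d in range(values.shape[1]):
            out[d] = np.interp(s, arclen, values[:, d])
        return out

    def point_at(self, branch: str, s: float) -> np.ndarray:
        pts, _, arclen = self.branch_arrays(branch)
        return self._interp(branch, s, pts, arclen)

    def tangent_at(self, branch: str, s: float) -> np.ndarray:
        _, tan, arclen = self.branch_arrays(branch)
        t = self._interp(branch, s, tan, arclen)
        return t / np.linalg.norm(t)

    def to_json(self) -> str:
        return json.dumps(
            {
                "points": self.points.tolist(),
                "tangents": self.tangents.tolist(),
                "arclength": self.arclength.tolist(),
                "branch": self.branch.tolist(),
                "bifurcation_index": int(self.bifurcation_index),
                "markers": {k: float(v) for k, v in self.markers.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Centerline":
        d = json.loads(text)
        return cls(
            np.asarray(d["points"]),
            np.asarray(d["tangents"]),
            np.asarray(d["arclength"]),
            np.asarray(d["branch"]),
            int(d["bifurcation_index"]),
            {k: float(v) for k, v in d["markers"].items()},
        )


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_branch(points: np.ndarray, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample one branch polyline at equal arc-length spacing.

    Returns (points, per-point arc length from the branch start).  Tangents
    are computed afterwards by central differences.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ValueError("need at least two 3D points per branch")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg < 1e-12):
        raise ValueError("duplicate consecutive centerline points")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / step_mm)), 1)
    new_s = np.linspace(0.0, total, n + 1)
    new_pts = np.column_stack([np.interp(new_s, s, points[:, d]) for d in range(3)])
    return new_pts, new_s


def _central_diff_tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def resample_centerline(
    raw_points: np.ndarray | Mapping[str, np.ndarray],
    step_mm: float = 0.5,
    markers: Mapping[str, float] | None = None,
) -> Centerline:
    """Resample raw centerline points to equal arc-length spacing ``step_mm``.

    ``raw_points`` is either a single ``(N, 3)`` array (treated as a pure CCA
    segment) or a mapping with keys among ``{"CCA", "ICA", "ECA"}``; daughter
    branches are expected to start at (or near) the CCA's distal end.  Unit
    tangents are estimated by central differences.  The ``FD`` marker defaults
    to the bifurcation arc length when a bifurcation is present.
    """
    if isinstance(raw_points, np.ndarray) or (
        not isinstance(raw_points, Mapping) and np.ndim(raw_points) == 2
    ):
        raw_points = {"CCA": np.asarray(raw_points)}
    if "CCA" not in raw_points:
        raise ValueError("a CCA branch is required")

    all_pts, all_tan, all_s, all_branch = [], [], [], []
    cca_pts, cca_s = _resample_branch(raw_points["CCA"], step_mm)
    cca_end = cca_s[-1]
    all_pts.append(cca_pts)
    all_tan.append(_central_diff_tangents(cca_pts))
    all_s.append(cca_s)
    all_branch.append(np.full(len(cca_pts), "CCA"))
    bifurcation_index = len(cca_pts)

    for b in ("ICA", "ECA"):
        if b in raw_points:
            pts, s = _resample_branch(np.asarray(raw_points[b]), step_mm)
            # daughter branches share the bifurcation parameter; drop the
            # duplicated junction point
            all_pts.append(pts[1:])
            all_tan.append(_central_diff_tangents(pts)[1:])
            all_s.append(s[1:] + cca_end)
            all_branch.append(np.full(len(pts) - 1, b))

    marker_dict = dict(markers or {})
    if len(all_pts) > 1:
        marker_dict.setdefault("FD", float(cca_end))

    return Centerline(
        np.concatenate(all_pts),
        np.concatenate(all_tan),
        np.concatenate(all_s),
        np.concatenate(all_branch),
        bifurcation_index,
        marker_dict,
    )


# ---------------------------------------------------------------------------
# planes
# ---------------------------------------------------------------------------


@dataclass
class PlaneSpec:
    """An oriented square sampling grid in 3D space.

    ``{axis_u, axis_v, normal}`` form a right-handed orthonormal triad with
    ``normal`` equal to the local centerline tangent; ``axis_u`` is the
    in-plane projection of the anterior axis so the patch frame is
    anatomically anchored.  Pixel ``(i, j)`` of the ``n_px`` x ``n_px`` grid
    lies at ``center + (i-(n-1)/2)*pixel_mm*axis_u + (j-(n-1)/2)*pixel_mm*axis_v``.
    """

    center: np.ndarray
    normal: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    fov_mm: float = DEFAULT_FOV_MM
    pixel_mm: float = DEFAULT_PIXEL_MM
    n_px: int = DEFAULT_N_PX
    plane_id: int | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.axis_u = np.asarray(self.axis_u, dtype=float)
        self.axis_v = np.asarray(self.axis_v, dtype=float)
        for v in (self.normal, self.axis_u, self.axis_v):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError("frame vectors must be unit-norm")
        if abs(self.axis_u @ self.normal) > 1e-6 or abs(self.axis_v @ self.normal) > 1e-6:
            raise ValueError("axes must be orthogonal to the normal")
        if np.linalg.norm(np.cross(self.axis_u, self.axis_v) - self.normal) > 1e-6:
            raise ValueError("{axis_u, axis_v, normal} must be right-handed")
        if self.n_px * self.pixel_mm > self.fov_mm + self.pixel_mm + 1e-9:
            raise ValueError("pixel grid exceeds the field of view")

    def pixel_world_positions(self) -> np.ndarray:
        """World positions of all pixel centers, shape (n_px, n_px, 3)."""
        half = (self.n_px - 1) / 2.0
        ij = (np.arange(self.n_px) - half) * self.pixel_mm
        uu = ij[:, None, None] * self.axis_u[None, None, :]
        vv = ij[None, :, None] * self.axis_v[None, None, :]
        return self.center[None, None, :] + uu + vv

    def pixel_to_mm(self, ij: np.ndarray) -> np.ndarray:
        """Fractional pixel indices (i, j) -> in-plane mm coordinates (u, v)."""
        half = (self.n_px - 1) / 2.0
        return (np.asarray(ij, dtype=float) - half) * self.pixel_mm

    def mm_to_pixel(self, uv: np.ndarray) -> np.ndarray:
        half = (self.n_px - 1) / 2.0
        return np.asarray(uv, dtype=float) / self.pixel_mm + half

    def world_of_mm(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return self.center + uv[:, :1] * self.axis_u + uv[:, 1:2] * self.axis_v

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "normal": self.normal.tolist(),
            "axis_u": self.axis_u.tolist(),
            "axis_v": self.axis_v.tolist(),
            "fov_mm": self.fov_mm,
            "pixel_mm": self.pixel_mm,
            "n_px": self.n_px,
            "plane_id": self.plane_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneSpec":
        return cls(
            np.asarray(d["center"]),
            np.asarray(d["normal"]),
            np.asarray(d["axis_u"]),
            np.asarray(d["axis_v"]),
            float(d["fov_mm"]),
            float(d["pixel_mm"]),
            int(d["n_px"]),
            d.get("plane_id"),
        )


@dataclass
class CrossSection:
    """A 2D patch resampled on a :class:`PlaneSpec` grid."""

    image: np.ndarray
    plane: PlaneSpec
    normalized: bool = False

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.shape != (self.plane.n_px, self.plane.n_px):
            raise ValueError("image shape does not match the plane grid")


def plane_frame(
    centerline: Centerline,
    s: float,
    up_hint: np.ndarray = ANTERIOR_AXIS,
    branch: str = "CCA",
    **plane_kwargs,
) -> PlaneSpec:
    """Build the perpendicular plane at arc length ``s`` on ``branch``.

    The plane normal is the local tangent; ``axis_u`` is the Gram-Schmidt
    projection of ``up_hint`` (default: the anterior axis) onto the plane and
    ``axis_v = normal x axis_u`` completes the right-handed triad.  If the
    hint is (near) parallel to the tangent an alternate axis is substituted
    with a warning.
    """
    normal = centerline.tangent_at(branch, s)
    center = centerline.point_at(branch, s)
    up = np.asarray(up_hint, dtype=float)
    up = up / np.linalg.norm(up)
    if abs(up @ normal) > 0.999:
        logger.warning(
            "up hint %s nearly parallel to tangent at s=%.2f; using fallback axis", up, s
        )
        alternates = np.eye(3)
        up = alternates[int(np.argmin(np.abs(normal)))]
    axis_u = up - (up @ normal) * normal
    axis_u = axis_u / np.linalg.norm(axis_u)
    axis_v = np.cross(normal, axis_u)
    return PlaneSpec(center, normal, axis_u, axis_v, **plane_kwargs)


DEFAULT_PLANE_OFFSETS: dict[str, tuple[float, ...]] = {
    # offsets in mm relative to the FD marker: CCA planes proximal (negative
    # direction along the CCA), ICA/ECA planes distal to the bifurcation
    "CCA": (10.0, 5.0),
    "ICA": (2.5, 5.0, 7.5, 10.0, 15.0),
    "ECA": (5.0,),
}


def place_planes(
    centerline: Centerline,
    offsets: Mapping[str, Sequence[float]] | None = None,
    **plane_kwargs,
) -> list[PlaneSpec]:
    """Place the eight standardized analysis planes on a carotid centerline.

    Two planes in the CCA (proximal to the flow diverter), five in the ICA
    and one in the ECA, each perpendicular to the local tangent.  Plane ids
    run 1..8 from the proximal CCA to the distal ICA, with the ECA plane
    last.  Offsets (mm from the FD marker) are configurable per branch.
    """
    if "FD" not in centerline.markers:
        raise ValueError("centerline needs an FD marker to place planes")
    offsets = dict(DEFAULT_PLANE_OFFSETS if offsets is None else offsets)
    fd = centerline.markers["FD"]

    planes: list[PlaneSpec] = []
    plane_id = 1
    for branch, sign in (("CCA", -1.0), ("ICA", +1.0), ("ECA", +1.0)):
        lo, hi = centerline.branch_range(branch)
        for off in offsets[branch]:
            s = fd + sign * off
            if s < lo - 1e-9 or s > hi + 1e-9:
                raise ValueError(
                    f"branch {branch} too short for a plane {off:.1f} mm "
                    f"{'proximal' if sign < 0 else 'distal'} to the FD"
                )
            planes.append(
                replace(
                    plane_frame(centerline, s, branch=branch, **plane_kwargs),
                    plane_id=plane_id,
                )
            )
            plane_id += 1
    if len(planes) != 8:
        raise ValueError(f"expected 8 planes, got {len(planes)}")
    return planes


def place_stenosis_plane(
    centerline: Centerline,
    thickness_profile: Callable[[str, float], float],
    **plane_kwargs,
) -> PlaneSpec:
    """Place one plane at the arc length of maximal wall thickness.

    ``thickness_profile(branch, s)`` is evaluated at every centerline sample;
    ties pick the most proximal maximizer (a flat profile therefore yields
    the proximal end, with a log entry).
    """
    best: tuple[float, str, float] | None = None
    tie = False
    for branch in centerline.present_branches():
        _, _, arclen = centerline.branch_arrays(branch)
        for s in arclen:
            t = float(thickness_profile(branch, float(s)))
            if best is None or t > best[0] + 1e-12:
                best = (t, branch, float(s))
            elif abs(t - best[0]) <= 1e-12:
                tie = True
    assert best is not None
    if tie:
        logger.info(
            "thickness profile has ties; keeping the most proximal maximum "
            "(branch %s, s=%.2f mm)",
            best[1],
            best[2],
        )
    return plane_frame(centerline, best[2], branch=best[1], **plane_kwargs)


# ---------------------------------------------------------------------------
# multiplanar reconstruction
# ---------------------------------------------------------------------------


def extract_mpr(volume: Volume, plane: PlaneSpec, mode: str = "linear") -> CrossSection:
    """Resample a 2D cross-section of ``volume`` on the plane's pixel grid.

    ``mode="linear"`` uses trilinear interpolation (exact on linear intensity
    fields); ``mode="nearest"`` is for integer label volumes.  Pixels whose
    sampling point falls outside the volume are filled with 0.
    """
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("volume contains non-finite voxels")
    order = {"linear": 1, "nearest": 0}[mode]
    pos = plane.pixel_world_positions()
    idx = volume.world_to_index(pos.reshape(-1, 3)).T  # (3, n*n)
    out_of_bounds = np.any((idx < -0.5) | (idx > np.array(volume.data.shape)[:, None] - 0.5), axis=0)
    img = map_coordinates(
        np.asarray(volume.data, dtype=float), idx, order=order, mode="constant", cval=0.0
    ).reshape(plane.n_px, plane.n_px)
    if np.any(out_of_bounds):
        logger.warning(
            "%d / %d MPR pixels sampled outside the volume (filled with 0)",
            int(out_of_bounds.sum()),
            out_of_bounds.size,
        )
    return CrossSection(img, plane, normalized=False)


def normalize_patch(cs: CrossSection) -> CrossSection:
    """Normalize a cross-section to zero mean / unit standard deviation.

    A (near-)constant patch carries no contrast; it is returned as all zeros
    with a warning instead of dividing by a vanishing spread.
    """
    img = np.asarray(cs.image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("patch contains non-finite pixels")
    std = img.std()
    if std < 1e-8:
        logger.warning("constant patch; normalization returns zeros")
        return CrossSection(np.zeros_like(img), cs.plane, normalized=True)
    return CrossSection((img - img.mean()) / std, cs.plane, normalized=True)
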