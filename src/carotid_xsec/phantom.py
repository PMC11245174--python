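"""Synthetic black-blood-MRI-like phantoms of a bifurcating carotid artery.

The phantom is a bifurcating tube (CCA splitting into ICA and ECA) rendered
into a 3D volume with the intensity ordering of T1-weighted black-blood MRI:
dark lumen (suppressed blood), brighter wall, intermediate background.  Every
phantom carries exact analytic ground truth -- the centerline and a per-plane
contour function -- so the whole segmentation and quantification pipeline can
be tested without patient data.

Geometry: each branch is a straight tube segment; the vessel is the union of
the three tube distance fields, which keeps the bifurcation watertight
without any mesh modelling.  Lumen radius and wall thickness are functions of
the signed arc length from the flow diverter (FD, the bifurcation landmark;
negative = proximal CCA) and, for the thickness, optionally of the angular
position -- which supports eccentric walls and focal stenosis bumps.

Rendering is partial-volume aware: each voxel is supersampled (default 3x3x3)
and the mean tissue intensity is taken, so edges are soft like MRI rather
than binary.  Noise is additive Gaussian.  Two confound types seen in real
black-blood MRI can be injected: bright flow artifacts inside the lumen and
dark calcifications inside the wall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .geometry import (
    ANTERIOR_AXIS,
    Centerline,
    PlaneSpec,
    Volume,
    resample_centerline,
)

# Intensity ordering mimics black-blood contrast: lumen < background < wall.
DEFAULT_INTENSITY_LEVELS = {"background": 0.3, "wall": 0.7, "lumen": 0.1}

# Radius and thickness functions are vectorized: ``s`` (signed arc length
# from the FD, mm) and ``theta`` (angular position, rad) may be arrays and
# broadcast against each other.
RadiusFn = Callable[[str, "float | np.ndarray"], "float | np.ndarray"]
ThicknessFn = Callable[[str, "float | np.ndarray", "float | np.ndarray"], np.ndarray]


def constant_radius(r_mm: float) -> RadiusFn:
    def fn(branch, s):
        return np.full_like(np.asarray(s, dtype=float), r_mm)

    return fn


def tapered_radius(r_cca: float, r_ica: float, r_eca: float, taper_mm: float = 10.0) -> RadiusFn:
    """CCA radius tapering linearly into the daughter-branch radii."""

    def fn(branch, s):
        s = np.asarray(s, dtype=float)
        if branch == "CCA":
            return np.full_like(s, r_cca)
        target = r_ica if branch == "ICA" else r_eca
        f = np.clip(s / taper_mm, 0.0, 1.0)
        return (1 - f) * r_cca + f * target

    return fn


def constant_thickness(t_mm: float) -> ThicknessFn:
    def fn(branch, s, theta):
        shape = np.broadcast_shapes(np.shape(s), np.shape(theta))
        return np.full(shape, t_mm)

    return fn


def stenosis_thickness(
    base_mm: float,
    bump_mm: float = 0.0,
    bump_branch: str = "ICA",
    bump_center_s_mm: float = 5.0,
    bump_width_mm: float = 4.0,
    bump_theta_deg: float | None = None,
    bump_theta_width_deg: float = 90.0,
) -> ThicknessFn:
    """Wall thickness with an optional Gaussian focal thickening (stenosis).

    The bump peaks at ``base_mm + bump_mm`` at arc length ``bump_center_s_mm``
    on ``bump_branch``.  If ``bump_theta_deg`` is given the thickening is
    eccentric, concentrated around that angular position; otherwise it is
    circumferential.
    """

    def fn(branch, s, theta):
        s = np.asarray(s, dtype=float)
        theta = np.asarray(theta, dtype=float)
        t = np.full(np.broadcast_shapes(s.shape, theta.shape), base_mm)
        if bump_mm > 0 and branch == bump_branch:
            g = np.exp(-0.5 * ((s - bump_center_s_mm) / (bump_width_mm / 2.0)) ** 2)
            if bump_theta_deg is None:
                ang = 1.0
            else:
                d = np.angle(np.exp(1j * (theta - np.deg2rad(bump_theta_deg))))
                ang = np.exp(-0.5 * (d / np.deg2rad(bump_theta_width_deg / 2.0)) ** 2)
            t = t + bump_mm * g * ang
        return t

    return fn


@dataclass
class ArtifactSpec:
    """A localized image confound.

    ``flow_artifact``: residual bright blood signal inside the lumen (mimics
    wall tissue); ``calcification``: dark plaque component inside the wall
    (mimics lumen).  The blob is a Gaussian intensity shift of spatial scale
    ``size_mm`` at the given branch arc length (from the FD) and angular
    position, masked to its host region so it never leaks outside it.
    """

    kind: str
    branch: str = "ICA"
    center_arclength_mm: float = 5.0
    angular_position_deg: float = 0.0
    size_mm: float = 1.2
    intensity_delta: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("flow_artifact", "calcification"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")


@dataclass
class PhantomSpec:
    """Full description of a synthetic carotid phantom.

    The default geometry is a 38 x 38 x 50 mm volume at 0.6 mm isotropic
    spacing containing a CCA that bifurcates into a slightly tilted ICA and
    ECA.  ``lumen_radius_mm(branch, s)`` and
    ``wall_thickness_mm(branch, s, theta)`` take the signed arc length from
    the FD in mm (negative proximal).  Identical spec + seed produces a
    bit-identical volume.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 84)
    voxel_size_mm: float = 0.6
    lumen_radius_mm: RadiusFn = field(default_factory=lambda: constant_radius(3.0))
    wall_thickness_mm: ThicknessFn = field(default_factory=lambda: constant_thickness(1.0))
    bifurcation_point_mm: tuple[float, float, float] = (19.2, 19.2, 20.0)
    branch_directions: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "CCA": (0.0, 0.0, 1.0),
            "ICA": (0.12, 0.05, 0.99),
            "ECA": (-0.38, -0.12, 0.92),
        }
    )
    # daughter branches sprout from laterally offset points at the flow
    # divider, as at a real carotid bifurcation: the two lumens are separate
    # immediately distal to the FD instead of interpenetrating
    branch_offsets_mm: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ICA": (2.2, 0.7, 0.4),
            "ECA": (-2.6, -0.8, 0.4),
        }
    )
    branch_lengths_mm: Mapping[str, float] = field(
        default_factory=lambda: {"CCA": 16.0, "ICA": 18.0, "ECA": 10.0}
    )
    intensity_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_LEVELS)
    )
    noise_sigma: float = 0.03
    artifacts: Sequence[ArtifactSpec] = field(default_factory=tuple)
    supersample: int = 3
    centerline_step_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.intensity_levels["lumen"] >= self.intensity_levels["wall"]:
            raise ValueError("black-blood contrast requires lumen mean < wall mean")
        if self.supersample < 1:
            raise ValueError("supersample factor must be >= 1")

    # -- branch geometry ----------------------------------------------------

    def branch_segment(self, branch: str) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) world points of a branch's straight axis segment."""
        bif = np.asarray(self.bifurcation_point_mm, dtype=float)
        d = np.asarray(self.branch_directions[branch], dtype=float)
        d = d / np.linalg.norm(d)
        length = self.branch_lengths_mm[branch]
        if branch == "CCA":
            return bif - length * d, bif
        start = bif + np.asarray(self.branch_offsets_mm.get(branch, (0.0, 0.0, 0.0)), dtype=float)
        return start, start + length * d

    def branch_frame(self, branch: str) -> tuple[np.ndarray, np.ndarray]:
        """In-plane (u, v) axes perpendicular to a branch, anterior-anchored."""
        d = np.asarray(self.branch_directions[branch], dtype=float)
        d = d / np.linalg.norm(d)
        up = ANTERIOR_AXIS
        if abs(up @ d) > 0.999:
            up = np.array([1.0, 0.0, 0.0])
        u = up - (up @ d) * d
        u = u / np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v

    def centerline(self) -> Centerline:
        raw = {}
        for b in ("CCA", "ICA", "ECA"):
            a, e = self.branch_segment(b)
            raw[b] = np.array([a, e])
        cl = resample_centerline(raw, self.centerline_step_mm)
        cl.markers["ICA"] = cl.markers["FD"] + self.branch_lengths_mm["ICA"]
        return cl


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a rendered phantom."""

    spec: PhantomSpec
    centerline: Centerline

    def radii_at(
        self, branch: str, s_from_fd: float, theta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Inner and outer tube radius at angular positions ``theta`` (rad)."""
        theta = np.asarray(theta, dtype=float)
        inner = float(self.spec.lumen_radius_mm(branch, s_from_fd))
        outer = inner + self.spec.wall_thickness_mm(branch, s_from_fd, theta)
        return np.full_like(theta, inner), outer

    def locate_plane(self, plane: PlaneSpec, tol_mm: float = 0.5) -> tuple[str, float]:
        """Find (branch, signed arc length from FD) of a plane center."""
        cl = self.centerline
        d = np.linalg.norm(cl.points - plane.center, axis=1)
        i = int(np.argmin(d))
        if d[i] > tol_mm:
            raise ValueError("plane center does not lie on the phantom centerline")
        branch = str(cl.branch[i])
        tangent = cl.tangents[i]
        if abs(float(plane.normal @ tangent)) < 0.995:
            raise ValueError("plane is not perpendicular to the local centerline tangent")
        return branch, float(cl.arclength[i] - cl.markers["FD"])

    def to_json(self, n_samples: int = 64) -> str:
        """Serialize the truth as centerline + radius/thickness samples."""
        samples = []
        cl = self.centerline
        for b in cl.present_branches():
            _, _, arclen = cl.branch_arrays(b)
            for s in np.linspace(arclen[0], arclen[-1], min(n_samples, len(arclen))):
                sf = float(s - cl.markers["FD"])
                r = float(self.spec.lumen_radius_mm(b, sf))
                t = float(np.mean(self.spec.wall_thickness_mm(b, sf, np.linspace(0, 2 * np.pi, 32))))
                samples.append({"branch": b, "s_from_fd_mm": sf, "inner_r_mm": r, "mean_vwt_mm": t})
        return json.dumps({"centerline": json.loads(self.centerline.to_json()), "samples": samples})


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _segment_geometry(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance to segment ab, axial parameter (mm from a) and radial vector."""
    d = b - a
    length = np.linalg.norm(d)
    d = d / length
    w = points - a
    t = np.clip(w @ d, 0.0, length)
    closest = a + t[:, None] * d
    radial = points - closest
    return np.linalg.norm(radial, axis=1), t, radial


def _labels_at(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Analytic tissue label (0 bg, 1 wall, 2 lumen) at arbitrary points.

    The vessel is the union of the three straight-tube distance fields; a
    point is lumen if inside any branch's inner radius, else wall if inside
    any branch's outer radius.
    """
    labels = np.zeros(len(points), dtype=np.uint8)
    fd_len = spec.branch_lengths_mm["CCA"]
    for branch in ("CCA", "ICA", "ECA"):
        a, b = spec.branch_segment(branch)
        dist, t, radial = _segment_geometry(points, a, b)
        s_from_fd = t - fd_len if branch == "CCA" else t
        u, v = spec.branch_frame(branch)
        theta = np.arctan2(-(radial @ v), radial @ u)
        inner = np.asarray(spec.lumen_radius_mm(branch, s_from_fd), dtype=float)
        outer = inner + spec.wall_thickness_mm(branch, s_from_fd, theta)
        labels = np.maximum(
            labels, np.where(dist < inner, 2, np.where(dist < outer, 1, 0)).astype(np.uint8)
        )
    return labels


def _check_bounds(spec: PhantomSpec) -> None:
    extent = np.array(spec.volume_shape) * spec.voxel_size_mm
    theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    fd_len = spec.branch_lengths_mm["CCA"]
    for branch in ("CCA", "ICA", "ECA"):
        a, b = spec.branch_segment(branch)
        u, v = spec.branch_frame(branch)
        for f in np.linspace(0, 1, 21):
            p = a + f * (b - a)
            t_ax = f * spec.branch_lengths_mm[branch]
            s = t_ax - fd_len if branch == "CCA" else t_ax
            r = float(spec.lumen_radius_mm(branch, s))
            outer = r + np.max(spec.wall_thickness_mm(branch, s, theta))
            ring = p[None, :] + outer * (
                np.cos(theta)[:, None] * u[None, :] - np.sin(theta)[:, None] * v[None, :]
            )
            if np.any(ring < -1e-9) or np.any(ring > extent[None, :] + 1e-9):
                raise ValueError(
                    f"vessel outer wall exceeds volume bounds on branch {branch} "
                    f"at arc length {s:.1f} mm from the FD"
                )


def _artifact_center(spec: PhantomSpec, art: ArtifactSpec) -> np.ndarray:
    """World position of an artifact blob, inside its host region."""
    a, b = spec.branch_segment(art.branch)
    d = (b - a) / np.linalg.norm(b - a)
    fd_len = spec.branch_lengths_mm["CCA"]
    t_ax = art.center_arclength_mm + (fd_len if art.branch == "CCA" else 0.0)
    t_ax = np.clip(t_ax, 0.0, spec.branch_lengths_mm[art.branch])
    p = a + t_ax * d
    u, v = spec.branch_frame(art.branch)
    theta = np.deg2rad(art.angular_position_deg)
    ray = np.cos(theta) * u - np.sin(theta) * v
    r = float(spec.lumen_radius_mm(art.branch, art.center_arclength_mm))
    th = float(
        np.mean(spec.wall_thickness_mm(art.branch, art.center_arclength_mm, np.array([theta])))
    )
    if art.kind == "flow_artifact":
        radial = max(r - art.size_mm, 0.0) * 0.7  # keep the blob well inside the lumen
    else:
        radial = r + th / 2.0  # mid-wall
    return p + radial * ray


def make_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Render a phantom volume and return it with its analytic ground truth.

    Each voxel is supersampled ``spec.supersample`` times per axis and the
    mean of the tissue intensity levels is taken (soft, partial-volume
    edges).  Artifacts are applied after base rendering, masked to their
    host region; Gaussian noise (``noise_sigma``) is added last.  The same
    spec and seed always produce a bit-identical volume.
    """
    _check_bounds(spec)
    shape = tuple(int(n) for n in spec.volume_shape)
    ss = spec.supersample
    vox = spec.voxel_size_mm
    levels = np.array(
        [
            spec.intensity_levels["background"],
            spec.intensity_levels["wall"],
            spec.intensity_levels["lumen"],
        ]
    )

    # fine-grid offsets inside one voxel (voxel center at index * vox)
    off = (np.arange(ss) + 0.5) / ss - 0.5
    intens = np.empty(shape, dtype=float)
    iy = np.arange(shape[1]) * vox
    iz = np.arange(shape[2]) * vox
    for ix in range(shape[0]):  # slab by slab to bound memory
        x = ix * vox + off * vox
        gx, gy, gz = np.meshgrid(
            x, (iy[:, None] + off[None, :] * vox).ravel(), (iz[:, None] + off[None, :] * vox).ravel(),
            indexing="ij",
        )
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        lab = _labels_at(spec, pts).reshape(ss, shape[1], ss, shape[2], ss)
        lvl = levels[lab]
        intens[ix] = lvl.mean(axis=(0, 2, 4))

    # artifacts: Gaussian intensity shifts masked to their host tissue label
    if spec.artifacts:
        centers = np.stack(
            np.meshgrid(
                np.arange(shape[0]) * vox,
                np.arange(shape[1]) * vox,
                np.arange(shape[2]) * vox,
                indexing="ij",
            ),
            axis=-1,
        )
        voxel_labels = _labels_at(spec, centers.reshape(-1, 3)).reshape(shape)
        for art in spec.artifacts:
            c = _artifact_center(spec, art)
            d2 = np.sum((centers - c) ** 2, axis=-1)
            blob = art.intensity_delta * np.exp(-0.5 * d2 / (art.size_mm / 2.0) ** 2)
            host = 2 if art.kind == "flow_artifact" else 1
            intens = np.where(voxel_labels == host, intens + blob, intens)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        intens = intens + rng.normal(0.0, spec.noise_sigma, size=shape)

    vol = Volume(intens, vox)
    return vol, PhantomTruth(spec, spec.centerline())


def label_volume(spec: PhantomSpec) -> Volume:
    """Voxel-center tissue labels (0 bg, 1 wall, 2 lumen) of a phantom."""
    shape = tuple(int(n) for n in spec.volume_shape)
    vox = spec.voxel_size_mm
    grid = np.stack(
        np.meshgrid(
            np.arange(shape[0]) * vox,
            np.arange(shape[1]) * vox,
            np.arange(shape[2]) * vox,
            indexing="ij",
        ),
        axis=-1,
    )
    labels = _labels_at(spec, grid.reshape(-1, 3)).reshape(shape)
    return Volume(labels.astype(np.uint8), vox)


def truth_contours(truth: PhantomTruth, plane: PlaneSpec, n_vertices: int = 120):
    """Exact inner/outer wall contours of a phantom on an analysis plane.

    The plane center must lie on a branch centerline and the plane must be
    perpendicular to the local tangent.  Contour vertices are returned in
    patch mm coordinates (closed polylines, ``n_vertices`` each).
    """
    from .annotation import ContourPair  # local import to avoid a cycle

    if n_vertices < 90:
        raise ValueError("contours are sampled at >= 90 vertices")
    branch, s = truth.locate_plane(plane)
    spec = truth.spec
    u, v = spec.branch_frame(branch)
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    inner_r, outer_r = truth.radii_at(branch, s, theta)
    ray = np.cos(theta)[:, None] * u[None, :] - np.sin(theta)[:, None] * v[None, :]
    axis_pt = truth.centerline.point_at(branch, s + truth.centerline.markers["FD"])
    inner_w = axis_pt[None, :] + inner_r[:, None] * ray
    outer_w = axis_pt[None, :] + outer_r[:, None] * ray

    def project(pts_w: np.ndarray) -> np.ndarray:
        rel = pts_w - plane.center[None, :]
        return np.column_stack([rel @ plane.axis_u, rel @ plane.axis_v])

    return ContourPair(project(inner_w), project(outer_w))
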