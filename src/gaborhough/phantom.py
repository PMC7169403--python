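"""Synthetic echocardiography-like phantoms with known ground truth.

Clinical echocardiographic stills cannot be redistributed, so this module
generates seeded stand-ins that reproduce the image features the marking
pipeline relies on: a dark fan-shaped scan sector on a black background, a
dark crescent/elliptical left-ventricular cavity bounded by a brighter
myocardial wall whose septal (left) side is better visualized than its
lateral (right) side, multiplicative speckle-like noise, and a known affine
pose (translation, rotation, anisotropic scale) of the ground-truth
endocardial boundary.

The speckle model is deliberately simple — the clean image multiplied by
``1 + speckle_scale * n`` where ``n`` is a smoothed unit-variance Gaussian
field — and makes no claim of physical fidelity; it is visually speckle-like
and fully seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .ght import PoseParameters
from .template import GuidedTemplate, apply_pose, canonical_lv_template

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "InvalidSpecError",
    "generate_phantom",
    "boundary_error",
    "write_phantom",
]

# intensity levels (8-bit) of the clean phantom
_BACKGROUND = 8.0
_SECTOR = 55.0
_CAVITY = 22.0
_WALL = 210.0


class InvalidSpecError(ValueError):
    """Raised when the posed cavity does not fit inside the scan sector."""


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs give identical images."""

    image_size: tuple[int, int] = (256, 256)  # (H, W)
    sector_apex: tuple[float, float] = (128.0, 8.0)  # (x, y)
    sector_angle: float = 1.4  # full opening angle, radians
    sector_radius: float | None = None  # default 0.92 * H
    cavity_center: tuple[float, float] = (128.0, 130.0)
    cavity_axes: tuple[float, float] = (40.0, 55.0)  # semi-axes (a, b)
    wall_thickness: float = 12.0
    pose: PoseParameters | None = None  # None = identity
    speckle_scale: float = 0.0
    lateral_attenuation: float = 0.0
    n_distractors: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise InvalidSpecError("image_size must be positive")
        if self.speckle_scale < 0:
            raise InvalidSpecError("speckle_scale must be >= 0")
        if not (0.0 <= self.lateral_attenuation <= 1.0):
            raise InvalidSpecError("lateral_attenuation must lie in [0, 1]")

    @property
    def radius(self) -> float:
        return self.sector_radius or 0.92 * self.image_size[0]


@dataclass
class GroundTruth:
    """True endocardial boundary of a phantom, with its pose and limbs."""

    boundary: np.ndarray  # (N, 2) subpixel (x, y)
    pose: PoseParameters
    septal_polyline: np.ndarray
    lateral_polyline: np.ndarray

    def to_dict(self) -> dict:
        return {
            "boundary": self.boundary.tolist(),
            "pose": self.pose.to_dict(),
            "septal_polyline": self.septal_polyline.tolist(),
            "lateral_polyline": self.lateral_polyline.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            np.array(d["boundary"], dtype=float),
            PoseParameters.from_dict(d["pose"]),
            np.array(d["septal_polyline"], dtype=float),
            np.array(d["lateral_polyline"], dtype=float),
        )


def phantom_template(spec: PhantomSpec, lateral_halfwidth: float = 6.0) -> GuidedTemplate:
    """The canonical guided template matching a phantom's cavity geometry."""
    return canonical_lv_template(
        cavity_center=spec.cavity_center,
        cavity_axes=spec.cavity_axes,
        lateral_halfwidth=lateral_halfwidth,
    )


def _sector_mask(spec: PhantomSpec, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    ax, ay = spec.sector_apex
    dx, dy = xx - ax, yy - ay
    rad = np.hypot(dx, dy)
    # beam axis points straight down (+y); angle measured from it
    ang = np.abs(np.arctan2(dx, dy))
    return (ang <= spec.sector_angle / 2) & (rad <= spec.radius) & (dy >= 0)


def _in_sector(spec: PhantomSpec, pts: np.ndarray, margin: float) -> np.ndarray:
    ax, ay = spec.sector_apex
    d = pts - np.array([ax, ay])
    rad = np.hypot(d[:, 0], d[:, 1])
    ang = np.abs(np.arctan2(d[:, 0], d[:, 1]))
    half = spec.sector_angle / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ang_margin = np.where(rad > 0, margin / rad, np.inf)
    return (
        (d[:, 1] >= margin)
        & (rad <= spec.radius - margin)
        & (ang <= half - ang_margin)
    )


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom image and its matching ground truth.

    Returns an 8-bit grayscale image (dark background, brighter myocardium,
    dark cavity) whose pixels are a deterministic function of the spec.

    Raises
    ------
    InvalidSpecError
        If the posed boundary, padded by the wall thickness, leaves the scan
        sector.
    """
    h, w = spec.image_size
    pose = spec.pose or PoseParameters(
        position=_canonical_reference(spec), scales=(1.0, 1.0), rotation=0.0
    )
    tpl = phantom_template(spec)
    full = tpl.full_template()
    boundary = apply_pose(full.points, full.reference, pose)
    if not _in_sector(spec, boundary, spec.wall_thickness).all():
        raise InvalidSpecError("posed cavity (plus wall) leaves the scan sector")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), _BACKGROUND)
    sector = _sector_mask(spec, xx, yy)
    img[sector] = _SECTOR

    # map pixels into the canonical (un-posed) frame of the template
    pos = np.asarray(pose.position, dtype=float)
    c, s = np.cos(pose.rotation), np.sin(pose.rotation)
    dx, dy = xx - pos[0], yy - pos[1]
    ux = (c * dx + s * dy) / pose.scales[0] + full.reference[0]
    uy = (-s * dx + c * dy) / pose.scales[1] + full.reference[1]
    a, b = spec.cavity_axes
    cx, cy = spec.cavity_center
    eu, ev = ux - cx, uy - cy
    q_in = (eu / a) ** 2 + (ev / b) ** 2
    ao, bo = a + spec.wall_thickness, b + spec.wall_thickness
    q_out = (eu / ao) ** 2 + (ev / bo) ** 2

    wall = sector & (q_in > 1.0) & (q_out <= 1.0) & (ev >= 0)
    cavity = sector & (q_in <= 1.0)
    lateral_side = eu > 0
    wall_val = np.where(
        lateral_side,
        _SECTOR + (_WALL - _SECTOR) * (1.0 - spec.lateral_attenuation),
        _WALL,
    )
    img[wall] = wall_val[wall]
    img[cavity] = _CAVITY

    rng = np.random.default_rng(spec.seed)
    if spec.n_distractors > 0:
        protected = q_out <= 1.2
        img = _paint_distractors(spec, img, sector, protected, xx, yy, rng)

    if spec.speckle_scale > 0:
        n = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=1.0)
        n = (n - n.mean()) / n.std()
        img = img * (1.0 + spec.speckle_scale * n)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    gt = GroundTruth(
        boundary=boundary,
        pose=pose,
        septal_polyline=apply_pose(tpl.septal.points, tpl.reference, pose),
        lateral_polyline=apply_pose(tpl.lateral.points, tpl.reference, pose),
    )
    return img, gt


def _paint_distractors(
    spec: PhantomSpec,
    img: np.ndarray,
    sector: np.ndarray,
    protected: np.ndarray,
    xx: np.ndarray,
    yy: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add dimmer chamber-like structures emulating off-target anatomy.

    In an apical view the left ventricle is not alone: other chambers are
    bounded by similar U-shaped walls, only less strongly visualized.  Each
    distractor is a half-elliptical band (the same morphology as the LV
    wall) at an intensity between the sector fill and the true wall.  The
    unweighted Hough voting can lock onto such a structure in a whole-image
    search, while the amplitude-sensitive Gabor response still favors the
    brighter true wall — the clutter the ROI restriction is meant to
    exclude.  Distractors never overwrite the cavity or wall (``protected``).
    """
    ax, ay = spec.sector_apex
    out = img.copy()
    for _ in range(spec.n_distractors):
        # placed in the sector's mid-to-far field, off to a side
        ang = rng.uniform(-0.42, 0.42) * spec.sector_angle
        rad = rng.uniform(0.45, 0.8) * spec.radius
        cx = ax + rad * np.sin(ang)
        cy = ay + rad * np.cos(ang)
        a = rng.uniform(0.7, 1.2) * spec.cavity_axes[0]
        b = rng.uniform(0.7, 1.2) * spec.cavity_axes[1]
        th = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(th), np.sin(th)
        du, dv = xx - cx, yy - cy
        u = c * du + s * dv
        v = -s * du + c * dv
        q_i = (u / a) ** 2 + (v / b) ** 2
        tk = spec.wall_thickness * rng.uniform(0.7, 1.0)
        q_o = (u / (a + tk)) ** 2 + (v / (b + tk)) ** 2
        band = sector & ~protected & (q_i > 1.0) & (q_o <= 1.0) & (v >= 0)
        out[band] = rng.uniform(120.0, 170.0)
    return out


def _canonical_reference(spec: PhantomSpec) -> tuple[float, float]:
    tpl = phantom_template(spec)
    ref = tpl.full_template().reference
    return (float(ref[0]), float(ref[1]))


def identity_pose(spec: PhantomSpec) -> PoseParameters:
    """The pose that places the template exactly at its canonical position."""
    return PoseParameters(
        position=_canonical_reference(spec), scales=(1.0, 1.0), rotation=0.0
    )


def boundary_error(
    detected: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Symmetric mean and maximum (Hausdorff) nearest-neighbor distances.

    Both point lists must be non-empty; distances are in pixels and >= 0.
    """
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        raise ValueError("point lists must be non-empty")
    d_dt = cKDTree(truth).query(detected)[0]
    d_td = cKDTree(detected).query(truth)[0]
    mean_dist = 0.5 * (d_dt.mean() + d_td.mean())
    hausdorff = max(d_dt.max(), d_td.max())
    return float(mean_dist), float(hausdorff)


def write_phantom(spec: PhantomSpec, image_path, truth_path=None) -> None:
    """Write the phantom as an 8-bit PNG plus a ground-truth JSON sidecar."""
    import imageio.v3 as iio

    img, gt = generate_phantom(spec)
    iio.imwrite(image_path, img)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(gt.to_dict(), fh)
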