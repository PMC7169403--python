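"""Boundary templates and the guided deformable template.

A :class:`BoundaryTemplate` is an ordered list of contour points with a
reference point (the barycenter by default) and a per-point edge orientation
(the contour normal direction, reduced mod pi).  Templates can be extracted
from a hand-drawn binary sketch or built analytically.

The :class:`GuidedTemplate` models the clinical asymmetry of the left
ventricle in an apical view: the septal (medial) wall is usually well
visualized and serves as a thin, rigid guidance limb for pose localization,
while the lateral wall is often obscured and is represented as a thick band
inside which the final border is free to deform.  :func:`deform_band` carries
out that deformation: each lateral point may slide along its posed normal
within the band half-width, and the polyline that maximizes image gradient
magnitude under a smoothness penalty is found exactly by dynamic programming.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label
from skimage.morphology import skeletonize

__all__ = [
    "BoundaryTemplate",
    "GuidedTemplate",
    "template_from_sketch",
    "canonical_lv_template",
    "deform_band",
]


@dataclass
class BoundaryTemplate:
    """Ordered contour points, reference point and per-point orientations.

    ``orientations`` hold the direction of the contour normal (the gradient
    direction of an ideal edge along the contour), reduced mod pi to [0, pi).
    """

    points: np.ndarray  # (N, 2) float, columns (x, y)
    reference: np.ndarray  # (2,) float
    orientations: np.ndarray  # (N,) float in [0, pi)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.reference = np.asarray(self.reference, dtype=float).reshape(2)
        self.orientations = np.mod(
            np.asarray(self.orientations, dtype=float).ravel(), np.pi
        )
        if len(self.points) == 0:
            raise ValueError("template must have at least one point")
        if len(self.points) != len(self.orientations):
            raise ValueError("points and orientations must have equal length")

    @classmethod
    def from_points(
        cls, points: np.ndarray, reference: np.ndarray | None = None
    ) -> "BoundaryTemplate":
        """Build a template from an ordered polyline; orientations from tangents."""
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        if reference is None:
            reference = points.mean(axis=0)
        return cls(points, reference, _normal_orientations(points))

    def __len__(self) -> int:
        return len(self.points)

    def to_dict(self) -> dict:
        return {
            "points": self.points.tolist(),
            "reference": self.reference.tolist(),
            "orientations": self.orientations.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoundaryTemplate":
        return cls(
            np.array(d["points"], dtype=float),
            np.array(d["reference"], dtype=float),
            np.array(d["orientations"], dtype=float),
        )


def _normal_orientations(points: np.ndarray) -> np.ndarray:
    """Contour normal direction per point, mod pi, from central differences."""
    d = np.empty_like(points)
    d[1:-1] = points[2:] - points[:-2]
    d[0] = points[1] - points[0] if len(points) > 1 else (1.0, 0.0)
    d[-1] = points[-1] - points[-2] if len(points) > 1 else (1.0, 0.0)
    tangent = np.arctan2(d[:, 1], d[:, 0])
    return np.mod(tangent + np.pi / 2, np.pi)


@dataclass
class GuidedTemplate:
    """Thin septal guidance limb plus thick deformable lateral band.

    Both segments share one reference point.  ``lateral_halfwidth`` must
    exceed ``septal_halfwidth``: the septal limb is used only for pose
    orientation while the lateral band is where the border is refined.
    """

    septal: BoundaryTemplate
    lateral: BoundaryTemplate
    septal_halfwidth: float = 1.0
    lateral_halfwidth: float = 6.0

    def __post_init__(self) -> None:
        if not np.allclose(self.septal.reference, self.lateral.reference):
            raise ValueError("septal and lateral segments must share a reference")
        if self.lateral_halfwidth <= self.septal_halfwidth:
            raise ValueError("lateral band must be thicker than the septal limb")

    @property
    def reference(self) -> np.ndarray:
        return self.septal.reference

    def full_template(self) -> BoundaryTemplate:
        """Septal + lateral points merged, sharing the common reference."""
        return BoundaryTemplate(
            np.vstack([self.septal.points, self.lateral.points]),
            self.reference,
            np.concatenate([self.septal.orientations, self.lateral.orientations]),
        )

    def to_dict(self) -> dict:
        return {
            "septal": self.septal.to_dict(),
            "lateral": self.lateral.to_dict(),
            "septal_halfwidth": self.septal_halfwidth,
            "lateral_halfwidth": self.lateral_halfwidth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GuidedTemplate":
        return cls(
            BoundaryTemplate.from_dict(d["septal"]),
            BoundaryTemplate.from_dict(d["lateral"]),
            float(d["septal_halfwidth"]),
            float(d["lateral_halfwidth"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GuidedTemplate":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _trace_skeleton(mask: np.ndarray) -> np.ndarray:
    """Order the pixels of a 1-px-wide skeleton into a path.

    Starts at an endpoint (degree-1 pixel) if one exists, else anywhere
    (closed curves), and walks greedily to the nearest unvisited neighbor.
    """
    ys, xs = np.nonzero(mask)
    pts = set(zip(xs.tolist(), ys.tolist()))
    if not pts:
        raise ValueError("empty skeleton")

    def neighbors(p):
        x, y = p
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                q = (x + dx, y + dy)
                if q in pts:
                    out.append(q)
        return out

    start = None
    for p in sorted(pts):
        if len(neighbors(p)) == 1:
            start = p
            break
    if start is None:
        start = min(pts)
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        best = None
        for q in neighbors(cur):
            if q in visited:
                continue
            d = (q[0] - cur[0]) ** 2 + (q[1] - cur[1]) ** 2
            if best is None or d < best or (d == best and q < nxt):
                best, nxt = d, q
        if nxt is None:
            break
        path.append(nxt)
        visited.add(nxt)
        cur = nxt
    return np.array(path, dtype=float)


def _resample_arclength(points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample an ordered polyline at fixed arc-length spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1].copy()
    n = max(int(np.floor(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])]
    )


def template_from_sketch(sketch: np.ndarray, spacing: float = 1.0) -> BoundaryTemplate:
    """Extract a boundary template from a hand-drawn binary sketch.

    The largest connected foreground component is skeletonized to a
    1-px-wide curve, ordered into a path, and resampled at ``spacing``-px
    arc length.  The reference point is the barycenter; orientations are the
    local tangents rotated by pi/2, mod pi.
    """
    sketch = np.asarray(sketch) > 0
    if not sketch.any():
        raise ValueError("sketch has no foreground pixels")
    labels = label(sketch, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = labels == areas.argmax()
    skel = skeletonize(keep)
    path = _trace_skeleton(skel)
    points = _resample_arclength(path, spacing)
    return BoundaryTemplate.from_points(points)


def canonical_lv_template(
    cavity_center: tuple[float, float] = (128.0, 130.0),
    cavity_axes: tuple[float, float] = (40.0, 55.0),
    spacing: float = 1.0,
    lateral_halfwidth: float = 6.0,
) -> GuidedTemplate:
    """Canonical U-shaped endocardial template: a half-ellipse cavity border.

    The lower half of an ellipse (open toward the scan-sector apex / valve
    plane) sampled at ``spacing``-px arc length.  The left limb (septal wall,
    the better-visualized side) is the thin guidance segment; the right limb
    (lateral wall) is the thick deformable band.
    """
    a, b = cavity_axes
    cx, cy = cavity_center
    # dense parameter sweep, then arc-length resampling; t=0 at the lateral
    # (right) opening, t=pi at the septal (left) opening, bottom in between
    t = np.linspace(0.0, np.pi, 4096)
    pts = np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])
    pts = _resample_arclength(pts, spacing)
    ref = pts.mean(axis=0)
    orient = _normal_orientations(pts)
    # split at the bottom of the U (maximum y): first half lateral, rest septal
    split = int(np.argmax(pts[:, 1]))
    split = np.clip(split, 2, len(pts) - 2)
    lateral = BoundaryTemplate(pts[:split], ref, orient[:split])
    septal = BoundaryTemplate(pts[split:], ref, orient[split:])
    return GuidedTemplate(
        septal=septal, lateral=lateral, lateral_halfwidth=lateral_halfwidth
    )


def signed_normals(points: np.ndarray) -> np.ndarray:
    """Consistently oriented unit normals along an ordered polyline.

    The tangent from central differences rotated by +pi/2 (``(-ty, tx)``),
    so the normal field never flips direction along the path — unlike the
    mod-pi orientations stored for R-table binning.
    """
    points = np.asarray(points, dtype=float)
    d = np.empty_like(points)
    d[1:-1] = points[2:] - points[:-2]
    d[0] = points[1] - points[0]
    d[-1] = points[-1] - points[-2]
    n = np.column_stack([-d[:, 1], d[:, 0]])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _pose_arrays(pose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = np.asarray(pose.position, dtype=float)
    sx, sy = pose.scales
    c, s = np.cos(pose.rotation), np.sin(pose.rotation)
    rot = np.array([[c, -s], [s, c]])
    scale = np.array([sx, sy], dtype=float)
    return pos, rot, scale


def apply_pose(points: np.ndarray, reference: np.ndarray, pose) -> np.ndarray:
    """Map template points into the image: p = y + Rot(theta) S (x - ref)."""
    pos, rot, scale = _pose_arrays(pose)
    return pos + (np.asarray(points, dtype=float) - reference) * scale @ rot.T


def deform_band(
    img: np.ndarray,
    gt: GuidedTemplate,
    pose,
    beta: float = 0.1,
    step: float = 1.0,
) -> np.ndarray:
    """Refine the lateral border inside the posed thick band.

    Each posed lateral point may move along its posed unit normal by a
    scalar offset discretized at ``step``-px intervals within
    ``+-lateral_halfwidth * mean(scale)``.  The offsets maximize the summed
    image gradient magnitude minus ``beta * (offset difference)^2`` between
    neighbors, solved exactly by dynamic programming.  Ties prefer smaller
    absolute offsets, then negative ones, so a gradient-free image returns
    the posed polyline unchanged.

    Returns
    -------
    (N, 2) array
        One refined point per lateral template point.
    """
    img = np.asarray(img, dtype=float)
    pos, rot, scale = _pose_arrays(pose)
    pts = apply_pose(gt.lateral.points, gt.reference, pose)
    normals = signed_normals(gt.lateral.points) @ rot.T
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    halfw = gt.lateral_halfwidth * float(np.mean(scale))
    nsteps = int(np.floor(halfw / step))
    offsets = np.arange(-nsteps, nsteps + 1, dtype=float) * step
    # tie preference: smaller |offset| first, then negative before positive
    pref = np.lexsort((offsets, np.abs(offsets)))

    gx = ndi.sobel(img, axis=1)
    gy = ndi.sobel(img, axis=0)
    grad = np.hypot(gx, gy)

    # sample gradient magnitude at every (point, offset) position
    sample = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    h, w = img.shape
    inside = (
        (sample[..., 0] >= 0)
        & (sample[..., 0] <= w - 1)
        & (sample[..., 1] >= 0)
        & (sample[..., 1] <= h - 1)
    )
    if not inside.any():
        raise ValueError("posed band lies entirely outside the image")
    coords = np.stack([sample[..., 1].ravel(), sample[..., 0].ravel()])
    g = ndi.map_coordinates(grad, coords, order=1, mode="nearest").reshape(
        sample.shape[:2]
    )
    g[~inside] = -np.inf

    n, d = g.shape
    penalty = beta * (offsets[:, None] - offsets[None, :]) ** 2  # (to, from)
    # forward pass in tie-preference order so argmax picks the preferred state
    gp = g[:, pref]
    pen = penalty[np.ix_(pref, pref)]
    score = gp[0].copy()
    back = np.zeros((n, d), dtype=int)
    for i in range(1, n):
        trans = score[None, :] - pen  # (to, from)
        back[i] = np.argmax(trans, axis=1)
        score = gp[i] + trans[np.arange(d), back[i]]
    best = int(np.argmax(score))
    idx = np.empty(n, dtype=int)
    idx[-1] = best
    for i in range(n - 1, 0, -1):
        idx[i - 1] = back[i, idx[i]]
    chosen = offsets[pref[idx]]
    return pts + chosen[:, None] * normals
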