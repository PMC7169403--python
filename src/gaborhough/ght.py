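"""Anisotropic generalized Hough transform (GHT).

The GHT detects a template shape by letting every edge point of the image
vote for candidate poses.  A pose is ``a = (y, S, theta)``: a reference-point
position ``y = (x_r, y_r)``, independent scales ``S = (Sx, Sy)`` along the
two orthogonal axes, and a rotation ``theta``.

At build time, each template boundary point ``x_B`` with gradient direction
``phi(x_B)`` stores its displacement to the reference, ``r = y - x_B``, in
polar form in the R-table bin indexed by ``phi mod pi`` discretized into
``n_bins`` intervals of width ``delta_t = pi / n_bins``.

At detection time an edge point with orientation ``phi`` under hypothesis
``(S, theta)`` looks up bin ``(phi - theta) mod pi`` and casts one vote per
stored entry at ``x_B + Rot(theta) diag(Sx, Sy) r``.  Vote counts accumulate
in a 5-D array over (Sx-bin, Sy-bin, theta-bin, y, x); its maxima are the
detections and the vote count at a maximum is the detection's *rate*.

Orientation matching under anisotropic scaling ignores the shear of edge
normals (the lookup bin is shifted by theta only) — the standard GHT
approximation, shared by the stamping helper so that self-detection is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .template import BoundaryTemplate, apply_pose

__all__ = [
    "PoseParameters",
    "EdgePointSet",
    "RTable",
    "SearchGrid",
    "Accumulator",
    "Detection",
    "detect_edges",
    "build_rtable",
    "accumulate",
    "top_candidates",
    "stamp_template",
]


@dataclass(frozen=True)
class PoseParameters:
    """A GHT pose: reference position (x, y), scales (Sx, Sy), rotation."""

    position: tuple[float, float]
    scales: tuple[float, float] = (1.0, 1.0)
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.scales[0] <= 0 or self.scales[1] <= 0:
            raise ValueError("scales must be positive")

    @property
    def isotropic(self) -> bool:
        return np.isclose(self.scales[0], self.scales[1])

    def to_dict(self) -> dict:
        return {
            "position": [float(self.position[0]), float(self.position[1])],
            "scales": [float(self.scales[0]), float(self.scales[1])],
            "rotation": float(self.rotation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoseParameters":
        return cls(tuple(d["position"]), tuple(d["scales"]), float(d["rotation"]))


@dataclass
class EdgePointSet:
    """Edge pixels with gradient orientations (mod pi) and magnitudes."""

    points: np.ndarray  # (N, 2) float, (x, y)
    orientations: np.ndarray  # (N,) in [0, pi)
    magnitudes: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.orientations = np.mod(
            np.asarray(self.orientations, dtype=float).ravel(), np.pi
        )
        self.magnitudes = np.asarray(self.magnitudes, dtype=float).ravel()
        if not (len(self.points) == len(self.orientations) == len(self.magnitudes)):
            raise ValueError("points/orientations/magnitudes lengths differ")

    def __len__(self) -> int:
        return len(self.points)


class RTable:
    """Orientation-binned polar displacement vectors encoding a template.

    ``bins[n]`` holds the ``(rho, alpha)`` polar displacements ``r = y - x_B``
    of every template point whose orientation falls in
    ``[n * delta_t, (n+1) * delta_t)`` with ``delta_t = pi / n_bins``.
    """

    def __init__(self, n_bins: int, bins: list[np.ndarray]):
        if n_bins < 1 or len(bins) != n_bins:
            raise ValueError("bins list must have exactly n_bins entries")
        self.n_bins = int(n_bins)
        self.bins = [np.asarray(b, dtype=float).reshape(-1, 2) for b in bins]

    @property
    def delta_t(self) -> float:
        return np.pi / self.n_bins

    @property
    def n_entries(self) -> int:
        return sum(len(b) for b in self.bins)

    def to_dict(self) -> dict:
        return {"n_bins": self.n_bins, "bins": [b.tolist() for b in self.bins]}

    @classmethod
    def from_dict(cls, d: dict, expected_entries: int | None = None) -> "RTable":
        rt = cls(int(d["n_bins"]), [np.array(b, dtype=float) for b in d["bins"]])
        if expected_entries is not None and rt.n_entries != expected_entries:
            raise ValueError(
                f"R-table holds {rt.n_entries} entries, expected {expected_entries}"
            )
        return rt


def build_rtable(t: BoundaryTemplate, n_bins: int = 36) -> RTable:
    """Build the R-table of a template: one polar entry per template point."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    dt = np.pi / n_bins
    disp = t.reference[None, :] - t.points  # r = y - x_B
    rho = np.linalg.norm(disp, axis=1)
    alpha = np.arctan2(disp[:, 1], disp[:, 0])
    idx = np.floor(np.mod(t.orientations, np.pi) / dt).astype(int) % n_bins
    bins = [
        np.column_stack([rho[idx == n], alpha[idx == n]]) for n in range(n_bins)
    ]
    return RTable(n_bins, bins)


def detect_edges(
    img: np.ndarray,
    roi=None,
    percentile: float = 75.0,
) -> EdgePointSet:
    """Extract edge points by Sobel gradient and a percentile threshold.

    Points are pixels inside ``roi`` (or the whole image) whose gradient
    magnitude is at least the given percentile of the nonzero magnitudes in
    that region.  Orientations are the gradient direction mod pi.
    """
    img = np.asarray(img, dtype=float)
    gx = ndi.sobel(img, axis=1)
    gy = ndi.sobel(img, axis=0)
    mag = np.hypot(gx, gy)
    region = np.ones(img.shape, dtype=bool)
    if roi is not None:
        region = np.asarray(roi.mask if hasattr(roi, "mask") else roi, dtype=bool)
    vals = mag[region & (mag > 0)]
    if vals.size == 0:
        return EdgePointSet(np.empty((0, 2)), np.empty(0), np.empty(0))
    thr = np.percentile(vals, percentile)
    keep = region & (mag >= thr) & (mag > 0)
    ys, xs = np.nonzero(keep)
    phi = np.mod(np.arctan2(gy[ys, xs], gx[ys, xs]), np.pi)
    return EdgePointSet(
        np.column_stack([xs, ys]).astype(float), phi, mag[ys, xs]
    )


@dataclass
class SearchGrid:
    """Pose search grid: scale and rotation bin centers plus a position bbox.

    ``bbox`` is half-open ``(x0, y0, x1, y1)``; every pixel inside it is a
    candidate reference-point position.
    """

    sx: np.ndarray
    sy: np.ndarray
    theta: np.ndarray
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        self.sx = np.atleast_1d(np.asarray(self.sx, dtype=float))
        self.sy = np.atleast_1d(np.asarray(self.sy, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        x0, y0, x1, y1 = self.bbox
        if self.sx.size == 0 or self.sy.size == 0 or self.theta.size == 0:
            raise ValueError("grid axes must be non-empty")
        if x1 <= x0 or y1 <= y0:
            raise ValueError("empty position bbox")

    @classmethod
    def from_ranges(
        cls,
        bbox: tuple[int, int, int, int],
        sx: tuple[float, float, float] = (0.85, 1.15, 0.05),
        sy: tuple[float, float, float] | None = None,
        theta: tuple[float, float, float] = (-np.pi / 6, np.pi / 6, np.pi / 36),
    ) -> "SearchGrid":
        if sy is None:
            sy = sx

        def axis(lo, hi, step):
            n = int(round((hi - lo) / step)) + 1
            return lo + step * np.arange(n)

        return cls(axis(*sx), axis(*sy), axis(*theta), bbox)

    @property
    def n_pose_cells(self) -> int:
        return self.sx.size * self.sy.size * self.theta.size


@dataclass
class Accumulator:
    """Integer vote array over (Sx-bin, Sy-bin, theta-bin, y, x)."""

    votes: np.ndarray  # int32, shape (n_sx, n_sy, n_theta, H, W)
    grid: SearchGrid

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            votes=self.votes,
            sx=self.grid.sx,
            sy=self.grid.sy,
            theta=self.grid.theta,
            bbox=np.array(self.grid.bbox),
        )

    @classmethod
    def load(cls, path) -> "Accumulator":
        with np.load(path) as z:
            grid = SearchGrid(z["sx"], z["sy"], z["theta"], tuple(z["bbox"]))
            return cls(z["votes"], grid)


def accumulate(edges: EdgePointSet, rt: RTable, grid: SearchGrid) -> Accumulator:
    """Cast GHT votes for every (edge point, R-table entry, pose cell) triple.

    For pose hypothesis ``(Sx, Sy, theta)`` an edge point at ``x_B`` with
    orientation ``phi`` looks up the R-table bin of ``(phi - theta) mod pi``
    and, for every stored polar displacement ``r``, votes at the pixel
    ``round(x_B + Rot(theta) diag(Sx, Sy) r)`` (round-half-to-even).  Votes
    landing outside the grid's position bbox are discarded.
    """
    x0, y0, x1, y1 = grid.bbox
    h, w = y1 - y0, x1 - x0
    votes = np.zeros(
        (grid.sx.size, grid.sy.size, grid.theta.size, h, w), dtype=np.int32
    )
    if len(edges) == 0 or rt.n_entries == 0:
        return Accumulator(votes, grid)

    dt = rt.delta_t
    px, py = edges.points[:, 0], edges.points[:, 1]
    for it, th in enumerate(grid.theta):
        lookup = np.floor(np.mod(edges.orientations - th, np.pi) / dt).astype(
            int
        ) % rt.n_bins
        # pair every edge point with every entry of its lookup bin
        pxs, pys, dxs, dys = [], [], [], []
        for b in range(rt.n_bins):
            ent = rt.bins[b]
            if len(ent) == 0:
                continue
            sel = np.nonzero(lookup == b)[0]
            if sel.size == 0:
                continue
            rho, alpha = ent[:, 0], ent[:, 1]
            rx, ry = rho * np.cos(alpha), rho * np.sin(alpha)
            pxs.append(np.repeat(px[sel], len(ent)))
            pys.append(np.repeat(py[sel], len(ent)))
            dxs.append(np.tile(rx, sel.size))
            dys.append(np.tile(ry, sel.size))
        if not pxs:
            continue
        bx = np.concatenate(pxs)
        by = np.concatenate(pys)
        rx = np.concatenate(dxs)
        ry = np.concatenate(dys)
        c, s = np.cos(th), np.sin(th)
        for isx, sxv in enumerate(grid.sx):
            for isy, syv in enumerate(grid.sy):
                ax = rx * sxv
                ay = ry * syv
                vx = np.rint(bx + c * ax - s * ay).astype(np.int64)
                vy = np.rint(by + s * ax + c * ay).astype(np.int64)
                ok = (vx >= x0) & (vx < x1) & (vy >= y0) & (vy < y1)
                if not ok.any():
                    continue
                flat = (vy[ok] - y0) * w + (vx[ok] - x0)
                votes[isx, isy, it] += np.bincount(
                    flat, minlength=h * w
                ).reshape(h, w).astype(np.int32)
    return Accumulator(votes, grid)


@dataclass(frozen=True)
class Detection:
    """One ranked GHT detection: a pose and its accumulator rate."""

    pose: PoseParameters
    rate: int
    bins: tuple[int, int, int] = (0, 0, 0)  # (Sx-bin, Sy-bin, theta-bin)

    def to_dict(self) -> dict:
        return {"pose": self.pose.to_dict(), "rate": int(self.rate)}


def _cell_detection(acc: Accumulator, isx, isy, it, iy, ix) -> Detection:
    g = acc.grid
    x0, y0, _, _ = g.bbox
    pose = PoseParameters(
        position=(float(ix + x0), float(iy + y0)),
        scales=(float(g.sx[isx]), float(g.sy[isy])),
        rotation=float(g.theta[it]),
    )
    return Detection(pose, int(acc.votes[isx, isy, it, iy, ix]), (isx, isy, it))


def top_candidates(
    acc: Accumulator, k: int = 10, suppression_radius: float = 5.0
) -> list[Detection]:
    """The ``k`` best recognition poses, ranked by accumulator rate.

    Cells sort by rate descending, ties broken lexicographically ascending on
    (theta-bin, Sx-bin, Sy-bin, y, x).  Greedy non-maximum suppression drops
    any candidate whose (x, y) distance to an already accepted detection is
    strictly below ``suppression_radius`` (a radius of 0 therefore suppresses
    nothing).  All-zero accumulators yield an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    votes = acc.votes
    nsx, nsy, nt, h, w = votes.shape
    if not votes.any():
        return []

    if suppression_radius <= 0:
        # exact full sort over every nonzero cell
        isx, isy, it, iy, ix = np.nonzero(votes)
        r = votes[isx, isy, it, iy, ix]
        order = np.lexsort((ix, iy, isy, isx, it, -r))
        return [
            _cell_detection(acc, isx[j], isy[j], it[j], iy[j], ix[j])
            for j in order[:k]
        ]

    # with a positive radius, any later cell at an accepted (x, y) is itself
    # suppressed, so only the best cell per position can ever be selected:
    # reduce over pose axes first (argmax of the (theta, Sx, Sy)-ordered
    # stack returns the lexicographically smallest tied pose)
    stack = votes.transpose(2, 0, 1, 3, 4).reshape(nt * nsx * nsy, h, w)
    best = stack.max(axis=0)
    arg = stack.argmax(axis=0)
    iy, ix = np.nonzero(best)
    r = best[iy, ix]
    a = arg[iy, ix]
    order = np.lexsort((ix, iy, a, -r))
    out: list[Detection] = []
    r2 = suppression_radius ** 2
    accepted: list[tuple[int, int]] = []
    for j in order:
        x, y = int(ix[j]), int(iy[j])
        if any((x - ax) ** 2 + (y - ay) ** 2 < r2 for ax, ay in accepted):
            continue
        ai = int(a[j])
        it_, rem = divmod(ai, nsx * nsy)
        isx_, isy_ = divmod(rem, nsy)
        out.append(_cell_detection(acc, isx_, isy_, it_, y, x))
        accepted.append((x, y))
        if len(out) == k:
            break
    return out


def stamp_template(t: BoundaryTemplate, pose: PoseParameters) -> EdgePointSet:
    """Synthesize the edge set of a template placed at a pose.

    Points are the posed template points; orientations are the template
    orientations shifted by the pose rotation (mod pi), matching the GHT's
    orientation-lookup convention, so accumulating a stamped set scores the
    full template point count at the stamped pose.
    """
    pts = apply_pose(t.points, t.reference, pose)
    phi = np.mod(t.orientations + pose.rotation, np.pi)
    return EdgePointSet(pts, phi, np.ones(len(pts)))
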