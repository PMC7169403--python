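import numpy as np
import pytest

import gaborhough as gh


@pytest.fixture(scope="session")
def small_spec():
    """A 128x128 phantom geometry used across tests (fast to render)."""
    return gh.PhantomSpec(
        image_size=(128, 128),
        sector_apex=(64.0, 4.0),
        sector_angle=1.4,
        cavity_center=(64.0, 65.0),
        cavity_axes=(20.0, 28.0),
        wall_thickness=7.0,
    )


@pytest.fixture(scope="session")
def small_template(small_spec):
    return gh.phantom_template(small_spec)


def brute_force_accumulate(edges, rt, grid):
    """Independent triple-loop GHT oracle: count every vote one by one."""
    x0, y0, x1, y1 = grid.bbox
    h, w = y1 - y0, x1 - x0
    votes = np.zeros((grid.sx.size, grid.sy.size, grid.theta.size, h, w), dtype=int)
    for isx, sxv in enumerate(grid.sx):
        for isy, syv in enumerate(grid.sy):
            for it, th in enumerate(grid.theta):
                c, s = np.cos(th), np.sin(th)
                for (px, py), phi in zip(edges.points, edges.orientations):
                    b = int(np.floor(((phi - th) % np.pi) / rt.delta_t)) % rt.n_bins
                    for rho, alpha in rt.bins[b]:
                        ax = rho * np.cos(alpha) * sxv
                        ay = rho * np.sin(alpha) * syv
                        vx = int(np.rint(px + c * ax - s * ay))
                        vy = int(np.rint(py + s * ax + c * ay))
                        if x0 <= vx < x1 and y0 <= vy < y1:
                            votes[isx, isy, it, vy - y0, vx - x0] += 1
    return votes


def random_ght_instance(seed, max_edges=200, image=64):
    """A random small GHT problem: template, edges and a compact pose grid."""
    rng = np.random.default_rng(seed)
    n_t = int(rng.integers(20, 60))
    t = np.linspace(0, 2 * np.pi, n_t, endpoint=False)
    pts = np.column_stack(
        [
            image / 2 + rng.uniform(8, 14) * np.cos(t),
            image / 2 + rng.uniform(10, 16) * np.sin(t),
        ]
    )
    template = gh.BoundaryTemplate.from_points(pts)
    rt = gh.build_rtable(template, n_bins=int(rng.integers(4, 12)))
    n_e = int(rng.integers(30, max_edges + 1))
    edges = gh.EdgePointSet(
        points=rng.uniform(0, image - 1, size=(n_e, 2)),
        orientations=rng.uniform(0, np.pi, size=n_e),
        magnitudes=np.ones(n_e),
    )
    grid = gh.SearchGrid(
        sx=rng.uniform(0.8, 1.2, size=3),
        sy=rng.uniform(0.8, 1.2, size=3),
        theta=rng.uniform(-0.5, 0.5, size=int(rng.integers(2, 5))),
        bbox=(0, 0, image, image),
    )
    return edges, rt, grid
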