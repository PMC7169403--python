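"""GHT core: edge extraction, R-table, voting and candidate ranking."""

import numpy as np
import pytest

import gaborhough as gh
from gaborhough.gabor import RoiMask

from conftest import brute_force_accumulate, random_ght_instance


def circle_template(radius=12.0, n=60, center=(32.0, 32.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )
    return gh.BoundaryTemplate.from_points(pts)


class TestDetectEdges:
    def test_constant_image_yields_no_edges(self):
        edges = gh.detect_edges(np.full((32, 32), 120.0))
        assert len(edges) == 0

    def test_vertical_step_edge(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 200.0
        edges = gh.detect_edges(img, percentile=50)
        assert len(edges) > 0
        assert np.all(np.abs(edges.points[:, 0] - 16) <= 1)
        # gradient of a vertical edge is horizontal: orientation ~ 0 mod pi
        folded = np.minimum(edges.orientations, np.pi - edges.orientations)
        assert np.all(folded < 0.05)

    def test_roi_restriction_is_exact_subset(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (40, 40))
        full = gh.detect_edges(img, percentile=80)
        mask = np.zeros((40, 40), dtype=bool)
        mask[:20] = True
        top = gh.detect_edges(img, roi=RoiMask(mask=mask, bbox=(0, 0, 40, 20)),
                              percentile=80)
        # each restricted point appears in the full set's top half... but the
        # percentile threshold is recomputed inside the ROI, so compare
        # against a full-image run using the ROI's own threshold region:
        full_pts = {tuple(p) for p in full.points}
        kept = {tuple(p) for p in top.points if p[1] < 19}
        # with a common threshold the restricted set is exactly the top-half
        # subset; verify via a threshold-free check on the strongest edges
        strongest = sorted(zip(top.magnitudes, map(tuple, top.points)))[-5:]
        for _, p in strongest:
            assert p[1] < 20

    def test_roi_with_common_threshold_restricts_exactly(self):
        img = np.zeros((30, 30))
        img[:, 15:] = 100.0  # uniform-magnitude edge through both halves
        full = gh.detect_edges(img, percentile=0)
        mask = np.zeros((30, 30), dtype=bool)
        mask[:15] = True
        half = gh.detect_edges(img, roi=RoiMask(mask=mask, bbox=(0, 0, 30, 15)),
                               percentile=0)
        full_set = {tuple(p) for p in full.points}
        half_set = {tuple(p) for p in half.points}
        assert half_set == {p for p in full_set if p[1] < 15}


class TestRTable:
    def test_circle_displacements_equal_radius(self):
        rt = gh.build_rtable(circle_template(radius=12.0), n_bins=36)
        rhos = np.concatenate([b[:, 0] for b in rt.bins if len(b)])
        assert np.all(np.abs(rhos - 12.0) < 1.5)

    def test_single_bin_holds_everything(self):
        t = circle_template(n=40)
        rt = gh.build_rtable(t, n_bins=1)
        assert len(rt.bins[0]) == 40

    def test_entry_conservation(self):
        t = circle_template(n=100)
        rt = gh.build_rtable(t, n_bins=36)
        assert rt.n_entries == 100

    def test_json_round_trip_validates_conservation(self):
        t = circle_template(n=50)
        rt = gh.build_rtable(t, n_bins=8)
        back = gh.RTable.from_dict(rt.to_dict(), expected_entries=50)
        assert back.n_bins == 8
        for b0, b1 in zip(rt.bins, back.bins):
            assert np.allclose(b0, b1)
        with pytest.raises(ValueError):
            gh.RTable.from_dict(rt.to_dict(), expected_entries=49)


class TestAccumulate:
    def test_stamped_template_votes_fully_at_identity(self):
        t = circle_template()
        rt = gh.build_rtable(t, n_bins=36)
        pose = gh.PoseParameters(position=(32.0, 32.0))
        edges = gh.stamp_template(t, pose)
        grid = gh.SearchGrid(sx=[1.0], sy=[1.0], theta=[0.0], bbox=(0, 0, 64, 64))
        acc = gh.accumulate(edges, rt, grid)
        assert acc.votes[0, 0, 0, 32, 32] == len(t)

    def test_rotated_stamp_moves_argmax_not_rate(self):
        t = circle_template()
        rt = gh.build_rtable(t, n_bins=36)
        grid = gh.SearchGrid(
            sx=[1.0], sy=[1.0], theta=[0.0, np.pi / 18], bbox=(0, 0, 64, 64)
        )
        rates = []
        for it, theta in enumerate(grid.theta):
            pose = gh.PoseParameters(position=(30.0, 33.0), rotation=theta)
            acc = gh.accumulate(gh.stamp_template(t, pose), rt, grid)
            idx = np.unravel_index(acc.votes.argmax(), acc.votes.shape)
            assert idx[2] == it and (idx[4], idx[3]) == (30, 33)
            rates.append(acc.votes[idx])
        assert rates[0] == rates[1] == len(t)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        edges, rt, grid = random_ght_instance(seed, max_edges=120)
        acc = gh.accumulate(edges, rt, grid)
        oracle = brute_force_accumulate(edges, rt, grid)
        assert np.array_equal(acc.votes, oracle)

    def test_empty_edges_give_zero_votes(self):
        t = circle_template()
        rt = gh.build_rtable(t, n_bins=12)
        grid = gh.SearchGrid(sx=[1.0], sy=[1.0], theta=[0.0], bbox=(0, 0, 16, 16))
        edges = gh.EdgePointSet(np.empty((0, 2)), np.empty(0), np.empty(0))
        assert gh.accumulate(edges, rt, grid).votes.sum() == 0

    def test_deleting_edges_never_increases_votes(self):
        edges, rt, grid = random_ght_instance(7, max_edges=100)
        full = gh.accumulate(edges, rt, grid).votes
        sub = gh.EdgePointSet(
            edges.points[::2], edges.orientations[::2], edges.magnitudes[::2]
        )
        assert np.all(gh.accumulate(sub, rt, grid).votes <= full)

    def test_translation_equivariance(self):
        t = circle_template()
        rt = gh.build_rtable(t, n_bins=36)
        pose = gh.PoseParameters(position=(25.0, 26.0))
        edges = gh.stamp_template(t, pose)
        grid = gh.SearchGrid(sx=[1.0], sy=[1.0], theta=[0.0], bbox=(0, 0, 64, 64))
        a0 = gh.accumulate(edges, rt, grid).votes
        dx, dy = 6, -4
        shifted = gh.EdgePointSet(
            edges.points + [dx, dy], edges.orientations, edges.magnitudes
        )
        a1 = gh.accumulate(shifted, rt, grid).votes
        i0 = np.unravel_index(a0.argmax(), a0.shape)
        i1 = np.unravel_index(a1.argmax(), a1.shape)
        assert (i1[4] - i0[4], i1[3] - i0[3]) == (dx, dy)
        assert i1[:3] == i0[:3]


class TestTopCandidates:
    def _acc_from_votes(self, votes, bbox=None):
        votes = np.asarray(votes, dtype=np.int32)
        nsx, nsy, nt, h, w = votes.shape
        grid = gh.SearchGrid(
            sx=np.linspace(0.9, 1.1, nsx),
            sy=np.linspace(0.9, 1.1, nsy),
            theta=np.linspace(-0.2, 0.2, nt),
            bbox=bbox or (0, 0, w, h),
        )
        return gh.Accumulator(votes, grid)

    def test_single_cell(self):
        votes = np.zeros((2, 2, 2, 8, 8))
        votes[1, 0, 1, 3, 5] = 7
        dets = gh.top_candidates(self._acc_from_votes(votes), k=4)
        assert len(dets) == 1
        assert dets[0].rate == 7
        assert dets[0].pose.position == (5.0, 3.0)

    def test_tie_breaks_lexicographically(self):
        votes = np.zeros((2, 2, 2, 8, 8))
        votes[1, 1, 1, 4, 4] = 5
        votes[0, 0, 0, 6, 6] = 5
        dets = gh.top_candidates(self._acc_from_votes(votes), k=2,
                                 suppression_radius=1)
        assert dets[0].bins == (0, 0, 0)
        assert dets[1].bins == (1, 1, 1)

    def test_radius_zero_equals_full_sort(self):
        rng = np.random.default_rng(13)
        votes = rng.integers(0, 6, size=(4, 4, 4, 16, 16))
        acc = self._acc_from_votes(votes)
        dets = gh.top_candidates(acc, k=25, suppression_radius=0)
        # independent full sort of every nonzero cell
        cells = [
            (-int(votes[isx, isy, it, y, x]), it, isx, isy, y, x)
            for isx in range(4) for isy in range(4) for it in range(4)
            for y in range(16) for x in range(16)
            if votes[isx, isy, it, y, x] > 0
        ]
        cells.sort()
        for d, c in zip(dets, cells[:25]):
            assert d.rate == -c[0]
            assert d.bins == (c[2], c[3], c[1])
            assert d.pose.position == (float(c[5]), float(c[4]))

    def test_suppression_removes_nearby_positions(self):
        votes = np.zeros((1, 1, 1, 20, 20))
        votes[0, 0, 0, 10, 10] = 9
        votes[0, 0, 0, 10, 12] = 8  # within radius 5 of the peak
        votes[0, 0, 0, 3, 3] = 7
        dets = gh.top_candidates(self._acc_from_votes(votes), k=3,
                                 suppression_radius=5)
        positions = [d.pose.position for d in dets]
        assert positions == [(10.0, 10.0), (3.0, 3.0)]

    def test_all_zero_accumulator_gives_empty_list(self):
        votes = np.zeros((1, 1, 1, 8, 8))
        assert gh.top_candidates(self._acc_from_votes(votes)) == []


def test_roi_restriction_never_raises_the_best_rate():
    # with a threshold common to both runs, restricting edges to an ROI can
    # only remove votes, so the global maximum rate cannot increase
    rng = np.random.default_rng(17)
    img = rng.uniform(0, 255, (64, 64))
    t = circle_template(radius=10.0)
    rt = gh.build_rtable(t, n_bins=18)
    grid = gh.SearchGrid(sx=[1.0], sy=[0.9, 1.1], theta=[0.0], bbox=(0, 0, 64, 64))
    full_edges = gh.detect_edges(img, percentile=0)
    mask = np.zeros((64, 64), dtype=bool)
    mask[16:48, 16:48] = True
    keep = mask[full_edges.points[:, 1].astype(int),
                full_edges.points[:, 0].astype(int)]
    sub_edges = gh.EdgePointSet(full_edges.points[keep],
                                full_edges.orientations[keep],
                                full_edges.magnitudes[keep])
    full_max = gh.accumulate(full_edges, rt, grid).votes.max()
    sub_max = gh.accumulate(sub_edges, rt, grid).votes.max()
    assert sub_max <= full_max


def test_accumulator_npz_round_trip(tmp_path):
    edges, rt, grid = random_ght_instance(3, max_edges=60)
    acc = gh.accumulate(edges, rt, grid)
    path = tmp_path / "acc.npz"
    acc.save(path)
    back = gh.Accumulator.load(path)
    assert np.array_equal(back.votes, acc.votes)
    assert np.allclose(back.grid.sx, acc.grid.sx)
    assert back.grid.bbox == acc.grid.bbox
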