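"""DBSCAN hotspot detection, metrics, projection masks, track association."""

import numpy as np
import pandas as pd
import pytest

from smlmkit import (
    HotspotDetector,
    HotspotParams,
    PALM_PARAMS,
    Rect,
    Track,
    TrackSet,
    associate_tracks,
    dbscan_hotspots,
    hotspot_metrics,
    mask_overlap,
    render_projection,
)
from smlmkit.simulate import generate_hotspot_localizations


def brute_force_dbscan(points, eps, min_pts):
    """Textbook density-connectivity DBSCAN (the independent oracle).

    Points are scanned in index order; clusters grow breadth-first from
    core points; border points keep the label of the first cluster that
    reaches them. Returns labels with -1 for noise.
    """
    n = len(points)
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -2)  # -2 unvisited
    cluster = -1
    for i in range(n):
        if labels[i] != -2:
            continue
        if not core[i]:
            labels[i] = -1
            continue
        cluster += 1
        labels[i] = cluster
        queue = list(neighbors[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cluster  # border point
            if labels[j] != -2:
                continue
            labels[j] = cluster
            if core[j]:
                queue.extend(neighbors[j])
    labels[labels == -2] = -1
    return labels


def disc_points(center, radius, n, rng):
    theta = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )


class TestDBSCANHotspots:
    def test_single_dense_disc_is_one_hotspot(self, rng):
        pts = disc_points((1000.0, 1000.0), 50.0, 20, rng)
        hs = dbscan_hotspots(pts, HotspotParams(eps=80.0, min_density=20,
                                                min_locs_per_hotspot=18))
        assert len(hs) == 1
        assert hs[0].n_locs == 20

    def test_seventeen_points_fail_the_min_size_filter(self, rng):
        pts = disc_points((1000.0, 1000.0), 50.0, 17, rng)
        # low minPts so a cluster forms; the 18-localization filter rejects it
        hs = dbscan_hotspots(pts, HotspotParams(eps=80.0, min_density=5,
                                                min_locs_per_hotspot=18))
        assert hs == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_density_connectivity_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 250))
        eps = float(rng.uniform(30, 120))
        min_pts = int(rng.integers(3, 10))
        # mixture of clumps and background to exercise border cases
        pts = np.concatenate(
            [
                rng.uniform(0, 2000, (n // 2, 2)),
                disc_points(rng.uniform(300, 1700, 2), 60.0, n // 4, rng),
                disc_points(rng.uniform(300, 1700, 2), 60.0, n - n // 2 - n // 4, rng),
            ]
        )
        det = HotspotDetector(eps=eps, min_density=min_pts,
                              min_locs_per_hotspot=2).fit(pts)
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        oracle_sorted = brute_force_dbscan(pts[order], eps, min_pts)
        oracle = np.empty(len(pts), dtype=int)
        oracle[order] = oracle_sorted
        # same noise set and same cluster partition (labels up to renaming)
        np.testing.assert_array_equal(det.labels_ == -1, oracle == -1)
        for lab in np.unique(oracle[oracle >= 0]):
            members = det.labels_[oracle == lab]
            assert len(set(members)) == 1 and members[0] >= 0

    def test_membership_invariant_under_input_permutation(self, rng):
        pts = np.concatenate(
            [disc_points((500.0, 500.0), 60.0, 30, rng),
             rng.uniform(0, 2000, (60, 2))]
        )
        perm = rng.permutation(len(pts))
        h1 = dbscan_hotspots(pts, HotspotParams(80, 10, 18))
        h2 = dbscan_hotspots(pts[perm], HotspotParams(80, 10, 18))
        assert len(h1) == len(h2)
        for a, b in zip(h1, h2):
            np.testing.assert_allclose(
                np.sort(a.points, axis=0), np.sort(b.points, axis=0)
            )

    def test_every_hotspot_respects_min_size(self):
        table, _ = generate_hotspot_localizations(
            roi=Rect(0, 0, 5000, 5000), background_density=5.0,
            centers=[[1000, 1000], [2500, 2500], [4000, 4000]],
            radii=40.0, counts=25, seed=7,
        )
        for h in dbscan_hotspots(table, HotspotParams(80, 10, 18)):
            assert h.n_locs >= 18

    def test_planted_hotspots_with_18_locs_pass_filter(self):
        table, truth = generate_hotspot_localizations(
            roi=Rect(0, 0, 5000, 5000), background_density=0.5,
            centers=[[1200, 1200], [3600, 3600]], radii=40.0, counts=18, seed=8,
        )
        hs = dbscan_hotspots(table, HotspotParams(80, 10, 18))
        assert len(hs) == len(truth.centers)

    def test_palm_mode_parameters(self):
        assert PALM_PARAMS.eps == 100.0
        assert PALM_PARAMS.min_locs_per_hotspot == 10


class TestHotspotMetrics:
    def test_square_corner_cluster_area_by_shoelace(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]])
        det = HotspotDetector(eps=200.0, min_density=2, min_locs_per_hotspot=2).fit(pts)
        m = hotspot_metrics(det.hotspots_[0])
        assert m["area_um2"] == pytest.approx(0.01)
        assert m["n_locs"] == 4
        assert m["density_per_um2"] == pytest.approx(400.0)

    def test_two_point_cluster_has_no_area(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        det = HotspotDetector(eps=50.0, min_density=2, min_locs_per_hotspot=2).fit(pts)
        assert np.isnan(det.hotspots_[0].area_um2)

    def test_wider_scatter_gives_larger_mean_area(self):
        areas = {}
        for sigma in (40.0, 80.0):
            table, _ = generate_hotspot_localizations(
                roi=Rect(0, 0, 8000, 8000), background_density=0.0,
                centers=[[2000, 2000], [4000, 4000], [6000, 6000]],
                radii=sigma, counts=30, seed=9,
            )
            hs = dbscan_hotspots(table, HotspotParams(eps=3 * sigma, min_density=5,
                                                      min_locs_per_hotspot=18))
            areas[sigma] = np.mean([h.area_um2 for h in hs])
        assert areas[80.0] > areas[40.0]


class TestProjectionMask:
    def test_single_localization_gives_disc(self):
        mask = render_projection(
            np.array([[1000.0, 1000.0]]), pixel_size=100.0,
            threshold_quantile=0.95, shape=(20, 20),
        )
        assert mask[10, 10]
        assert 0 < mask.sum() < mask.size

    def test_empty_table_gives_background(self):
        mask = render_projection(np.empty((0, 2)), shape=(10, 10))
        assert not mask.any()

    def test_hotspot_centroids_land_in_mask_foreground(self):
        table, _ = generate_hotspot_localizations(
            roi=Rect(0, 0, 5000, 5000), background_density=1.0,
            centers=[[1000, 1000], [2500, 2500], [4000, 4000]],
            radii=40.0, counts=30, seed=10,
        )
        hs = dbscan_hotspots(table, HotspotParams(80, 10, 18))
        mask = render_projection(table, threshold_quantile=0.9, shape=(50, 50))
        hits = [
            mask[int(h.centroid[1] // 100), int(h.centroid[0] // 100)] for h in hs
        ]
        assert np.mean(hits) >= 0.9


class TestMaskOverlap:
    def test_identical_masks(self):
        m = np.zeros((20, 20), bool)
        m[5:10, 5:10] = True
        res = mask_overlap(m, m)
        assert res.pearson == pytest.approx(1.0)
        assert res.manders_m1 == 1.0 and res.manders_m2 == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:5], b[10:15] = True, True
        res = mask_overlap(a, b)
        assert res.manders_m1 == 0.0 and res.manders_m2 == 0.0
        assert res.pearson < 0

    def test_subset_mask_asymmetry(self):
        b = np.zeros((20, 20), bool)
        b[0:10] = True          # |B| = 200
        a = np.zeros((20, 20), bool)
        a[0:5] = True           # A ⊂ B, |A| = |B|/2
        res = mask_overlap(a, b)
        assert res.manders_m1 == 1.0
        assert res.manders_m2 == 0.5

    def test_pearson_symmetric_manders_swap(self, rng):
        a = rng.random((30, 30)) > 0.6
        b = rng.random((30, 30)) > 0.4
        r1 = mask_overlap(a, b)
        r2 = mask_overlap(b, a)
        assert r1.pearson == pytest.approx(r2.pearson)
        assert r1.manders_m1 == pytest.approx(r2.manders_m2)

    def test_empty_mask_flagged_nan(self):
        a = np.zeros((10, 10), bool)
        b = np.ones((10, 10), bool)
        res = mask_overlap(a, b)
        assert np.isnan(res.manders_m1)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_overlap(np.zeros((5, 5)), np.zeros((6, 6)))


class TestTrackAssociation:
    @staticmethod
    def _hotspot_at(center, rng, n=20, sigma=40.0):
        pts = center + rng.normal(0, sigma, (n, 2))
        det = HotspotDetector(eps=150.0, min_density=3, min_locs_per_hotspot=5).fit(pts)
        assert det.n_clusters_ == 1
        return det.hotspots_[0]

    @staticmethod
    def _track(tid, start, step_nm, n=10):
        pos = np.asarray(start, float) + step_nm * np.arange(n)[:, None]
        return Track(tid, np.arange(n), pos, 0.05)

    def test_track_through_polygon_counted_once(self, rng):
        h = self._hotspot_at(np.array([500.0, 500.0]), rng)
        # crosses the hotspot with several interior points
        tr = self._track("through", [400.0, 400.0], np.array([20.0, 20.0]))
        res = associate_tracks(TrackSet(tracks=[tr]), [h])
        assert res["per_hotspot_track_count"][0] == 1
        assert res["fraction_hotspots_visited"] == 1.0

    def test_outside_track_never_associates(self, rng):
        h = self._hotspot_at(np.array([500.0, 500.0]), rng)
        tr = self._track("far", [5000.0, 5000.0], np.array([10.0, 0.0]))
        res = associate_tracks(TrackSet(tracks=[tr]), [h])
        assert res["per_hotspot_track_count"][0] == 0
        assert res["fraction_hotspots_visited"] == 0.0

    def test_visiting_tracks_are_slower_when_planted_so(self, rng):
        from smlmkit.simulate import TrackSimParams, generate_tracks

        h = self._hotspot_at(np.array([1000.0, 1000.0]), rng, n=30, sigma=100.0)
        slow, _ = generate_tracks(
            n_tracks=15, class_weights=(0, 0, 0, 1, 0),
            params=TrackSimParams(diffusion_coefficient=0.02), n_frames=20, seed=1,
        )
        fast, _ = generate_tracks(
            n_tracks=15, class_weights=(0, 0, 0, 1, 0),
            params=TrackSimParams(diffusion_coefficient=0.3), n_frames=20, seed=2,
        )
        tracks = []
        for i, tr in enumerate(slow):  # pin slow tracks inside the hotspot
            tr.track_id = f"slow_{i}"
            tr.positions = tr.positions - tr.positions[0] + h.centroid
            tracks.append(tr)
        for i, tr in enumerate(fast):  # keep fast tracks far away
            tr.track_id = f"fast_{i}"
            tr.positions = tr.positions - tr.positions[0] + np.array([8000.0, 8000.0])
            tracks.append(tr)
        res = associate_tracks(TrackSet(tracks=tracks), [h])
        assert res["visiting_d_mean"] < res["non_visiting_d_mean"]
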