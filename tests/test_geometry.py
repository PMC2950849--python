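"""Home-range geometry, availability sampling, patch extraction, thinning."""

import numpy as np
import pytest

from rsfbayes import (
    Activity,
    DegenerateGeometryError,
    InfeasibleDesignError,
    OutOfBoundsError,
    Point,
    Polygon,
    TimedFix,
    TrackOrderError,
    make_landscape,
    minimum_convex_polygon,
    sample_availability,
    sample_patch,
    thin_track,
)


def gift_wrap(points: np.ndarray) -> np.ndarray:
    """Independent convex-hull oracle (Jarvis march), CCW vertex order."""
    pts = np.unique(points, axis=0)
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            a = pts[cand] - pts[cur]
            b = pts[j] - pts[cur]
            cross = a[0] * b[1] - a[1] * b[0]
            d_cand = np.linalg.norm(pts[cand] - pts[cur])
            d_j = np.linalg.norm(pts[j] - pts[cur])
            if cross < 0 or (cross == 0 and d_j > d_cand):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    return pts[hull]


def shoelace(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def as_ring_set(verts: np.ndarray) -> set:
    return {tuple(v) for v in verts}


class TestMinimumConvexPolygon:
    def test_triangle_is_its_own_hull(self):
        hull = minimum_convex_polygon([Point(0, 0), Point(4, 0), Point(0, 3)])
        assert len(hull.vertices) == 3
        assert hull.area == pytest.approx(6.0)

    def test_interior_point_dropped(self):
        pts = [Point(0, 0), Point(2, 0), Point(2, 2), Point(0, 2), Point(1, 1)]
        hull = minimum_convex_polygon(pts)
        assert len(hull.vertices) == 4
        assert (1.0, 1.0) not in as_ring_set(hull.vertices)
        assert hull.area == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_gift_wrapping_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 100, size=(25, 2))
        hull = minimum_convex_polygon([Point(*p) for p in xy])
        oracle = gift_wrap(xy)
        assert as_ring_set(hull.vertices) == as_ring_set(oracle)
        assert hull.area == pytest.approx(shoelace(oracle), rel=1e-9)
        inside = hull.contains_points(xy)
        assert inside.all()

    def test_invariant_under_permutation_and_duplication(self):
        rng = np.random.default_rng(42)
        xy = rng.uniform(0, 50, size=(20, 2))
        base = minimum_convex_polygon([Point(*p) for p in xy])
        perm = rng.permutation(len(xy))
        shuffled = minimum_convex_polygon([Point(*p) for p in xy[perm]])
        centroid = xy.mean(axis=0)
        dup = np.vstack([xy, centroid, centroid])
        duplicated = minimum_convex_polygon([Point(*p) for p in dup])
        for other in (shuffled, duplicated):
            assert as_ring_set(base.vertices) == as_ring_set(other.vertices)

    @pytest.mark.parametrize(
        "pts",
        [
            [Point(0, 0), Point(1, 1)],
            [Point(0, 0), Point(1, 1), Point(2, 2), Point(3, 3)],
        ],
        ids=["too_few", "collinear"],
    )
    def test_degenerate_input_errors(self, pts):
        with pytest.raises(DegenerateGeometryError) as exc:
            minimum_convex_polygon(pts, label="bird_07")
        assert "bird_07" in str(exc.value)

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Point(np.nan, 0.0)


class TestSampleAvailability:
    square = Polygon(np.array([[0.0, 0.0], [200.0, 0.0], [200.0, 200.0], [0.0, 200.0]]))

    def test_zero_points_gives_empty_list(self):
        assert sample_availability(self.square, [], 0, rng_seed=1) == []

    def test_exclusion_and_containment(self):
        rng = np.random.default_rng(5)
        used = [Point(*p) for p in rng.uniform(20, 180, size=(30, 2))]
        pts = sample_availability(self.square, used, 500, exclusion_radius=10.0, rng_seed=11)
        assert len(pts) == 500
        xy = np.array([[p.x, p.y] for p in pts])
        assert self.square.contains_points(xy).all()
        uxy = np.array([[p.x, p.y] for p in used])
        d = np.hypot(*(xy[:, None, :] - uxy[None, :, :]).transpose(2, 0, 1))
        assert d.min() > 10.0

    def test_seed_determinism(self):
        used = [Point(100, 100)]
        a = sample_availability(self.square, used, 50, rng_seed=3)
        b = sample_availability(self.square, used, 50, rng_seed=3)
        c = sample_availability(self.square, used, 50, rng_seed=4)
        assert a == b
        assert a != c

    def test_infeasible_design_reports_fraction(self):
        # exclusion circle covers the whole small polygon
        tiny = Polygon(np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 5.0], [0.0, 5.0]]))
        with pytest.raises(InfeasibleDesignError) as exc:
            sample_availability(tiny, [Point(2.5, 2.5)], 10, exclusion_radius=10.0,
                                rng_seed=0, attempt_factor=50)
        assert exc.value.feasible_fraction == 0.0

    def test_feasible_fraction_matches_grid_oracle(self):
        """Acceptance rate of rejection sampling vs 1 m raster of the design."""
        poly = Polygon(np.array([[0.0, 0.0], [60.0, 0.0], [60.0, 40.0], [0.0, 40.0]]))
        used = [Point(15, 20), Point(30, 20), Point(45, 20)]
        n = 4000
        rng = np.random.default_rng(9)
        cand = np.column_stack([rng.uniform(0, 60, n), rng.uniform(0, 40, n)])
        uxy = np.array([[p.x, p.y] for p in used])
        dmin = np.hypot(*(cand[:, None] - uxy[None]).transpose(2, 0, 1)).min(axis=1)
        emp = (dmin > 10).mean()
        # 1 m-grid rasterization oracle over the bounding box
        gx, gy = np.meshgrid(np.arange(0.5, 60), np.arange(0.5, 40))
        gxy = np.column_stack([gx.ravel(), gy.ravel()])
        gmin = np.hypot(*(gxy[:, None] - uxy[None]).transpose(2, 0, 1)).min(axis=1)
        oracle = (gmin > 10).mean()
        assert emp == pytest.approx(oracle, abs=0.02)


class TestSamplePatch:
    def test_fully_bare_circle(self):
        land = make_landscape((40, 40), grain=0.5, bare_fraction=0.5, patch_scale=2, seed=1)
        land.bare_mask[:] = True
        land.height[:] = 0.0
        cov = sample_patch(land, Point(20, 20), 1.0)
        assert cov.bare == 1.0
        assert cov.height == 0.0

    def test_uniform_grass_circle(self):
        land = make_landscape((40, 40), grain=0.5, bare_fraction=0.5, patch_scale=2, seed=1)
        land.bare_mask[:] = False
        land.height[:] = 12.0
        cov = sample_patch(land, Point(20, 20), 1.0)
        assert cov.bare == 0.0
        assert cov.height == pytest.approx(12.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_monte_carlo_integration_oracle(self, seed):
        land = make_landscape((60, 60), grain=0.5, bare_fraction=0.4, patch_scale=1.5, seed=3)
        rng = np.random.default_rng(seed)
        center = Point(*rng.uniform(10, 50, 2))
        cov = sample_patch(land, center, 1.0)
        # 10^4-point Monte-Carlo integration over the same circle
        ang = rng.uniform(0, 2 * np.pi, 10_000)
        rad = np.sqrt(rng.uniform(0, 1, 10_000))
        px = center.x + rad * np.cos(ang)
        py = center.y + rad * np.sin(ang)
        ix = (px // land.grain).astype(int)
        iy = (py // land.grain).astype(int)
        mc_bare = land.bare_mask[iy, ix].mean()
        assert cov.bare == pytest.approx(mc_bare, abs=0.02)

    def test_circle_exiting_landscape_errors(self):
        land = make_landscape((40, 40), grain=0.5, bare_fraction=0.5, patch_scale=2, seed=1)
        with pytest.raises(OutOfBoundsError):
            sample_patch(land, Point(0.5, 20.0), 1.0)


def fix(x, y, t, act=Activity.FORAGING):
    return TimedFix(point=Point(x, y), t=t, activity=act)


class TestThinTrack:
    def test_single_fix_kept(self):
        track = [fix(0, 0, 0)]
        assert thin_track(track) == track

    def test_five_minute_boundary(self):
        same_place = [fix(0, 0, 0), fix(0, 0, 299)]
        assert thin_track(same_place) == same_place[:1]
        apart = [fix(0, 0, 0), fix(0, 0, 301)]
        assert thin_track(apart) == apart

    def test_moved_to_another_site_overrides_interval(self):
        track = [fix(0, 0, 0), fix(0, 50, 60)]
        assert thin_track(track, site_radius=10.0) == track

    def test_hand_simulated_eight_fix_track(self):
        # greedy pass worked out by hand: keep 0; drop 1 (60 s, 2 m);
        # keep 2 (moved 30 m); keep 3 (+400 s); drop 4 (non-foraging);
        # drop 5 (100 s, 5 m); keep 6 (moved 25 m); keep 7 (+350 s)
        track = [
            fix(0, 0, 0),
            fix(2, 0, 60),
            fix(30, 0, 120),
            fix(30, 2, 520),
            fix(60, 0, 600, Activity.OTHER),
            fix(33, 2, 620),
            fix(30, 27, 700),
            fix(30, 27, 1050),
        ]
        expected = [track[0], track[2], track[3], track[6], track[7]]
        assert thin_track(track, min_interval=300, site_radius=10.0) == expected

    def test_output_subsequence_and_idempotent(self):
        rng = np.random.default_rng(2)
        t = np.cumsum(rng.integers(30, 400, 40))
        track = [
            fix(float(x), float(y), float(ti),
                Activity.FORAGING if f else Activity.OTHER)
            for x, y, ti, f in zip(
                rng.uniform(0, 100, 40), rng.uniform(0, 100, 40), t,
                rng.random(40) < 0.8,
            )
        ]
        once = thin_track(track)
        it = iter(track)
        assert all(any(k == x for x in it) for k in once)  # subsequence
        assert thin_track(once) == once

    def test_unsorted_track_errors(self):
        with pytest.raises(TrackOrderError):
            thin_track([fix(0, 0, 100), fix(0, 0, 50)])
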