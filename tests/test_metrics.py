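import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import conedetect as cd


def oracle_closest_pair_matching(auto: np.ndarray, manual: np.ndarray,
                                 d: float) -> list[tuple[int, int]]:
    """Naive matching oracle: repeatedly take the globally closest unmatched
    (automatic, manual) pair within distance d, ties broken on the lower
    manual then automatic index."""
    dist = np.linalg.norm(auto[:, None] - manual[None], axis=2)
    a_free = set(range(len(auto)))
    m_free = set(range(len(manual)))
    pairs = []
    while True:
        best = None
        for ai in sorted(a_free):
            for mi in sorted(m_free):
                if dist[ai, mi] <= d:
                    key = (dist[ai, mi], mi, ai)
                    if best is None or key < best:
                        best = key
        if best is None:
            return pairs
        _, mi, ai = best
        pairs.append((ai, mi))
        a_free.remove(ai)
        m_free.remove(mi)


class TestMatchRadius:
    def test_square_lattice(self):
        xs, ys = np.meshgrid(np.arange(0, 50, 10), np.arange(0, 50, 10))
        cones = cd.MarkedCones(np.column_stack([xs.ravel(), ys.ravel()]))
        assert cd.match_radius(cones) == pytest.approx(7.5)

    def test_collinear_three_points(self):
        cones = cd.MarkedCones([(0, 0), (10, 0), (30, 0)])
        # nearest-neighbor distances {10, 10, 20}, median 10
        assert cd.match_radius(cones) == pytest.approx(7.5)

    def test_jittered_hex_lattice_near_lattice_constant(self):
        img, truth = cd.generate_mosaic(cd.MosaicParams(rng_seed=3))
        d = cd.match_radius(truth)
        a = 14.0
        assert 0.6 * a <= d / 0.75 <= 1.0 * a  # median NN spacing vs lattice constant
        # brute-force re-computation
        pts = truth.points
        nn = [min(np.hypot(*(q - p)) for j, q in enumerate(pts) if j != i)
              for i, p in enumerate(pts)]
        assert d == pytest.approx(0.75 * np.median(nn))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cd.match_radius(cd.MarkedCones([(1.0, 2.0)]))

    def test_voronoi_spacing_option_close_to_nearest_on_mosaic(self):
        _, truth = cd.generate_mosaic(cd.MosaicParams(rng_seed=8))
        d_nn = cd.match_radius(truth)
        d_vor = cd.match_radius(truth, method="voronoi")
        # Voronoi-neighbor mean spacing >= nearest-neighbor spacing, same scale
        assert d_nn <= d_vor <= 1.6 * d_nn
        with pytest.raises(ValueError):
            cd.match_radius(truth, method="bogus")


class TestMatching:
    def test_identical_sets_all_tp(self, rng):
        pts = rng.uniform(20, 80, (30, 2))
        auto = cd.MarkedCones(pts, source="automatic")
        manual = cd.MarkedCones(pts.copy())
        m = cd.match_cones(auto, manual, d=3.0, image_dims=(100, 100))
        assert (m.n_tp, m.n_fp, m.n_fn) == (30, 0, 0)
        assert all(dist == 0 for _, _, dist in m.pairs)

    def test_closest_of_two_candidates_wins(self):
        manual = cd.MarkedCones([(50.0, 50.0)])
        auto = cd.MarkedCones([(52.0, 50.0), (54.0, 50.0)], source="automatic")
        m = cd.match_cones(auto, manual, d=5.0, image_dims=(100, 100))
        assert m.n_tp == 1 and m.pairs[0][0] == 0  # the nearer automatic cone
        assert m.unmatched_auto == [1]

    def test_border_pruning_applied_to_both_sets(self):
        manual = cd.MarkedCones([(3.0, 50.0), (50.0, 50.0)])
        auto = cd.MarkedCones([(3.0, 50.0), (50.0, 50.0)], source="automatic")
        m = cd.match_cones(auto, manual, d=2.0, image_dims=(100, 100), border=7)
        assert m.n_tp == 1 and m.n_manual == 1 and m.n_automatic == 1

    def test_matching_respects_radius(self, rng):
        auto = cd.MarkedCones(rng.uniform(10, 90, (25, 2)), source="automatic")
        manual = cd.MarkedCones(rng.uniform(10, 90, (25, 2)))
        m = cd.match_cones(auto, manual, d=4.0, image_dims=(100, 100))
        assert all(dist <= 4.0 for _, _, dist in m.pairs)
        # one-to-one
        assert len({p[0] for p in m.pairs}) == len(m.pairs)
        assert len({p[1] for p in m.pairs}) == len(m.pairs)

    def test_count_identities_on_random_pairs(self, rng):
        """N_automatic = N_TP + N_FP and N_manual = N_TP + N_FN after pruning."""
        for _ in range(50):
            na, nm = rng.integers(0, 40, 2)
            auto = cd.MarkedCones(rng.uniform(0, 60, (na, 2)), source="automatic")
            manual = cd.MarkedCones(rng.uniform(0, 60, (nm, 2)))
            m = cd.match_cones(auto, manual, d=3.0, image_dims=(60, 60))
            assert m.n_automatic == m.n_tp + m.n_fp
            assert m.n_manual == m.n_tp + m.n_fn

    def test_greedy_equals_bruteforce_closest_pair_oracle(self, rng):
        """The sorted-candidate matcher reproduces a naive O(n^3) oracle that
        repeatedly extracts the globally closest unmatched pair."""
        for _ in range(20):
            na, nm = rng.integers(5, 16, 2)
            a = rng.uniform(0, 30, (na, 2))
            mm = rng.uniform(0, 30, (nm, 2))
            m = cd.match_cones(cd.MarkedCones(a, source="automatic"),
                               cd.MarkedCones(mm), d=4.0)
            oracle = oracle_closest_pair_matching(a, mm, 4.0)
            assert sorted((p[0], p[1]) for p in m.pairs) == sorted(oracle)

    def test_matching_is_maximal(self, rng):
        """No unmatched automatic cone remains within d of an unmatched manual."""
        for _ in range(20):
            na, nm = rng.integers(5, 20, 2)
            a = rng.uniform(0, 30, (na, 2))
            mm = rng.uniform(0, 30, (nm, 2))
            m = cd.match_cones(cd.MarkedCones(a, source="automatic"),
                               cd.MarkedCones(mm), d=4.0)
            for ai in m.unmatched_auto:
                for mi in m.unmatched_manual:
                    assert np.hypot(*(a[ai] - mm[mi])) > 4.0


class TestMetricsArithmetic:
    def test_hand_computed_example(self):
        m = cd.MatchResult(pairs=[(i, i, 1.0) for i in range(95)],
                           unmatched_auto=list(range(95, 100)),
                           unmatched_manual=list(range(95, 100)), d=5.0)
        rec = cd.compute_metrics(m)
        assert rec.true_positive_rate == pytest.approx(0.95)
        assert rec.false_discovery_rate == pytest.approx(0.05)
        assert rec.dice == pytest.approx(0.95)

    def test_perfect_detection(self):
        m = cd.MatchResult([(0, 0, 0.0)], [], [], d=1.0)
        rec = cd.compute_metrics(m)
        assert (rec.true_positive_rate, rec.false_discovery_rate, rec.dice) == (1.0, 0.0, 1.0)

    def test_zero_tp_dice_zero(self):
        m = cd.MatchResult([], [0, 1], [0], d=1.0)
        assert cd.compute_metrics(m).dice == 0.0

    def test_zero_denominators_flagged_none(self):
        m = cd.MatchResult([], [], [], d=1.0)
        rec = cd.compute_metrics(m)
        assert rec.true_positive_rate is None
        assert rec.false_discovery_rate is None
        assert rec.dice is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_rates_in_unit_interval(self, tp, fp, fn):
        m = cd.MatchResult([(i, i, 0.5) for i in range(tp)],
                           list(range(tp, tp + fp)), list(range(tp, tp + fn)), d=2.0)
        rec = cd.compute_metrics(m)
        for v in (rec.true_positive_rate, rec.false_discovery_rate, rec.dice):
            assert v is None or 0.0 <= v <= 1.0


class TestDensity:
    def _image(self, size=100, scale=1.0):
        return cd.ConeImage(np.zeros((size, size)), scale=scale)

    def test_simple_division(self):
        # 100 cones in a 0.005 mm^2 ROI -> 20000 cones/mm^2
        rng = np.random.default_rng(0)
        img = cd.ConeImage(np.zeros((100, 100)), scale=np.sqrt(0.005) * 1000 / 100)
        cones = cd.MarkedCones(rng.uniform(5, 95, (100, 2)))
        assert cd.cone_density(cones, img) == pytest.approx(20000, rel=1e-9)

    def test_scale_doubling_quarters_density(self, rng):
        cones = cd.MarkedCones(rng.uniform(5, 95, (50, 2)))
        d1 = cd.cone_density(cones, self._image(scale=1.0))
        d2 = cd.cone_density(cones, self._image(scale=2.0))
        assert d1 == pytest.approx(4 * d2)

    def test_missing_scale_errors(self, rng):
        cones = cd.MarkedCones(rng.uniform(5, 95, (10, 2)))
        with pytest.raises(ValueError):
            cd.cone_density(cones, cd.ConeImage(np.zeros((100, 100))))

    def test_border_prune_and_pruned_area_options(self):
        # uniform grid: pruning count and area together leaves density unchanged
        xs, ys = np.meshgrid(np.arange(5, 100, 10), np.arange(5, 100, 10))
        cones = cd.MarkedCones(np.column_stack([xs.ravel(), ys.ravel()]).astype(float))
        img = cd.ConeImage(np.zeros((100, 100)), scale=1.0)
        full = cd.cone_density(cones, img)
        pruned_count_only = cd.cone_density(cones, img, border_px=10)
        both = cd.cone_density(cones, img, border_px=10, pruned_area=True)
        assert pruned_count_only < full
        assert both == pytest.approx(full, rel=0.30)  # grid discreteness
        assert both > pruned_count_only

    def test_planted_density_recovered(self):
        params = cd.MosaicParams(rng_seed=21)
        img, truth = cd.generate_mosaic(params)
        measured = cd.cone_density(truth, img)
        area = img.area_mm2()
        assert measured == pytest.approx(len(truth) / area, rel=1e-12)


class TestBlandAltman:
    def test_all_zero(self):
        ba = cd.bland_altman(np.zeros(5))
        assert (ba.mean_difference, ba.lower_limit, ba.upper_limit) == (0, 0, 0)

    def test_two_point_arithmetic(self):
        ba = cd.bland_altman([-1.0, 1.0])
        assert ba.mean_difference == 0
        assert ba.sd == pytest.approx(np.sqrt(2))
        assert ba.upper_limit == pytest.approx(1.96 * np.sqrt(2))
        assert ba.lower_limit == pytest.approx(-1.96 * np.sqrt(2))

    def test_limits_cover_95pct_gaussian(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(2.0, 3.0, 1000)
        ba = cd.bland_altman(diffs)
        frac = np.mean((diffs >= ba.lower_limit) & (diffs <= ba.upper_limit))
        assert frac == pytest.approx(0.95, abs=0.02)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            cd.bland_altman([1.0])
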