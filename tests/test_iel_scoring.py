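import numpy as np
import pytest
from shapely.geometry import Polygon, box

from ielscore.io_annotations import NucleusRecord, SlideAnnotation
from ielscore.iel_scoring import (
    ScoreParams,
    UndefinedScoreError,
    compute_iel_c,
    compute_iel_i,
    compute_iel_pc,
    compute_iel_pi,
    nuclei_in_dysplasia,
    score_slide,
    window_counts,
    window_grid,
)
from ielscore.synthetic_data import SlideSimParams, simulate_slide

from oracles import exhaustive_window_peak, points_in_polygons


def _ann(nuclei, regions, mpp=1.0, slide_id="t"):
    return SlideAnnotation(slide_id, nuclei, regions, base_mpp=mpp)


SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


class TestRestriction:
    def test_inside_vs_outside_unit_square(self):
        ann = _ann(
            [NucleusRecord(0.5, 0.5, "epithelial"), NucleusRecord(2, 2, "epithelial")],
            [SQUARE],
        )
        epi, iel = nuclei_in_dysplasia(ann)
        assert len(epi) == 1 and len(iel) == 0

    def test_boundary_nucleus_is_retained(self):
        ann = _ann([NucleusRecord(1.0, 0.5, "iel")], [SQUARE])
        _, iel = nuclei_in_dysplasia(ann)
        assert len(iel) == 1

    def test_matches_brute_force_with_overlapping_regions(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 10, size=(500, 2))
        sq1 = np.array([[1, 1], [6, 1], [6, 6], [1, 6]], dtype=float)
        sq2 = np.array([[4, 4], [9, 4], [9, 9], [4, 9]], dtype=float)
        nuclei = [NucleusRecord(x, y, "epithelial") for x, y in pts]
        epi, _ = nuclei_in_dysplasia(_ann(nuclei, [sq1, sq2]))
        expected = points_in_polygons(pts, [sq1, sq2])
        # de-duplicated: each nucleus at most once even in the overlap
        assert len(epi) == expected.sum()

    def test_no_regions_is_an_error(self):
        ann = _ann([NucleusRecord(1, 1, "iel")], [])
        with pytest.raises(ValueError, match="no dysplasia"):
            nuclei_in_dysplasia(ann)


class TestGlobalScores:
    @pytest.mark.parametrize(
        "n_iel,n_epi,expected",
        [(20, 200, 10.0), (0, 100, 0.0), (947, 9470, 10.0)],
    )
    def test_iel_c_arithmetic(self, n_iel, n_epi, expected):
        assert compute_iel_c(n_iel, n_epi) == pytest.approx(expected)

    def test_iel_c_undefined_without_epithelium(self):
        with pytest.raises(UndefinedScoreError):
            compute_iel_c(5, 0)

    @pytest.mark.parametrize("n_iel,area,expected", [(50, 2.0, 25.0), (0, 1.0, 0.0)])
    def test_iel_i_arithmetic(self, n_iel, area, expected):
        assert compute_iel_i(n_iel, area) == pytest.approx(expected)

    def test_iel_i_on_shoelace_square(self):
        # 1000x1000 px at 1.0 mpp is exactly 1 mm² by the shoelace formula
        sq = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], dtype=float)
        ann = _ann([], [sq])
        assert ann.region_area_mm2() == pytest.approx(1.0)
        assert compute_iel_i(37, ann.region_area_mm2()) == pytest.approx(37.0)

    def test_iel_i_undefined_for_zero_area(self):
        with pytest.raises(UndefinedScoreError):
            compute_iel_i(3, 0.0)


class TestWindowedScores:
    def test_window_counts_match_double_loop(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1000, size=(400, 2))
        xs, ys = window_grid(pts, 256, 128)
        counts = window_counts(pts, xs, ys, 256)
        for i, oy in enumerate(ys):
            for j, ox in enumerate(xs):
                manual = np.sum(
                    (pts[:, 0] >= ox) & (pts[:, 0] < ox + 256)
                    & (pts[:, 1] >= oy) & (pts[:, 1] < oy + 256)
                )
                assert counts[i, j] == manual

    def test_single_cluster_equals_global_ratio(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(100, 300, size=(60, 2))  # all within one 512-window
        nuclei = [NucleusRecord(x, y, "epithelial") for x, y in pts[:50]] + [
            NucleusRecord(x, y, "iel") for x, y in pts[50:]
        ]
        # min_epi equal to the cluster size forces the full-cluster window,
        # where the peak equals the global ratio
        score, hotspot = compute_iel_pc(_ann(nuclei, []), 512, 256, min_epi=50)
        assert score == pytest.approx(100 * 10 / 50)
        assert hotspot is not None

    def test_two_separated_clusters_peak_and_mediant(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 40, size=(102, 2))
        b = rng.uniform(5000, 5040, size=(130, 2))
        nuclei = (
            [NucleusRecord(x, y, "epithelial") for x, y in a[:100]]
            + [NucleusRecord(x, y, "iel") for x, y in a[100:]]
            + [NucleusRecord(x, y, "epithelial") for x, y in b[:100]]
            + [NucleusRecord(x, y, "iel") for x, y in b[100:]]
        )
        ann = _ann(nuclei, [])
        score, hotspot = compute_iel_pc(ann, 512, 256, min_epi=20)
        # brute force over the same grid windows
        epi = ann.nucleus_coords("epithelial")
        iel = ann.nucleus_coords("iel")
        xs, ys = window_grid(ann.nucleus_coords(), 512, 256)
        best = -np.inf
        for oy in ys:
            for ox in xs:
                in_w = lambda p: (p[:, 0] >= ox) & (p[:, 0] < ox + 512) & (
                    p[:, 1] >= oy
                ) & (p[:, 1] < oy + 512)
                ne, ni = in_w(epi).sum(), in_w(iel).sum()
                if ne >= 20:
                    best = max(best, 100 * ni / ne)
        assert score == pytest.approx(best)
        # the high-IEL cluster B wins and the peak dominates the global ratio
        assert score >= 30.0 - 1e-9
        assert hotspot[0] > 4000 and hotspot[1] > 4000
        iel_c = compute_iel_c(32, 200)
        assert iel_c == pytest.approx(16.0)
        assert score >= iel_c

    def test_strided_peak_matches_exhaustive_at_stride_one(self, small_slide):
        ann, _ = small_slide
        nuclei = [NucleusRecord(np.floor(n.x), np.floor(n.y), n.cls) for n in ann.nuclei]
        ann_int = _ann(nuclei, ann.regions)
        epi = ann_int.nucleus_coords("epithelial")
        iel = ann_int.nucleus_coords("iel")
        oracle = exhaustive_window_peak(epi, iel, 512, 20)
        ours, _ = compute_iel_pc(ann_int, 512, 1, 20)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_no_eligible_window_returns_absent_with_warning(self):
        nuclei = [NucleusRecord(10, 10, "epithelial"), NucleusRecord(12, 12, "iel")]
        with pytest.warns(UserWarning, match="IEL-PC undefined"):
            score, hotspot = compute_iel_pc(_ann(nuclei, []), 512, 256, min_epi=20)
        assert score is None and hotspot is None

    def test_window_params_validated(self, unit_square_annotation):
        with pytest.raises(ValueError):
            compute_iel_pc(unit_square_annotation, 0, 256, 20)
        with pytest.raises(ValueError):
            compute_iel_pc(unit_square_annotation, 512, -1, 20)

    def test_resolution_must_be_scoring_resolution(self):
        ann = _ann([NucleusRecord(1, 1, "iel")], [], mpp=0.25)
        with pytest.raises(ValueError, match="rescale"):
            compute_iel_pc(ann)

    def test_iel_pi_full_window_arithmetic(self):
        # dysplasia covers the whole window: denominator 512² px² = 0.262144 mm²
        big = np.array([[0, 0], [1800, 0], [1800, 1800], [0, 1800]], float)
        rng = np.random.default_rng(4)
        pts = rng.uniform(700, 900, size=(26, 2))
        nuclei = [NucleusRecord(x, y, "iel") for x, y in pts] + [
            NucleusRecord(x, y + 1, "epithelial") for x, y in pts
        ]
        ann = SlideAnnotation("t", nuclei, [big], base_mpp=1.0)
        score, hotspot = compute_iel_pi(ann, 512, 256, min_area_mm2=0.262144 - 1e-9)
        assert score == pytest.approx(26 / 0.262144, rel=1e-9)

    def test_iel_pi_matches_scalar_clipping_oracle(self, small_slide):
        ann, _ = small_slide
        score, hotspot = compute_iel_pi(ann, 512, 256, min_area_mm2=0.05)
        union = ann.region_union()
        iel = ann.nucleus_coords("iel")
        xs, ys = window_grid(ann.nucleus_coords(), 512, 256)
        best = -np.inf
        arg = None
        for oy in ys:
            for ox in xs:
                area = union.intersection(box(ox, oy, ox + 512, oy + 512)).area * 1e-6
                if area < 0.05:
                    continue
                ni = np.sum(
                    (iel[:, 0] >= ox) & (iel[:, 0] < ox + 512)
                    & (iel[:, 1] >= oy) & (iel[:, 1] < oy + 512)
                )
                if ni / area > best:
                    best, arg = ni / area, (ox, oy)
        assert score == pytest.approx(best, rel=1e-9)
        assert hotspot == pytest.approx(arg)

    def test_iel_pi_absent_when_no_window_has_enough_dysplasia(self):
        tiny = np.array([[0, 0], [50, 0], [50, 50], [0, 50]], float)
        nuclei = [NucleusRecord(10, 10, "iel"), NucleusRecord(20, 20, "epithelial")]
        with pytest.warns(UserWarning, match="IEL-PI undefined"):
            score, _ = compute_iel_pi(_ann(nuclei, [tiny]), 512, 256, min_area_mm2=0.1)
        assert score is None


class TestScoreSlideProperties:
    def test_orchestrated_scores_and_mediant(self, small_slide):
        ann, truth = small_slide
        s = score_slide(ann, ScoreParams(min_epi=1))
        assert s.n_epi == truth["n_epi"]
        assert s.n_iel == truth["n_iel"]
        assert s.iel_c == pytest.approx(100 * s.n_iel / s.n_epi)
        assert s.iel_i == pytest.approx(s.n_iel / s.dysplasia_area_mm2)
        # with min_epi=1 and half-window stride every nucleus is covered, so
        # the global ratio is a weighted mediant of window ratios
        assert s.iel_pc >= s.iel_c - 1e-12

    @pytest.mark.parametrize("seed", range(12))
    def test_mediant_property_across_seeds(self, seed):
        from ielscore.synthetic_data import blob_polygon

        rng = np.random.default_rng(seed)
        poly = blob_polygon(rng, center=(500, 500), mean_radius=300)
        ann, _ = simulate_slide(
            SlideSimParams(seed=seed, regions=[poly], epi_density=1500, iel_fraction=0.1)
        )
        s = score_slide(ann, ScoreParams(min_epi=1))
        assert s.iel_pc >= s.iel_c - 1e-12

    def test_translation_invariance(self, small_slide):
        ann, _ = small_slide
        shift = np.array([313.0, 517.0])
        nuclei = [NucleusRecord(n.x + shift[0], n.y + shift[1], n.cls) for n in ann.nuclei]
        regions = [r + shift for r in ann.regions]
        moved = SlideAnnotation(ann.slide_id, nuclei, regions, ann.base_mpp)
        a = score_slide(ann)
        b = score_slide(moved)
        assert b.iel_c == pytest.approx(a.iel_c, abs=1e-12)
        assert b.iel_pc == pytest.approx(a.iel_pc, rel=1e-12)
        assert b.iel_i == pytest.approx(a.iel_i, rel=1e-9)
        assert b.iel_pi == pytest.approx(a.iel_pi, rel=1e-9)

    def test_resolution_invariance_of_ratio_and_area_scores(self, small_slide):
        ann, _ = small_slide
        # the same physical slide expressed at scanner resolution 0.25 mpp
        f = 1.0 / 0.25
        nuclei = [NucleusRecord(n.x * f, n.y * f, n.cls) for n in ann.nuclei]
        regions = [r * f for r in ann.regions]
        fine = SlideAnnotation(ann.slide_id, nuclei, regions, base_mpp=0.25)
        a = score_slide(ann)
        b = score_slide(fine)
        assert b.iel_c == pytest.approx(a.iel_c, rel=1e-9)
        assert b.iel_i == pytest.approx(a.iel_i, rel=1e-9)

    def test_adding_an_iel_never_decreases_iel_c_or_iel_i(self, small_slide):
        ann, _ = small_slide
        base = score_slide(ann)
        centroid = ann.region_union().representative_point()
        nuclei = ann.nuclei + [NucleusRecord(centroid.x, centroid.y, "iel")]
        more = SlideAnnotation(ann.slide_id, nuclei, ann.regions, ann.base_mpp)
        s = score_slide(more)
        assert s.iel_c >= base.iel_c
        assert s.iel_i >= base.iel_i

    def test_zero_iels_gives_zero_scores(self):
        ann, _ = simulate_slide(SlideSimParams(seed=5, epi_density=2000, iel_fraction=0.0))
        s = score_slide(ann)
        assert s.iel_c == 0.0 and s.iel_pc == 0.0
        assert s.iel_i == 0.0 and s.iel_pi == 0.0

    def test_planted_hotspot_is_localized(self):
        ann, truth = simulate_slide(
            SlideSimParams(
                seed=9,
                epi_density=3000,
                iel_fraction=0.08,
                hotspots=[(1200.0, 1200.0, 250.0, 0.5)],
            )
        )
        s = score_slide(ann)
        cx, cy, r, _ = truth["hotspots"][0]
        wx, wy = s.hotspot_pc
        # window center within hotspot radius + one window of the planted center
        assert abs(wx + 256 - cx) <= r + 512
        assert abs(wy + 256 - cy) <= r + 512

    def test_epithelium_free_slide_nulls_ratio_scores_only(self):
        sq = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], float)
        nuclei = [NucleusRecord(500, 500, "iel")]
        with pytest.warns(UserWarning):
            s = score_slide(SlideAnnotation("t", nuclei, [sq], 1.0))
        assert s.iel_c is None and s.iel_pc is None
        assert s.iel_i == pytest.approx(1.0)
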