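import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiicsig.errors import UndefinedDensityError
from tiicsig.spatial_metrics import (
    effective_density,
    effective_score,
    nearest_tumour_distance,
    pairwise_distances,
    spatial_table,
)


def frame(points, roi="r1"):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return pd.DataFrame({
        "roi_id": roi, "x_um": pts[:, 0], "y_um": pts[:, 1],
    })


# ---------------------------------------------------------------- oracles

def brute_force_paired(immune, tumour, r):
    """O(n^2) pairing oracle over same-ROI pairs."""
    n_paired = 0
    for _, ic in immune.iterrows():
        for _, tc in tumour.iterrows():
            if ic["roi_id"] != tc["roi_id"]:
                continue
            d = np.hypot(ic["x_um"] - tc["x_um"], ic["y_um"] - tc["y_um"])
            if d <= r:
                n_paired += 1
                break
    return n_paired


def brute_force_nearest(immune, tumour):
    out = []
    for _, ic in immune.iterrows():
        best = np.nan
        for _, tc in tumour.iterrows():
            if ic["roi_id"] != tc["roi_id"]:
                continue
            d = np.hypot(ic["x_um"] - tc["x_um"], ic["y_um"] - tc["y_um"])
            if not np.isfinite(best) or d < best:
                best = d
        out.append(best)
    return np.array(out)


class TestPairwiseDistances:
    def test_3_4_5_triangle(self):
        d = pairwise_distances([(0, 0)], [(3, 4)])
        assert d[0, 0] == pytest.approx(5.0)

    def test_zero_diagonal_and_symmetry(self):
        pts = [(0, 0), (1, 2), (5, 5)]
        d = pairwise_distances(pts, pts)
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)

    def test_empty_input_empty_matrix(self):
        assert pairwise_distances(np.empty((0, 2)), [(1, 1)]).shape == (0, 1)

    def test_against_formula_loop(self, rng):
        a = rng.uniform(0, 100, (20, 2))
        b = rng.uniform(0, 100, (15, 2))
        d = pairwise_distances(a, b)
        for i in range(20):
            for j in range(15):
                expect = np.sqrt(((a[i] - b[j]) ** 2).sum())
                assert abs(d[i, j] - expect) < 1e-9


class TestEffectiveScore:
    def test_worked_example(self):
        immune = frame([(0, 0), (15, 0), (100, 100), (30, 0)])
        tumour = frame([(10, 0), (50, 50), (12, 0)])
        res = effective_score(immune, tumour, 20)
        assert res.n_paired == 3
        assert res.effective_score == pytest.approx(0.75)

    def test_single_cell_within_radius(self):
        res = effective_score(frame([(0, 0)]), frame([(3, 4)]), 10)
        assert res.effective_score == 1.0

    def test_boundary_tie_included(self):
        # closed pairing interval: d == r counts
        res = effective_score(frame([(0, 0)]), frame([(20, 0)]), 20)
        assert res.n_paired == 1

    def test_monotone_in_radius(self):
        immune = frame([(0, 0), (15, 0), (100, 100), (30, 0)])
        tumour = frame([(10, 0), (50, 50), (12, 0)])
        s10 = effective_score(immune, tumour, 10).effective_score
        s30 = effective_score(immune, tumour, 30).effective_score
        assert s10 <= s30

    def test_no_immune_cells_missing_not_zero(self):
        res = effective_score(frame(np.empty((0, 2))), frame([(1, 1)]), 20)
        assert res.n_immune == 0
        assert np.isnan(res.effective_score)

    def test_cross_roi_pairs_never_formed(self):
        immune = frame([(0, 0)], roi="r1")
        tumour = frame([(1, 0)], roi="r2")
        res = effective_score(immune, tumour, 20)
        assert res.n_paired == 0

    def test_pooling_across_rois_single_division(self):
        immune = pd.concat([frame([(0, 0), (500, 500)], "r1"),
                            frame([(0, 0)], "r2")], ignore_index=True)
        tumour = pd.concat([frame([(5, 0)], "r1"), frame([(400, 400)], "r2")],
                           ignore_index=True)
        res = effective_score(immune, tumour, 20)
        assert (res.n_immune, res.n_paired) == (3, 1)
        assert res.effective_score == pytest.approx(1 / 3)

    def test_score_times_n_immune_is_integer(self, rng):
        immune = frame(rng.uniform(0, 900, (57, 2)))
        tumour = frame(rng.uniform(0, 900, (40, 2)))
        res = effective_score(immune, tumour, 25)
        prod = res.effective_score * res.n_immune
        assert prod == pytest.approx(round(prod))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_kdtree_equals_brute_force(self, seed):
        r = np.random.default_rng(seed)
        immune = frame(r.uniform(0, 300, (r.integers(1, 60), 2)))
        tumour = frame(r.uniform(0, 300, (r.integers(0, 40), 2)))
        radius = float(r.uniform(5, 60))
        res = effective_score(immune, tumour, radius)
        assert res.n_paired == brute_force_paired(immune, tumour, radius)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_translation_rotation_invariance(self, seed):
        r = np.random.default_rng(seed)
        ia = r.uniform(100, 200, (20, 2))
        ta = r.uniform(100, 200, (15, 2))
        theta, shift = r.uniform(0, 2 * np.pi), r.uniform(-50, 50, 2)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        res = effective_score(frame(ia), frame(ta), 25)
        res2 = effective_score(frame(ia @ rot.T + shift), frame(ta @ rot.T + shift), 25)
        assert res.n_paired == res2.n_paired


class TestEffectiveDensity:
    def test_worked_example_in_one_mm2(self):
        immune = frame([(0, 0), (15, 0), (100, 100), (30, 0)])
        tumour = frame([(10, 0), (50, 50), (12, 0)])
        assert effective_density(immune, tumour, area_mm2=1.0, radius_um=20) == pytest.approx(3.0)

    def test_no_tumour_cells_zero(self):
        immune = frame([(0, 0)])
        tumour = frame(np.empty((0, 2)))
        assert effective_density(immune, tumour, area_mm2=1.0) == 0.0

    def test_zero_area_errors(self):
        with pytest.raises(UndefinedDensityError):
            effective_density(frame([(0, 0)]), frame([(1, 1)]), area_mm2=0.0)

    def test_effective_density_bounded_by_density(self, rng):
        # property sweep over 50 random configurations
        for _ in range(50):
            n_i = int(rng.integers(1, 80))
            immune = frame(rng.uniform(0, 930, (n_i, 2)))
            tumour = frame(rng.uniform(0, 930, (int(rng.integers(0, 60)), 2)))
            area = float(rng.uniform(0.2, 1.0))
            ed = effective_density(immune, tumour, area_mm2=area, radius_um=20)
            assert ed <= n_i / area + 1e-12


class TestNearestTumourDistance:
    def test_trivial_min(self):
        d = nearest_tumour_distance(frame([(0, 0)]), frame([(3, 4), (6, 8)]))
        assert d.iloc[0] == pytest.approx(5.0)

    def test_coincident_zero(self):
        d = nearest_tumour_distance(frame([(7, 7)]), frame([(7, 7)]))
        assert d.iloc[0] == 0.0

    def test_roi_without_tumour_cells_missing(self):
        immune = pd.concat([frame([(0, 0)], "r1"), frame([(0, 0)], "r2")],
                           ignore_index=True)
        tumour = frame([(1, 1)], "r1")
        d = nearest_tumour_distance(immune, tumour)
        assert np.isfinite(d.iloc[0])
        assert np.isnan(d.iloc[1])

    def test_against_brute_force(self, rng):
        immune = frame(rng.uniform(0, 500, (30, 2)))
        tumour = frame(rng.uniform(0, 500, (25, 2)))
        got = nearest_tumour_distance(immune, tumour).to_numpy()
        expect = brute_force_nearest(immune, tumour)
        assert np.allclose(got, expect)


class TestSpatialTable:
    def test_long_format_and_monotonicity(self, small_study):
        from tiicsig.phenotyping import default_registry

        t = small_study.table
        df = spatial_table(t.cells, t.rois, default_registry(),
                           phenotypes=["CD8+", "CD68+STING+"])
        assert set(df["radius_um"]) == {10.0, 20.0, 30.0}
        wide = df.pivot_table(index=["patient_id", "phenotype"],
                              columns="radius_um", values="effective_score")
        assert (wide[10.0] <= wide[20.0] + 1e-12).all()
        assert (wide[20.0] <= wide[30.0] + 1e-12).all()

    def test_effective_density_le_density(self, small_study):
        from tiicsig.density_metrics import density_table
        from tiicsig.phenotyping import default_registry

        t = small_study.table
        reg = default_registry()
        spat = spatial_table(t.cells, t.rois, reg, phenotypes=["CD8+"], radii_um=(20,))
        dens = density_table(t.cells, t.rois, reg, phenotypes=["CD8+"], roi_classes=("TC",))
        merged = spat.merge(dens, on=["patient_id", "phenotype"])
        assert (merged["effective_density"] <= merged["density"] + 1e-12).all()
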