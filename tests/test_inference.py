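"""Cluster extraction, jackknife sensitivity, and Egger bias tests."""

import numpy as np
import pytest
from scipy import stats

import coordmeta as cm
from coordmeta.inference import ThresholdSpec, _egger_fit


def _z_p_maps(grid, z_values):
    z = cm.VolumeMap(grid, z_values, "z")
    p = cm.VolumeMap(grid, np.clip(2 * stats.norm.sf(np.abs(z_values)), 1e-300, 1.0), "p")
    return z, p


def _blob_values(grid, center, radius, z_val):
    coords = grid.mask_coords_mm()
    vals = np.zeros(grid.n_voxels)
    inside = np.linalg.norm(coords - np.asarray(center, float), axis=1) <= radius
    vals[inside] = z_val
    return vals, int(inside.sum())


class TestExtractClusters:
    def test_null_map_yields_no_clusters(self, small_grid):
        z, p = _z_p_maps(small_grid, np.zeros(small_grid.n_voxels))
        assert cm.extract_clusters(z, p) == []

    def test_blob_of_twelve_voxels_is_one_cluster(self, small_grid):
        coords = small_grid.mask_coords_mm()
        vals = np.zeros(small_grid.n_voxels)
        order = np.argsort(np.linalg.norm(coords - np.array([0.0, 0.0, 0.0]), axis=1))
        vals[order[:12]] = -4.0
        z, p = _z_p_maps(small_grid, vals)
        clusters = cm.extract_clusters(z, p)
        assert len(clusters) == 1
        assert clusters[0].extent == 12
        assert clusters[0].sign == "reduction"

    def test_blob_below_extent_threshold_discarded(self, small_grid):
        coords = small_grid.mask_coords_mm()
        vals = np.zeros(small_grid.n_voxels)
        order = np.argsort(np.linalg.norm(coords - np.array([0.0, 0.0, 0.0]), axis=1))
        vals[order[:9]] = -4.0
        z, p = _z_p_maps(small_grid, vals)
        assert cm.extract_clusters(z, p) == []

    def test_low_peak_z_discarded(self, small_grid):
        vals, n = _blob_values(small_grid, (0, 0, 0), 8.0, -3.5)
        z, p = _z_p_maps(small_grid, vals)
        spec = ThresholdSpec(p_voxel=0.005, min_peak_abs_z=4.0, min_extent_voxels=10)
        assert cm.extract_clusters(z, p, spec) == []

    def test_signs_processed_separately(self, small_grid):
        vneg, _ = _blob_values(small_grid, (-10, 0, 0), 6.0, -4.0)
        vpos, _ = _blob_values(small_grid, (10, 0, 0), 6.0, 4.0)
        z, p = _z_p_maps(small_grid, vneg + vpos)
        clusters = cm.extract_clusters(z, p)
        assert sorted(c.sign for c in clusters) == ["increase", "reduction"]

    def test_raising_min_extent_never_adds_clusters(self, small_grid):
        rng = np.random.default_rng(9)
        z, p = _z_p_maps(small_grid, rng.normal(0, 1.6, small_grid.n_voxels))
        counts = []
        for ext in (1, 5, 10, 20, 40):
            spec = ThresholdSpec(p_voxel=0.01, min_peak_abs_z=1.0, min_extent_voxels=ext)
            counts.append(len(cm.extract_clusters(z, p, spec)))
        assert counts == sorted(counts, reverse=True)

    def test_peak_is_max_abs_z_with_smallest_index_tie_break(self, small_grid):
        vals, _ = _blob_values(small_grid, (0, 0, 0), 8.0, -4.0)  # flat plateau: tie
        z, p = _z_p_maps(small_grid, vals)
        (cluster,) = cm.extract_clusters(z, p)
        lin = sorted(cluster.voxel_indices)
        z3 = z.to_3d(0.0).ravel(order="C")
        peak_candidates = [l for l in lin if abs(z3[l]) == max(abs(z3[l2]) for l2 in lin)]
        ijk = np.unravel_index(min(peak_candidates), small_grid.shape, order="C")
        expected_mm = tuple(small_grid.ijk_to_mm(np.array(ijk))[0])
        assert cluster.peak_mni == pytest.approx(expected_mm)

    def test_determinism(self, small_grid):
        rng = np.random.default_rng(10)
        z, p = _z_p_maps(small_grid, rng.normal(0, 1.8, small_grid.n_voxels))
        a = cm.extract_clusters(z, p, ThresholdSpec(p_voxel=0.05, min_extent_voxels=5))
        b = cm.extract_clusters(z, p, ThresholdSpec(p_voxel=0.05, min_extent_voxels=5))
        assert a == b


def _constant_maps(grid, study_id, effect, variance=0.04):
    return cm.StudyMaps(
        study_id,
        cm.VolumeMap(grid, np.asarray(effect, float), "effect_size"),
        cm.VolumeMap(grid, np.full(grid.n_voxels, variance), "variance"),
    )


class TestJackknife:
    def _strong_identical(self, grid, n):
        vals, _ = _blob_values(grid, (0, 0, 0), 8.0, -1.0)
        return [_constant_maps(grid, f"S{i}", vals) for i in range(n)]

    def test_identical_studies_replicate_fully(self, small_grid):
        n = 6
        result = cm.jackknife(self._strong_identical(small_grid, n))
        assert result.n_iterations == n
        assert (result.totals == n).all()
        assert result.table.all().all()

    def test_table_shape_contract(self, small_grid):
        n = 5
        result = cm.jackknife(self._strong_identical(small_grid, n))
        assert result.table.shape[0] == n
        assert list(result.table.index) == [f"S{i}" for i in range(n)]

    def test_single_carrier_cluster_drops_when_omitted(self, small_grid):
        # a weak cluster carried by one study of six survives everyone
        # else's omission but vanishes when its carrier is left out
        shared, _ = _blob_values(small_grid, (-10, 0, 0), 6.0, -1.0)
        carried, _ = _blob_values(small_grid, (12, 0, 0), 6.0, -1.0)
        sm = [_constant_maps(small_grid, "carrier", shared + carried)] + [
            _constant_maps(small_grid, f"N{i}", shared) for i in range(5)
        ]
        lenient = ThresholdSpec(p_voxel=0.4, min_peak_abs_z=0.5, min_extent_voxels=5)
        result = cm.jackknife(sm, lenient)
        assert result.table.shape[1] == 2  # shared + carried clusters
        carried_col = result.table.columns[result.totals.argmin()]
        assert not result.table.loc["carrier", carried_col]
        assert result.table.drop(index="carrier")[carried_col].all()
        shared_col = [c for c in result.table.columns if c != carried_col][0]
        assert result.table[shared_col].all()

    def test_requires_three_studies(self, small_grid):
        with pytest.raises(ValueError):
            cm.jackknife(self._strong_identical(small_grid, 2))


class TestEgger:
    def test_identical_studies_zero_intercept(self, small_grid):
        vals, _ = _blob_values(small_grid, (0, 0, 0), 8.0, -1.0)
        sm = [_constant_maps(small_grid, f"S{i}", vals) for i in range(5)]
        maps = cm.pooled_maps(sm)
        clusters = cm.extract_clusters(maps["z"], maps["p"])
        assert clusters
        (res,) = cm.egger_at_peaks(sm, clusters[:1])
        assert res.intercept == 0.0
        assert res.n_studies == 5

    def test_four_study_textbook_wls(self):
        # frozen oracle: OLS of g/s on 1/s, computed independently by hand
        g = np.array([0.5, 0.8, 0.2, 0.6])
        s = np.array([0.2, 0.4, 0.25, 0.3])
        b0, se, t, p = _egger_fit(g, s)
        assert b0 == pytest.approx(1.4979296066252583, abs=1e-9)
        assert se == pytest.approx(1.8309785167459847, abs=1e-9)
        assert t == pytest.approx(0.8181033217622777, abs=1e-9)
        assert p == pytest.approx(0.4992626016212832, abs=1e-9)

    def test_funnel_coordinates_returned(self, small_grid):
        rng = np.random.default_rng(11)
        vals, _ = _blob_values(small_grid, (0, 0, 0), 8.0, -1.0)
        sm = [
            _constant_maps(small_grid, f"S{i}", vals * rng.uniform(0.8, 1.2), variance=float(rng.uniform(0.02, 0.1)))
            for i in range(6)
        ]
        maps = cm.pooled_maps(sm)
        clusters = cm.extract_clusters(maps["z"], maps["p"])
        res = cm.egger_at_peaks(sm, clusters)[0]
        assert list(res.funnel.columns) == ["study_id", "effect", "precision"]
        assert len(res.funnel) == 6
        assert np.all(res.funnel["precision"] > 0)

    def test_requires_three_studies(self, small_grid):
        vals, _ = _blob_values(small_grid, (0, 0, 0), 8.0, -1.0)
        sm = [_constant_maps(small_grid, f"S{i}", vals) for i in range(2)]
        with pytest.raises(ValueError):
            cm.egger_at_peaks(sm, [])


class TestClusterEffectPeak:
    def test_effect_extremum_located(self, small_grid):
        coords = small_grid.mask_coords_mm()
        vals = -np.exp(-np.linalg.norm(coords - np.array([4.0, 0.0, -2.0]), axis=1) ** 2 / 50.0)
        z, p = _z_p_maps(small_grid, vals * 6.0)
        (cluster,) = cm.extract_clusters(z, p, ThresholdSpec(p_voxel=0.05, min_extent_voxels=5))
        eff_map = cm.VolumeMap(small_grid, vals, "effect_size")
        mm, value = cm.cluster_effect_peak(eff_map, cluster)
        assert np.allclose(mm, (4.0, 0.0, -2.0))
        assert value == pytest.approx(vals.min())
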