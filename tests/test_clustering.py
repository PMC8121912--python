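"""Tessellation clustering: densities, segmentation, sizing, counting."""

import numpy as np
import pytest

from synapsim.clustering import (Cluster, ClusterError, EmitterCalibration,
                                 LocalizationField, centroid_distances,
                                 cluster_report, estimate_molecule_count,
                                 fit_anisotropic_gaussian, local_density,
                                 segment_level1, segment_level2)
from synapsim.synthetic import (GaussianClusterSpec, SMLMFieldSpec,
                                gen_smlm_field)

FWHM = 2.3548200450309493


def planted_field(rng, n_cluster=300, r_cluster=150.0, contrast=10.0,
                  size=2000.0):
    """Uniform background plus a uniform disc cluster of the given
    density contrast; returns (field, cluster_point_mask)."""
    cluster_density = n_cluster / (np.pi * r_cluster ** 2)
    bg_density = cluster_density / contrast
    n_bg = rng.poisson(bg_density * size ** 2)
    bg = rng.random((n_bg, 2)) * size
    rr = r_cluster * np.sqrt(rng.random(n_cluster))
    th = 2 * np.pi * rng.random(n_cluster)
    cl = size / 2 + np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    pts = np.vstack([bg, cl])
    mask = np.zeros(len(pts), dtype=bool)
    mask[n_bg:] = True
    return LocalizationField(points=pts), mask


class TestLocalDensity:
    def test_regular_grid_interior_density(self):
        s = 10.0
        xs = np.arange(30) * s
        gx, gy = np.meshgrid(xs, xs)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        dens = local_density(pts)
        interior = ((pts[:, 0] > 2 * s) & (pts[:, 0] < 27 * s)
                    & (pts[:, 1] > 2 * s) & (pts[:, 1] < 27 * s))
        assert np.allclose(dens[interior], 1 / s ** 2, rtol=0.05)

    def test_scaling_law(self, rng):
        pts = rng.random((200, 2)) * 1000
        d1 = local_density(pts)
        d2 = local_density(2 * pts)
        nz = d1 > 0
        assert np.allclose(d2[nz], d1[nz] / 4.0)

    def test_three_points_all_border(self):
        dens = local_density(np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]))
        assert np.allclose(dens, 0.0)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        with pytest.raises(ClusterError):
            local_density(pts)


class TestSegmentation:
    def test_planted_cluster_recovered(self, rng):
        """One 10x-contrast disc cluster: exactly one level-1 cluster,
        precision and recall >= 0.9."""
        field, mask = planted_field(rng)
        clusters = segment_level1(field)
        assert len(clusters) == 1
        members = np.zeros(len(field), dtype=bool)
        members[clusters[0].members] = True
        recall = (members & mask).sum() / mask.sum()
        precision = (members & mask).sum() / members.sum()
        assert recall >= 0.9
        assert precision >= 0.9

    def test_uniform_field_yields_no_clusters(self):
        """Density fluctuations of a uniform field stay below the
        min_points filter (the calibration behind the default)."""
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            field = LocalizationField(points=rng.random((1500, 2)) * 2000)
            assert len(segment_level1(field)) == 0

    def test_nanoclusters_nested_and_disjoint(self, rng):
        """Two hotspots inside one cluster -> two level-2 nanoclusters
        with disjoint members, all inside the parent."""
        parent_pts = rng.random((600, 2)) * 300
        hot1 = rng.normal((80, 80), 30, size=(150, 2))    # ~4x parent density
        hot2 = rng.normal((220, 220), 30, size=(150, 2))
        bg = rng.random((4000, 2)) * 3000
        pts = np.vstack([bg, parent_pts, hot1, hot2])
        field = LocalizationField(points=pts)
        lvl1 = segment_level1(field)
        assert len(lvl1) >= 1
        parent = max(lvl1, key=lambda c: c.n_points)
        lvl2 = segment_level2(field, parent)
        assert len(lvl2) == 2
        parent_set = set(parent.members.tolist())
        seen = set()
        for nc in lvl2:
            s = set(nc.members.tolist())
            assert s <= parent_set          # nesting
            assert not (s & seen)           # disjoint within level
            seen |= s
        cents = lvl2.centroids()
        assert np.hypot(*(cents[0] - cents[1])) > 100

    def test_homogeneous_parent_has_no_nanoclusters(self, rng):
        pts = rng.random((400, 2)) * 200
        parent = Cluster(level=1, members=np.arange(400),
                         centroid=pts.mean(axis=0), n_points=400, area=4e4)
        field = LocalizationField(points=pts)
        assert len(segment_level2(field, parent)) == 0


class TestMoleculeCount:
    def test_ratio_arithmetic(self):
        calib = EmitterCalibration(10.0)
        assert estimate_molecule_count(200, calib) == 20
        assert estimate_molecule_count(0, calib) == 0
        assert estimate_molecule_count(25, calib) == 3      # half-up
        assert estimate_molecule_count(25, calib, rounded=False) == 2.5

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ClusterError):
            EmitterCalibration(0.0)

    def test_generator_recovery_within_20pct(self):
        """15 emitters with mean-12 blinking: emitter-normalized counts
        recover the truth within ±20% for most fields and on average."""
        calib = EmitterCalibration(12.0)
        estimates = []
        for seed in range(60):
            spec = SMLMFieldSpec(background_density=0.0,
                                 clusters=(GaussianClusterSpec(
                                     (1000.0, 1000.0), 34.0, 15),),
                                 seed=seed)
            field, truth = gen_smlm_field(spec)
            estimates.append(estimate_molecule_count(len(field), calib))
        estimates = np.asarray(estimates)
        assert abs(estimates.mean() - 15) / 15 < 0.10
        assert np.mean(np.abs(estimates - 15) / 15 <= 0.20) >= 0.70


class TestGaussianFWHM:
    def test_isotropic_sigma34_gives_80nm(self, rng):
        pts = rng.normal(scale=34.0, size=(5000, 2))
        fw_maj, fw_min, fw_mean = fit_anisotropic_gaussian(pts)
        assert fw_mean == pytest.approx(FWHM * 34.0, rel=0.02)

    def test_anisotropy_ratio(self, rng):
        pts = rng.normal(size=(5000, 2)) * [40.0, 20.0]
        fw_maj, fw_min, _ = fit_anisotropic_gaussian(pts)
        assert fw_maj / fw_min == pytest.approx(2.0, rel=0.05)

    def test_large_sample_sigma50(self, rng):
        pts = rng.normal(scale=50.0, size=(10000, 2))
        _, _, fw_mean = fit_anisotropic_gaussian(pts)
        assert fw_mean == pytest.approx(117.7, rel=0.03)

    def test_estimator_consistency(self, rng):
        """Relative error shrinks as the sample grows."""
        errs = []
        for n in (50, 500, 50000):
            pts = rng.normal(scale=30.0, size=(n, 2))
            _, _, fw = fit_anisotropic_gaussian(pts)
            errs.append(abs(fw - FWHM * 30.0) / (FWHM * 30.0))
        assert errs[-1] < 0.01
        assert errs[-1] <= errs[0]

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ClusterError):
            fit_anisotropic_gaussian(rng.normal(size=(9, 2)))


def square_clusters(centers):
    cs = [Cluster(level=2, members=np.empty(0, int), centroid=np.asarray(c),
                  n_points=10, area=1.0) for c in centers]
    from synapsim.clustering import ClusterSet
    return ClusterSet(level=2, clusters=cs)


class TestCentroidDistances:
    def test_identical_centroids_give_zero(self):
        a = square_clusters([(0, 0), (100, 100)])
        df = centroid_distances(a, a, pairing_radius=50.0)
        assert np.allclose(df.distance_nm, 0.0)

    def test_uniform_shift(self):
        a = square_clusters([(0, 0), (200, 0), (0, 300)])
        b = square_clusters([(40, 0), (240, 0), (40, 300)])
        df = centroid_distances(a, b, pairing_radius=100.0)
        assert np.allclose(df.distance_nm, 40.0)

    def test_unpaired_beyond_radius(self):
        a = square_clusters([(0, 0)])
        b = square_clusters([(500, 0)])
        df = centroid_distances(a, b, pairing_radius=100.0)
        assert not df.paired.iloc[0]
        assert np.isnan(df.distance_nm.iloc[0])

    def test_two_channel_offset_recovered(self):
        """Two channels of the same emitters offset by 30 nm: paired
        centroid distances concentrate near 30 nm at high counts."""
        base = dict(background_density=0.0,
                    clusters=(GaussianClusterSpec((800.0, 800.0), 30.0, 60),),
                    loc_noise_nm=5.0)
        fa, _ = gen_smlm_field(SMLMFieldSpec(channel="a", seed=5, **base))
        fb, _ = gen_smlm_field(SMLMFieldSpec(channel="b", seed=5,
                                             channel_offset_nm=(30.0, 0.0),
                                             **base))
        ca = segment_level1(fa)
        cb = segment_level1(fb)
        assert len(ca) == 1 and len(cb) == 1
        df = centroid_distances(ca, cb, pairing_radius=100.0)
        assert df.distance_nm.iloc[0] == pytest.approx(30.0, abs=5.0)


class TestRigidInvariance:
    def test_statistics_invariant_under_rotation_translation(self, rng):
        field, _ = planted_field(rng)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = LocalizationField(points=field.points @ rot.T + [500.0, -200.0])
        t1 = cluster_report(field, EmitterCalibration(12.0))
        t2 = cluster_report(moved, EmitterCalibration(12.0))
        assert len(t1) == len(t2)
        assert t1.n_locs.tolist() == t2.n_locs.tolist()
        assert np.allclose(t1.fwhm_mean_nm, t2.fwhm_mean_nm, rtol=1e-6)
        assert np.allclose(t1.area_nm2, t2.area_nm2, rtol=1e-6)
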