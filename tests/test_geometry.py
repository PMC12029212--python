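import numpy as np
import pandas as pd
import pytest

from nlo.geometry import (
    asymmetric_distance,
    centromere_distance,
    mask_morphology,
    morphology_pca,
    normalize_nucleus,
    polarity_metrics,
    rim_pole_contrast,
    tsa_convolve,
)


def digitized_sphere(r, pad=5):
    n = 2 * r + 2 * pad + 1
    zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= r**2


VOX100 = (100.0, 100.0, 100.0)


class TestMorphology:
    @pytest.mark.parametrize("r,tol", [(10, 0.05), (25, 0.02)])
    def test_sphere_volume_and_area_vs_analytic(self, r, tol):
        rep = mask_morphology(digitized_sphere(r), VOX100)
        r_um = r * 0.1
        assert abs(rep["volume_um3"] - 4 / 3 * np.pi * r_um**3) < tol * 4 / 3 * np.pi * r_um**3
        assert abs(rep["surface_area_um2"] - 4 * np.pi * r_um**2) < tol * 4 * np.pi * r_um**2

    def test_single_voxel_volume_exact(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        rep = mask_morphology(m, VOX100)
        assert rep["volume_um3"] == pytest.approx(1e-3)
        assert rep["n_components"] == 1

    def test_two_disjoint_spheres_additive(self):
        a = digitized_sphere(6, pad=3)
        m = np.concatenate([a, np.zeros_like(a), a], axis=2)
        rep = mask_morphology(m, VOX100)
        single = mask_morphology(a, VOX100)
        assert rep["n_components"] == 2
        assert rep["volume_um3"] == pytest.approx(2 * single["volume_um3"])

    def test_empty_mask_zero_report(self):
        rep = mask_morphology(np.zeros((4, 4, 4), bool), VOX100)
        assert rep["n_components"] == 0 and rep["volume_um3"] == 0.0

    def test_voxel_face_mode_bounds_mesh_area(self):
        m = digitized_sphere(10)
        mesh = mask_morphology(m, VOX100)["surface_area_um2"]
        faces = mask_morphology(m, VOX100, area_mode="voxel")["surface_area_um2"]
        assert faces > mesh  # face counting overestimates curved surfaces


class TestAsymmetricDistance:
    def test_identical_masks_zero(self):
        m = digitized_sphere(5)
        rep = asymmetric_distance(m, m, VOX100)
        assert rep["mean_nm"] == 0.0

    def test_two_spheres_separation(self):
        # centers 3 um apart, radii 0.5 um -> nearest surfaces ~2 um apart
        n = 61
        zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        a = zz**2 + yy**2 + (xx + 15) ** 2 <= 5**2
        b = zz**2 + yy**2 + (xx - 15) ** 2 <= 5**2
        rep = asymmetric_distance(a, b, VOX100)
        assert rep["mean_nm"] == pytest.approx(2000.0, abs=200.0)

    def test_asymmetry_with_unequal_component_counts(self):
        n = 81
        zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        one = zz**2 + yy**2 + (xx + 30) ** 2 <= 4**2
        three = np.zeros_like(one)
        for off in (-10, 10, 30):
            three |= zz**2 + (yy - off) ** 2 + (xx - 20) ** 2 <= 4**2
        d_one_to_three = asymmetric_distance(one, three, VOX100)
        d_three_to_one = asymmetric_distance(three, one, VOX100)
        assert d_one_to_three["n_components"] == 1
        assert d_three_to_one["n_components"] == 3
        assert d_one_to_three["mean_nm"] != pytest.approx(d_three_to_one["mean_nm"], rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            asymmetric_distance(np.zeros((3, 3, 3), bool), digitized_sphere(1), VOX100)


class TestTsaConvolve:
    def test_point_source_center_and_one_micron_values(self):
        m = np.zeros((31, 31, 31), bool)
        m[15, 15, 15] = True
        f = tsa_convolve(m, VOX100)
        assert f[15, 15, 15] == pytest.approx(5.86, abs=1e-9)
        assert f[15, 15, 25] == pytest.approx(5.86 * np.exp(-3.0), rel=1e-9)

    def test_superposition_of_two_sources(self):
        a = np.zeros((21, 21, 21), bool)
        b = np.zeros_like(a)
        a[5, 10, 10] = True
        b[15, 10, 10] = True
        f_sum = tsa_convolve(a | b, VOX100)
        assert np.allclose(f_sum, tsa_convolve(a, VOX100) + tsa_convolve(b, VOX100), atol=1e-9)

    def test_matches_direct_sum_oracle_on_random_mask(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(size=(16, 16, 16)) < 0.1
        vox = (125.0, 125.0, 125.0)
        f = tsa_convolve(m, vox)
        B, R, cutoff = 5.86, 3.0, 0.01
        src = np.argwhere(m)
        oracle = np.zeros(m.shape)
        coords = np.indices(m.shape).reshape(3, -1).T
        d = np.sqrt(
            (((coords[:, None, :] - src[None, :, :]) * (np.array(vox) / 1000)) ** 2).sum(-1)
        )
        k = B * np.exp(-R * d)
        k[k < cutoff * B] = 0.0
        oracle = k.sum(1).reshape(m.shape)
        assert np.abs(f - oracle).max() < 1e-6

    def test_linear_in_amplitude_and_decaying(self):
        m = np.zeros((25, 25, 25), bool)
        m[12, 12, 12] = True
        f1 = tsa_convolve(m, VOX100, B=1.0)
        f2 = tsa_convolve(m, VOX100, B=2.0)
        assert np.allclose(f2, 2 * f1, atol=1e-12)
        line = f1[12, 12, 12:]
        assert (np.diff(line[line > 0]) <= 1e-12).all()
        assert (f1 >= 0).all()

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            tsa_convolve(np.ones((3, 3, 3), bool), VOX100, cutoff_frac=1.5)

    def test_equatorial_rim_exceeds_poles_on_flat_nucleus(self):
        from nlo.synth import make_nucleus_scene

        sc = make_nucleus_scene("flat", voxel_nm=150.0, seed=0, n_speckles=0, n_nucleoli=0)
        ratio = rim_pole_contrast(
            sc.masks["NP"], sc.masks["nucleus"], (150.0,) * 3, (8.0, 4.0, 2.0)
        )
        assert ratio > 1.05


class TestNormalizeNucleus:
    def _cloud(self, seed=0, n=100, scale=(2000, 800, 300)):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(n, 3)) * scale
        return pd.DataFrame({"x_nm": P[:, 0], "y_nm": P[:, 1], "z_nm": P[:, 2]})

    def _coords(self, df):
        return df[["x_norm", "y_norm", "z_norm"]].to_numpy()

    def test_rigid_xy_rotation_invariance(self):
        df = self._cloud()
        base = self._coords(normalize_nucleus(df))
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = df[["x_nm", "y_nm"]].to_numpy() @ rot.T
        rotated = df.copy()
        rotated["x_nm"], rotated["y_nm"] = xy[:, 0], xy[:, 1]
        assert np.abs(self._coords(normalize_nucleus(rotated)) - base).max() < 1e-9

    def test_long_axis_maps_to_x(self):
        df = self._cloud(scale=(300, 2500, 100))
        out = normalize_nucleus(df)
        assert out["x_norm"].std() > out["y_norm"].std()

    def test_bounds_are_exact(self):
        out = self._coords(normalize_nucleus(self._cloud(seed=3)))
        assert np.allclose(out.min(0), [0, 0, 0], atol=1e-12)
        assert np.allclose(out.max(0), [4, 2, 1], atol=1e-12)

    def test_idempotent_on_normalized_cloud(self):
        first = normalize_nucleus(self._cloud(seed=4))
        renamed = pd.DataFrame(
            {"x_nm": first["x_norm"], "y_nm": first["y_norm"], "z_nm": first["z_norm"]}
        )
        again = normalize_nucleus(renamed)
        assert np.abs(self._coords(again) - self._coords(first)).max() < 1e-9

    def test_collinear_cloud_rejected(self):
        t = np.linspace(0, 1, 30)
        df = pd.DataFrame({"x_nm": t, "y_nm": 2 * t, "z_nm": np.random.default_rng(0).normal(size=30)})
        with pytest.raises(ValueError, match="degenerate"):
            normalize_nucleus(df)


class TestPolarity:
    def test_center_and_pole_probes(self):
        df = pd.DataFrame(
            {"x_norm": [2.0, 2.0], "y_norm": [1.0, 1.0], "z_norm": [0.5, 1.0]}
        )
        out = polarity_metrics(df)
        assert out["equatorial_dist"].tolist() == [0.0, 0.5]
        assert out["center_dist"].tolist() == [0.0, 0.0]

    def test_polarity_bias_lowers_equatorial_distance(self):
        from scipy.stats import ranksums
        from nlo.synth import make_nucleus_scene

        def per_nucleus_means(bias):
            means = []
            for i in range(50):
                sc = make_nucleus_scene(
                    "flat", voxel_nm=500.0, n_speckles=0, n_nucleoli=0,
                    polarity_bias=bias, seed=9, nucleus_id=i, n_probes=40,
                )
                norm = normalize_nucleus(sc.probes)
                means.append(polarity_metrics(norm)["equatorial_dist"].mean())
            return np.array(means)

        flat, biased = per_nucleus_means(0.0), per_nucleus_means(3.0)
        assert ranksums(flat, biased).pvalue < 0.01
        assert biased.mean() < flat.mean()


class TestCentromereDistance:
    def _bands(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [0, 50_000_000, 55_000_000],
                "end": [50_000_000, 55_000_000, 100_000_000],
                "name": ["p11", "cen", "q11"],
                "stain": ["gpos", "acen", "gneg"],
            }
        )

    def _probes(self, mids):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [m - 500 for m in mids],
                "end": [m + 500 for m in mids],
            }
        )

    def test_left_arm_distance_to_acen_start(self):
        d = centromere_distance(self._probes([40_000_000]), self._bands())
        assert d[0] == pytest.approx(10.0)

    def test_inside_acen_is_zero(self):
        d = centromere_distance(self._probes([52_000_000]), self._bands())
        assert d[0] == 0.0

    def test_right_arm_uses_acen_end(self):
        d = centromere_distance(self._probes([70_000_000]), self._bands())
        assert d[0] == pytest.approx(15.0)

    def test_missing_acen_gives_nan(self):
        probes = self._probes([1_000_000])
        probes["chrom"] = "chrX"
        assert np.isnan(centromere_distance(probes, self._bands())[0])


class TestMorphologyPca:
    def test_perfectly_correlated_pair_pc1_explains_all(self):
        x = np.arange(10.0)
        rep = morphology_pca(pd.DataFrame({"a": x, "b": 2 * x}))
        assert rep["explained"][0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        rep = morphology_pca(pd.DataFrame(rng.normal(size=(40, 6)),
                                          columns=list("abcdef")))
        assert rep["explained"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_clusters_separate_on_pc1(self):
        # clusters shifted 10 sd on three correlated metrics: PC1 captures
        # their shared axis and separates the groups with zero overlap
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(30, 5))
        b = rng.normal(0, 1, size=(30, 5))
        b[:, 1:4] += 10.0
        rep = morphology_pca(pd.DataFrame(np.vstack([a, b]), columns=list("vwxyz")))
        s = rep["scores"][:, 0]
        assert s[:30].max() < s[30:].min() or s[30:].max() < s[:30].min()

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        df["c"] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            rep = morphology_pca(df)
        assert rep["columns"] == ["a", "b"]

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            morphology_pca(df)
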