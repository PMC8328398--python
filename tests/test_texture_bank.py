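"""Feature bank: manifest cardinality, map oracles, aggregation, fusion."""

import numpy as np
import pandas as pd
import pytest

import octradiomics as o
from octradiomics.texture_bank import (
    AGG_STATS,
    FeatureBankManifest,
    HARALICK_STATS,
    collage_angle_codes,
    dominant_orientation_angles,
    glcm_stat_maps,
    laws_energy_map,
    laws_response,
    quantize,
)

from _oracles import haralick_oracle, laws_dense_response


class TestManifest:
    def test_family_counts_match_published_totals(self, manifest):
        assert manifest.family_counts() == {
            "Haralick": 52, "Laws": 501, "Gabor": 383, "CoLlAGe": 26
        }
        assert manifest.total == 962

    def test_descriptor_names_unique_and_patterned(self, manifest):
        names = manifest.descriptor_names()
        assert len(set(names)) == 962
        assert "Median-Laws_E3S3S3" in names
        assert "Skewness-Laws_E3L3S3" in names
        assert "Skewness-Laws_S3S3L3" in names
        stats = {n.split("-", 1)[0] for n in names}
        assert stats <= set(AGG_STATS)

    def test_json_roundtrip(self, manifest, tmp_path):
        path = tmp_path / "manifest.json"
        manifest.to_json(path)
        back = FeatureBankManifest.from_json(path)
        assert back.pairs == manifest.pairs
        assert back.version == manifest.version

    def test_wrong_counts_rejected(self, manifest):
        pairs = {f: list(p) for f, p in manifest.pairs.items()}
        pairs["Laws"] = pairs["Laws"][:500]
        with pytest.raises(o.ValidationError):
            FeatureBankManifest(pairs=pairs)


class TestLaws:
    def test_zero_sum_kernels_annihilate_constants(self):
        vol = np.full((8, 8, 8), 7.0)
        assert np.abs(laws_energy_map(vol, "E3S3S3", 5)).max() < 1e-9

    def test_l3l3l3_constant_response_is_64c(self):
        c = 2.5
        resp = laws_response(np.full((8, 8, 8), c), "L3L3L3")
        assert np.allclose(resp, 64 * c)

    @pytest.mark.parametrize("triplet", ["E3S3S3", "E3L3S3", "S3S3L3", "L5E5W5", "R5S5L5"])
    def test_matches_dense_3d_convolution(self, rng, triplet):
        vol = rng.standard_normal((8, 8, 8))
        assert np.abs(laws_response(vol, triplet) - laws_dense_response(vol, triplet)).max() < 1e-10

    def test_impulse_response_center_is_central_coefficient_product(self, rng):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        resp = laws_response(vol, "L3S3L3")
        # correlate: center response = product of central kernel coefficients
        assert resp[4, 4, 4] == pytest.approx(2 * 2 * 2)
        assert np.abs(resp - laws_dense_response(vol, "L3S3L3")).max() < 1e-12

    def test_too_small_volume_rejected(self):
        with pytest.raises(o.ValidationError):
            laws_response(np.zeros((2, 8, 8)), "E3S3S3")


class TestGabor:
    def test_constant_volume_gives_zero_magnitude(self, manifest):
        maps = o.gabor_maps(np.full((3, 16, 16), 9.0), manifest)
        assert all(np.abs(m.values).max() < 1e-9 for m in maps)

    def test_dc_offset_invariance(self, manifest, rng):
        vol = rng.standard_normal((3, 16, 16))
        a = o.gabor_maps(vol, manifest)
        b = o.gabor_maps(vol + 100.0, manifest)
        for ma, mb in zip(a, b):
            assert np.allclose(ma.values, mb.values, atol=1e-8)

    def test_matched_filter_wins_on_pure_sinusoid(self, manifest):
        # modulation along the A-scan axis at wavelength 6 matches t0/wl6
        a = np.arange(48)[None, None, :]
        vol = np.cos(2 * np.pi * a / 6.0) * np.ones((4, 48, 48))
        maps = o.gabor_maps(vol, manifest)
        means = {m.descriptor: m.values[:, 12:36, 12:36].mean() for m in maps}
        winner = max(means, key=means.get)
        assert winner.startswith("Gabor_t0_wl6")
        top = means[winner]
        assert all(v < top for k, v in means.items() if k != winner)

    def test_sub_nyquist_wavelength_rejected(self):
        from octradiomics.texture_bank import _gabor_kernel

        with pytest.raises(o.ValidationError):
            _gabor_kernel(0.0, 1.5, 1.0)


class TestHaralick:
    def test_constant_volume_contrast_zero_energy_one(self, manifest):
        vol = np.full((5, 5, 5), 3.0)
        mask = np.ones(vol.shape, dtype=bool)
        maps = {m.descriptor: m.values for m in o.haralick_maps(vol, mask, manifest)}
        assert np.allclose(maps["Haralick_contrast"], 0.0)
        assert np.allclose(maps["Haralick_energy"], 1.0)
        assert np.allclose(maps["Haralick_entropy"], 0.0)

    def test_checkerboard_matches_bruteforce_glcm(self):
        z, d, a = np.indices((4, 4, 4))
        codes = ((z + d + a) % 2).astype(np.int64)
        valid = np.ones(codes.shape, dtype=bool)
        ours = glcm_stat_maps(codes, valid, window=9, n_levels=2)
        oracle = haralick_oracle(codes, valid, half=4, n_levels=2)
        for i, name in enumerate(HARALICK_STATS):
            assert np.nanmax(np.abs(ours[i] - oracle[name])) < 1e-10, name

    def test_random_volume_matches_bruteforce_glcm(self, rng):
        vol = rng.integers(0, 40, size=(4, 4, 4)).astype(float)
        mask = np.ones(vol.shape, dtype=bool)
        mask[0, 0, 0] = False  # exercise mask clipping
        codes = quantize(vol, mask, 8)
        ours = glcm_stat_maps(codes, mask, window=5, n_levels=8)
        oracle = haralick_oracle(codes, mask, half=2, n_levels=8)
        for i, name in enumerate(HARALICK_STATS):
            assert np.nanmax(np.abs(ours[i] - oracle[name])) < 1e-10, name

    def test_single_gray_level_zero_entropy(self, manifest):
        vol = np.full((5, 5, 5), 42.0)  # min == max -> one level
        mask = np.ones(vol.shape, dtype=bool)
        maps = {m.descriptor: m.values for m in o.haralick_maps(vol, mask, manifest)}
        for name in ("entropy", "sum_entropy", "difference_entropy"):
            assert np.allclose(maps[f"Haralick_{name}"], 0.0)


class TestCollage:
    def test_linear_ramp_single_orientation_zero_entropy(self, manifest):
        d = np.arange(16)[None, :, None]
        vol = (d * np.ones((6, 16, 16))).astype(float)
        mask = np.zeros(vol.shape, dtype=bool)
        mask[2:4, 4:12, 4:12] = True
        maps = {m.descriptor: m.values for m in o.collage_maps(vol, mask, manifest)}
        ent = maps["CoLlAGe_inplane_entropy"][mask]
        assert np.nanmax(np.abs(ent)) < 1e-12

    def test_orientation_matches_plane_fit_oracle(self, rng):
        # smooth low-order field: windowed structure tensor and a local
        # least-squares plane fit must agree on the dominant orientation
        z, d, a = np.indices((8, 8, 8)).astype(float)
        vol = 2.0 * d + 1.0 * a + 0.3 * d * a / 8.0
        inplane, through, _ = dominant_orientation_angles(vol, window=3)
        for center in [(4, 4, 4), (3, 5, 2), (5, 2, 5)]:
            zc, dc, ac = center
            # independent plane fit on the same 3x3x3 neighborhood
            pts, vals = [], []
            for dz in (-1, 0, 1):
                for dd in (-1, 0, 1):
                    for da in (-1, 0, 1):
                        pts.append((zc + dz, dc + dd, ac + da))
                        vals.append(vol[zc + dz, dc + dd, ac + da])
            A = np.array([[1.0, p[0], p[1], p[2]] for p in pts])
            coef, *_ = np.linalg.lstsq(A, np.array(vals), rcond=None)
            grad = coef[1:]
            expected = np.mod(np.arctan2(grad[2], grad[1]), np.pi)
            assert inplane[center] == pytest.approx(expected, abs=1e-2)
            assert through[center] == pytest.approx(0.0, abs=1e-2)

    def test_quarter_turn_rotation_shifts_orientation_bin(self, manifest):
        d = np.arange(16)[None, :, None]
        a = np.arange(16)[None, None, :]
        ramp_d = (d * np.ones((6, 16, 16))).astype(float)
        ramp_a = (a * np.ones((6, 16, 16))).astype(float)
        codes_d = collage_angle_codes(ramp_d, manifest)[0]
        codes_a = collage_angle_codes(ramp_a, manifest)[0]
        interior = np.s_[2:4, 4:12, 4:12]
        shift = manifest.collage_bins // 2  # pi/2 of the [0, pi) range
        assert np.all((codes_d[interior] + shift) % manifest.collage_bins == codes_a[interior])
        # in-plane co-occurrence stats of a constant field are unchanged
        mask = np.zeros(ramp_d.shape, dtype=bool)
        mask[interior] = True
        m_d = {m.descriptor: m for m in o.collage_maps(ramp_d, mask, manifest)}
        m_a = {m.descriptor: m for m in o.collage_maps(ramp_a, mask, manifest)}
        for name in ("CoLlAGe_inplane_entropy", "CoLlAGe_inplane_energy"):
            assert np.allclose(m_d[name].values[mask], m_a[name].values[mask], equal_nan=True)


class TestAggregation:
    def test_hand_computed_statistics(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0]).reshape(1, 1, 5)
        mask = np.ones(vals.shape, dtype=bool)
        agg = o.aggregate(vals, mask)
        assert agg == pytest.approx(
            {"Median": 3.0, "Variance": 2.0, "Skewness": 0.0, "Kurtosis": 1.7}
        )

    def test_constant_sample_convention(self):
        vals = np.full((1, 1, 4), 6.0)
        mask = np.ones(vals.shape, dtype=bool)
        agg = o.aggregate(vals, mask)
        assert agg == {"Median": 6.0, "Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}

    def test_single_voxel_higher_moments_missing(self):
        vals = np.array([[[4.2]]])
        mask = np.ones(vals.shape, dtype=bool)
        agg = o.aggregate(vals, mask)
        assert agg["Median"] == 4.2
        assert np.isnan(agg["Variance"]) and np.isnan(agg["Skewness"])

    def test_matches_scipy_on_random_samples(self, rng):
        from scipy import stats as ss

        vals = rng.standard_normal((4, 5, 6))
        mask = rng.random((4, 5, 6)) < 0.5
        agg = o.aggregate(vals, mask)
        v = vals[mask]
        assert agg["Median"] == pytest.approx(np.median(v))
        assert agg["Variance"] == pytest.approx(np.var(v))
        assert agg["Skewness"] == pytest.approx(ss.skew(v, bias=True))
        assert agg["Kurtosis"] == pytest.approx(ss.kurtosis(v, fisher=False, bias=True))


class TestExtraction:
    def test_962_values_per_compartment_and_determinism(self, tiny_cohort, manifest):
        eye = tiny_cohort[0]
        comps = o.derive_compartments(eye.surfaces, eye.fluid)
        rows = o.extract_features(eye.volume, comps, manifest)
        again = o.extract_features(eye.volume, comps, manifest)
        for comp in ("IRF", "SRF", "RTC1", "RTC2"):
            assert len(rows[comp]) == 962
            assert rows[comp] == again[comp]

    def test_empty_compartment_yields_all_missing(self, manifest):
        spec = o.CohortSpec(
            n_rebounder=1, n_nonrebounder=1, volume_shape=(12, 48, 32),
            n_irf_pockets=(0, 0), n_srf_pockets=(0, 0), seed=2,
        )
        eye = o.generate_cohort(spec)[0]
        comps = o.derive_compartments(eye.surfaces, eye.fluid)
        rows = o.extract_features(eye.volume, comps, manifest)
        assert all(np.isnan(v) for v in rows["IRF"].values())
        assert sum(np.isfinite(v) for v in rows["RTC1"].values()) == 962

    def test_translation_invariance_of_masked_aggregates(self, rng, manifest):
        # Laws, Haralick and CoLlAGe aggregates over an interior mask must
        # not change when volume and mask translate together
        base = rng.standard_normal((20, 20, 20))
        vol = np.zeros((24, 24, 24))
        vol[:20, :20, :20] = base
        vol_shift = np.zeros((24, 24, 24))
        vol_shift[2:22, 2:22, 2:22] = base
        mask = np.zeros(vol.shape, dtype=bool)
        mask[8:12, 8:12, 8:12] = True
        mask_shift = np.roll(mask, 2, axis=(0, 1, 2))

        for m0, m1 in [
            (laws_energy_map(vol, "E3S3S3", 5), laws_energy_map(vol_shift, "E3S3S3", 5)),
        ]:
            assert o.aggregate(m0, mask) == pytest.approx(o.aggregate(m1, mask_shift))
        h0 = {m.descriptor: m for m in o.haralick_maps(vol, mask, manifest)}
        h1 = {m.descriptor: m for m in o.haralick_maps(vol_shift, mask_shift, manifest)}
        for name in ("Haralick_contrast", "Haralick_entropy", "Haralick_correlation"):
            assert o.aggregate(h0[name], mask) == pytest.approx(
                o.aggregate(h1[name], mask_shift)
            )


class TestFusion:
    def _tables(self, manifest, rng, n=3):
        names = manifest.descriptor_names()
        idx = [f"e{i}" for i in range(n)]
        return {
            comp: pd.DataFrame(rng.standard_normal((n, 962)), index=idx, columns=names)
            for comp in ("IRF", "SRF", "RTC1", "RTC2")
        }

    def test_fused_column_counts(self, manifest, rng):
        tables = self._tables(manifest, rng)
        assert o.fuse(tables, "f").shape[1] == 1924
        assert o.fuse(tables, "rtc").shape[1] == 1924
        assert o.fuse(tables, "oct").shape[1] == 3848

    def test_self_fusion_doubles_columns_pairwise_equal(self, manifest, rng):
        t = self._tables(manifest, rng)["IRF"]
        fused = o.fuse({"IRF": t, "SRF": t}, "f")
        assert fused.shape[1] == 2 * t.shape[1]
        assert np.array_equal(
            fused[[f"IRF/{c}" for c in t.columns]].to_numpy(),
            fused[[f"SRF/{c}" for c in t.columns]].to_numpy(),
        )

    def test_eye_id_mismatch_lists_difference(self, manifest, rng):
        tables = self._tables(manifest, rng)
        tables["SRF"] = tables["SRF"].rename(index={"e2": "e9"})
        with pytest.raises(o.ValidationError, match="e2"):
            o.fuse(tables, "f")


class TestZNormalize:
    def test_hand_example(self):
        t = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        z = o.znormalize(t)
        assert np.allclose(z["x"], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_normalized_columns_have_zero_mean_unit_sd(self, rng):
        t = pd.DataFrame(rng.standard_normal((20, 7)) * 5 + 3)
        z = o.znormalize(t)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0, ddof=0) - 1).max() < 1e-9

    def test_idempotent(self, rng):
        t = pd.DataFrame(rng.standard_normal((10, 3)))
        z1 = o.znormalize(t)
        z2 = o.znormalize(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_constant_column_zeroed_and_flagged(self):
        t = pd.DataFrame({"c": [5.0, 5.0, 5.0], "x": [1.0, 2.0, 3.0]})
        z = o.znormalize(t)
        assert np.allclose(z["c"], 0.0)
        assert z.attrs["constant_columns"] == ["c"]
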