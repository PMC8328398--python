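"""Generator geometry, determinism, and the planted class effect."""

import numpy as np
import pytest

import octradiomics as o
from octradiomics.compartments import derive_compartments
from octradiomics.synthetic_data import ellipsoid_mask
from octradiomics.texture_bank import laws_energy_map

from conftest import TEST_SHAPE


def _median_irf_e3s3s3(eye):
    comps = derive_compartments(eye.surfaces, eye.fluid)
    mask = comps.masks["IRF"]
    if not mask.any():
        return None
    return float(np.median(laws_energy_map(eye.volume.data.astype(float), "E3S3S3", 5)[mask]))


class TestCohortGeneration:
    def test_default_cohort_has_11_rebounders_and_17_nonrebounders(self):
        eyes = o.generate_cohort(o.CohortSpec())
        labels = [e.label for e in eyes]
        assert len(eyes) == 28
        assert labels.count("rebounder") == 11
        assert labels.count("nonrebounder") == 17

    def test_same_spec_reproduces_volumes_bitwise(self, tiny_spec, tiny_cohort):
        again = o.generate_cohort(tiny_spec)
        for a, b in zip(tiny_cohort, again):
            assert np.array_equal(a.volume.data, b.volume.data)
            assert np.array_equal(a.fluid.irf, b.fluid.irf)
            assert np.array_equal(a.fluid.srf, b.fluid.srf)
            assert a.seed == b.seed

    def test_zero_irf_range_gives_empty_irf_masks(self):
        spec = o.CohortSpec(
            n_rebounder=1, n_nonrebounder=1, volume_shape=TEST_SHAPE,
            n_irf_pockets=(0, 0), n_srf_pockets=(1, 1), seed=3,
        )
        for eye in o.generate_cohort(spec):
            assert not eye.fluid.irf.any()
            assert eye.fluid.srf.any()

    @pytest.mark.parametrize(
        "field,value",
        [("n_rebounder", -1), ("volume_shape", (4, 8, 4)), ("effect_size", -0.5)],
    )
    def test_invalid_spec_raises_naming_the_field(self, field, value):
        spec = o.CohortSpec(**{field: value})
        with pytest.raises(o.ValidationError):
            spec.validate()


class TestSurfaces:
    def test_flat_mode_gives_constant_depths(self):
        s = o.make_surfaces(TEST_SHAPE, seed=0, amplitude=0.0, fovea_depth=0.0)
        for surf in (s.ilm, s.ez, s.rpe):
            assert np.ptp(surf) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_ordering_invariant_any_seed(self, seed):
        s = o.make_surfaces(TEST_SHAPE, seed=seed)
        assert (s.ez - s.ilm).min() >= 1
        assert (s.rpe - s.ez).min() >= 0

    def test_different_seeds_give_different_surfaces(self):
        for seed in range(10):
            a = o.make_surfaces(TEST_SHAPE, seed=seed)
            b = o.make_surfaces(TEST_SHAPE, seed=seed + 1000)
            assert not np.array_equal(a.ilm, b.ilm)

    def test_foveal_depression_deepens_central_ilm(self):
        s = o.make_surfaces((11, 48, 33), seed=1, amplitude=0.0, fovea_depth=4.0)
        center = s.ilm[5, 16]
        corner = s.ilm[0, 0]
        assert center > corner + 2


class TestFluid:
    def test_ellipsoid_matches_bruteforce_enumeration(self):
        shape, center, radii = (9, 11, 13), (4.0, 5.0, 6.0), (3.0, 3.0, 3.0)
        mask = ellipsoid_mask(shape, center, radii)
        expected = np.zeros(shape, dtype=bool)
        for z in range(shape[0]):
            for d in range(shape[1]):
                for a in range(shape[2]):
                    r = (
                        ((z - center[0]) / radii[0]) ** 2
                        + ((d - center[1]) / radii[1]) ** 2
                        + ((a - center[2]) / radii[2]) ** 2
                    )
                    expected[z, d, a] = r <= 1.0
        assert np.array_equal(mask, expected)

    def test_pockets_clipped_to_their_bands(self, tiny_cohort):
        for eye in tiny_cohort:
            d = np.arange(TEST_SHAPE[1])[None, :, None]
            inner = (d >= eye.surfaces.ilm[:, None, :]) & (d < eye.surfaces.ez[:, None, :])
            outer = (d >= eye.surfaces.ez[:, None, :]) & (d < eye.surfaces.rpe[:, None, :])
            assert not (eye.fluid.irf & ~inner).any()
            assert not (eye.fluid.srf & ~outer).any()
            assert not (eye.fluid.irf & eye.fluid.srf).any()

    def test_oversized_pocket_never_escapes_band(self):
        surfaces = o.make_surfaces(TEST_SHAPE, seed=2, amplitude=0.0, fovea_depth=0.0)
        spec = o.CohortSpec(volume_shape=TEST_SHAPE, n_irf_pockets=(5, 5), n_srf_pockets=(5, 5))
        fluid = o.plant_fluid(surfaces, spec, seed=9)
        d = np.arange(TEST_SHAPE[1])[None, :, None]
        inner = (d >= surfaces.ilm[:, None, :]) & (d < surfaces.ez[:, None, :])
        assert not (fluid.irf & ~inner).any()


class TestRendering:
    def test_fluid_is_hyporeflective_every_eye(self, tiny_cohort):
        for eye in tiny_cohort:
            comps = derive_compartments(eye.surfaces, eye.fluid, slice_window=(1, TEST_SHAPE[0]))
            irf, rtc1 = comps.masks["IRF"], comps.masks["RTC1"]
            if irf.any():
                assert eye.volume.data[irf].mean() < eye.volume.data[rtc1].mean()

    def test_labels_exchangeable_at_zero_effect(self):
        spec = o.CohortSpec(volume_shape=TEST_SHAPE, effect_size=0.0)
        surfaces = o.make_surfaces(TEST_SHAPE, seed=4)
        fluid = o.plant_fluid(surfaces, spec, seed=5)
        a = o.render_eye(surfaces, fluid, "rebounder", spec, seed=6)
        b = o.render_eye(surfaces, fluid, "nonrebounder", spec, seed=6)
        assert np.array_equal(a.data, b.data)

    def test_effect_confined_to_irf_mask(self):
        spec = o.CohortSpec(volume_shape=TEST_SHAPE, effect_size=2.0)
        surfaces = o.make_surfaces(TEST_SHAPE, seed=4)
        fluid = o.plant_fluid(surfaces, spec, seed=5)
        assert fluid.irf.any()
        reb = o.render_eye(surfaces, fluid, "rebounder", spec, seed=6)
        non = o.render_eye(surfaces, fluid, "nonrebounder", spec, seed=6)
        differs = reb.data != non.data
        assert differs.any()
        assert not (differs & ~fluid.irf).any()

    def test_effect_contrast_monotone_in_effect_size(self):
        diffs = []
        for effect in (0.0, 1.0, 2.0):
            spec = o.CohortSpec(
                n_rebounder=10, n_nonrebounder=10, volume_shape=TEST_SHAPE,
                effect_size=effect, seed=11,
            )
            reb, non = [], []
            for eye in o.generate_cohort(spec):
                v = _median_irf_e3s3s3(eye)
                if v is None:
                    continue
                (reb if eye.label == "rebounder" else non).append(v)
            diffs.append(np.mean(reb) - np.mean(non))
        assert diffs[0] <= diffs[1] <= diffs[2]

    def test_null_effect_classes_indistinguishable(self):
        # spot-energy distributions should not separate classes without an effect
        from scipy.stats import mannwhitneyu

        spec = o.CohortSpec(
            n_rebounder=50, n_nonrebounder=50, volume_shape=TEST_SHAPE,
            effect_size=0.0, seed=21,
        )
        reb, non = [], []
        for eye in o.generate_cohort(spec):
            v = _median_irf_e3s3s3(eye)
            if v is None:
                continue
            (reb if eye.label == "rebounder" else non).append(v)
        p = mannwhitneyu(reb, non, alternative="two-sided").pvalue
        assert p > 0.01

    def test_planted_effect_dominates_in_paired_draws(self):
        wins = total = 0
        for seed in range(50):
            spec = o.CohortSpec(
                n_rebounder=1, n_nonrebounder=1, volume_shape=TEST_SHAPE,
                effect_size=2.0, seed=1000 + seed,
            )
            vals = {}
            for eye in o.generate_cohort(spec):
                v = _median_irf_e3s3s3(eye)
                if v is not None:
                    vals[eye.label] = v
            if len(vals) == 2:
                total += 1
                wins += vals["rebounder"] > vals["nonrebounder"]
        assert total >= 40
        assert wins / total >= 0.95
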