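"""SUV arithmetic, asymmetry mapping, lesion recovery and cohort statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from smartpet.phantom import (Lesion, PhantomSpec, ScanMeta, build_phantom,
                              simulate_low_dose, simulate_standard_dose)
from smartpet.quantify import (compare_cohort, cohort_suvr_table,
                               hypometabolic_roi, smooth, suv_map, suvr,
                               zai_map)
from smartpet.volume_io import Volume


META = ScanMeta("sub-000", body_weight=70.0, injected_dose=200.0)


class TestSUV:
    def test_uniform_concentration_arithmetic_oracle(self):
        """C = 5 kBq/mL, BW = 70 kg, Dose = 200 MBq -> SUV = 1.75 (g/mL)."""
        v = Volume(np.full((6, 6, 6), 5.0), (2.0, 2.0, 2.0))
        suv = suv_map(v, META)
        assert np.allclose(suv.voxels, 5.0 * 70.0 / 200.0)

    def test_zero_activity_and_linearity(self, rng):
        c = rng.random((6, 6, 6))
        v = Volume(c, (2.0, 2.0, 2.0))
        assert np.all(suv_map(Volume(np.zeros((6, 6, 6)), (2, 2, 2)), META).voxels == 0)
        assert np.allclose(suv_map(Volume(3 * c, (2, 2, 2)), META).voxels,
                           3 * suv_map(v, META).voxels, rtol=1e-6)

    def test_nonpositive_meta_rejected(self):
        v = Volume(np.ones((4, 4, 4)), (2, 2, 2))
        with pytest.raises(ValueError):
            suv_map(v, ScanMeta("s", 0.0, 200.0))
        with pytest.raises(ValueError):
            suv_map(v, ScanMeta("s", 70.0, -1.0))


class TestSmooth:
    def test_constant_volume_unchanged(self):
        v = Volume(np.full((10, 10, 10), 3.0), (2.09, 2.09, 2.03))
        assert np.allclose(smooth(v, 2.0).voxels, 3.0, atol=1e-6)

    def test_mass_conserved_for_interior_signal(self, rng):
        vox = np.zeros((20, 20, 20))
        vox[6:14, 6:14, 6:14] = rng.random((8, 8, 8))
        v = Volume(vox, (2.0, 2.0, 2.0))
        out = smooth(v, 2.0)
        assert out.voxels.sum() == pytest.approx(vox.sum(), rel=1e-6)

    def test_sigma_follows_fwhm_identity(self):
        """FWHM 2 mm at 2.09 mm spacing is sigma ~ 0.406 voxels: a centred
        impulse spreads with exactly that Gaussian width."""
        from scipy.ndimage import gaussian_filter
        vox = np.zeros((21, 21, 21))
        vox[10, 10, 10] = 1.0
        out = smooth(Volume(vox, (2.09, 2.09, 2.03)), 2.0).voxels
        sigma = 2.0 / (2 * np.sqrt(2 * np.log(2)))
        expected = gaussian_filter(vox, [sigma / 2.09, sigma / 2.09, sigma / 2.03])
        assert sigma / 2.09 == pytest.approx(0.4064, abs=1e-4)
        assert np.allclose(out, expected, atol=1e-9)


class TestSUVr:
    def test_reference_region_is_exactly_one(self, phantom32):
        activity, labels = phantom32
        tab = suvr(suv_map(activity, META), labels, "cerebellum")
        assert tab.loc[tab.region == "cerebellum", "suvr"].item() == 1.0

    def test_invariant_to_global_scaling(self, phantom32):
        activity, labels = phantom32
        a = suvr(suv_map(activity, META), labels, "occipital")
        scaled = activity.copy_with(activity.voxels * 7.3)
        b = suvr(suv_map(scaled, META), labels, "occipital")
        assert np.allclose(a["suvr"], b["suvr"], rtol=1e-9)

    def test_lesion_suvr_tracks_multiplier(self, spec32):
        les = Lesion((10, 16, 16), 8.0, 0.6)
        spec = PhantomSpec(grid_shape=spec32.grid_shape,
                           voxel_size_mm=spec32.voxel_size_mm, lesion_list=[les])
        activity, labels = build_phantom(spec)
        tab = suvr(suv_map(activity, META), labels, "cerebellum")
        lesion_suvr = tab.loc[tab.region == "lesion_0", "suvr"].item()
        # homologous tissue on the mirrored side carries the unlesioned value
        mirror = labels.mask("lesion_0")[::-1, :, :]
        ref = activity.voxels[labels.mask("cerebellum")].mean()
        homolog = activity.voxels[mirror].mean() / ref
        assert lesion_suvr == pytest.approx(0.6 * homolog, rel=1e-6)

    def test_empty_reference_rejected(self, phantom32):
        activity, labels = phantom32
        lab2 = labels.__class__(labels.labels, {**labels.names, "nowhere": 999},
                                labels.spacing_mm)
        with pytest.raises(ValueError):
            suvr(suv_map(activity, META), lab2, "nowhere")


class TestZAI:
    def test_symmetric_phantom_yields_zero_map(self, phantom32):
        activity, labels = phantom32
        z = zai_map(suv_map(activity, META), labels.brain_mask())
        assert np.all(z.voxels == 0.0)

    def test_left_lesion_minimum_inside_lesion_label(self, spec32):
        les = Lesion((8, 16, 16), 10.0, 0.6)
        spec = PhantomSpec(grid_shape=spec32.grid_shape,
                           voxel_size_mm=spec32.voxel_size_mm, lesion_list=[les])
        activity, labels = build_phantom(spec)
        z = zai_map(smooth(suv_map(activity, META)), labels.brain_mask())
        argmin = np.unravel_index(np.argmin(z.voxels), z.voxels.shape)
        assert labels.mask("lesion_0")[argmin]

    def test_antisymmetric_up_to_z_normalization(self, spec32):
        les = Lesion((8, 16, 16), 10.0, 0.6)
        spec = PhantomSpec(grid_shape=spec32.grid_shape,
                           voxel_size_mm=spec32.voxel_size_mm, lesion_list=[les])
        activity, labels = build_phantom(spec)
        z = zai_map(suv_map(activity, META), labels.brain_mask()).voxels
        mask = labels.brain_mask() & labels.brain_mask()[::-1, :, :]
        s = z + z[::-1, :, :]  # AI antisymmetry makes this constant in-mask
        assert np.ptp(s[mask]) < 1e-5


class TestHypometabolicROI:
    def test_zero_map_has_no_components(self):
        z = Volume(np.zeros((16, 16, 16)), (5, 5, 5))
        roi = hypometabolic_roi(z)
        assert roi.volumes_mm3 == {}

    def test_planted_lesion_recovered_with_dice_above_half(self, spec32):
        # focal zone comfortably above the 4 mm PSF at 5 mm voxels
        les = Lesion((8, 16, 16), 15.0, 0.6)
        spec = PhantomSpec(grid_shape=spec32.grid_shape,
                           voxel_size_mm=spec32.voxel_size_mm,
                           total_counts_standard=20_000_000,  # low-noise arm
                           lesion_list=[les], seed=5)
        activity, labels = build_phantom(spec)
        std = simulate_standard_dose(activity, spec)
        z = zai_map(smooth(suv_map(std, META)), labels.brain_mask())
        roi = hypometabolic_roi(z, threshold=-2.0)
        pred = roi.label_map > 0
        truth = labels.mask("lesion_0")
        dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())
        assert dice > 0.5
        assert all(v > 0 for v in roi.volumes_mm3.values())

    def test_noisier_input_yields_at_least_as_many_components(self, spec32):
        spec = PhantomSpec(grid_shape=spec32.grid_shape,
                           voxel_size_mm=spec32.voxel_size_mm,
                           total_counts_standard=2_000_000, seed=8)
        activity, labels = build_phantom(spec)
        std = simulate_standard_dose(activity, spec)
        low = simulate_low_dose(std, spec)
        n_clean = len(hypometabolic_roi(
            zai_map(smooth(suv_map(std, META)), labels.brain_mask())).volumes_mm3)
        n_noisy = len(hypometabolic_roi(
            zai_map(smooth(suv_map(low, META)), labels.brain_mask())).volumes_mm3)
        assert n_noisy >= n_clean


def mannwhitney_oracle(x, y):
    """U statistic by pair counting and exact p by full enumeration of the
    C(8,4) rank assignments (no ties)."""
    x, y = np.asarray(x), np.asarray(y)
    u_obs = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    pooled = np.concatenate([x, y])
    n = len(x)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(comb)]
        ys = pooled[[i for i in range(len(pooled)) if i not in comb]]
        us.append(sum(xi > yi for xi in xs for yi in ys))
    us = np.asarray(us)
    # two-sided: double the smaller tail
    p = 2 * min((us >= u_obs).mean(), (us <= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestCompareCohort:
    def _tables(self, dn_vals, sd_vals, region="occipital"):
        dn = pd.DataFrame({"subject": range(len(dn_vals)), "region": region,
                           "suvr": dn_vals})
        sd = pd.DataFrame({"subject": range(len(sd_vals)), "region": region,
                           "suvr": sd_vals})
        return dn, sd

    def test_identical_arms_not_significant_and_zero_deviation(self):
        vals = [1.0, 1.1, 1.2, 1.3]
        dn, sd = self._tables(vals, vals)
        out = compare_cohort(dn, sd)
        assert not out["significant"].item()
        assert out["p"].item() > 0.9
        assert out["pct_dev_mean"].item() == 0.0

    def test_u_statistic_matches_exhaustive_enumeration(self):
        x = [1.3, 2.1, 0.7, 3.3]
        y = [0.9, 1.8, 2.5, 0.4]
        u_oracle, p_oracle = mannwhitney_oracle(x, y)
        u, p = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == u_oracle
        assert p == pytest.approx(p_oracle, rel=1e-9)
        dn, sd = self._tables(x, y)
        out = compare_cohort(dn, sd)
        assert out["U"].item() == u_oracle

    def test_small_arms_rejected(self):
        dn, sd = self._tables([1.0, 1.1], [1.0, 1.2])
        with pytest.raises(ValueError):
            compare_cohort(dn, sd)

    def test_cohort_table_covers_regions_and_subjects(self, phantom32):
        activity, labels = phantom32
        suvs = [suv_map(activity, META) for _ in range(3)]
        tab = cohort_suvr_table(suvs, [labels] * 3, "cerebellum")
        assert set(tab["subject"]) == {0, 1, 2}
        assert set(tab["region"]) == set(labels.region_names())
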