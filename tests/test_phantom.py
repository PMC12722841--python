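"""Phantom and cohort generator: determinism, noise statistics, planted effects."""

import numpy as np
import pytest
from scipy import stats

from qt1pipe.phantom import (
    CohortEffectSpec,
    PhantomSpec,
    default_roi_catalog,
    make_cohort,
    make_phantom,
    simulate_dam,
    simulate_spgr,
)
from qt1pipe.relaxometry import AcquisitionProtocol, spgr_signal_echo


class TestMakePhantom:
    def test_uniform_spec_gives_constant_t1_in_foreground(self, flat_phantom):
        fg = flat_phantom.foreground()
        assert np.all(flat_phantom.t1_map[fg] == 1400.0)
        assert np.all(flat_phantom.t1_map[~fg] == 0.0)

    def test_deterministic_for_fixed_spec(self):
        spec = PhantomSpec(grid_shape=(16, 16, 16), rois_per_hemisphere=2, seed=7)
        a, b = make_phantom(spec), make_phantom(spec)
        np.testing.assert_array_equal(a.t1_map, b.t1_map)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.b1_map, b.b1_map)

    def test_seed_changes_only_random_b1(self):
        base = dict(grid_shape=(16, 16, 16), rois_per_hemisphere=2, b1_model="random")
        a = make_phantom(PhantomSpec(**base, seed=1))
        b = make_phantom(PhantomSpec(**base, seed=2))
        np.testing.assert_array_equal(a.t1_map, b.t1_map)
        assert not np.array_equal(a.b1_map, b.b1_map)

    def test_dk_catalog_has_68_entries_across_hemispheres(self):
        phantom = make_phantom(PhantomSpec(grid_shape=(48, 48, 48), rois_per_hemisphere=34))
        assert len(phantom.roi_catalog) == 68
        hemis = {h for _, h in phantom.roi_catalog.values()}
        assert hemis == {"left", "right"}
        assert set(np.unique(phantom.labels)) - {0} == set(phantom.roi_catalog)
        names = {n for n, _ in phantom.roi_catalog.values()}
        assert "cuneus" in names and "temporalpole" in names

    def test_b1_bowl_within_declared_range(self, bowl_phantom):
        assert bowl_phantom.b1_map.min() >= 0.85 - 1e-12
        assert bowl_phantom.b1_map.max() <= 1.15 + 1e-12

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            make_phantom(PhantomSpec(grid_shape=(2, 16, 16)))
        with pytest.raises(ValueError):
            make_phantom(PhantomSpec(grid_shape=(8, 8, 8), rois_per_hemisphere=500))


class TestSimulateSpgr:
    def test_noiseless_matches_closed_form(self, flat_phantom):
        proto = AcquisitionProtocol.multi_echo()
        vols = simulate_spgr(flat_phantom, proto, noise_sigma=0.0)
        fg = flat_phantom.foreground()
        for alpha in proto.flip_angles:
            for te in proto.echo_times:
                expected = spgr_signal_echo(1.0, 1400.0, 50.0, proto.tr, alpha, te)
                np.testing.assert_allclose(vols.get(alpha, te)[fg], expected, rtol=1e-12)
                assert np.all(vols.get(alpha, te)[~fg] == 0.0)

    def test_seeded_noise_reproducible(self, flat_phantom):
        proto = AcquisitionProtocol.single_echo()
        a = simulate_spgr(flat_phantom, proto, noise_sigma=0.01, seed=3)
        b = simulate_spgr(flat_phantom, proto, noise_sigma=0.01, seed=3)
        c = simulate_spgr(flat_phantom, proto, noise_sigma=0.01, seed=4)
        for key in a.volumes:
            np.testing.assert_array_equal(a.volumes[key], b.volumes[key])
        assert not np.array_equal(a.get(3.0, 4.948), c.get(3.0, 4.948))

    def test_rician_mean_matches_rice_distribution(self, rng):
        # 1e4 identical voxels: the sample mean must sit within 3 standard
        # errors of the analytic Rice mean (and above the noiseless value).
        from qt1pipe.phantom import _add_noise

        signal, sigma, n = 0.05, 0.01, 10_000
        clean = np.full(n, signal)
        noisy = _add_noise(clean, sigma, rng)
        rice_mean = stats.rice(b=signal / sigma, scale=sigma).mean()
        se = noisy.std(ddof=1) / np.sqrt(n)
        assert noisy.mean() > signal
        assert abs(noisy.mean() - rice_mean) < 3 * se

    def test_background_noise_is_rayleigh(self, rng):
        # M0 = 0 voxels: magnitude noise is Rayleigh with SD sigma*sqrt(2-pi/2)
        from qt1pipe.phantom import _add_noise

        sigma, n = 0.02, 200_000
        noisy = _add_noise(np.zeros(n), sigma, rng)
        expected_sd = sigma * np.sqrt(2.0 - np.pi / 2.0)
        assert noisy.std() == pytest.approx(expected_sd, rel=0.05)


class TestSimulateDam:
    def test_unit_kappa_ratio_is_half(self, flat_phantom):
        vols = simulate_dam(flat_phantom, noise_sigma=0.0)
        fg = flat_phantom.foreground()
        te = vols.protocol.echo_times[0]
        ratio = vols.get(120.0, te)[fg] / (2 * vols.get(60.0, te)[fg])
        np.testing.assert_allclose(ratio, 0.5, rtol=1e-12)

    def test_kappa_1p1_ratio_is_cos66(self):
        phantom = make_phantom(
            PhantomSpec(grid_shape=(16, 16, 16), rois_per_hemisphere=2,
                        b1_model="uniform", b1_range=(1.1, 1.1))
        )
        vols = simulate_dam(phantom, noise_sigma=0.0)
        te = vols.protocol.echo_times[0]
        fg = phantom.foreground()
        ratio = vols.get(120.0, te)[fg] / (2 * vols.get(60.0, te)[fg])
        np.testing.assert_allclose(ratio, np.cos(np.deg2rad(66.0)), rtol=1e-12)
        assert ratio[0] == pytest.approx(0.4067, abs=1e-4)

    def test_seed_contract_with_noise(self, flat_phantom):
        a = simulate_dam(flat_phantom, noise_sigma=0.01, seed=11)
        b = simulate_dam(flat_phantom, noise_sigma=0.01, seed=11)
        for key in a.volumes:
            np.testing.assert_array_equal(a.volumes[key], b.volumes[key])


class TestMakeCohort:
    def test_study_shaped_covariate_table(self):
        catalog = default_roi_catalog(34)
        cohort = make_cohort(14, 7, roi_catalog=catalog)
        assert len(cohort.covariates) == 21
        assert cohort.covariates["cpze"].isna().sum() == 7
        assert (cohort.covariates["group"] == "SSD").sum() == 14
        assert set(cohort.covariates["sex"]) <= {"M", "F"}
        assert len(cohort.true_roi_means) == 21 * 68

    def test_degenerate_spec_gives_pure_baseline(self):
        catalog = default_roi_catalog(2)
        effects = CohortEffectSpec(baseline_t1=1400.0, between_subject_sd=0.0)
        cohort = make_cohort(3, 3, roi_catalog=catalog, effects=effects)
        assert np.all(cohort.true_roi_means["true_t1"] == 1400.0)

    def test_planted_group_effect_is_exact(self):
        catalog = default_roi_catalog(2)
        effects = CohortEffectSpec(group_effect={1: 100.0}, between_subject_sd=0.0)
        cohort = make_cohort(5, 4, roi_catalog=catalog, effects=effects)
        df = cohort.true_roi_means.merge(cohort.covariates, on="subject_id")
        roi1 = df[df["roi_id"] == 1]
        diff = (
            roi1.loc[roi1["group"] == "SSD", "true_t1"].mean()
            - roi1.loc[roi1["group"] == "HC", "true_t1"].mean()
        )
        assert diff == pytest.approx(100.0, abs=1e-12)

    def test_bookkeeping_matches_analytic_effect_sum(self):
        catalog = default_roi_catalog(2)
        effects = CohortEffectSpec(
            baseline_t1=1400.0,
            group_effect={1: 80.0},
            sex_effect={1: -50.0, 3: -50.0},
            age_slope=-0.5,
            cpze_slope=-0.05,
            between_subject_sd=0.0,
            seed=9,
        )
        cohort = make_cohort(4, 3, roi_catalog=catalog, effects=effects)
        df = cohort.true_roi_means.merge(cohort.covariates, on="subject_id")
        for _, row in df.iterrows():
            expected = (
                1400.0
                + (80.0 if (row["roi_id"] == 1 and row["group"] == "SSD") else 0.0)
                + (-50.0 if (row["sex"] == "F" and row["roi_id"] in (1, 3)) else 0.0)
                - 0.5 * row["age"]
                - 0.05 * (0.0 if np.isnan(row["cpze"]) else row["cpze"])
            )
            assert row["true_t1"] == pytest.approx(expected, abs=1e-9)

    def test_unknown_roi_id_rejected(self):
        catalog = default_roi_catalog(2)
        with pytest.raises(ValueError, match="unknown ROI"):
            make_cohort(2, 2, roi_catalog=catalog,
                        effects=CohortEffectSpec(group_effect={99: 10.0}))

    def test_image_simulation_embeds_true_means(self, flat_phantom):
        effects = CohortEffectSpec(group_effect={1: 100.0}, between_subject_sd=0.0)
        cohort = make_cohort(
            2, 2, truth_template=flat_phantom, effects=effects,
            protocols=(AcquisitionProtocol.single_echo(),),
        )
        sid = cohort.subjects[0].subject_id
        truth = cohort.truths[sid]
        true_row = cohort.true_roi_means.query(
            "subject_id == @sid and roi_id == 1"
        )["true_t1"].iloc[0]
        assert np.all(truth.t1_map[truth.labels == 1] == true_row)
        assert set(cohort.acquisitions[sid]) == {"SE-qT1"}
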