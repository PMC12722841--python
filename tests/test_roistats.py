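"""ROI aggregation, case-control GLM, effect sizes, FDR, reliability summaries."""

import logging

import numpy as np
import pandas as pd
import pytest

from qt1pipe.phantom import CohortEffectSpec, default_roi_catalog, make_cohort
from qt1pipe.roistats import (
    bh_fdr,
    cohens_d_from_t,
    cohens_d_se,
    covariate_analysis,
    extract_roi_means,
    fit_group_glm,
    group_analysis,
    hemisphere_sd_summary,
    interprotocol_correlation,
)
from qt1pipe.t1fit import T1Map


def _t1map_from(values: np.ndarray, valid=None):
    if valid is None:
        valid = np.isfinite(values) & (values > 0)
    return T1Map(np.where(valid, values, np.nan), np.ones_like(values),
                 valid, "SE-qT1", np.eye(4))


def _roi_table_from_true(cohort, protocol="SE-qT1"):
    """Treat the generator's true ROI means as perfectly measured data."""
    df = cohort.true_roi_means.rename(columns={"true_t1": "mean_qt1"}).copy()
    df["protocol"] = protocol
    df["voxel_count"] = 100
    return df


class TestExtractRoiMeans:
    def test_uniform_map_gives_uniform_means(self):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[:4, 2:6, 2:6] = 1
        labels[4:, 2:6, 2:6] = 2
        catalog = {1: ("sector01", "left"), 2: ("sector01", "right")}
        t1map = _t1map_from(np.where(labels > 0, 1400.0, np.nan))
        table = extract_roi_means(t1map, labels, catalog, "sub-001")
        assert set(table["mean_qt1"]) == {1400.0}
        assert len(table) == 2

    def test_distinct_roi_values(self):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[:4] = 1
        labels[4:] = 2
        vals = np.where(labels == 1, 1000.0, 2000.0)
        catalog = {1: ("a", "left"), 2: ("b", "right")}
        table = extract_roi_means(_t1map_from(vals), labels, catalog, "s")
        assert table.set_index("roi_id")["mean_qt1"].to_dict() == {1: 1000.0, 2: 2000.0}

    def test_fully_invalid_roi_omitted_with_warning(self, caplog):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[:4] = 1
        labels[4:] = 2
        valid = labels == 1
        t1map = _t1map_from(np.full(labels.shape, 1400.0), valid=valid)
        catalog = {1: ("a", "left"), 2: ("b", "right")}
        with caplog.at_level(logging.WARNING):
            table = extract_roi_means(t1map, labels, catalog, "s")
        assert list(table["roi_id"]) == [1]
        assert any("no valid voxels" in r.message for r in caplog.records)

    def test_unknown_label_rejected(self):
        labels = np.ones((4, 4, 4), dtype=int)
        with pytest.raises(ValueError, match="catalog"):
            extract_roi_means(_t1map_from(np.full(labels.shape, 1400.0)),
                              labels, {2: ("b", "left")}, "s")


class TestEffectSizes:
    # reference rows: adjusted difference / SE converted through the
    # two-group design n1 = 14, n2 = 7
    @pytest.mark.parametrize(
        "diff,se,expected_d",
        [(171.05, 87.30, 0.91), (85.90, 25.05, 1.59), (0.0, 10.0, 0.0)],
    )
    def test_d_from_t(self, diff, se, expected_d):
        d = cohens_d_from_t(diff / se, 14, 7)
        assert round(d, 2) == pytest.approx(expected_d, abs=0.011)

    @pytest.mark.parametrize(
        "d,expected_se",
        [(1.59, 0.52), (0.0, 0.4629), (0.9, 0.48)],
    )
    def test_d_se(self, d, expected_se):
        assert cohens_d_se(d, 14, 7) == pytest.approx(expected_se, abs=0.005)

    def test_d_se_floor(self):
        # SE(d) can never fall below the zero-effect value sqrt((n1+n2)/(n1 n2))
        floor = np.sqrt(21.0 / 98.0)
        for d in (-2.0, -0.3, 0.0, 0.7, 3.0):
            assert cohens_d_se(d, 14, 7) >= floor

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 1, 7)


class TestGroupGlm:
    def _balanced_cohort(self, group_shift=100.0):
        rows, cov = [], []
        # two subjects per (group, sex) cell, identical ages: perfectly balanced
        sid = 0
        for group in ("SSD", "HC"):
            for sex in ("M", "F"):
                for age in (35.0, 45.0):  # ages balanced across every cell
                    sid += 1
                    cov.append((f"s{sid}", group, age, sex,
                                300.0 if group == "SSD" else np.nan))
                    val = 1400.0 + (group_shift if group == "SSD" else 0.0)
                    rows.append((f"s{sid}", 1, "sector01", "left", "SE-qT1", val, 50))
        table = pd.DataFrame(rows, columns=[
            "subject_id", "roi_id", "roi_name", "hemisphere", "protocol",
            "mean_qt1", "voxel_count"])
        covariates = pd.DataFrame(cov, columns=["subject_id", "group", "age", "sex", "cpze"])
        return table, covariates

    def test_planted_effect_recovered_exactly(self):
        table, cov = self._balanced_cohort(100.0)
        row = fit_group_glm(table, cov, 1)
        assert row["group_coef"] == pytest.approx(100.0, abs=1e-9)
        assert row["p_raw"] < 1e-12

    def test_balanced_design_group_coef_equals_raw_difference(self):
        rng = np.random.default_rng(3)
        table, cov = self._balanced_cohort(0.0)
        table["mean_qt1"] += rng.normal(0, 30.0, len(table))
        row = fit_group_glm(table, cov, 1)
        assert row["group_coef"] == pytest.approx(row["raw_diff"], abs=1e-9)

    def test_single_sex_sample_named_in_error(self):
        table, cov = self._balanced_cohort()
        cov["sex"] = "M"
        with pytest.raises(ValueError, match="sex"):
            fit_group_glm(table, cov, 1)

    def test_group_analysis_applies_hemisphere_fdr(self):
        catalog = default_roi_catalog(3)
        cohort = make_cohort(8, 8, roi_catalog=catalog,
                             effects=CohortEffectSpec(between_subject_sd=30.0, seed=2))
        table = _roi_table_from_true(cohort)
        out = group_analysis(table, cohort.covariates)
        assert len(out) == 6
        assert (out["p_fdr"] >= out["p_raw"] - 1e-15).all()
        for hemi in ("left", "right"):
            sub = out[out["hemisphere"] == hemi]
            expected = bh_fdr(sub["p_raw"].to_numpy())
            np.testing.assert_allclose(sub["p_fdr"].to_numpy(), expected)

    def test_null_coverage_with_age_effect_only(self):
        # age slope planted, no group effect: the 95% CI on the group
        # coefficient must cover zero in >= 93% of replicates
        catalog = default_roi_catalog(1)
        covered = 0
        n_rep = 500
        for i in range(n_rep):
            cohort = make_cohort(
                10, 10, roi_catalog=catalog,
                effects=CohortEffectSpec(age_slope=-2.0, between_subject_sd=40.0, seed=i),
            )
            row = fit_group_glm(_roi_table_from_true(cohort), cohort.covariates, 1)
            half = 2.1199 * row["coef_se"]  # t(16, 0.975)
            covered += abs(row["group_coef"]) <= half
        assert covered / n_rep >= 0.93


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_and_singleton_inputs(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_fdr([0.123]), [0.123])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_never_decreases_p(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            assert (bh_fdr(p) >= p - 1e-15).all()

    def test_grouped_equals_per_family(self, rng):
        p = rng.random(40)
        hemi = np.array(["left", "right"] * 20)
        grouped = bh_fdr(p, groups=hemi)
        for h in ("left", "right"):
            np.testing.assert_allclose(grouped[hemi == h], bh_fdr(p[hemi == h]))

    def test_adjusted_p_reproduces_step_up_decisions(self, rng):
        # the defining property of BH adjusted p-values: thresholding them at
        # alpha yields exactly the step-up rejection set
        for _ in range(50):
            p = rng.random(rng.integers(1, 25))
            alpha = rng.uniform(0.01, 0.2)
            adj = bh_fdr(p)
            m = len(p)
            order = np.argsort(p)
            k = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= rank * alpha / m:
                    k = rank
            rejected = np.zeros(m, dtype=bool)
            rejected[order[:k]] = True
            np.testing.assert_array_equal(adj <= alpha, rejected)


class TestCorrelationAndSd:
    def _table(self, values, protocol, roi_id=1, hemi="left"):
        n = len(values)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "roi_id": roi_id, "roi_name": "sector01", "hemisphere": hemi,
            "protocol": protocol, "mean_qt1": values, "voxel_count": 10,
        })

    def test_identical_tables_r_one(self, rng):
        vals = 1400 + rng.normal(0, 50, 10)
        a = self._table(vals, "SE-qT1")
        b = self._table(vals, "ME-qT1")
        out = interprotocol_correlation(a, b)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_tables_r_minus_one(self, rng):
        vals = 1400 + rng.normal(0, 50, 10)
        out = interprotocol_correlation(
            self._table(vals, "SE-qT1"), self._table(-vals + 3000, "ME-qT1")
        )
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_too_few_subjects_rejected(self):
        a = self._table([1.0, 2.0], "SE-qT1")
        b = self._table([2.0, 3.0], "ME-qT1")
        with pytest.raises(ValueError, match=">=3"):
            interprotocol_correlation(a, b)

    def test_sd_summary_identical_subjects_zero(self):
        table = pd.concat([self._table([1400.0] * 5, "SE-qT1")])
        out = hemisphere_sd_summary(table)
        assert out["mean_roi_sd"].iloc[0] == 0.0

    def test_sd_summary_hand_value(self):
        out = hemisphere_sd_summary(self._table([1000.0, 1400.0], "SE-qT1"))
        assert out["mean_roi_sd"].iloc[0] == pytest.approx(282.84, abs=0.01)

    def test_noisier_table_dominates_sd_summary(self, rng):
        # i.i.d. noise with larger sigma on the ME table: its summary must
        # exceed the SE one in nearly every replicate
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            base = 1400 + rng.normal(0, 10, 15)
            se_tab = self._table(base + rng.normal(0, 20, 15), "SE-qT1")
            me_tab = self._table(base + rng.normal(0, 60, 15), "ME-qT1")
            both = pd.concat([se_tab, me_tab], ignore_index=True)
            out = hemisphere_sd_summary(both).set_index("protocol")["mean_roi_sd"]
            wins += out["ME-qT1"] > out["SE-qT1"]
        assert wins / n_rep >= 0.95


class TestCovariateAnalysis:
    def _ssd_cohort(self, sex_effect=0.0, cpze_slope=0.0, sd=0.0, seed=0):
        catalog = default_roi_catalog(1)
        effects = CohortEffectSpec(
            sex_effect={rid: sex_effect for rid in catalog},
            cpze_slope=cpze_slope, between_subject_sd=sd, seed=seed,
        )
        cohort = make_cohort(14, 2, roi_catalog=catalog, effects=effects)
        return _roi_table_from_true(cohort), cohort.covariates

    def test_planted_sex_effect_exact(self):
        table, cov = self._ssd_cohort(sex_effect=-80.0)
        out = covariate_analysis(table, cov)
        sex_row = out[out["covariate"] == "sex"].iloc[0]
        assert sex_row["coef"] == pytest.approx(-80.0, abs=1e-9)

    def test_planted_cpze_slope_exact(self):
        table, cov = self._ssd_cohort(cpze_slope=-0.05)
        out = covariate_analysis(table, cov)
        cpze_row = out[out["covariate"] == "cpze"].iloc[0]
        assert cpze_row["coef"] == pytest.approx(-0.05, abs=1e-12)

    def test_only_ssd_subjects_used(self):
        table, cov = self._ssd_cohort(sd=20.0, seed=4)
        out = covariate_analysis(table, cov)
        assert (out["n"] == 14).all()

    def test_missing_cpze_rejected(self):
        table, cov = self._ssd_cohort()
        cov.loc[cov.index[0], "cpze"] = np.nan
        with pytest.raises(ValueError, match="CPZe"):
            covariate_analysis(table, cov)
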