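"""Reliability statistics against hand-coded ANOVA oracles, pingouin, and
simulations with known variance components."""

import numpy as np
import pandas as pd
import pytest

from accelee.equations import ALL_EQUATION_IDS, EEResult
from accelee.errors import DataError, DegenerateInputError
from accelee.reliability import (agreement_table, cronbach_alpha_standardized,
                                 icc_two_way_mixed, paired_values)
from accelee.signal_io import ManifestRecord, StudyManifest


def hand_icc(values):
    """Independent ANOVA mean-squares computation with explicit loops."""
    values = np.asarray(values, float)
    n, k = values.shape
    grand = values.sum() / values.size
    ss_rows = sum(k * (values[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (values[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((values[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    single = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    average = (ms_rows - ms_err) / ms_rows
    return single, average


class TestICC:
    def test_identical_columns_give_icc_1(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = icc_two_way_mixed(m)
        assert res.icc_single == pytest.approx(1.0)
        assert res.icc_average == pytest.approx(1.0)

    def test_hand_anova_oracle_fixed_matrix(self):
        m = np.array([[1, 2], [2, 1], [3, 3], [4, 4], [5, 5]], float)
        single, average = hand_icc(m)
        res = icc_two_way_mixed(m)
        assert res.icc_single == pytest.approx(single, abs=1e-12)
        assert res.icc_average == pytest.approx(average, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_hand_anova_oracle_random_10x2(self, seed):
        m = np.random.default_rng(seed).normal(size=(10, 2))
        single, average = hand_icc(m)
        res = icc_two_way_mixed(m)
        assert res.icc_single == pytest.approx(single, abs=1e-10)
        assert res.icc_average == pytest.approx(average, abs=1e-10)

    def test_matches_pingouin_icc3(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        m = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        df = pd.DataFrame(m, columns=["a", "b", "c"]).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score")
        icc = pingouin.intraclass_corr(df, targets="index", raters="rater",
                                       ratings="score").set_index("Type")
        res = icc_two_way_mixed(m)
        # consistency-type rows: labelled ICC(C,1)/ICC(C,k) (a.k.a. ICC3/ICC3k)
        assert res.icc_single == pytest.approx(icc.loc["ICC(C,1)", "ICC"], abs=1e-8)
        assert res.icc_average == pytest.approx(icc.loc["ICC(C,k)", "ICC"], abs=1e-8)

    def test_independent_columns_icc_near_zero(self):
        m = np.random.default_rng(123).normal(size=(10000, 2))
        assert abs(icc_two_way_mixed(m).icc_single) < 0.05

    def test_negative_icc_possible_and_reported(self):
        m = np.array([[1, 5], [2, 4], [3, 3], [4, 2], [5, 1]], float)
        assert icc_two_way_mixed(m).icc_single < 0

    def test_shift_invariance_common_constant(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(15, 2))
        a = icc_two_way_mixed(m).icc_single
        b = icc_two_way_mixed(m + 17.3).icc_single
        assert a == pytest.approx(b, abs=1e-12)

    def test_consistency_invariant_to_per_rater_offsets(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(15, 2))
        shifted = m + np.array([1.0, -2.5])
        assert icc_two_way_mixed(m).icc_single == pytest.approx(
            icc_two_way_mixed(shifted).icc_single, abs=1e-10)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            icc_two_way_mixed(np.full((5, 2), 3.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DataError, match="3 subjects"):
            icc_two_way_mixed(np.random.default_rng(0).normal(size=(2, 2)))

    def test_parameter_recovery_known_variance_components(self):
        # subject effect sd 1, rater noise sd 0.5 -> ICC(3,1) = 1/(1+0.25) = 0.8
        rng = np.random.default_rng(2024)
        n, k = 200, 2
        sb, se = 1.0, 0.5
        subject = rng.normal(0, sb, size=(n, 1))
        m = subject + rng.normal(0, se, size=(n, k))
        truth = sb ** 2 / (sb ** 2 + se ** 2)
        assert icc_two_way_mixed(m).icc_single == pytest.approx(truth, abs=0.05)


class TestAlpha:
    def test_perfect_correlation_gives_1(self):
        x = np.arange(10.0)
        m = np.column_stack([x, 2 * x + 3])
        assert cronbach_alpha_standardized(m) == pytest.approx(1.0)

    def test_closed_form_r_half(self):
        # alpha_std = 2*0.5/1.5 for k=2, r=0.5 (checked through the formula
        # with an exactly-constructed correlation)
        rng = np.random.default_rng(7)
        z = rng.normal(size=1000)
        a = z + rng.normal(size=1000)
        b = z + rng.normal(size=1000)
        m = np.column_stack([a, b])
        r = np.corrcoef(a, b)[0, 1]
        assert cronbach_alpha_standardized(m) == pytest.approx(2 * r / (1 + r), abs=1e-12)

    def test_matches_independent_pearson_r(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(20, 2))
        x, y = m[:, 0], m[:, 1]
        r = (np.sum((x - x.mean()) * (y - y.mean()))
             / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert cronbach_alpha_standardized(m) == pytest.approx(2 * r / (1 + r), abs=1e-12)

    def test_zero_variance_column_rejected(self):
        m = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(DegenerateInputError):
            cronbach_alpha_standardized(m)

    def test_k2_alpha_close_to_average_icc_on_exchangeable_columns(self):
        rng = np.random.default_rng(9)
        subject = rng.normal(0, 1, size=(500, 1))
        m = subject + rng.normal(0, 0.4, size=(500, 2))
        res = icc_two_way_mixed(m)
        assert res.alpha_standardized == pytest.approx(res.icc_average, abs=0.01)


def _ee_from_table(values_by_record):
    return [EEResult(rid, {eq: v for eq in ALL_EQUATION_IDS},
                     {eq: "light" for eq in ALL_EQUATION_IDS})
            for rid, v in values_by_record.items()]


def _paired_manifest(n_subjects, speeds=(5.0, 6.0)):
    recs = []
    for p in range(n_subjects):
        for s, speed in enumerate(speeds):
            recs.append(ManifestRecord(f"a{p}s{s}", f"p{p}", "actigraph",
                                       "wrist", 1, speed, 2.0))
            recs.append(ManifestRecord(f"b{p}s{s}", f"p{p}", "sensorid",
                                       "wrist", 1, speed, 2.0))
    return StudyManifest(recs)


class TestAgreementTable:
    def test_duplicated_device_data_gives_icc_1_everywhere(self):
        rng = np.random.default_rng(10)
        manifest = _paired_manifest(6)
        ee = []
        for p in range(6):
            for s in range(2):
                base = float(rng.uniform(2, 8))
                mets = {eq: base + 0.1 * i for i, eq in enumerate(ALL_EQUATION_IDS)}
                for rid in (f"a{p}s{s}", f"b{p}s{s}"):
                    ee.append(EEResult(rid, dict(mets),
                                       {eq: "moderate" for eq in ALL_EQUATION_IDS}))
        res = agreement_table(ee, manifest, "device_at_placement", "wrist")
        icc_cols = res.table[list(ALL_EQUATION_IDS)]
        assert np.allclose(icc_cols.to_numpy(dtype=float), 1.0)
        assert res.table.loc["MEAN", "freedson1998"] == pytest.approx(1.0)

    def test_low_noise_pairs_give_high_icc(self):
        # rater noise sd = 0.1 x subject sd: expected ICC ~ 0.99
        rng = np.random.default_rng(12)
        manifest = _paired_manifest(10)
        ee = []
        for p in range(10):
            for s in range(2):
                subj = float(rng.normal(5, 1))
                for rid in (f"a{p}s{s}", f"b{p}s{s}"):
                    val = subj + float(rng.normal(0, 0.1))
                    ee.append(EEResult(rid, {eq: val for eq in ALL_EQUATION_IDS},
                                       {eq: "moderate" for eq in ALL_EQUATION_IDS}))
        res = agreement_table(ee, manifest, "device_at_placement", "wrist")
        per_speed = res.table.drop(index="MEAN")[list(ALL_EQUATION_IDS)]
        assert (per_speed.to_numpy(dtype=float) > 0.9).all()

    def test_table_shape_matches_design(self):
        rng = np.random.default_rng(13)
        speeds = (1.4, 2.9, 4.3, 5.0, 6.0, 6.5, 7.0, 8.0, 9.0, 10.0)
        manifest = _paired_manifest(4, speeds=speeds)
        ee = []
        for rec in manifest:
            ee.append(EEResult(rec.record_id,
                               {eq: float(rng.uniform(1, 9)) for eq in ALL_EQUATION_IDS},
                               {eq: "moderate" for eq in ALL_EQUATION_IDS}))
        res = agreement_table(ee, manifest, "device_at_placement", "wrist")
        assert list(res.table.columns) == ["alpha_std", *ALL_EQUATION_IDS]
        assert len(res.table) == 11  # 10 speeds + MEAN
        assert res.table.index[-1] == "MEAN"

    def test_unmatched_pairs_reported_not_fatal(self):
        manifest = _paired_manifest(4)
        # drop one sensorid record's EE -> that cell becomes unmatched
        ee = []
        rng = np.random.default_rng(14)
        for rec in manifest:
            if rec.record_id == "b0s0":
                continue
            ee.append(EEResult(rec.record_id,
                               {eq: float(rng.uniform(1, 9)) for eq in ALL_EQUATION_IDS},
                               {eq: "moderate" for eq in ALL_EQUATION_IDS}))
        res = agreement_table(ee, manifest, "device_at_placement", "wrist")
        assert len(res.skipped) == 1
        assert "p0" in res.skipped.iloc[0]["participant_id"]

    def test_paired_values_orientation(self):
        manifest = _paired_manifest(3)
        ee = _ee_from_table({rec.record_id: float(i)
                             for i, rec in enumerate(manifest)})
        mats, skipped = paired_values(ee, manifest, "device_at_placement", "wrist")
        assert set(mats) == {5.0, 6.0}
        assert mats[5.0]["freedson1998"].shape == (3, 2)
        assert len(skipped) == 0
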