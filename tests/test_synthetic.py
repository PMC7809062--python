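"""Synthetic cohort generator: determinism, labels, moments, correlation."""

import numpy as np
import pandas as pd
import pytest

from radfusion.synthetic import (
    EXCLUDED,
    SimulationConfig,
    derive_two_year_label,
    generate_cohort,
    generate_roi_images,
    records_to_frame,
    study_cohorts,
    write_cohort,
)


class TestConfig:
    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=10, noise_sd=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=10, shared_fraction=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=10, hazard_coefs=(1.0,))


class TestTwoYearLabel:
    @pytest.mark.parametrize("time,event,expected", [
        (400, 1, 1),         # death before the horizon
        (900, 0, 0),         # followed beyond the horizon
        (500, 0, 0),         # censored early: survivor by last follow-up
        (80, 1, EXCLUDED),   # early post-surgery death
        (90, 1, EXCLUDED),   # boundary day included in the exclusion
        (731, 1, 0),         # death just past the horizon
    ])
    def test_rules(self, time, event, expected):
        assert derive_two_year_label(time, event) == expected

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            derive_two_year_label(100, 1, horizon_days=0)


class TestGenerateCohort:
    def test_same_config_bit_identical(self):
        cfg = SimulationConfig.pdac_like(30, seed=9, n_features_bankR=50, block_sizes=(5, 5))
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a[0].equals(b[0]) and a[1].equals(b[1]) and a[2] == b[2]

    def test_no_censoring_means_all_events(self):
        cfg = SimulationConfig(n_samples=200, n_features_bankR=10, n_features_bankT=5,
                               censor_rate=0.0, seed=1)
        _, _, records = generate_cohort(cfg)
        assert all(r.event == 1 for r in records)

    def test_exclusion_flag_consistent(self):
        _, _, records = generate_cohort(SimulationConfig.pdac_like(
            120, seed=3, n_features_bankR=20, block_sizes=(5, 5)))
        for r in records:
            assert r.excluded_90d == int(r.event == 1 and r.time_days <= 90)
            assert (r.label_2yr == EXCLUDED) == bool(r.excluded_90d)

    def test_feature_moments_match_model(self):
        # Gaussian base model: Var(x) = loading^2 + noise_sd^2, mean 0
        cfg = SimulationConfig(n_samples=1000, n_features_bankR=12, n_features_bankT=6,
                               seed=4)
        bank_r, _, _ = generate_cohort(cfg)
        x = bank_r.to_numpy()
        var_expected = cfg.loading_R[0] ** 2 + 1.0  # first block loads latent 0
        col = x[:, 0]
        se = var_expected * np.sqrt(2 / 999)
        assert abs(col.var(ddof=1) - var_expected) < 3 * se
        assert abs(col.mean()) < 3 * np.sqrt(var_expected / 1000)

    def test_null_hazard_gives_chance_level_auc(self):
        from sklearn.linear_model import LogisticRegression
        aucs = []
        for seed in range(20):
            cfg = SimulationConfig(n_samples=80, n_features_bankR=15, n_features_bankT=5,
                                   hazard_coefs=(0.0, 0.0, 0.0), seed=seed)
            bank_r, _, records = generate_cohort(cfg)
            df = records_to_frame(records)
            keep = df.label_2yr >= 0
            y = df.label_2yr[keep].to_numpy()
            if len(np.unique(y)) < 2:
                continue
            x = bank_r[keep.to_numpy()].to_numpy()
            half = len(y) // 2
            model = LogisticRegression(max_iter=500).fit(x[:half], y[:half])
            from radfusion.evaluation import roc_auc
            if len(np.unique(y[half:])) == 2:
                aucs.append(roc_auc(model.predict_proba(x[half:])[:, 1], y[half:]))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_unlinked_banks_are_uncorrelated(self):
        cfg = SimulationConfig(n_samples=500, n_features_bankR=40, n_features_bankT=10,
                               loading_T=(0.0, 0.0, 0.0), shared_fraction=0.0,
                               n_latent=3, loading_R=(0.9, 1.1, 0.0),
                               hazard_coefs=(0.0, 1.0, 1.0), seed=6)
        bank_r, bank_t, _ = generate_cohort(cfg)
        cross = np.corrcoef(np.hstack([bank_r, bank_t]), rowvar=False)[:40, 40:]
        assert np.abs(cross).mean() <= 0.1

    def test_calibrated_cross_bank_correlation_target(self):
        bank_r, bank_t, _ = generate_cohort(SimulationConfig.pdac_like(500, seed=3))
        cross = np.corrcoef(np.hstack([bank_r, bank_t]),
                            rowvar=False)[:bank_r.shape[1], bank_r.shape[1]:]
        assert abs(np.abs(cross).mean() - 0.17) < 0.05


class TestRoiImages:
    def test_deterministic_and_masking_rule_exercised(self):
        a = generate_roi_images(10, seed=5)
        b = generate_roi_images(10, seed=5)
        for (ia, ma, la), (ib, mb, lb) in zip(a, b):
            assert np.array_equal(ia, ib) and np.array_equal(ma, mb) and la == lb
        from radfusion.radiomics import apply_intensity_mask
        for img, mask, _ in a:
            assert (img[mask] > 500).any() and (img[mask] < -10).any()
            refined = apply_intensity_mask(img, mask)
            assert refined.sum() < mask.sum()

    def test_size_validation(self):
        with pytest.raises(ValueError):
            generate_roi_images(3, size=4)
        with pytest.raises(ValueError):
            generate_roi_images(0)


def test_write_cohort_round_trips(tmp_path, small_cohort):
    bank_r, bank_t, df = small_cohort
    from radfusion.synthetic import SurvivalRecord
    records = [SurvivalRecord(i, row.time_days, int(row.event), int(row.label_2yr),
                              int(row.excluded_90d)) for i, row in df.iterrows()]
    write_cohort(tmp_path, bank_r, bank_t, records)
    back = pd.read_csv(tmp_path / "bankR.csv", index_col=0)
    assert back.shape == bank_r.shape
    surv = pd.read_csv(tmp_path / "survival.csv", index_col=0)
    assert {"time_days", "event", "label_2yr"} <= set(surv.columns)


def test_study_cohorts_shapes_and_exclusion():
    tr_r, tr_t, tr_df, te_r, te_t, te_df = study_cohorts(0, n_train=40, n_test=20,
                                                         n_features_bankR=80)
    assert tr_r.shape == (40, 80) and tr_t.shape == (40, 35)
    assert te_r.shape == (20, 80)
    assert (tr_df.label_2yr >= 0).all() and (te_df.label_2yr >= 0).all()
    assert tr_r.index.equals(tr_t.index)
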