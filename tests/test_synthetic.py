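"""Statistical correctness of the synthetic cohort generator."""

import numpy as np
import pytest

from recovnet.datatypes import LanguageRecord, RecoveryTrajectory
from recovnet.recovery import classify_recovery
from recovnet.synthetic import (
    CohortConfig,
    apply_disruption,
    build_target_covariance,
    generate_cohort,
    generate_patient,
    make_symmetric_network,
    simulate_timeseries,
)


class TestTargetCovariance:
    def test_block_structure_by_construction(self, two_networks):
        cfg = CohortConfig(base_within_corr=0.45, base_between_corr=0.08)
        cov, ids = build_target_covariance(cfg, two_networks)
        assert cov.shape == (12, 12)
        assert np.allclose(np.diag(cov), 1.0)
        # two 6x6 within blocks of 0.45 off-diagonal
        a = cov[:6, :6]
        assert np.allclose(a[~np.eye(6, dtype=bool)], 0.45)
        assert np.allclose(cov[:6, 6:], 0.08)

    def test_zero_correlations_give_identity(self, two_networks):
        cfg = CohortConfig(base_within_corr=0.0, base_between_corr=0.0)
        cov, _ = build_target_covariance(cfg, two_networks)
        assert np.allclose(cov, np.eye(12))

    def test_large_equicorrelated_block_is_psd(self):
        net = make_symmetric_network("lang", 68)
        cfg = CohortConfig(base_within_corr=0.45)
        cov, _ = build_target_covariance(cfg, [net])
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_overlapping_networks_rejected(self, two_networks):
        cfg = CohortConfig()
        with pytest.raises(ValueError, match="disjoint"):
            build_target_covariance(cfg, [two_networks[0], two_networks[0]])


class TestSimulateTimeseries:
    def test_independent_nodes_stay_uncorrelated_at_large_n(self):
        x = simulate_timeseries(np.eye(4), 100_000, ar1=0.0, seed=42)
        r = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(r, 0.0)
        assert np.abs(r).max() < 0.02

    def test_block_correlation_recovered_at_large_n(self, two_networks):
        cfg = CohortConfig(base_within_corr=0.45, base_between_corr=0.08)
        cov, _ = build_target_covariance(cfg, two_networks)
        x = simulate_timeseries(cov, 100_000, ar1=0.3, seed=7)
        r = np.corrcoef(x, rowvar=False)
        assert np.abs(r - cov).max() < 0.01 + 1e-9

    def test_same_seed_is_bit_identical(self):
        a = simulate_timeseries(np.eye(3), 100, ar1=0.3, seed=5)
        b = simulate_timeseries(np.eye(3), 100, ar1=0.3, seed=5)
        assert np.array_equal(a, b)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            simulate_timeseries(np.eye(2), 1, seed=0)

    def test_ar1_autocorrelation_recovered(self):
        x = simulate_timeseries(np.eye(1), 100_000, ar1=0.6, seed=3)[:, 0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 == pytest.approx(0.6, abs=0.02)


class TestDisruption:
    def test_zero_attenuation_is_identity(self, two_networks):
        cfg = CohortConfig()
        cov, ids = build_target_covariance(cfg, two_networks)
        out = apply_disruption(cov, ids, two_networks, ["alpha_L1"], 0.0)
        assert np.array_equal(out, cov)

    def test_full_attenuation_zeroes_incident_edges(self, two_networks):
        cfg = CohortConfig()
        cov, ids = build_target_covariance(cfg, two_networks)
        out = apply_disruption(cov, ids, two_networks, ["alpha_L1"], 1.0)
        i = ids.index("alpha_L1")
        row = np.delete(out[i], i)
        assert np.allclose(row, 0.0)

    def test_contralateral_homologue_also_attenuated(self, two_networks):
        cfg = CohortConfig()
        cov, ids = build_target_covariance(cfg, two_networks)
        out = apply_disruption(cov, ids, two_networks, ["alpha_L2"], 0.5)
        i, j = ids.index("alpha_R2"), ids.index("alpha_L3")
        # homologue of alpha_L2 is alpha_R2 (same within-hemisphere index)
        assert out[i, j] == pytest.approx(cov[i, j] * 0.5)

    def test_untouched_entries_bit_identical(self, two_networks):
        cfg = CohortConfig()
        cov, ids = build_target_covariance(cfg, two_networks)
        out = apply_disruption(cov, ids, two_networks, ["alpha_L1"], 0.5)
        affected = {ids.index("alpha_L1"), ids.index("alpha_R1")}
        for i in range(len(ids)):
            for j in range(len(ids)):
                if i not in affected and j not in affected:
                    assert out[i, j] == cov[i, j]

    def test_attenuation_range_validated(self, two_networks):
        cfg = CohortConfig()
        cov, ids = build_target_covariance(cfg, two_networks)
        with pytest.raises(ValueError):
            apply_disruption(cov, ids, two_networks, ["alpha_L1"], 1.5)

    def test_peritumoral_nodes_must_share_hemisphere(self, two_networks):
        cfg = CohortConfig()
        cov, ids = build_target_covariance(cfg, two_networks)
        with pytest.raises(ValueError, match="hemisphere"):
            apply_disruption(cov, ids, two_networks, ["alpha_L1", "alpha_R1"], 0.5)


class TestPatientGeneration:
    def test_full_recovery_profile_restores_baseline_aq(self, two_networks):
        cfg = CohortConfig(recovery_profile={"w2": 1.0, "m3": 0.0},
                           language_link_noise_sd=0.0, disruption_frac=1.0,
                           language_link_slope=0.4)
        _, records, _ = generate_patient(cfg, two_networks,
                                         timepoints=("pre", "w2", "m3"),
                                         with_timeseries=False, seed=1)
        by_tp = {r.timepoint: r.aq for r in records}
        assert by_tp["m3"] == pytest.approx(by_tp["pre"])
        # slope 0.4 x attenuation 1.0 -> 40-point AQ drop at the nadir
        assert by_tp["w2"] == pytest.approx(max(0.0, by_tp["pre"] - 40.0))

    def test_subscores_consistent_with_aq_formula(self, two_networks):
        cfg = CohortConfig(language_link_noise_sd=2.0)
        _, records, _ = generate_patient(cfg, two_networks, with_timeseries=False,
                                         seed=4)
        for r in records:
            # LanguageRecord validates AQ-subscore consistency on construction
            assert isinstance(r, LanguageRecord)
            assert 0.0 <= r.aq <= 100.0

    def test_most_full_recovery_patients_classified_good(self, two_networks):
        # 200 noisy patients with a full-recovery profile
        cfg = CohortConfig(recovery_profile={"w2": 1.0, "m3": 0.0},
                           language_link_slope=0.4, disruption_frac=1.0,
                           language_link_noise_sd=2.0)
        rng = np.random.default_rng(123)
        n_good = 0
        for _ in range(200):
            _, records, _ = generate_patient(cfg, two_networks,
                                             timepoints=("pre", "w2", "m3"),
                                             with_timeseries=False, seed=rng)
            traj = RecoveryTrajectory(
                subject="p", values={r.timepoint: r.aq for r in records})
            n_good += classify_recovery(traj) == "good"
        assert n_good >= 190  # >= 95%

    def test_motion_spikes_present_postoperatively(self, small_config,
                                                   two_networks):
        series, _, _ = generate_patient(small_config, two_networks,
                                        timepoints=("pre", "w2"), seed=2)
        from recovnet.preprocessing import compute_fd

        fd_post = compute_fd(series["w2"].motion)
        assert (fd_post > 0.5).sum() >= 1


class TestCohortDeterminism:
    def test_identical_config_and_seed_bit_identical(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        assert np.array_equal(a.controls[0].data, b.controls[0].data)
        assert np.array_equal(a.patients["P001"]["w2"].data,
                              b.patients["P001"]["w2"].data)
        assert [r.aq for r in a.language] == [r.aq for r in b.language]

    def test_different_seed_differs(self, small_config):
        import dataclasses

        a = generate_cohort(small_config)
        b = generate_cohort(dataclasses.replace(small_config, seed=99))
        assert not np.array_equal(a.controls[0].data, b.controls[0].data)

    def test_manifest_describes_cohort(self, small_config):
        cohort = generate_cohort(small_config)
        m = cohort.manifest()
        assert m["n_controls"] == 4
        assert m["n_patients"] == 2
        assert m["networks"] == {"alpha": 6, "beta": 6}


class TestConfigValidation:
    def test_recovery_profile_must_be_one_at_subacute(self):
        with pytest.raises(ValueError, match="subacute"):
            CohortConfig(recovery_profile={"w2": 0.5, "m3": 0.1})

    def test_correlations_validated(self):
        with pytest.raises(ValueError):
            CohortConfig(base_within_corr=1.2)
        with pytest.raises(ValueError):
            CohortConfig(ar1_coeff=1.0)
        with pytest.raises(ValueError):
            CohortConfig(disruption_frac=-0.1)
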