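"""Generator contracts: planted structure, determinism, convergence."""

import numpy as np
import pytest

from fcbench import qc, synthetic
from fcbench.synthetic import (make_ground_truth, simulate_confounds,
                               simulate_dataset, simulate_label_volume,
                               simulate_scan)


class TestGroundTruth:
    def test_zero_differential_edges_gives_identical_state_covariances(self):
        gt = make_ground_truth(10, n_diff_edges=0, effect_size=0.3, seed=7)
        np.testing.assert_array_equal(gt.cov_eo, gt.cov_ec)

    def test_planted_deltas_appear_exactly_on_recorded_edges(self):
        gt = make_ground_truth(6, n_diff_edges=3, effect_size=0.3, seed=1)
        diff = gt.cov_ec - gt.cov_eo
        expected = np.zeros((6, 6))
        for i, j, d in gt.diff_edges:
            assert abs(d) == pytest.approx(0.3)
            expected[i, j] = expected[j, i] = d
        # off-diagonal differences are exactly the requested deltas
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(diff[off], expected[off], atol=1e-12)
        assert len(gt.diff_edges) == 3

    def test_state_covariances_are_spd(self):
        gt = make_ground_truth(12, n_diff_edges=4, effect_size=0.3, seed=3)
        for cov in (gt.cov_eo, gt.cov_ec):
            assert np.linalg.eigvalsh(cov)[0] > 0
            np.testing.assert_allclose(cov, cov.T)

    def test_infeasible_effect_size_raises(self):
        with pytest.raises(ValueError):
            make_ground_truth(4, n_diff_edges=1, effect_size=5.0, seed=0)

    def test_deterministic_given_seed(self):
        a = make_ground_truth(8, 3, 0.3, seed=11)
        b = make_ground_truth(8, 3, 0.3, seed=11)
        np.testing.assert_array_equal(a.cov_ec, b.cov_ec)
        assert a.diff_edges == b.diff_edges


class TestConfounds:
    def test_zero_motion_amplitude_gives_zero_fd(self):
        conf = simulate_confounds(60, 2.0, motion_amplitude=0.0, seed=0)
        assert np.all(conf.data["framewise_displacement"].to_numpy() == 0)
        assert np.all(conf.data["rmsd"].to_numpy() == 0)

    def test_tables_bit_identical_under_fixed_seed(self):
        a = simulate_confounds(240, 2.0, 0.1, seed=5)
        b = simulate_confounds(240, 2.0, 0.1, seed=5)
        assert a.data.equals(b.data)

    def test_mean_fd_grows_with_motion_amplitude(self):
        means = [simulate_confounds(120, 2.5, amp, seed=9)
                 .data["framewise_displacement"].mean()
                 for amp in (0.05, 0.1, 0.2)]
        assert means[0] < means[1] < means[2]

    def test_fd_and_rmsd_columns_delegate_to_qc(self):
        conf = simulate_confounds(80, 2.0, 0.1, seed=2)
        np.testing.assert_allclose(
            conf.data["framewise_displacement"].to_numpy(),
            qc.framewise_displacement(conf.motion()))
        np.testing.assert_allclose(conf.data["rmsd"].to_numpy(),
                                   qc.relative_rmsd(conf.motion()))

    def test_acompcor_shares_positive_and_sorted(self):
        conf = simulate_confounds(60, 2.0, seed=1)
        assert (conf.acompcor_shares > 0).all()
        assert (np.diff(conf.acompcor_shares) <= 0).all()

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            simulate_confounds(60, 2.0, motion_amplitude=-0.1)


def _identity_gt(R=6):
    gt = make_ground_truth(R, n_diff_edges=0, seed=0)
    gt.cov_eo = np.eye(R)
    gt.cov_ec = np.eye(R)
    return gt


class TestScan:
    def test_noise_free_uncoupled_identity_scan_reproduces_latent_draws(self):
        gt = _identity_gt()
        conf = simulate_confounds(50, 2.0, 0.1, seed=3)
        scan = simulate_scan(gt, conf, "EO", "site_A", coupling_strength=0.0,
                             seed=42, noise_sigma=0.0)
        rng = np.random.default_rng(42)
        z = np.column_stack([synthetic._ar1(rng, 50, 0.3) for _ in range(6)])
        np.testing.assert_allclose(scan.timeseries, z)

    def test_sample_covariance_converges_to_state_covariance(self):
        gt = make_ground_truth(8, n_diff_edges=2, effect_size=0.3, seed=4)
        errs = []
        for seed in range(5):
            conf = simulate_confounds(5000, 2.5, 0.0, seed=seed)
            scan = simulate_scan(gt, conf, "EO", "site_A",
                                 coupling_strength=0.0, seed=seed,
                                 noise_sigma=0.0)
            emp = np.cov(scan.timeseries, rowvar=False)
            errs.append(np.linalg.norm(emp - gt.cov_eo))
        assert np.mean(errs) < 0.15 * np.linalg.norm(gt.cov_eo)

    def test_covariance_error_shrinks_with_scan_length(self):
        gt = make_ground_truth(8, n_diff_edges=0, seed=4)
        mean_err = []
        for T in (200, 800, 3200):
            errs = []
            for seed in range(5):
                conf = simulate_confounds(T, 2.0, 0.0, seed=seed)
                scan = simulate_scan(gt, conf, "EC", "site_A", 0.0, seed=seed,
                                     noise_sigma=0.0)
                errs.append(np.linalg.norm(
                    np.cov(scan.timeseries, rowvar=False) - gt.cov_ec))
            mean_err.append(np.mean(errs))
        assert mean_err[0] > mean_err[1] > mean_err[2]

    def test_invalid_state_rejected(self):
        gt = _identity_gt()
        conf = simulate_confounds(40, 2.0, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_scan(gt, conf, "open", "site_A")


@pytest.fixture(scope="module")
def small():
    params = {
        "site_A": synthetic.SiteParams(2.5, 40, 4),
        "site_B": synthetic.SiteParams(2.0, 60, 3, scale=1.2),
    }
    gt = make_ground_truth(6, 2, 0.3, seed=5, site_params=params)
    return gt, simulate_dataset(gt, seed=8, size="full")


class TestDataset:
    def test_scan_counts_follow_session_schedule(self, small):
        gt, ds = small
        mf = synthetic.manifest_frame(ds)
        assert (mf.site == "site_A").sum() == 2 * 4
        assert (mf.site == "site_B").sum() == 3 * 3
        assert mf.scan_id.is_unique

    def test_every_subject_has_both_states(self, small):
        _, ds = small
        mf = synthetic.manifest_frame(ds)
        per = mf.groupby("subject").state.agg(set)
        assert all(s == {"EO", "EC"} for s in per)

    def test_dataset_bit_reproducible(self, small):
        gt, ds = small
        again = simulate_dataset(gt, seed=8, size="full")
        np.testing.assert_array_equal(ds[0][0].timeseries,
                                      again[0][0].timeseries)
        np.testing.assert_array_equal(ds[-1][0].timeseries,
                                      again[-1][0].timeseries)

    def test_desk_manifest_matches_design_manifest(self):
        gt = make_ground_truth(6, 2, 0.3, seed=5)
        designed = synthetic.design_manifest(gt, size="desk")
        assert (designed.site == "site_A").sum() == 40
        assert (designed.site == "site_B").sum() == 36


def test_states_separate_in_pooled_edge_space(study, covs_s3):
    """EO and EC scans are farther apart than same-state scans on average."""
    from fcbench import classify, experiments
    mf = classify.select_classification_scans(study.manifest)
    X = experiments.edge_table(covs_s3, mf.scan_id, "pearson")
    is_eo = (mf.state == "EO").to_numpy()
    from scipy.spatial.distance import cdist, pdist
    between = cdist(X[is_eo], X[~is_eo]).mean()
    within = np.concatenate([pdist(X[is_eo]), pdist(X[~is_eo])]).mean()
    assert between > within


class TestLabelVolume:
    def test_label_histogram_covers_background_and_parcels(self):
        labels, _ = simulate_label_volume((4, 4, 4), 2, seed=0)
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_deterministic_under_seed(self):
        a = simulate_label_volume((5, 5, 5), 3, seed=4)
        b = simulate_label_volume((5, 5, 5), 3, seed=4)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_too_many_parcels_rejected(self):
        with pytest.raises(ValueError):
            simulate_label_volume((2, 2, 2), 9, seed=0)
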