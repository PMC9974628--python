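import numpy as np
import pytest
from scipy import stats

from caepdetect.detectors import (
    CovarianceModel,
    RankDeficiencyError,
    detect_f,
    f_inference,
    hotelling_t2,
    qmod,
    qmod_statistic,
    t2_diag,
    t2_diag_statistic,
    t2_freq_statistic,
    t2_time_statistic,
    t2_toep_statistic,
    t2_toeplitz,
    toeplitz_cov,
)
from caepdetect.features import PolarFeatures
from caepdetect.signal_model import ContinuousRecording, EpochEnsemble
from caepdetect.simulate import SimulationConfig, simulate_ensemble

FS = 500.0


def _brute_force_t2(v, mu=None):
    """Independent oracle: explicit covariance sum then quadratic form."""
    n, p = v.shape
    xbar = v.mean(axis=0)
    d = xbar - (np.zeros(p) if mu is None else mu)
    s = np.zeros((p, p))
    for row in v:
        s += np.outer(row - xbar, row - xbar)
    s /= n - 1
    return float(n * d @ np.linalg.inv(s) @ d)


class TestHotellingT2:
    def test_univariate_equals_squared_t(self):
        values = np.array([[1.0], [2.0], [3.0]])
        assert hotelling_t2(values) == pytest.approx(12.0)  # N xbar^2 / s^2
        t, _ = stats.ttest_1samp(values[:, 0], 0.0)
        assert hotelling_t2(values) == pytest.approx(t**2)

    def test_univariate_equals_squared_t_random(self, rng):
        for _ in range(10):
            x = rng.standard_normal((rng.integers(5, 40), 1)) + rng.normal()
            t, _ = stats.ttest_1samp(x[:, 0], 0.0)
            assert hotelling_t2(x) == pytest.approx(t**2, rel=1e-10)

    def test_zero_when_mean_equals_mu(self, rng):
        v = rng.standard_normal((10, 3))
        assert hotelling_t2(v, mu=v.mean(axis=0)) == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_oracle(self, rng):
        v = rng.standard_normal((10, 3)) * 5 + 1
        assert hotelling_t2(v) == pytest.approx(_brute_force_t2(v), rel=1e-10)

    def test_rank_deficiency_raises(self, rng):
        with pytest.raises(RankDeficiencyError):
            hotelling_t2(rng.standard_normal((5, 5)))


class TestFInference:
    def test_univariate_identity(self):
        inf = f_inference(12.0, n=3, p=1)
        assert inf.f_stat == pytest.approx(12.0)  # (N-p)/(p(N-1)) = 2/2
        assert (inf.v1, inf.v2) == (1, 2)

    def test_zero_statistic(self):
        inf = f_inference(0.0, n=20, p=14)
        assert inf.f_stat == 0.0
        assert inf.p_value == 1.0

    def test_requires_more_epochs_than_features(self):
        with pytest.raises(ValueError):
            f_inference(5.0, n=14, p=14)

    def test_null_pvalues_uniform_for_iid_gaussian(self, rng):
        # 5000 iid-feature null simulations: rejection at alpha=0.01 must sit
        # inside the exact binomial 99% interval
        n, p, sims, alpha = 40, 14, 5000, 0.01
        rejections = 0
        for _ in range(sims):
            t2 = hotelling_t2(rng.standard_normal((n, p)))
            if f_inference(t2, n, p).p_value <= alpha:
                rejections += 1
        lo = stats.binom.ppf(0.005, sims, alpha) / sims
        hi = stats.binom.ppf(0.995, sims, alpha) / sims
        assert lo <= rejections / sims <= hi


class TestToeplitzCovariance:
    def test_structure_is_symmetric_toeplitz(self, white_recording):
        cov = toeplitz_cov(white_recording, 50.0, 14)
        s = cov.matrix
        assert np.allclose(s, s.T)
        for lag in range(14):
            diag = np.diagonal(s, offset=lag)
            assert np.allclose(diag, cov.gamma[lag])

    def test_white_noise_gives_near_diagonal(self, rng):
        rec = ContinuousRecording(rng.standard_normal(500000), FS)
        cov = toeplitz_cov(rec, 50.0, 8)
        assert cov.gamma[0] == pytest.approx(1.0 / 25.0, rel=0.05)  # var of 25-sample means
        assert np.all(np.abs(cov.gamma[1:]) < 0.1 * cov.gamma[0])

    def test_ar1_interval_means_match_closed_form(self, rng):
        # upsample an AR(1) series so the interval means are exactly AR(1)
        phi, m = 0.8, 40000
        y = np.empty(m)
        y[0] = rng.standard_normal() / np.sqrt(1 - phi**2)
        e = rng.standard_normal(m)
        for i in range(1, m):
            y[i] = phi * y[i - 1] + e[i]
        samples = np.repeat(y, 25)
        cov = toeplitz_cov(samples, 50.0, 5, fs=FS)
        ratio = cov.gamma / cov.gamma[0]
        assert np.allclose(ratio, phi ** np.arange(5), atol=0.04)

    def test_too_short_recording_raises(self, rng):
        with pytest.raises(ValueError):
            toeplitz_cov(rng.standard_normal(200), 50.0, 14, fs=FS)


class TestT2Toeplitz:
    def test_zero_difference(self, white_recording):
        cov = toeplitz_cov(white_recording, 50.0, 4)
        xbar = np.array([1.0, 2.0, 3.0, 4.0])
        assert t2_toeplitz(xbar, cov, mu=xbar) == pytest.approx(0.0, abs=1e-18)

    def test_identity_covariance_reduces_to_squared_norm(self):
        cov = CovarianceModel(kind="toeplitz", matrix=np.eye(2), gamma=np.array([1.0, 0.0]))
        assert t2_toeplitz(np.array([3.0, 4.0]), cov) == pytest.approx(25.0)

    def test_scale_invariance(self, white_recording):
        ens_data = white_recording.samples[:7000].reshape(20, 350)
        ens = EpochEnsemble(ens_data, FS)
        base = t2_toep_statistic(ens, white_recording)
        scaled = t2_toep_statistic(
            EpochEnsemble(ens_data * -3.7, FS),
            ContinuousRecording(white_recording.samples * -3.7, FS),
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_sample_covariance_substitution_matches_hotelling(self, rng):
        # same quadratic form code path: with S_sample plugged in, the
        # statistic must equal Hotelling's T2 / N
        v = rng.standard_normal((30, 5))
        s = np.cov(v, rowvar=False, ddof=1)
        cov = CovarianceModel(kind="toeplitz", matrix=s, gamma=np.array([s[0, 0]]))
        assert t2_toeplitz(v.mean(axis=0), cov) == pytest.approx(
            hotelling_t2(v) / 30.0, rel=1e-9
        )


class TestT2Diag:
    def test_zero_mean(self):
        assert t2_diag(np.zeros(4), np.ones(4)) == 0.0

    def test_unit_case(self):
        assert t2_diag(np.ones(4), np.ones(4)) == pytest.approx(4.0)

    def test_weighted_case(self):
        stat = t2_diag(
            np.array([2.0, 0.0, 2.0, 0.0]),
            np.ones(4),
            weights=np.array([1.0, 1.0, 0.5, 0.5]),
        )
        assert stat == pytest.approx(5.0)  # 4 + 1

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            t2_diag(np.ones(2), np.array([1.0, 0.0]))

    def test_scale_invariance_of_pipeline(self, small_ensemble):
        base = t2_diag_statistic(small_ensemble)
        scaled = t2_diag_statistic(EpochEnsemble(small_ensemble.data * 0.01, FS))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestQMod:
    def test_single_epoch_single_band_value_mode(self):
        pol = PolarFeatures(np.array([[2.0]]), np.array([[1.234]]))
        assert qmod(pol, "V4") == pytest.approx(4.0)  # r^2 (cos^2 + sin^2)

    def test_two_epoch_rank_phase_value_amplitude(self):
        # phases rank to angles pi and 2 pi; amplitudes 1, 2
        pol = PolarFeatures(np.array([[1.0], [2.0]]), np.array([[-1.0], [1.0]]))
        assert qmod(pol, "V1") == pytest.approx(1.0)

    def test_zero_amplitudes(self):
        # value-amplitude variants vanish; rank-amplitude variants assign
        # tied ranks (N W + 1)/2 to every zero, so they do not
        pol = PolarFeatures(np.zeros((3, 2)), np.ones((3, 2)))
        for variant in ("V1", "V4"):
            assert qmod(pol, variant) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            qmod(PolarFeatures(np.ones((2, 2)), np.ones((2, 2))), "V5")

    def test_rank_modes_scale_invariant_value_modes_quadratic(self, small_ensemble):
        c = 2.5
        scaled = EpochEnsemble(small_ensemble.data * c, FS)
        # V2 (both ranks) exactly invariant; V3 invariant (phases unchanged,
        # amplitude ranks unchanged); V4 scales as c^2
        for variant in ("V2", "V3"):
            assert qmod_statistic(scaled, variant=variant) == pytest.approx(
                qmod_statistic(small_ensemble, variant=variant), rel=1e-9
            )
        assert qmod_statistic(scaled, variant="V4") == pytest.approx(
            c**2 * qmod_statistic(small_ensemble, variant="V4"), rel=1e-9
        )


class TestDetectorPipelines:
    def test_t2_family_scale_invariance(self, simulated_h0):
        rec, ens = simulated_h0
        c = -4.2
        ens_c = EpochEnsemble(ens.data * c, FS)
        rec_c = ContinuousRecording(rec.samples * c, FS, rec.onsets)
        assert t2_time_statistic(ens_c) == pytest.approx(t2_time_statistic(ens), rel=1e-8)
        assert t2_freq_statistic(ens_c) == pytest.approx(t2_freq_statistic(ens), rel=1e-8)
        assert t2_toep_statistic(ens_c, rec_c) == pytest.approx(
            t2_toep_statistic(ens, rec), rel=1e-8
        )
        assert t2_diag_statistic(ens_c) == pytest.approx(t2_diag_statistic(ens), rel=1e-8)

    def test_detect_f_reports_dof_and_decision(self, simulated_h0):
        _, ens = simulated_h0
        res = detect_f(ens, method="t2_time", alpha=0.01)
        assert res.dof == (14, 6)
        assert res.detected == (res.p_value <= 0.01)
        res_f = detect_f(ens, method="t2_freq")
        assert res_f.dof == (12, 8)

    def test_statistics_nonnegative(self, rng):
        for _ in range(5):
            cfg = SimulationConfig(n_epochs=20, snr_db=-10)
            rec, ens = simulate_ensemble(cfg, rng)
            assert t2_time_statistic(ens) >= 0
            assert t2_freq_statistic(ens) >= 0
            assert t2_toep_statistic(ens, rec) >= 0
            assert t2_diag_statistic(ens) >= 0
            assert qmod_statistic(ens) >= 0
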