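import numpy as np
import pytest

from epiopt.exceptions import EmptyROIError
from epiopt.snr_engine import (EPITimeSeries, KSpaceSeries, fft2c, ifft2c,
                               noise_ratio, pseudo_replica_snr,
                               reconstruct_rss, summarize_snr, temporal_snr)


def uniform_kspace(value=100.0, shape=(16, 16, 1), psi=None):
    img = np.full(shape, float(value), dtype=complex)
    ksp = fft2c(img[None], axes=(1, 2))
    if psi is None:
        psi = np.array([[50.0 + 0j]])  # complex noise variance 50
    return KSpaceSeries(ksp, psi)


class TestPseudoReplicaSNR:
    def test_uniform_closed_form(self):
        """Single coil, |S|=100, complex noise var 50 -> SNR 100/5 = 20."""
        snr = pseudo_replica_snr(uniform_kspace(), n_replicas=128, seed=1)
        tol = 2 * 20 / np.sqrt(2 * 127)  # 2 SE of the SD estimate
        assert np.mean(snr) == pytest.approx(20.0, abs=tol)

    def test_zero_signal(self):
        snr = pseudo_replica_snr(uniform_kspace(value=0.0), n_replicas=64,
                                 seed=2)
        # Rayleigh magnitude floor: mean/SD = sqrt(pi/2)/sqrt(2-pi/2) ~ 1.9
        assert np.mean(snr) < 3.0

    def test_noise_scaling_law(self):
        """Scaling the noise covariance by 4 halves the SNR map."""
        a = pseudo_replica_snr(uniform_kspace(), n_replicas=64, seed=3)
        b = pseudo_replica_snr(
            uniform_kspace(psi=np.array([[200.0 + 0j]])), n_replicas=64,
            seed=3)
        assert np.median(a / b) == pytest.approx(2.0, rel=0.05)

    def test_kspace_scale_invariance(self):
        """Scaling k-space and noise SD together leaves SNR unchanged."""
        base = uniform_kspace()
        scaled = KSpaceSeries(base.data * 3.0,
                              base.noise_cov * 9.0)
        a = pseudo_replica_snr(base, n_replicas=64, seed=4)
        b = pseudo_replica_snr(scaled, n_replicas=64, seed=4)
        assert np.allclose(a, b, rtol=1e-10)

    def test_non_positive_definite_psi(self):
        bad = uniform_kspace(shape=(8, 8, 1))
        ks = KSpaceSeries(np.repeat(bad.data, 2, axis=0),
                          np.array([[1.0, 1.0], [1.0, 1.0]], dtype=complex))
        with pytest.raises(ValueError, match="positive-definite"):
            pseudo_replica_snr(ks, n_replicas=16, seed=5)

    def test_few_replicas_warns(self):
        with pytest.warns(UserWarning, match="replicas"):
            pseudo_replica_snr(uniform_kspace(shape=(8, 8, 1)), n_replicas=4,
                               seed=6)

    @pytest.mark.parametrize("n_replicas", [32, 128])
    def test_estimator_precision_scales_with_replicas(self, n_replicas):
        """Across seeds, rel. SD of the SNR estimate ~ 1/sqrt(2(n-1))."""
        ks = uniform_kspace(shape=(12, 12, 1))
        maps = np.stack([
            pseudo_replica_snr(ks, n_replicas=n_replicas, seed=s)
            for s in range(16)])
        rel_sd = np.mean(np.std(maps, axis=0, ddof=1) / np.mean(maps, axis=0))
        assert rel_sd == pytest.approx(1 / np.sqrt(2 * (n_replicas - 1)),
                                       rel=0.35)


class TestReconstruction:
    def test_parseval(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((2, 16, 16, 3)) + \
            1j * rng.standard_normal((2, 16, 16, 3))
        ksp = fft2c(img, axes=(1, 2))
        assert np.sum(np.abs(ksp) ** 2) == pytest.approx(
            np.sum(np.abs(img) ** 2), rel=1e-12)
        assert np.allclose(ifft2c(ksp, axes=(1, 2)), img)

    def test_rss_round_trip(self):
        img = np.zeros((8, 8, 2))
        img[3, 4, 0] = 7.0
        ksp = fft2c(img[None].astype(complex), axes=(1, 2))
        assert np.allclose(reconstruct_rss(ksp), np.abs(img), atol=1e-12)


class TestTemporalSNR:
    def test_closed_form(self):
        rng = np.random.default_rng(10)
        data = 100.0 + rng.normal(0, 5.0, size=(12, 12, 2, 64))
        tsnr = temporal_snr(data)
        assert np.mean(tsnr) == pytest.approx(20.0, rel=0.05)

    def test_constant_series_flagged_infinite(self):
        tsnr = temporal_snr(np.full((4, 4, 1, 16), 50.0))
        assert np.isinf(tsnr).all()

    def test_physiological_noise_lowers_tsnr(self):
        """1% signal fluctuation: tSNR drops to ~100/sqrt(26) < pSNR."""
        rng = np.random.default_rng(11)
        phys = 1.0 * rng.standard_normal((12, 12, 2, 256))
        data = 100.0 + phys + rng.normal(0, 5.0, size=phys.shape)
        tsnr = temporal_snr(data)
        assert np.mean(tsnr) == pytest.approx(100 / np.sqrt(26), rel=0.05)
        assert np.mean(tsnr) < 20.0

    def test_detrend_removes_drift(self):
        rng = np.random.default_rng(12)
        t = np.arange(64)
        drift = 0.5 * (t - t.mean())
        data = 100.0 + drift + rng.normal(0, 5.0, size=(8, 8, 1, 64))
        raw = temporal_snr(data)
        det = temporal_snr(data, detrend=True)
        assert np.mean(det) > 2 * np.mean(raw)
        assert np.mean(det) == pytest.approx(20.0, rel=0.1)

    def test_too_few_repetitions(self):
        with pytest.raises(ValueError):
            temporal_snr(np.ones((4, 4, 1, 4)))

    def test_accepts_series_object(self):
        rng = np.random.default_rng(13)
        series = EPITimeSeries(100 + rng.normal(0, 5, (6, 6, 1, 32)), tr=2000)
        assert np.mean(temporal_snr(series)) == pytest.approx(20.0, rel=0.1)


class TestNoiseRatio:
    def test_equal_snr_is_zero(self):
        assert noise_ratio(42.0, 42.0) == 0.0

    def test_dominance_threshold(self):
        """pSNR = sqrt(2) tSNR marks sigma_P = sigma_T."""
        assert noise_ratio(np.sqrt(2.0) * 30.0, 30.0) == pytest.approx(1.0)

    def test_exact_algebra(self):
        assert noise_ratio(100.0, 60.0) == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_undefined_flagged_nan(self):
        assert np.isnan(noise_ratio(10.0, 12.0))
        out = noise_ratio(np.array([10.0, 20.0]), np.array([12.0, 10.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(np.sqrt(3.0))

    def test_zero_tsnr_raises(self):
        with pytest.raises(ZeroDivisionError):
            noise_ratio(10.0, 0.0)


class TestSummarizeSNR:
    def _rois(self, shape):
        a = np.zeros(shape, dtype=bool)
        b = np.zeros(shape, dtype=bool)
        a[: shape[0] // 2] = True
        b[shape[0] // 2:] = True
        return {"front": a, "back": b}

    def test_identical_maps_zero_ratio(self):
        m = np.full((6, 6, 2), 30.0)
        summ = summarize_snr(m, m, self._rois(m.shape))
        assert (summ.table["ratio_of_means"] == 0.0).all()

    def test_roi_counts_partition(self):
        m = np.full((6, 6, 2), 30.0)
        summ = summarize_snr(m, m, self._rois(m.shape))
        assert summ.table["n_voxels"].sum() == m.size

    def test_both_ratio_variants_reported(self):
        rng = np.random.default_rng(14)
        p = 50.0 + rng.normal(0, 1, (6, 6, 2))
        t = 40.0 + rng.normal(0, 1, (6, 6, 2))
        summ = summarize_snr(p, t, self._rois(p.shape))
        for col in ("ratio_of_means", "voxel_ratio_mean",
                    "ratio_defined_frac"):
            assert col in summ.table.columns
        assert (summ.table["ratio_defined_frac"] == 1.0).all()

    def test_empty_roi_raises(self):
        m = np.full((4, 4, 1), 30.0)
        with pytest.raises(EmptyROIError):
            summarize_snr(m, m, {"empty": np.zeros_like(m, dtype=bool)})


class TestKSpaceIO:
    def test_hdf5_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        data = (rng.standard_normal((2, 8, 8, 1, 3))
                + 1j * rng.standard_normal((2, 8, 8, 1, 3))).astype(
                    np.complex64)
        psi = np.array([[1.0, 0.1], [0.1, 1.0]], dtype=complex)
        ks = KSpaceSeries(data, psi, te=55.0, tr=1200.0,
                          voxel_dims=(4.0, 4.0, 4.0))
        path = tmp_path / "k.h5"
        ks.to_hdf5(path)
        back = KSpaceSeries.from_hdf5(path)
        assert np.allclose(back.data, data)
        assert np.allclose(back.noise_cov, psi)
        assert back.te == 55.0 and back.n_reps == 3
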