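import dataclasses

import numpy as np
import pytest

from conftest import with_lambda
from epiopt.exceptions import InvalidConfigError
from epiopt.phantom import (PhantomSpec, calibrate_lambda,
                            ground_truth_summary, make_tissue_phantom,
                            simulate_epi_timeseries, simulate_megre,
                            synthesize_coils)
from epiopt.protocols import MEGRE_ECHO_TIMES
from epiopt.relaxometry import fit_monoexp_voxel, map_t2star, roi_stats
from epiopt.snr_engine import (fft2c, pseudo_replica_snr, reconstruct_rss,
                               summarize_snr, temporal_snr)

TE = np.array(MEGRE_ECHO_TIMES)


class TestTissueGeometry:
    def test_compartments_disjoint_nonempty(self, small_phantom):
        masks = small_phantom.masks
        for m in masks.values():
            assert m.any()
        total = sum(m.astype(int) for m in masks.values())
        assert total.max() == 1  # pairwise disjoint

    def test_parameter_volumes_follow_masks(self, small_phantom):
        assert np.all(small_phantom.t2star_map[small_phantom.masks["gm"]]
                      == 86.3)
        assert np.all(small_phantom.t2star_map[small_phantom.masks["wm"]]
                      == 77.9)
        assert np.all(small_phantom.t2star_map[~small_phantom.brain_mask]
                      == 0.0)

    def test_deterministic_geometry(self, small_spec):
        a = make_tissue_phantom(small_spec)
        b = make_tissue_phantom(small_spec)
        assert np.array_equal(a.t2star_map, b.t2star_map)
        for k in a.masks:
            assert np.array_equal(a.masks[k], b.masks[k])

    def test_zero_thickness_shell_rejected(self):
        with pytest.raises(InvalidConfigError, match="empty|grid"):
            make_tissue_phantom(PhantomSpec(shape=(16, 16, 6), wm_frac=1.0))

    def test_oversized_compartment_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_tissue_phantom(PhantomSpec(outer_frac=(1.2, 0.9, 0.8)))


class TestCoils:
    def test_single_coil_uniform(self):
        sens, psi = synthesize_coils(1, (12, 12, 2))
        assert np.allclose(sens, 1.0)
        assert np.allclose(psi, np.eye(1))

    def test_uncoupled_psi_diagonal(self):
        _, psi = synthesize_coils(4, (12, 12, 2), rho=0.0)
        assert np.allclose(psi, np.eye(4))

    def test_rss_positive_inside_object(self, small_phantom):
        sens, _ = synthesize_coils(8, small_phantom.spec.shape)
        rss = np.sqrt((np.abs(sens) ** 2).sum(axis=0))
        assert (rss[small_phantom.brain_mask] > 0).all()

    def test_coupling_bounds(self):
        with pytest.raises(InvalidConfigError):
            synthesize_coils(4, (8, 8, 1), rho=1.0)
        with pytest.raises(InvalidConfigError):
            synthesize_coils(4, (8, 8, 1), rho=-0.5)

    def test_psi_positive_definite(self):
        _, psi = synthesize_coils(16, (8, 8, 1), rho=0.1)
        np.linalg.cholesky(psi)  # raises if not PD


class TestSimulateMeGRE:
    def test_noiseless_voxel_is_monoexponential(self, small_phantom):
        series = simulate_megre(small_phantom, TE, snr=None)
        gm_vox = np.argwhere(small_phantom.masks["gm"])[0]
        sig = series.data[tuple(gm_vox)]
        fit = fit_monoexp_voxel(sig, TE)
        assert fit.valid
        assert fit.t2star == pytest.approx(86.3, rel=1e-9)

    def test_relaxometry_round_trip(self, small_phantom):
        """GM ROI mean within 1% of truth at echo SNR 100."""
        series = simulate_megre(small_phantom, TE, snr=100.0, seed=21)
        t2map = map_t2star(series, mask=small_phantom.brain_mask)
        st_ = roi_stats(t2map, small_phantom.masks["gm"])
        assert st_.mean == pytest.approx(86.3, rel=0.01)

    def test_two_echoes_rejected_downstream(self, small_phantom):
        series = simulate_megre(small_phantom, TE[:2], snr=None)
        vox = series.data[small_phantom.masks["gm"]][0]
        with pytest.raises(ValueError, match="3 echoes"):
            fit_monoexp_voxel(vox, TE[:2])

    def test_decreasing_echoes_rejected(self, small_phantom):
        with pytest.raises(InvalidConfigError):
            simulate_megre(small_phantom, [10.0, 5.0], snr=None)


class TestSimulateEPI:
    def test_deterministic_given_seed(self, small_phantom,
                                      epi_protocol_factory):
        prot = epi_protocol_factory(small_phantom.spec, 55.0)
        a, _ = simulate_epi_timeseries(small_phantom, prot, n_repeats=2,
                                       seed=9)
        b, _ = simulate_epi_timeseries(small_phantom, prot, n_repeats=2,
                                       seed=9)
        assert np.array_equal(a.data, b.data)

    def test_grid_mismatch_rejected(self, small_phantom):
        other = PhantomSpec(shape=(16, 16, 4))
        prot = None
        from epiopt.report import _epi_protocol_for_phantom
        prot = _epi_protocol_for_phantom(other, 55.0, 18.3, 717.2)
        with pytest.raises(InvalidConfigError, match="match"):
            simulate_epi_timeseries(small_phantom, prot, n_repeats=1)

    def test_thermal_only_psnr_matches_tsnr(self, small_phantom,
                                            epi_protocol_factory):
        """Without physiological noise the two SNR estimates agree."""
        prot = epi_protocol_factory(small_phantom.spec, 55.0)
        ks, gt = simulate_epi_timeseries(small_phantom, prot, n_repeats=64,
                                         seed=30)
        frames = np.stack([reconstruct_rss(ks.data[..., t])
                           for t in range(64)], axis=-1)
        summ = summarize_snr(pseudo_replica_snr(ks, 128, seed=31),
                             temporal_snr(frames), small_phantom.masks)
        for roi in summ.table.index:
            p = summ.table.loc[roi, "psnr_mean"]
            t = summ.table.loc[roi, "tsnr_mean"]
            assert p == pytest.approx(t, rel=0.05)

    def test_target_psnr_calibration(self, small_phantom,
                                     epi_protocol_factory):
        """Measured GM pSNR lands on the requested thermal SNR target."""
        prot = epi_protocol_factory(small_phantom.spec, 55.0)
        ks, _ = simulate_epi_timeseries(small_phantom, prot, n_repeats=1,
                                        seed=32)
        psnr = pseudo_replica_snr(ks, 128, seed=33)
        gm_mean = psnr[small_phantom.masks["gm"]].mean()
        assert gm_mean == pytest.approx(small_phantom.spec.target_psnr,
                                        rel=0.05)

    def test_ground_truth_ratio_matches_injection(self, small_phantom,
                                                  epi_protocol_factory):
        prot = epi_protocol_factory(small_phantom.spec, 55.0)
        lam = calibrate_lambda(small_phantom, prot, 0.5, mode="const")
        ph = with_lambda(small_phantom, lambda_const=lam)
        _, gt = simulate_epi_timeseries(ph, prot, n_repeats=1, seed=34)
        assert ground_truth_summary(gt, ph.masks)["gm"] == pytest.approx(
            0.5, rel=1e-6)

    def test_bold_term_ground_truth_monotone_in_te(self, small_phantom,
                                                   epi_protocol_factory):
        """Analytic sigma_P/sigma_T grows with TE under the BOLD-like term."""
        ph = with_lambda(small_phantom, lambda_bold=3e-4)
        ratios = []
        for te in (25.0, 55.0, 85.0):
            prot = epi_protocol_factory(ph.spec, te)
            _, gt = simulate_epi_timeseries(ph, prot, n_repeats=1, seed=35)
            ratios.append(ground_truth_summary(gt, ph.masks)["gm"])
        assert ratios[0] < ratios[1] < ratios[2]

    def test_larger_voxels_raise_noise_ratio(self, epi_protocol_factory):
        """At fixed k-space noise, bigger voxels -> higher SNR -> higher
        physiological-to-thermal ratio (estimated and analytic)."""
        est, true = {}, {}
        for vs in (3.4, 4.0):
            spec = PhantomSpec(shape=(32, 32, 8), voxel_size=vs, seed=77,
                               thermal_sigma=0.58, lambda_const=0.012)
            ph = make_tissue_phantom(spec)
            prot = epi_protocol_factory(spec, 55.0)
            ks, gt = simulate_epi_timeseries(ph, prot, n_repeats=64, seed=36)
            frames = np.stack([reconstruct_rss(ks.data[..., t])
                               for t in range(64)], axis=-1)
            summ = summarize_snr(pseudo_replica_snr(ks, 128, seed=37),
                                 temporal_snr(frames), ph.masks)
            est[vs] = summ.table.loc["gm", "ratio_of_means"]
            true[vs] = ground_truth_summary(gt, ph.masks)["gm"]
        assert true[4.0] > true[3.4]
        assert est[4.0] > est[3.4]

    def test_parseval_forward_model(self, small_phantom,
                                    epi_protocol_factory):
        """Energy conservation between image and k-space domains."""
        prot = epi_protocol_factory(small_phantom.spec, 55.0)
        from epiopt.phantom import steady_state_image, synthesize_coils
        s0 = steady_state_image(small_phantom, prot.te, prot.tr,
                                prot.flip_angle)
        sens, _ = synthesize_coils(small_phantom.spec.n_coils,
                                   small_phantom.spec.shape)
        coil_imgs = sens * s0[None]
        ksp = fft2c(coil_imgs, axes=(1, 2))
        assert np.sum(np.abs(ksp) ** 2) == pytest.approx(
            np.sum(np.abs(coil_imgs) ** 2), rel=1e-10)


class TestLambdaCalibration:
    def test_zero_target(self, small_phantom, epi_protocol_factory):
        prot = epi_protocol_factory(small_phantom.spec, 55.0)
        assert calibrate_lambda(small_phantom, prot, 0.0) == 0.0

    def test_negative_target_rejected(self, small_phantom,
                                      epi_protocol_factory):
        prot = epi_protocol_factory(small_phantom.spec, 55.0)
        with pytest.raises(InvalidConfigError):
            calibrate_lambda(small_phantom, prot, -0.1)

    def test_bold_mode_hits_target_at_reference_te(self, small_phantom,
                                                   epi_protocol_factory):
        prot = epi_protocol_factory(small_phantom.spec, 55.0)
        lam = calibrate_lambda(small_phantom, prot, 0.4, mode="bold")
        ph = with_lambda(small_phantom, lambda_bold=lam)
        _, gt = simulate_epi_timeseries(ph, prot, n_repeats=1, seed=38)
        assert ground_truth_summary(gt, ph.masks)["gm"] == pytest.approx(
            0.4, rel=1e-6)
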