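import numpy as np
import pytest

import stafkit as sk
from stafkit.estimation import estimate_stafs_from_runs, _simulate_runs


@pytest.fixture(scope="module")
def cfg():
    return sk.EstimationConfig()


class TestEmKernel:
    def test_identical_traces_give_zero_kernel(self, m7_pair, cfg):
        y = np.random.default_rng(0).normal(size=127 * 2)
        k = sk.estimate_em_kernel(y, y.copy(), m7_pair[1], cfg)
        assert np.allclose(k.values, 0.0)

    def test_fm_only_plant_leaves_no_em_kernel(self, geometry, m7_pair,
                                               uniform_plant, cfg):
        """With no EM stream in the plant, the paired EM estimate vanishes to
        float tolerance at every lag."""
        em_zero = uniform_plant.staf_em_true.scaled(0.0)
        plant = sk.PlantModel(staf_em_true=em_zero,
                              staf_fm_true=uniform_plant.staf_fm_true,
                              noise_sigma=0.0)
        m_fm, m_em = m7_pair
        rp = sk.build_compound_protocol(m_fm, m_em, 1, 45.0, geometry, 4)
        rm = sk.build_compound_protocol(m_fm, m_em, -1, 45.0, geometry, 4)
        y1 = sk.simulate_response(plant, rp, geometry, noiseless=True)
        y2 = sk.simulate_response(plant, rm, geometry, noiseless=True)
        k = sk.estimate_em_kernel(y1, y2, m_em, cfg, geometry.frame_rate)
        scale = np.abs(plant.staf_fm_true.grid).max()
        assert np.max(np.abs(k.values)) < 1e-10 * scale

    def test_noiseless_recovery_of_known_kernel(self, geometry, m7_pair,
                                                uniform_plant,
                                                paired_uniform_run, cfg):
        """Paired noiseless estimation returns the ground-truth EM kernel at
        every lag, up to the uniform m-sequence dc offset sum(g)/(p+1)."""
        run = paired_uniform_run
        m_em = m7_pair[1]
        k = sk.estimate_em_kernel(run["y1"], run["y2"], m_em, cfg,
                                  geometry.frame_rate,
                                  gamma=run["real_p"].gamma)
        g_true = uniform_plant.staf_em_true.grid[:, 0]
        dc = g_true.sum() / (m_em.p + 1)
        assert np.max(np.abs(k.values + dc - g_true)) < 1e-12
        assert abs(k.centroid_azimuth) < 2 * geometry.pixel_pitch

    def test_length_mismatch_rejected(self, m7_pair, cfg):
        with pytest.raises(ValueError, match="equal length"):
            sk.estimate_em_kernel(np.zeros(127), np.zeros(254), m7_pair[1],
                                  cfg)


class TestFmKernel:
    def test_zero_traces_give_zero_kernel(self, m7_pair, cfg):
        k = sk.estimate_fm_kernel(np.zeros(127 * 2), np.zeros(127 * 2),
                                  m7_pair[0], cfg)
        assert np.allclose(k.values, 0.0)

    def test_uncorrected_cumsum_cancels_the_step(self, geometry, m7_pair,
                                                 paired_uniform_run,
                                                 uniform_plant):
        """Integrating the derivative estimate without dc correction nearly
        cancels the step response by lag p-1 even though the true asymptote
        is 1: the hallmark of the accumulating m-sequence dc error."""
        no_corr = sk.EstimationConfig(dc_correction="none")
        run = paired_uniform_run
        k = sk.estimate_fm_kernel(run["y1"], run["y2"], m7_pair[0], no_corr,
                                  geometry.frame_rate)
        asym_true = uniform_plant.staf_fm_true.grid[-1, 0]
        assert asym_true == pytest.approx(1.0, abs=1e-4)
        assert abs(k.values[-1]) < 0.02 * asym_true

    def test_corrected_kernel_recovers_step_asymptote(self, geometry,
                                                      m7_pair,
                                                      paired_uniform_run,
                                                      uniform_plant):
        """Closed-form dc correction recovers the known asymptote within 5%
        (in fact much closer) from noiseless traces."""
        run = paired_uniform_run
        k = sk.estimate_fm_kernel(run["y1"], run["y2"], m7_pair[0],
                                  sk.EstimationConfig(),
                                  geometry.frame_rate)
        g_true = uniform_plant.staf_fm_true.grid[:, 0]
        late = slice(50, 127)  # 2-5 s at 25 Hz
        est_asym = float(np.mean(k.values[late]))
        assert est_asym == pytest.approx(float(np.mean(g_true[late])),
                                         rel=0.05)
        assert np.max(np.abs(k.values - g_true)) < 0.01

    def test_literal_variant_corrects_partially(self, geometry, m7_pair,
                                                paired_uniform_run,
                                                uniform_plant):
        """The literal window-mean reading under-corrects (its asymptote
        estimate is itself shrunken by the accumulating error) but still
        lands strictly between the uncorrected estimate and the truth."""
        run = paired_uniform_run
        args = (run["y1"], run["y2"], m7_pair[0])
        k_none = sk.estimate_fm_kernel(
            *args, sk.EstimationConfig(dc_correction="none"),
            geometry.frame_rate)
        k_lit = sk.estimate_fm_kernel(
            *args, sk.EstimationConfig(dc_correction="literal"),
            geometry.frame_rate)
        truth = uniform_plant.staf_fm_true.grid[-1, 0]
        assert k_none.values[-1] < k_lit.values[-1] < truth

    def test_dc_window_beyond_period_rejected(self, m7_pair):
        config = sk.EstimationConfig(dc_window=(6.0, 7.0))
        with pytest.raises(ValueError, match="period"):
            sk.estimate_fm_kernel(np.zeros(127), np.zeros(127), m7_pair[0],
                                  config, frame_rate=25.0)


class TestDecontamination:
    def test_sign_flip_removes_cross_talk(self, geometry, m7_pair,
                                          uniform_plant,
                                          paired_uniform_run, cfg):
        """Paired estimation removes m_FM/m_EM cross-talk and dc position
        contamination to float tolerance; unpaired single-trace estimation
        on the same noiseless data leaves residuals at least 10x larger."""
        run = paired_uniform_run
        m_fm, m_em = m7_pair
        g_em = uniform_plant.staf_em_true.grid[:, 0]
        g_fm = uniform_plant.staf_fm_true.grid[:, 0]
        dc_em = g_em.sum() / (m_em.p + 1)

        k_pair = sk.estimate_em_kernel(run["y1"], run["y2"], m_em, cfg,
                                       geometry.frame_rate)
        k_single = sk.estimate_kernel_unpaired(run["y1"], m_em, "EM", cfg,
                                               geometry.frame_rate)
        res_pair = np.max(np.abs(k_pair.values + dc_em - g_em))
        res_single = np.max(np.abs(k_single.values + dc_em - g_em))
        assert res_single > 10 * res_pair

        kf_pair = sk.estimate_fm_kernel(run["y1"], run["y2"], m_fm, cfg,
                                        geometry.frame_rate)
        kf_single = sk.estimate_kernel_unpaired(run["y1"], m_fm, "FM", cfg,
                                                geometry.frame_rate)
        resf_pair = np.max(np.abs(kf_pair.values - g_fm))
        resf_single = np.max(np.abs(kf_single.values - g_fm))
        assert resf_single > 10 * resf_pair


class TestPipelineContracts:
    def test_estimation_homogeneity(self, geometry, m7_pair, uniform_plant,
                                    paired_uniform_run, cfg):
        """Doubling the plant's ground-truth amplitudes doubles every
        estimated kernel value."""
        run = paired_uniform_run
        doubled = sk.PlantModel(
            staf_em_true=uniform_plant.staf_em_true.scaled(2.0),
            staf_fm_true=uniform_plant.staf_fm_true.scaled(2.0),
            noise_sigma=0.0)
        y1 = sk.simulate_response(doubled, run["real_p"], geometry,
                                  noiseless=True)
        y2 = sk.simulate_response(doubled, run["real_m"], geometry,
                                  noiseless=True)
        for kind, m in (("EM", m7_pair[1]), ("FM", m7_pair[0])):
            est = (sk.estimate_em_kernel if kind == "EM"
                   else sk.estimate_fm_kernel)
            k1 = est(run["y1"], run["y2"], m, cfg, geometry.frame_rate)
            k2 = est(y1, y2, m, cfg, geometry.frame_rate)
            assert np.allclose(k2.values, 2.0 * k1.values, atol=1e-10)


class TestAssembly:
    def _kernel(self, values, az, kind="EM"):
        return sk.Kernel(values=values, raw_crosscorr=values,
                         centroid_azimuth=az, kind=kind, frame_rate=25.0)

    def test_identical_kernels_make_constant_staf(self, geometry, cfg):
        vals = np.sin(np.linspace(0, 3, 127))
        ks = [self._kernel(vals, az)
              for az in np.arange(-180 + 3.75, 180.1, 3.75)]
        staf = sk.assemble_staf(ks, geometry, cfg)
        assert np.allclose(staf.grid, staf.grid[:, :1])

    def test_boxcar_preserves_azimuthal_mean(self, geometry, cfg):
        rng = np.random.default_rng(4)
        ks = [self._kernel(rng.normal(size=127), az)
              for az in np.arange(-180 + 3.75, 180.1, 3.75)]
        staf = sk.assemble_staf(ks, geometry, cfg)
        assert staf.smoothing["boxcar_samples"] == 4
        raw = np.stack([k.values for k in ks], axis=1)
        assert np.allclose(staf.grid.mean(axis=1), raw.mean(axis=1))
        assert not np.allclose(staf.grid, raw)

    def test_repeats_are_averaged_per_position(self, geometry, cfg):
        ks = [self._kernel(np.full(127, v), az)
              for az in (0.0, 30.0) for v in (1.0, 3.0)]
        staf = sk.assemble_staf(ks, geometry, cfg)
        assert np.allclose(staf.grid, 2.0)

    def test_mixed_kinds_rejected(self, geometry, cfg):
        ks = [self._kernel(np.zeros(127), 0.0, "EM"),
              self._kernel(np.zeros(127), 30.0, "FM")]
        with pytest.raises(ValueError, match="mixed kinds"):
            sk.assemble_staf(ks, geometry, cfg)

    def test_single_position_rejected(self, geometry, cfg):
        with pytest.raises(ValueError, match="distinct centroid"):
            sk.assemble_staf([self._kernel(np.zeros(127), 0.0)], geometry,
                             cfg)


class TestFullProtocol:
    def test_noiseless_recovery_matches_ground_truth(self, geometry,
                                                     shaped_plant):
        """End-to-end recovery: noiseless paired protocol across the azimuth
        grid reproduces both ground-truth STAFs at the sampled centroids.
        The kernel at each position is an average over the figure's ~12-deg
        excursion, so columns on steep spatial flanks may deviate by an
        amount set by the profile curvature; 12% of the global peak bounds
        that quasi-linear averaging error."""
        protocol = sk.ProtocolConfig(n_repeats=1)
        staf_em, staf_fm = sk.run_staf_protocol(
            shaped_plant, protocol, geometry, sk.EstimationConfig(), seed=0)
        scale_em = np.abs(shaped_plant.staf_em_true.grid).max()
        scale_fm = np.abs(shaped_plant.staf_fm_true.grid).max()
        for rec, true, scale in (
                (staf_em, shaped_plant.staf_em_true, scale_em),
                (staf_fm, shaped_plant.staf_fm_true, scale_fm)):
            for j, az in enumerate(rec.azimuth_axis):
                jt = np.argmin(np.abs(sk.wrap_azimuth(true.azimuth_axis
                                                      - az)))
                err = np.max(np.abs(rec.grid[:, j] - true.grid[:, jt]))
                assert err < 0.12 * scale

    def test_em_only_plant_gives_null_fm_staf(self, geometry,
                                              uniform_plant):
        plant = sk.PlantModel(
            staf_em_true=uniform_plant.staf_em_true,
            staf_fm_true=uniform_plant.staf_fm_true.scaled(0.0),
            noise_sigma=0.0)
        protocol = sk.ProtocolConfig(n_repeats=1,
                                     start_azimuths=(0.0, 90.0, 180.0))
        staf_em, staf_fm = sk.run_staf_protocol(
            plant, protocol, geometry, sk.EstimationConfig(), seed=0)
        assert np.max(np.abs(staf_fm.grid)) < 1e-9
        assert np.max(np.abs(staf_em.grid)) > 0.5

    def test_block_and_sliding_modes_agree(self, geometry, uniform_plant):
        """Per-period sliding-window kernels agree with the block (period-
        averaged) estimate on the same noiseless records."""
        protocol_b = sk.ProtocolConfig(n_repeats=1,
                                       start_azimuths=(0.0, 120.0, -120.0))
        m_fm, m_em = protocol_b.sequences()
        runs = _simulate_runs(uniform_plant, protocol_b, geometry, m_fm,
                              m_em, seed=0)
        config = sk.EstimationConfig()
        em_b, fm_b = estimate_stafs_from_runs(runs, m_fm, m_em, geometry,
                                              config, mode="block")
        em_s, fm_s = estimate_stafs_from_runs(runs, m_fm, m_em, geometry,
                                              config, mode="sliding")
        scale = np.abs(em_b.grid).max()
        for b, s in ((em_b, em_s), (fm_b, fm_s)):
            for j, az in enumerate(b.azimuth_axis):
                js = np.argmin(np.abs(sk.wrap_azimuth(s.azimuth_axis - az)))
                assert np.max(np.abs(b.grid[:, j] - s.grid[:, js])) \
                    < 0.05 * scale

    def test_unpaired_runs_rejected(self, geometry, m7_pair):
        m_fm, m_em = m7_pair
        runs = [{"start_azimuth": 0.0, "sign": 1, "repeat": 0,
                 "y": np.zeros(127 * 2), "gamma": np.zeros(127 * 2)}]
        with pytest.raises(ValueError, match="unpaired"):
            estimate_stafs_from_runs(runs, m_fm, m_em, geometry,
                                     sk.EstimationConfig())
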