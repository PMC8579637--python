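"""Inverse-problem behaviour: round trips, nesting, masks, file I/O."""

import numpy as np
import pytest

from qmripred.map_fitting import (
    REPORTING_SCALE,
    ParameterMap,
    SignalVolume,
    fit_adc,
    fit_dki,
    fit_ivim_joint,
    fit_ivim_segmented,
    fit_tofts,
)
from qmripred.signal_models import (
    DceAcquisition,
    ParkerAif,
    StepAif,
    TissueParams,
    add_noise,
    dki_signal,
    dwi_signal,
    ivim_signal,
    tofts_concentration,
)


def _volume(signals, acq):
    return SignalVolume(np.asarray(signals).reshape(1, 1, 1, -1), acq)


class TestAdcFit:
    def test_two_point_inversion(self, dwi_acq):
        """With two b-values the fit is the analytic log-ratio."""
        sig = dwi_signal(TissueParams(S0=100.0, ADC=1238.43e-6), dwi_acq.b_values)
        adc, s0 = fit_adc(_volume(sig, dwi_acq))
        assert adc.reported()[0, 0, 0] == pytest.approx(1238.43, abs=1e-6)
        assert s0.values[0, 0, 0] == pytest.approx(100.0)

    def test_constant_signal_gives_zero_adc(self, dwi_acq):
        adc, _ = fit_adc(_volume([80.0, 80.0], dwi_acq))
        assert adc.values[0, 0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_voxel_flagged_not_fatal(self, dwi_acq):
        data = np.ones((2, 1, 1, 2)) * 50.0
        data[1, 0, 0, 1] = 0.0
        adc, _ = fit_adc(SignalVolume(data, dwi_acq))
        assert adc.mask[0, 0, 0] and not adc.mask[1, 0, 0]
        assert np.isnan(adc.reported()[1, 0, 0])

    def test_masked_voxels_do_not_leak(self, dwi_acq):
        rng = np.random.default_rng(0)
        data = rng.uniform(10, 100, (3, 1, 1, 2))
        mask = np.array([True, False, True]).reshape(3, 1, 1)
        full = fit_adc(SignalVolume(data, dwi_acq))[0]
        sub = fit_adc(SignalVolume(data, dwi_acq), mask=mask)[0]
        np.testing.assert_array_equal(full.values[mask], sub.values[mask])
        assert not sub.mask[1, 0, 0]


class TestDkiFit:
    def test_recovers_typical_tumor_values(self, dki_acq):
        p = TissueParams(S0=500.0, D=1.0125e-3, K=1.02)
        md, mk, s0 = fit_dki(_volume(dki_signal(p, dki_acq.b_values), dki_acq))
        assert md.values[0, 0, 0] == pytest.approx(p.D, rel=1e-4)
        assert mk.values[0, 0, 0] == pytest.approx(p.K, rel=1e-4)
        assert md.reported()[0, 0, 0] == pytest.approx(1012.5, rel=1e-4)

    def test_k_zero_data_reduces_to_adc_fit(self, dki_acq):
        sig = dwi_signal(TissueParams(S0=90.0, ADC=1.2e-3), dki_acq.b_values)
        md, mk, _ = fit_dki(_volume(sig, dki_acq))
        adc, _ = fit_adc(_volume(sig, dki_acq))
        assert mk.values[0, 0, 0] < 1e-3
        assert md.values[0, 0, 0] == pytest.approx(adc.values[0, 0, 0], rel=1e-3)

    def test_rician_noise_median_bias_small(self, dki_acq):
        """At SNR 50 the median MD estimate is within 3% of truth."""
        p = TissueParams(S0=1000.0, D=1.0125e-3, K=1.02)
        clean = dki_signal(p, dki_acq.b_values)
        data = add_noise(np.tile(clean, (200, 1, 1, 1)), 1000.0 / 50.0,
                         "rician", seed=123)
        md, mk, _ = fit_dki(SignalVolume(data, dki_acq))
        assert abs(np.median(md.values[md.mask]) / p.D - 1.0) < 0.03

    def test_too_few_bvalues_rejected(self, dwi_acq):
        with pytest.raises(ValueError):
            fit_dki(_volume([10.0, 5.0], dwi_acq))


class TestIvimFit:
    def test_recovers_typical_tumor_values(self, ivim_acq):
        p = TissueParams(S0=400.0, f=0.0199, Dslow=0.778e-3, Dfast=410.59e-4)
        vol = _volume(ivim_signal(p, ivim_acq.b_values), ivim_acq)
        dslow, dfast, pf, _ = fit_ivim_segmented(vol, b_threshold=200.0)
        assert dslow.values[0, 0, 0] == pytest.approx(p.Dslow, rel=0.02)
        assert abs(pf.values[0, 0, 0] - p.f) < 0.01
        assert dslow.reported()[0, 0, 0] == pytest.approx(778.0, rel=0.02)

    def test_f_zero_data_reduces_to_adc_fit(self, ivim_acq):
        sig = dwi_signal(TissueParams(S0=70.0, ADC=0.9e-3), ivim_acq.b_values)
        vol = _volume(sig, ivim_acq)
        dslow, dfast, pf, _ = fit_ivim_segmented(vol)
        adc, _ = fit_adc(vol)
        assert pf.values[0, 0, 0] == pytest.approx(0.0, abs=1e-6)
        assert dslow.values[0, 0, 0] == pytest.approx(adc.values[0, 0, 0], rel=1e-6)
        # no perfusion signal -> pseudo-diffusion unfit
        assert not dfast.mask[0, 0, 0]

    def test_segmented_agrees_with_joint_fit(self, ivim_acq):
        p = TissueParams(S0=300.0, f=0.15, Dslow=0.9e-3, Dfast=45e-3)
        vol = _volume(ivim_signal(p, ivim_acq.b_values), ivim_acq)
        seg = fit_ivim_segmented(vol)
        joint = fit_ivim_joint(vol)
        for s_map, j_map in zip(seg[:3], joint[:3]):
            assert s_map.values[0, 0, 0] == pytest.approx(
                j_map.values[0, 0, 0], rel=0.01, abs=1e-4)

    def test_threshold_needs_enough_points(self, ivim_acq):
        vol = _volume(np.ones(12), ivim_acq)
        with pytest.raises(ValueError):
            fit_ivim_segmented(vol, b_threshold=700.0)


class TestToftsFit:
    def test_recovers_typical_tumor_values(self, dce_acq):
        p = TissueParams(Ktrans=0.92, Kep=1.2395)
        aif = StepAif(1.0, onset_s=dce_acq.onset_s)
        vol = _volume(tofts_concentration(p, aif, dce_acq), dce_acq)
        kt, kep, ve = fit_tofts(vol, aif)
        assert kt.values[0, 0, 0] == pytest.approx(0.92, rel=1e-3)
        assert kep.values[0, 0, 0] == pytest.approx(1.2395, rel=1e-3)
        assert ve.values[0, 0, 0] == pytest.approx(0.742, abs=1e-3)

    def test_zero_concentration_gives_zero_ktrans(self, dce_acq):
        aif = ParkerAif(onset_s=dce_acq.onset_s)
        kt, _, ve = fit_tofts(_volume(np.zeros(len(dce_acq)), dce_acq), aif)
        assert kt.values[0, 0, 0] == 0.0

    def test_ve_is_ratio_of_rate_constants(self, dce_acq):
        rng = np.random.default_rng(5)
        aif = ParkerAif(onset_s=dce_acq.onset_s)
        curves = []
        for _ in range(4):
            kep = rng.uniform(0.5, 3.0)
            p = TissueParams(Ktrans=rng.uniform(0.1, 0.9) * kep, Kep=kep)
            curves.append(tofts_concentration(p, aif, dce_acq))
        vol = SignalVolume(np.asarray(curves).reshape(4, 1, 1, -1), dce_acq)
        kt, kep_m, ve = fit_tofts(vol, aif)
        np.testing.assert_allclose(ve.values[:, 0, 0],
                                   kt.values[:, 0, 0] / kep_m.values[:, 0, 0],
                                   rtol=1e-12)


class TestContainers:
    def test_reporting_scale_round_trip(self):
        vals = np.array([[[1.2e-3]]])
        pmap = ParameterMap("MD", vals, np.ones_like(vals, bool),
                            scale=REPORTING_SCALE["MD"])
        assert pmap.reported()[0, 0, 0] * pmap.scale == pytest.approx(1.2e-3)

    def test_parameter_map_nifti_round_trip(self, tmp_path):
        vals = np.arange(8.0).reshape(2, 2, 2) * 1e-6
        mask = vals > 0
        pmap = ParameterMap("ADC", vals, mask, scale=1e-6,
                            spacing_mm=(2.0, 2.0, 3.0))
        pmap.to_nifti(tmp_path / "adc.nii")
        back = ParameterMap.from_nifti(tmp_path / "adc.nii")
        assert back.name == "ADC" and back.scale == 1e-6
        np.testing.assert_allclose(back.values[mask], vals[mask], rtol=1e-6)
        np.testing.assert_array_equal(back.mask, mask)

    def test_signal_volume_nifti_round_trip(self, tmp_path, dwi_acq):
        data = np.random.default_rng(0).uniform(1, 100, (3, 4, 2, 2))
        vol = SignalVolume(data, dwi_acq, spacing_mm=(1.5, 1.5, 4.0))
        vol.to_nifti(tmp_path / "dwi.nii")
        back = SignalVolume.from_nifti(tmp_path / "dwi.nii", dwi_acq)
        np.testing.assert_allclose(back.data, data, rtol=1e-6)
        assert back.spacing_mm == (1.5, 1.5, 4.0)

    def test_shape_mismatches_rejected(self, dwi_acq):
        with pytest.raises(ValueError):
            SignalVolume(np.ones((2, 2, 2, 5)), dwi_acq)
        with pytest.raises(ValueError):
            ParameterMap("x", np.ones((2, 2)), np.ones((3, 2), bool))
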