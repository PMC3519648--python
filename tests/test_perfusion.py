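"""Concentration conversion, TTP/delay maps, SVD deconvolution, lesions."""
import numpy as np
import pytest

from strokemismatch.core import (
    AcquisitionParams,
    AifCurve,
    ConcentrationSeries,
    DSCSeries,
    GeometryParams,
    LesionMask,
)
from strokemismatch import perfusion as perf
from strokemismatch import synthetic as syn
from strokemismatch.synthetic import Region, RegionKinetics
from strokemismatch.volumetry import mask_volume


def _flat_series(acq, geometry, s0=100.0):
    data = np.full(tuple(geometry.grid_shape) + (acq.n_frames,), s0)
    return DSCSeries(data, acq, geometry)


TINY = GeometryParams(6.875, 6.0, (4, 4, 2))


class TestSignalToConcentration:
    def test_constant_signal_maps_to_zero(self, acq):
        conc = perf.signal_to_concentration(_flat_series(acq, TINY))
        assert np.allclose(conc.data, 0.0)

    def test_inverts_forward_relation_exactly(self, acq):
        s0, c_true = 80.0, 3.7
        series = _flat_series(acq, TINY, s0)
        series.data[..., 20] = s0 * np.exp(-1.0 * acq.te_s * c_true)
        conc = perf.signal_to_concentration(series, k_dsc=1.0)
        assert conc.data[0, 0, 0, 20] == pytest.approx(c_true, rel=1e-12)

    def test_round_trip_against_simulator_curves(self, phantom, noiseless_series, acq):
        conc = perf.signal_to_concentration(noiseless_series, phantom.brain_mask())
        for label in (Region.NORMAL_IPSI, Region.PENUMBRA, Region.CORE):
            truth = syn.region_concentration(phantom.region_kinetics[label], acq)
            vox = np.argwhere(phantom.label_map == label)[0]
            got = conc.data[tuple(vox)]
            assert np.max(np.abs(got - truth)) <= 1e-6 * truth.max()

    def test_nonpositive_baseline_flagged_not_zero_divided(self, acq):
        series = _flat_series(acq, TINY)
        series.data[0, 0, 0, :] = 0.0
        conc = perf.signal_to_concentration(series)
        assert conc.invalid_mask[0, 0, 0]
        assert np.all(conc.data[0, 0, 0] == 0.0)

    def test_too_few_baseline_frames_rejected(self):
        acq = AcquisitionParams(n_baseline_frames=2)
        with pytest.raises(ValueError, match="baseline"):
            perf.signal_to_concentration(_flat_series(acq, TINY))


class TestTtpMap:
    def test_single_spike_definition(self, acq):
        data = np.zeros(tuple(TINY.grid_shape) + (acq.n_frames,))
        data[..., 20] = 1.0
        conc = ConcentrationSeries(data, acq.time_axis_s, TINY)
        ttp = perf.compute_ttp_map(conc)
        assert np.all(ttp == 30.0)

    def test_shift_by_two_frames_adds_three_seconds(self, acq):
        data = np.zeros(tuple(TINY.grid_shape) + (acq.n_frames,))
        data[..., 20] = 1.0
        shifted = np.roll(data, 2, axis=-1)
        t = acq.time_axis_s
        a = perf.compute_ttp_map(ConcentrationSeries(data, t, TINY))
        b = perf.compute_ttp_map(ConcentrationSeries(shifted, t, TINY))
        assert np.all(b - a == 3.0)

    def test_values_lie_on_frame_grid(self, phantom, noiseless_series, acq):
        conc = perf.signal_to_concentration(noiseless_series, phantom.brain_mask())
        ttp = perf.compute_ttp_map(conc, search_start_frame=acq.n_baseline_frames)
        finite = ttp[np.isfinite(ttp)]
        assert np.allclose(finite / acq.tr_s, np.round(finite / acq.tr_s))

    def test_all_zero_voxel_gets_nan_sentinel(self, acq):
        data = np.zeros(tuple(TINY.grid_shape) + (acq.n_frames,))
        data[0, 0, 0, 15] = 1.0
        conc = ConcentrationSeries(data, acq.time_axis_s, TINY)
        ttp = perf.compute_ttp_map(conc)
        assert np.isnan(ttp[1, 1, 1]) and ttp[0, 0, 0] == 22.5

    def test_region_delays_recovered(self, acq, small_geometry):
        kin = {
            Region.NORMAL_IPSI: RegionKinetics(0.0, 6.0, 1.0),
            Region.NORMAL_CONTRA: RegionKinetics(0.0, 6.0, 1.0),
            Region.PENUMBRA: RegionKinetics(4.5, 6.0, 1.0),
            Region.CORE: RegionKinetics(9.0, 6.0, 1.0),
            Region.ARTERY: RegionKinetics(0.0, 1.5, 1.0),
        }
        ph = syn.make_phantom(small_geometry, 0.3, 40.0, kinetics=kin)
        series = syn.simulate_dsc(ph, acq, noise_sd=0.0)
        conc = perf.signal_to_concentration(series, ph.brain_mask())
        ttp = perf.compute_ttp_map(conc, search_start_frame=acq.n_baseline_frames)
        ref = np.nanmedian(ttp[ph.label_map == Region.NORMAL_IPSI])
        # delays placed on the TR grid; off-grid delays quantise to +- TR/2
        for label, delay in ((Region.PENUMBRA, 4.5), (Region.CORE, 9.0)):
            med = np.nanmedian(ttp[ph.label_map == label])
            assert med - ref == pytest.approx(delay, abs=acq.tr_s / 2)


class TestTtpDelay:
    def test_self_reference_has_zero_mean(self, phantom, noiseless_series, acq):
        conc = perf.signal_to_concentration(noiseless_series, phantom.brain_mask())
        ttp = perf.compute_ttp_map(conc, search_start_frame=acq.n_baseline_frames)
        roi = phantom.brain_mask() & np.isfinite(ttp)
        delay = perf.ttp_delay_map(ttp, roi)
        assert np.nanmean(delay[roi]) == pytest.approx(0.0, abs=1e-9)

    def test_shift_above_reference_mean(self):
        ttp = np.full((4, 4, 2), 20.0)
        ttp[0, 0, 0] = 25.0
        roi = np.ones_like(ttp, dtype=bool)
        roi[0, 0, 0] = False
        delay = perf.ttp_delay_map(ttp, roi)
        assert delay[0, 0, 0] == pytest.approx(5.0)

    def test_small_reference_roi_rejected(self):
        ttp = np.full((4, 4, 2), 20.0)
        roi = np.zeros_like(ttp, dtype=bool)
        roi[0, 0, 0] = True
        with pytest.raises(ValueError, match="reference ROI"):
            perf.ttp_delay_map(ttp, roi)


class TestThresholdTtpLesion:
    def test_zero_delay_gives_empty_mask(self):
        delay = np.zeros(TINY.grid_shape)
        brain = LesionMask(np.ones(TINY.grid_shape, np.uint8), TINY)
        mask = perf.threshold_ttp_lesion(delay, brain)
        assert mask.n_voxels == 0

    def test_exactly_four_seconds_excluded(self):
        delay = np.full(TINY.grid_shape, 4.0)
        brain = LesionMask(np.ones(TINY.grid_shape, np.uint8), TINY)
        mask = perf.threshold_ttp_lesion(delay, brain, threshold_s=4.0)
        assert mask.n_voxels == 0
        delay[0, 0, 0] = 4.0 + 1e-9
        assert perf.threshold_ttp_lesion(delay, brain).n_voxels == 1

    def test_exclusion_mask_removes_artifact_voxels(self):
        delay = np.full(TINY.grid_shape, 6.0)
        brain = LesionMask(np.ones(TINY.grid_shape, np.uint8), TINY)
        excl = np.zeros(TINY.grid_shape, bool)
        excl[0] = True
        mask = perf.threshold_ttp_lesion(delay, brain, excl)
        assert mask.n_voxels == int((~excl).sum())

    def test_phantom_lesion_volume_matches_truth(self, acq, small_geometry):
        # penumbra delayed 6 s, all else prompt; same MTT so only delay differs
        kin = {
            Region.NORMAL_IPSI: RegionKinetics(0.0, 6.0, 1.0),
            Region.NORMAL_CONTRA: RegionKinetics(0.0, 6.0, 1.0),
            Region.PENUMBRA: RegionKinetics(6.0, 6.0, 1.0),
            Region.CORE: RegionKinetics(6.0, 6.0, 1.0),
            Region.ARTERY: RegionKinetics(0.0, 1.5, 1.0),
        }
        ph = syn.make_phantom(small_geometry, 0.0, 50.0, kinetics=kin)
        series = syn.simulate_dsc(ph, acq, noise_sd=0.0)
        conc = perf.signal_to_concentration(series, ph.brain_mask())
        ttp = perf.compute_ttp_map(conc, search_start_frame=acq.n_baseline_frames)
        contra = ph.region_mask(Region.NORMAL_CONTRA)
        delay = perf.ttp_delay_map(ttp, contra.data)
        brain = LesionMask(ph.brain_mask().astype(np.uint8), small_geometry)
        lesion = perf.threshold_ttp_lesion(delay, brain, geometry=small_geometry)
        truth = ph.region_volume_ml(Region.PENUMBRA)
        assert mask_volume(lesion) == pytest.approx(truth, rel=0.05)


def _delay_free_phantom(small_geometry, mtt_lesion=10.0, mtt_normal=4.0, cbv=1.0):
    kin = {
        Region.NORMAL_IPSI: RegionKinetics(0.0, mtt_normal, cbv),
        Region.NORMAL_CONTRA: RegionKinetics(0.0, mtt_normal, cbv),
        Region.PENUMBRA: RegionKinetics(0.0, mtt_lesion, cbv),
        Region.CORE: RegionKinetics(0.0, mtt_lesion, cbv),
        Region.ARTERY: RegionKinetics(0.0, 1.5, 1.0),
    }
    return syn.make_phantom(small_geometry, 0.0, 50.0, kinetics=kin)


def _maps_for(ph, acq, truncation):
    series = syn.simulate_dsc(ph, acq, noise_sd=0.0)
    conc = perf.signal_to_concentration(series, ph.brain_mask())
    aif = perf.extract_aif(conc, ph.region_mask(Region.ARTERY).data)
    return perf.svd_deconvolve(conc, aif, truncation, ph.brain_mask())


class TestSvdDeconvolve:
    def test_tissue_equal_to_aif_gives_grid_limited_mtt(self, acq):
        t = acq.time_axis_s
        aif_vals = syn.gamma_variate_aif(t, acq.injection_delay_s + 2.0)
        data = np.broadcast_to(aif_vals, tuple(TINY.grid_shape) + (len(t),)).copy()
        conc = ConcentrationSeries(data, t, TINY)
        maps = perf.svd_deconvolve(conc, AifCurve(aif_vals, t), 0.01)
        # a delta residue cannot be resolved below the frame spacing
        assert np.nanmedian(maps.mtt_s) <= 2 * acq.tr_s
        assert np.nanmedian(maps.cbv_rel) == pytest.approx(1.0, rel=1e-6)

    def test_linearity_in_tissue_curve(self, phantom, noiseless_series, acq):
        conc = perf.signal_to_concentration(noiseless_series, phantom.brain_mask())
        aif = perf.extract_aif(conc, phantom.region_mask(Region.ARTERY).data)
        m1 = perf.svd_deconvolve(conc, aif, 0.2, phantom.brain_mask())
        scaled = ConcentrationSeries(
            3.0 * conc.data, conc.time_axis_s, conc.geometry, conc.invalid_mask
        )
        m3 = perf.svd_deconvolve(scaled, aif, 0.2, phantom.brain_mask())
        ok = np.isfinite(m1.cbf_rel)
        assert np.allclose(m3.cbf_rel[ok], 3.0 * m1.cbf_rel[ok])
        assert np.allclose(m3.cbv_rel[ok], 3.0 * m1.cbv_rel[ok])
        assert np.allclose(m3.mtt_s[ok], m1.mtt_s[ok], equal_nan=True)

    def test_truncation_never_increases_rank(self, acq):
        t = acq.time_axis_s
        aif_vals = syn.gamma_variate_aif(t, acq.injection_delay_s + 2.0)
        a = acq.tr_s * np.tril(
            np.array([[aif_vals[i - j] if i >= j else 0 for j in range(len(t))]
                      for i in range(len(t))])
        )
        s = np.linalg.svd(a, compute_uv=False)
        ranks = [(s >= f * s[0]).sum() for f in (0.05, 0.1, 0.2, 0.4)]
        assert ranks == sorted(ranks, reverse=True)

    @pytest.mark.parametrize("mtt_true", [4.0, 6.0, 8.0, 10.0])
    def test_noiseless_mtt_recovery_with_matched_regularisation(
        self, acq, small_geometry, mtt_true
    ):
        """Delay-free curves, truncation matched to zero noise: 15% accuracy."""
        ph = _delay_free_phantom(small_geometry, mtt_lesion=mtt_true)
        maps = _maps_for(ph, acq, truncation=0.01)
        med = np.nanmedian(maps.mtt_s[ph.label_map == Region.PENUMBRA])
        assert med == pytest.approx(mtt_true, rel=0.15)

    def test_default_truncation_overestimates_short_mtt(self, acq, small_geometry):
        """At the clinical default (0.2) truncated SVD smooths the residue and
        biases MTT high — the known cost of discarding 20% of the spectrum."""
        ph = _delay_free_phantom(small_geometry, mtt_lesion=6.0)
        maps = _maps_for(ph, acq, truncation=0.2)
        med = np.nanmedian(maps.mtt_s[ph.label_map == Region.PENUMBRA])
        assert med > 6.0

    def test_cbv_recovery_within_five_percent(self, acq, small_geometry):
        ph = _delay_free_phantom(small_geometry, mtt_lesion=6.0, cbv=1.0)
        maps = _maps_for(ph, acq, truncation=0.2)
        med = np.nanmedian(maps.cbv_rel[ph.label_map == Region.PENUMBRA])
        assert med == pytest.approx(1.0, rel=0.05)

    def test_zero_aif_rejected(self, acq):
        t = acq.time_axis_s
        with pytest.raises(ValueError, match="peak"):
            AifCurve(np.zeros(len(t)), t)


class TestMttLesion:
    def _maps_from_mtt(self, mtt):
        return perf.PerfusionMapSet(geometry=TINY, mtt_s=mtt)

    def test_uniform_mtt_gives_empty_lesion(self):
        maps = self._maps_from_mtt(np.full(TINY.grid_shape, 5.0))
        roi = np.ones(TINY.grid_shape, bool)
        assert perf.mtt_lesion_mask(maps, roi, 1.5).n_voxels == 0

    def test_two_region_construction(self):
        mtt = np.full(TINY.grid_shape, 5.0)
        mtt[:2] = 10.0  # ratio 2 vs reference
        roi = np.zeros(TINY.grid_shape, bool)
        roi[2:] = True
        maps = self._maps_from_mtt(mtt)
        lesion = perf.mtt_lesion_mask(maps, roi, 1.5)
        assert np.array_equal(lesion.data, mtt == 10.0)

    def test_phantom_lesion_volume_within_ten_percent(self, acq, small_geometry):
        ph = _delay_free_phantom(small_geometry, mtt_lesion=10.0, mtt_normal=5.0)
        maps = _maps_for(ph, acq, truncation=0.01)
        contra = ph.region_mask(Region.NORMAL_CONTRA)
        lesion = perf.mtt_lesion_mask(maps, contra.data, 1.5, ph.brain_mask())
        truth = ph.region_volume_ml(Region.PENUMBRA)
        assert mask_volume(lesion) == pytest.approx(truth, rel=0.10)
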