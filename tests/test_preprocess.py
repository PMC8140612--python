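"""Signal transforms: analytic oracles, simulation recovery, MNE cross-checks."""

import numpy as np
import pytest

import fnirsblock as fb
from fnirsblock.core import Recording, Unit
from fnirsblock.montage import Montage
from fnirsblock.preprocess import (
    _tddr_1d,
    apply_fir,
    design_bandpass,
    nearest_short_channel,
)
from fnirsblock.simulate import inject_step


def toy_recording(data, sfreq=5.0, unit=Unit.OPTICAL_DENSITY, distance=0.03):
    """One-channel recording with a controllable source-detector distance."""
    m = Montage(
        source_labels=["S1"], source_pos=np.zeros((1, 3)),
        detector_labels=["D1"], detector_pos=np.array([[distance, 0, 0]]),
        channels=[("S1", "D1")],
    )
    return Recording(data=np.asarray(data, float), sfreq=sfreq, unit=unit, montage=m)


class TestOpticalDensity:
    def test_constant_intensity_gives_zero(self):
        rec = toy_recording(np.ones((2, 50)), unit=Unit.RAW_INTENSITY)
        od = fb.to_optical_density(rec)
        np.testing.assert_allclose(od.data, 0.0, atol=1e-15)
        assert od.unit is Unit.OPTICAL_DENSITY

    def test_analytic_inverse_at_one_sample(self):
        data = np.ones((2, 100))
        data[0, 10] = np.exp(-0.5)  # mean ≈ 1, so OD ≈ 0.5 there
        od = fb.to_optical_density(toy_recording(data, unit=Unit.RAW_INTENSITY))
        mean = data[0].mean()
        assert od.data[0, 10] == pytest.approx(-np.log(data[0, 10] / mean), abs=1e-12)

    def test_unit_tag_enforced(self):
        rec = toy_recording(np.zeros((2, 50)), unit=Unit.OPTICAL_DENSITY)
        with pytest.raises(ValueError, match="raw_intensity"):
            fb.to_optical_density(rec)

    def test_matches_mne_oracle(self, quiet_session):
        """Independent cross-check against MNE's optical-density conversion."""
        import mne

        rec, _ = quiet_session
        ours = fb.to_optical_density(rec)
        info = mne.create_info(
            [f"S{i // 2 + 1}_D{i // 2 + 1} {760 if i % 2 == 0 else 850}"
             for i in range(6)],
            rec.sfreq, ch_types="fnirs_cw_amplitude",
        )
        for i, ch in enumerate(info["chs"]):
            ch["loc"][9] = 760.0 if i % 2 == 0 else 850.0
        raw = mne.io.RawArray(rec.data[:6], info, verbose="error")
        theirs = mne.preprocessing.nirs.optical_density(raw, verbose="error")
        np.testing.assert_allclose(ours.data[:6], theirs.get_data(), atol=1e-9)


class TestScalpCouplingIndex:
    def _cardiac_recording(self, shared, rng, snr=8.0, n=2000, sfreq=5.2):
        t = np.arange(n) / sfreq
        card = np.sin(2 * np.pi * 1.1 * t)
        data = np.empty((2, n))
        for k in range(2):
            noise = rng.standard_normal(n) * (1.0 / snr)
            data[k] = (card if shared else rng.standard_normal(n)) + noise
        return toy_recording(data, sfreq=sfreq)

    def test_shared_cardiac_scores_high(self):
        rng = np.random.default_rng(0)
        rep = fb.scalp_coupling_index(self._cardiac_recording(True, rng))
        assert rep.sci[0] > 0.8
        assert rep.kept == [0] and rep.dropped == []

    def test_independent_noise_scores_low(self):
        rng = np.random.default_rng(1)
        rep = fb.scalp_coupling_index(self._cardiac_recording(False, rng))
        assert abs(rep.sci[0]) < 0.3
        assert rep.dropped == [0]

    def test_anticorrelated_wavelengths_score_minus_one(self):
        rng = np.random.default_rng(2)
        n = 1500
        x = rng.standard_normal(n)
        rep = fb.scalp_coupling_index(toy_recording(np.vstack([x, -x])))
        assert rep.sci[0] == pytest.approx(-1.0, abs=1e-9)

    def test_low_sample_rate_rejected(self):
        rec = toy_recording(np.random.default_rng(0).standard_normal((2, 500)), sfreq=1.0)
        with pytest.raises(ValueError, match="cardiac band"):
            fb.scalp_coupling_index(rec)


class TestTddr:
    def test_clean_slow_sinusoid_shape_preserved(self):
        # the robust derivative reweighting mildly shrinks even a clean
        # sinusoid (an inherent property of the procedure), so the contract
        # is shape preservation and bounded distortion, not identity
        sfreq = 5.2
        t = np.arange(0, 120, 1 / sfreq)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = _tddr_1d(x, sfreq)
        assert np.abs(y - x).max() <= 0.10 * (x.max() - x.min())
        assert np.corrcoef(x, y)[0, 1] > 0.99

    def test_step_artifact_suppressed(self):
        rng = np.random.default_rng(3)
        sfreq = 5.2
        n = 1200
        sigma = 0.05
        x = np.sin(2 * np.pi * 0.05 * np.arange(n) / sfreq) + sigma * rng.standard_normal(n)
        step = 10 * x.std()
        xa = inject_step(x, n // 2, step)
        y = _tddr_1d(xa, sfreq)
        resid_step = np.mean(y[n // 2 + 50:]) - np.mean(y[:n // 2 - 50])
        assert abs(resid_step) <= 0.2 * step

    def test_zero_signal_stays_zero(self):
        rec = toy_recording(np.zeros((2, 100)))
        out = fb.tddr(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            fb.tddr(toy_recording(np.zeros((2, 2))))

    def test_matches_mne_oracle(self):
        """Independent cross-check against MNE's TDDR on a spiky trace."""
        import mne
        from mne.preprocessing.nirs import temporal_derivative_distribution_repair

        rng = np.random.default_rng(4)
        sfreq = 5.2
        n = 1000
        x = (np.sin(2 * np.pi * 0.05 * np.arange(n) / sfreq)
             + 0.05 * rng.standard_normal(n))
        x = inject_step(x, 400, 2.0)
        x = x - x.mean()  # common centred baseline for both implementations

        info = mne.create_info(["S1_D1 760", "S1_D1 850"], sfreq, "fnirs_od")
        for i, ch in enumerate(info["chs"]):
            ch["loc"][9] = 760.0 if i == 0 else 850.0
        raw = mne.io.RawArray(np.vstack([x, x]), info, verbose="error")
        theirs = temporal_derivative_distribution_repair(raw, verbose="error")
        ours = _tddr_1d(x, sfreq)
        np.testing.assert_allclose(ours, theirs.get_data()[0], atol=1e-6)


class TestShortChannelRegression:
    def _two_channel_rec(self, long_data, short_data, sfreq=5.0):
        m = Montage(
            source_labels=["S1", "S2"],
            source_pos=np.array([[0, 0, 0], [0.1, 0, 0]]),
            detector_labels=["D1", "D2"],
            detector_pos=np.array([[0.03, 0, 0], [0.105, 0, 0]]),
            channels=[("S1", "D1"), ("S2", "D2")],  # long then short
        )
        data = np.vstack([long_data, short_data])
        return Recording(data=data, sfreq=sfreq, unit=Unit.OPTICAL_DENSITY, montage=m)

    def test_proportional_short_removed_exactly(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal((2, 300))
        rec = self._two_channel_rec(2.0 * s, s)
        out = fb.short_channel_regress(rec)
        np.testing.assert_allclose(out.data[:2], 0.0, atol=1e-9)

    def test_orthogonal_short_leaves_long_unchanged(self):
        n = 400
        t = np.arange(n)
        long = np.vstack([np.sin(2 * np.pi * t / 50), np.sin(2 * np.pi * t / 50)])
        short = np.vstack([np.cos(2 * np.pi * t / 50), np.cos(2 * np.pi * t / 50)])
        rec = self._two_channel_rec(long, short)
        out = fb.short_channel_regress(rec)
        np.testing.assert_allclose(out.data[:2], long, atol=1e-9)

    def test_regression_reduces_variance_never_increases(self, quiet_cfg, montage):
        cfg = fb.SimulationConfig(seed=6, noise_sigma=0.3, trials_per_condition=4)
        rec, gt = fb.generate_session(cfg, 0, montage)
        od = fb.to_optical_density(rec)
        out = fb.short_channel_regress(od)
        for ch in montage.long_indices:
            for k in (0, 1):
                r = 2 * ch + k
                assert out.data[r].var() <= od.data[r].var() + 1e-15

    def test_correction_improves_neural_correlation(self, montage):
        cfg = fb.SimulationConfig(seed=7, mayer_amp=4.0, noise_sigma=0.2,
                                  trials_per_condition=6)
        rec, gt = fb.generate_session(cfg, 0, montage)
        od = fb.to_optical_density(rec)
        corrected = fb.short_channel_regress(od)
        ch = montage.roi_channels(fb.LEFT_STG)[0]
        r = 2 * ch + 1  # 850 nm carries the neural HbO signature strongly
        neural = gt.neural[2 * ch]
        before = abs(np.corrcoef(od.data[r], neural)[0, 1])
        after = abs(np.corrcoef(corrected.data[r], neural)[0, 1])
        assert after > before

    def test_no_short_channels_rejected(self):
        rec = toy_recording(np.random.default_rng(0).standard_normal((2, 100)))
        with pytest.raises(ValueError, match="short"):
            fb.short_channel_regress(rec)

    def test_nearest_short_is_spatially_nearest(self, montage):
        for ch in montage.long_indices[:6]:
            s = nearest_short_channel(montage, ch)
            d_s = np.linalg.norm(montage.midpoint(ch) - montage.midpoint(s))
            for other in montage.short_indices:
                d_o = np.linalg.norm(montage.midpoint(ch) - montage.midpoint(other))
                assert d_s <= d_o + 1e-12


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self):
        out = fb.beer_lambert(toy_recording(np.zeros((2, 10))))
        np.testing.assert_allclose(out.data, 0.0)
        assert out.unit is Unit.MOLAR
        assert out.row_chroma == ["hbo", "hbr"]

    def test_hand_computed_2x2_solve(self):
        # E = [[1, 2], [3, 1]], d·ppf = 1 (d=1 cm at ppf=1... encoded via
        # distance 0.01 m and ppf 1), ΔOD = [5, 5] -> [HbO, HbR] = [1, 2] M
        E = np.array([[1.0, 2.0], [3.0, 1.0]])
        od = np.full((2, 4), 5.0)
        rec = toy_recording(od, distance=0.01)
        out = fb.beer_lambert(rec, ppf=1.0, extinctions=E)
        np.testing.assert_allclose(out.data[0] / 1e6, 1.0, rtol=1e-12)
        np.testing.assert_allclose(out.data[1] / 1e6, 2.0, rtol=1e-12)

    def test_linearity(self, quiet_session):
        rec, _ = quiet_session
        od = fb.to_optical_density(rec)
        a = fb.beer_lambert(od)
        doubled = od.with_data(2.0 * od.data)
        b = fb.beer_lambert(doubled)
        np.testing.assert_allclose(b.data, 2.0 * a.data, rtol=1e-9)

    def test_singular_extinctions_rejected(self):
        rec = toy_recording(np.zeros((2, 10)))
        with pytest.raises(np.linalg.LinAlgError):
            fb.beer_lambert(rec, extinctions=np.ones((2, 2)))


class TestNegativeCorrelationEnhancement:
    def test_fixed_point_when_already_anticorrelated(self):
        rng = np.random.default_rng(8)
        hbo = rng.standard_normal(500)
        beta = 2.0
        hbr = -hbo / beta
        rec = toy_recording(np.vstack([hbo, hbr]), unit=Unit.MOLAR)
        out = fb.negative_correlation_enhance(rec)
        np.testing.assert_allclose(out.data[0], hbo, atol=1e-9)
        np.testing.assert_allclose(out.data[1], hbr, atol=1e-9)

    def test_output_correlation_is_minus_one(self):
        rng = np.random.default_rng(9)
        rec = toy_recording(rng.standard_normal((2, 800)), unit=Unit.MOLAR)
        out = fb.negative_correlation_enhance(rec)
        r = np.corrcoef(out.data[0], out.data[1])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_preserves_condition_contrast_sign(self, hb_session):
        hb, gt = hb_session
        enh = fb.negative_correlation_enhance(hb)
        for data in (hb, enh):
            avg = fb.average(fb.epoch(data))
            sp = fb.amplitude_window(avg, fb.LEFT_STG, "speech", "hbo")
            no = fb.amplitude_window(avg, fb.LEFT_STG, "noise", "hbo")
            assert sp - no > 0

    def test_zero_hbr_variance_rejected(self):
        data = np.vstack([np.random.default_rng(0).standard_normal(100), np.zeros(100)])
        with pytest.raises(ZeroDivisionError):
            fb.negative_correlation_enhance(toy_recording(data, unit=Unit.MOLAR))


class TestBandpass:
    def _probe(self, freq, sfreq=3.0, dur=1500.0):
        t = np.arange(0, dur, 1 / sfreq)
        return np.sin(2 * np.pi * freq * t), t

    def test_dc_removed(self):
        sfreq = 3.0
        data = np.full((2, 4500), 7.0)
        rec = toy_recording(data, sfreq=sfreq)
        out = fb.bandpass(rec)
        assert abs(out.data[0, 1000:-1000].mean()) < 0.1

    def test_passband_sinusoid_preserved(self):
        x, t = self._probe(0.05)
        rec = toy_recording(np.vstack([x, x]), sfreq=3.0)
        out = fb.bandpass(rec)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        amp = np.abs(out.data[0, mid]).max()
        assert amp == pytest.approx(1.0, rel=0.10)

    def test_stopband_sinusoid_attenuated_20db(self):
        x, t = self._probe(1.0)
        rec = toy_recording(np.vstack([x, x]), sfreq=3.0)
        out = fb.bandpass(rec)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.abs(out.data[0, mid]).max() < 0.1  # ≥ 20 dB down

    def test_infeasible_band_rejected(self):
        rec = toy_recording(np.zeros((2, 100)), sfreq=1.0)
        with pytest.raises(ValueError):
            fb.bandpass(rec)

    def test_analytic_response_matches_empirical(self):
        """freqz of the taps agrees with measured sinusoid attenuation."""
        from fnirsblock.qc import filter_response

        spec = fb.FilterSpec()
        sfreq = 3.0
        for freq in (0.05, 0.3):
            x, _ = self._probe(freq, sfreq=sfreq)
            y = apply_fir(x, design_bandpass(spec, sfreq))
            mid = slice(len(x) // 4, 3 * len(x) // 4)
            emp = np.abs(y[mid]).max()
            ana = filter_response(spec, sfreq, np.array([freq]))[0]
            assert 20 * abs(np.log10(max(emp, 1e-9)) - np.log10(ana)) < 1.0


class TestResampleAndPrune:
    def test_identity_at_same_rate(self, quiet_session):
        rec, _ = quiet_session
        out = fb.resample(rec, rec.sfreq)
        np.testing.assert_allclose(out.data, rec.data)

    def test_slow_sinusoid_survives_deep_downsampling(self):
        sfreq = 5.2
        t = np.arange(0, 1000, 1 / sfreq)
        x = np.sin(2 * np.pi * 0.05 * t)
        rec = toy_recording(np.vstack([x, x]), sfreq=sfreq)
        out = fb.resample(rec, 0.6)
        assert out.sfreq == pytest.approx(0.6, rel=1e-9)
        mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
        assert np.abs(out.data[0, mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_duration_preserved_within_one_sample(self, quiet_session):
        rec, _ = quiet_session
        out = fb.resample(rec, 1.0)
        assert abs(out.duration - rec.duration) <= 1.0 / out.sfreq + 1e-9

    def test_events_unchanged_in_seconds(self, quiet_session):
        rec, _ = quiet_session
        out = fb.resample(rec, 3.0)
        np.testing.assert_allclose(out.events.onsets, rec.events.onsets)

    def test_prune_keeps_all_in_bounds(self, hb_session):
        hb, _ = hb_session
        out = fb.prune_channels(hb)
        assert out.n_channels == hb.n_channels  # paper montage all in bounds

    def test_prune_drops_out_of_bounds_channel(self, hb_session):
        hb, _ = hb_session
        out = fb.prune_channels(hb, dist_bounds=(0.02, 0.035))
        dropped = [c for c in hb.montage.long_indices
                   if not 0.02 <= hb.montage.sd_distance(c) <= 0.035]
        assert out.n_channels == hb.n_channels - len(dropped)
        assert len(out.montage.short_indices) == 8

    def test_prune_respects_sci_report(self, default_session):
        rec, _ = default_session
        od = fb.to_optical_density(rec)
        rep = fb.scalp_coupling_index(od)
        # force three channels below threshold
        bad = od.montage.long_indices[:3]
        rep.sci[bad] = 0.0
        rep.dropped = sorted(set(rep.dropped) | set(bad))
        hb = fb.beer_lambert(od)
        out = fb.prune_channels(hb, sci_report=rep)
        dropped_long = [c for c in rep.dropped if c in hb.montage.long_indices]
        assert len(dropped_long) >= 3
        assert len(out.montage.long_indices) == (
            len(hb.montage.long_indices) - len(dropped_long)
        )

    def test_misordered_pipeline_fails_loudly(self, quiet_session):
        rec, _ = quiet_session
        with pytest.raises(ValueError):
            fb.beer_lambert(rec)  # raw intensity, not OD
        od = fb.to_optical_density(rec)
        with pytest.raises(ValueError):
            fb.negative_correlation_enhance(od)  # OD, not μM
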