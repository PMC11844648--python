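"""Referencing, filtering, detection, artifact rules, impedance QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from imeqc import (
    DetectionConfig,
    EphysSimConfig,
    Recording,
    UnitSpec,
    bandpass,
    biphasic_template,
    common_median_reference,
    detect_spikes,
    impedance_qc,
    reject_artifacts,
    simulate_recording,
)
from imeqc.preproc import SpikeEvent, robust_sigma

FS = 24414.0


class TestCommonMedianReference:
    def test_identical_channels_cancel(self):
        s = np.sin(np.linspace(0, 10, 1000))
        rec = Recording(np.tile(s, (16, 1)), FS)
        out = common_median_reference(rec)
        assert np.allclose(out.voltages, 0.0)

    def test_single_deviant_channel_survives(self):
        V = np.zeros((16, 100))
        V[3, 50] = 10.0
        out = common_median_reference(Recording(V, FS)).voltages
        assert out[3, 50] == 10.0
        assert np.all(out[np.arange(16) != 3] == 0.0)

    def test_matches_per_column_brute_force(self, rng):
        V = rng.normal(size=(16, 1000))
        out = common_median_reference(Recording(V, FS)).voltages
        # independent oracle: per-column even-count median = mean of the
        # middle two order statistics
        for t in rng.integers(0, 1000, size=20):
            col = np.sort(V[:, t])
            med = 0.5 * (col[7] + col[8])
            np.testing.assert_allclose(out[:, t], V[:, t] - med, atol=1e-12)
        assert np.allclose(np.median(out, axis=0), 0.0, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_median_reference(Recording(np.zeros((1, 100)), FS))

    def test_idempotent_once_median_is_zero(self, rng):
        V = rng.normal(size=(15, 500))  # odd count: median is a sample
        once = common_median_reference(Recording(V, FS))
        twice = common_median_reference(once)
        np.testing.assert_allclose(twice.voltages, once.voltages, atol=1e-12)


class TestBandpass:
    def test_dc_rejected(self):
        rec = Recording(np.full((2, 48828), 100.0), FS)
        out = bandpass(rec).voltages
        mid = out[:, 20000:28000]
        assert np.max(np.abs(mid)) < 1e-6 * 100.0

    def test_passband_and_stopband_gain(self):
        # oracle: the zero-phase realization applies the squared magnitude
        # response of the designed 4th-order Butterworth
        from scipy.signal import butter, sosfreqz

        sos = butter(4, [300, 3000], btype="bandpass", fs=FS, output="sos")
        t = np.arange(int(2 * FS)) / FS
        for freq, lo, hi in [(1000.0, 0.89, 1.12), (60.0, 0.0, 0.1)]:
            rec = Recording(np.sin(2 * np.pi * freq * t)[None, :], FS)
            out = bandpass(rec).voltages[0]
            measured = np.max(np.abs(out[int(0.5 * FS):int(1.5 * FS)]))
            _, h = sosfreqz(sos, worN=[freq], fs=FS)
            expected = np.abs(h[0]) ** 2  # forward+backward pass
            assert lo <= measured <= hi
            assert measured == pytest.approx(expected, rel=0.02)
        # 60 Hz attenuation >= 20 dB
        rec = Recording(np.sin(2 * np.pi * 60.0 * t)[None, :], FS)
        out = bandpass(rec).voltages[0]
        assert np.max(np.abs(out[int(0.5 * FS):int(1.5 * FS)])) < 0.1

    def test_linearity(self, rng):
        a = rng.normal(size=(1, 10000))
        b = rng.normal(size=(1, 10000))
        fa = bandpass(Recording(a, FS)).voltages
        fb = bandpass(Recording(b, FS)).voltages
        fab = bandpass(Recording(a + b, FS)).voltages
        np.testing.assert_allclose(fab, fa + fb,
                                   atol=1e-9 * np.max(np.abs(fa + fb)))

    def test_band_edge_at_nyquist_rejected(self):
        rec = Recording(np.zeros((2, 1000)), 1000.0)
        with pytest.raises(ValueError):
            bandpass(rec, (300.0, 500.0))


class TestDetectSpikes:
    def test_zero_signal_no_events(self):
        rec = Recording(np.zeros((2, 5000)), FS)
        assert detect_spikes(rec) == []

    def test_planted_spikes_all_found_few_false_positives(self):
        # trough -80 uV in sigma ~10 uV noise: every planted time matched
        # within +/-0.2 ms; noise-triggered false crossings < 1/s
        tmpl = biphasic_template(FS, 120.0)  # trough ~ -80 uV
        cfg = EphysSimConfig(n_channels=1, duration_s=60.0, fs_hz=FS,
                             noise_sd_uv=10.0,
                             units=[UnitSpec(0, tmpl, 5.0)], seed=2)
        rec, gt = simulate_recording(cfg)
        events = detect_spikes(bandpass(rec))
        times = np.array([e.peak_sample / FS for e in events])
        truth = gt.units[0][1]
        matched = sum(np.min(np.abs(times - t)) <= 0.2e-3 for t in truth)
        assert matched == truth.size
        fp = len(events) - matched
        assert fp / cfg.duration_s < 1.0

    def test_subthreshold_spikes_mostly_missed(self):
        # trough ~ -29 uV vs threshold ~ -4*sigma_hat ~ -38 uV: detection
        # needs the noise to carry the trough past threshold. Geometry
        # oracle: P ~ Phi((thr - trough)/sigma), inflated somewhat by the
        # correlated samples around the trough.
        tmpl = biphasic_template(FS, 45.0)
        cfg = EphysSimConfig(n_channels=1, duration_s=60.0, fs_hz=FS,
                             noise_sd_uv=10.0,
                             units=[UnitSpec(0, tmpl, 5.0)], seed=5)
        rec, gt = simulate_recording(cfg)
        filt = bandpass(rec)
        sigma = robust_sigma(filt.voltages[0])
        events = detect_spikes(filt)
        times = np.array([e.peak_sample / FS for e in events])
        truth = gt.units[0][1]
        frac = np.mean([np.min(np.abs(times - t)) <= 0.2e-3 for t in truth])
        p_oracle = stats.norm.cdf((-4 * sigma - tmpl.min()) / 10.0)
        assert p_oracle < 0.25
        assert 0.5 * p_oracle <= frac <= 2.5 * p_oracle
        assert frac < 0.35  # far below supra-threshold sensitivity

    def test_detection_count_monotone_in_k_sigma(self, small_scene_detected):
        filt = small_scene_detected["filt"]
        counts = [len(detect_spikes(filt, DetectionConfig(k_sigma=k)))
                  for k in (3.0, 4.0, 5.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_too_short_recording_rejected(self):
        rec = Recording(np.zeros((2, 10)), FS)
        with pytest.raises(ValueError):
            detect_spikes(rec)


def _event(channel, peak_sample, amp, n=37):
    wf = np.zeros(n)
    wf[n // 3] = amp
    return SpikeEvent(channel=channel, peak_sample=peak_sample,
                      peak_amplitude_uv=amp, waveform=wf,
                      window_ms=(0.5, 1.0))


class TestRejectArtifacts:
    cfg = DetectionConfig()

    def test_amplitude_rule(self):
        ev = _event(0, 1000, 600.0)
        kept, amp, mot = reject_artifacts([ev], self.cfg, FS)
        assert amp == [ev] and kept == [] and mot == []

    def test_amplitude_rule_checks_full_snippet(self):
        ev = _event(0, 1000, -80.0)
        ev.waveform[-1] = 501.0  # excursion away from the peak
        kept, amp, mot = reject_artifacts([ev], self.cfg, FS)
        assert amp == [ev]

    def test_motion_rule_15_of_16_channels(self):
        events = [_event(c, 1000 + c, -100.0) for c in range(15)]
        kept, amp, mot = reject_artifacts(events, self.cfg, FS)
        assert len(mot) == 15 and kept == [] and amp == []

    def test_exactly_14_channels_kept(self):
        events = [_event(c, 1000 + c, -100.0) for c in range(14)]
        kept, amp, mot = reject_artifacts(events, self.cfg, FS)
        assert len(kept) == 14 and mot == []

    def test_empty_input(self):
        assert reject_artifacts([], self.cfg, FS) == ([], [], [])

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(peaks=st.lists(st.tuples(st.integers(0, 15),
                                    st.integers(0, 100000),
                                    st.floats(-600, 600, allow_nan=False)),
                          max_size=60))
    def test_partition_exhaustive_and_disjoint(self, peaks):
        events = [_event(c, p, a) for c, p, a in peaks]
        kept, amp, mot = reject_artifacts(events, self.cfg, FS)
        assert len(kept) + len(amp) + len(mot) == len(events)
        ids = [id(e) for e in kept + amp + mot]
        assert len(set(ids)) == len(ids)


class TestImpedanceQC:
    def test_all_in_range_passes(self):
        rep = impedance_qc([5e5] * 16)
        assert rep.passed and rep.site_pass.all()

    def test_one_low_site_fails(self):
        z = [5e5] * 16
        z[7] = 5e4
        rep = impedance_qc(z)
        assert not rep.passed and rep.site_pass.sum() == 15

    def test_inclusive_lower_boundary(self):
        z = [5e5] * 16
        z[0] = 1e5
        assert impedance_qc(z).passed

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            impedance_qc([5e5] * 15 + [0.0])


@settings(derandomize=True, deadline=None, max_examples=20)
@given(arrays(np.float64, (4, 64),
              elements=st.floats(-100, 100, allow_nan=False)))
def test_reference_then_reference_is_stable(V):
    out1 = common_median_reference(Recording(V, FS)).voltages
    out2 = common_median_reference(Recording(out1, FS)).voltages
    # median of an even count is the mean of the middle two, so a second
    # pass subtracts an exactly-zero median
    np.testing.assert_allclose(out2, out1, atol=1e-10)
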