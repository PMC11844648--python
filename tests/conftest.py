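import numpy as np
import pytest

from imeqc import (
    DetectionConfig,
    EphysSimConfig,
    UnitSpec,
    bandpass,
    biphasic_template,
    common_median_reference,
    detect_spikes,
    reject_artifacts,
    simulate_recording,
)

FS = 24414.0


@pytest.fixture(scope="session")
def small_scene():
    """8-channel, 30 s scene with one well-separated planted unit per
    channel (Vpp 100-300 uV, rates 2-10 Hz) in 10 uV band-limited noise.
    Shared by detection/sorting/metrics recovery tests."""
    vpps = [100 + (c % 5) * 50 for c in range(8)]
    rates = [2.0 + (c % 5) * 2.0 for c in range(8)]
    units = [UnitSpec(c, biphasic_template(FS, vpps[c]), rates[c])
             for c in range(8)]
    cfg = EphysSimConfig(n_channels=8, duration_s=30.0, fs_hz=FS,
                         noise_sd_uv=10.0, units=units, seed=11)
    rec, gt = simulate_recording(cfg)
    return {"cfg": cfg, "rec": rec, "gt": gt, "vpps": vpps, "rates": rates}


@pytest.fixture(scope="session")
def small_scene_detected(small_scene):
    det = DetectionConfig()
    filt = bandpass(common_median_reference(small_scene["rec"]), det.band_hz)
    events = detect_spikes(filt, det)
    kept, rem_amp, rem_mot = reject_artifacts(events, det, FS)
    return {**small_scene, "filt": filt, "events": events, "kept": kept,
            "removed_amplitude": rem_amp, "removed_motion": rem_mot,
            "det": det}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
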