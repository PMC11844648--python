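"""Seeded, ground-truthed synthetic inputs for the analysis pipeline.

Three generators emulate the raw data the pipeline consumes:

* :func:`simulate_recording` — multichannel extracellular voltage with
  planted spike trains, band-limited noise, common-mode drift, motion
  artifacts, and amplitude outliers, plus a full ground-truth record.
* :func:`simulate_histology` — a radially structured 16-bit fluorescence
  image around a circular implant hole, with an inhomogeneous-Poisson
  neuron point process.
* :func:`simulate_release` — dialysis sample-and-replace measurements of
  a known cumulative release curve, with exact mass bookkeeping.

Every generator is a pure function of its config (which carries the seed):
identical config => bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .preproc import Recording

__all__ = [
    "UnitSpec",
    "MotionArtifactSpec",
    "AmplitudeOutlierSpec",
    "CommonModeSpec",
    "EphysSimConfig",
    "EphysGroundTruth",
    "HistoSimConfig",
    "ReleaseSimConfig",
    "biphasic_template",
    "biexponential_release",
    "simulate_recording",
    "simulate_histology",
    "simulate_release",
]


# --------------------------------------------------------------------------
# Extracellular recording simulator
# --------------------------------------------------------------------------

def biphasic_template(fs: float, vpp: float, dur_ms: float = 1.6,
                      band_hz: tuple[float, float] | None = (300.0, 3000.0)
                      ) -> np.ndarray:
    """Canonical extracellular spike shape: sharp negative trough followed
    by a slower positive rebound, scaled to peak-to-peak amplitude ``vpp``
    (uV). The trough carries ~2/3 of the peak-to-peak range, as is typical
    for somatic extracellular waveforms.

    By default the shape is band-limited to ``band_hz`` before scaling,
    because a spike as acquired has already passed the recording system's
    built-in band-pass; the planted peak-to-peak amplitude then survives
    in-pipeline re-filtering. Pass ``band_hz=None`` for the raw shape.
    """
    n = max(int(round(dur_ms * 1e-3 * fs)), 8)
    t = np.linspace(0.0, 1.0, n)
    # difference of gamma-like lobes; trough at ~1/3 of the window
    trough = -np.exp(-((t - 0.3) ** 2) / (2 * 0.07**2))
    rebound = 0.5 * np.exp(-((t - 0.62) ** 2) / (2 * 0.13**2))
    w = trough + rebound
    w -= w[0]
    if band_hz is not None:
        pad = max(int(round(0.01 * fs)), 4 * n)
        buf = np.zeros(n + 2 * pad)
        buf[pad:pad + n] = w
        sos = signal.butter(4, list(band_hz), btype="bandpass", fs=fs,
                            output="sos")
        buf = signal.sosfiltfilt(sos, buf)
        trough_i = int(np.argmin(buf))
        start = trough_i - int(round(0.3 * n))
        w = buf[start:start + n].copy()
        ramp = np.minimum(1.0, np.arange(n) / max(n // 8, 1))
        w *= ramp * ramp[::-1]  # taper crop edges to zero
    w *= vpp / (w.max() - w.min())
    return w.astype(np.float64)


@dataclass(frozen=True)
class UnitSpec:
    """A planted single unit: where it lives, what it looks like, how often
    it fires (homogeneous Poisson with 1 ms refractory thinning)."""

    channel: int
    template: np.ndarray  # uV, the waveform added at each spike time
    rate_hz: float

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("unit rate must be >= 0")


@dataclass(frozen=True)
class MotionArtifactSpec:
    """A ringing transient sweeping across many channels (animal movement).

    Each hit channel receives the same high-amplitude oscillatory wave
    packet, offset by a small per-channel delay (a mechanical disturbance
    reaches the sites at slightly different times). The stagger puts the
    channels at different carrier phases at any instant, so — like real
    grooming/movement artifacts — the packet survives common-median
    referencing; every hit channel produces several near-simultaneous
    threshold crossings that chain into one coincidence group: the
    signature the >14-channel rule removes.
    """

    time_s: float
    amplitude_uv: float        # packet envelope peak (trough depth), uV
    n_channels_hit: int
    channel_delay_ms: float = 0.25  # must stay below the coincidence window
    duration_ms: float = 6.0
    carrier_hz: float = 1300.0      # in-band ringing frequency


@dataclass(frozen=True)
class AmplitudeOutlierSpec:
    """A single abnormally large spike on one channel."""

    channel: int
    time_s: float
    peak_uv: float


@dataclass(frozen=True)
class CommonModeSpec:
    """Slow sinusoidal drift shared by all channels, uV."""

    amplitude_uv: float
    freq_hz: float = 1.0


@dataclass
class EphysSimConfig:
    n_channels: int = 16
    duration_s: float = 600.0
    fs_hz: float = 24414.0
    noise_sd_uv: float = 10.0  # in-band RMS after the 300-3000 Hz filter
    units: Sequence[UnitSpec] = ()
    common_mode: CommonModeSpec | None = None
    motion_artifacts: Sequence[MotionArtifactSpec] = ()
    amplitude_outliers: Sequence[AmplitudeOutlierSpec] = ()
    band_hz: tuple[float, float] = (300.0, 3000.0)
    refractory_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.duration_s <= 0 or self.n_channels < 1:
            raise ValueError("fs, duration and n_channels must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")


@dataclass
class EphysGroundTruth:
    """Everything that was planted, for recovery scoring downstream."""

    # per unit: (channel, spike peak times in s, template)
    units: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)
    # per motion artifact: (time s, set of channel indices hit)
    artifacts: list[tuple[float, frozenset[int]]] = field(default_factory=list)
    # per amplitude outlier: (channel, time s, peak uV)
    outliers: list[tuple[int, float, float]] = field(default_factory=list)


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float,
                   refractory_s: float) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration) with dead-time
    thinning: any event closer than the refractory period to the previous
    accepted event is dropped."""
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, size=n))
    if t.size == 0:
        return t
    keep = [t[0]]
    for x in t[1:]:
        if x - keep[-1] >= refractory_s:
            keep.append(x)
    return np.asarray(keep)


def simulate_recording(cfg: EphysSimConfig) -> tuple[Recording, EphysGroundTruth]:
    """Build a synthetic multichannel recording plus its ground truth.

    The voltage matrix is the sum of (i) Gaussian noise band-limited to
    ``cfg.band_hz`` and rescaled so its in-band RMS equals ``noise_sd_uv``,
    (ii) planted templates at Poisson spike times, (iii) an optional
    common-mode sinusoid on all channels, (iv) motion-artifact transients
    staggered across the configured channel count, and (v) single-spike
    amplitude outliers. Spike "times" in the ground truth are the trough (peak) times
    of each planted waveform, matching what detection reports.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(cfg.duration_s * cfg.fs_hz))
    for u in cfg.units:
        if len(u.template) > n_samp:
            raise ValueError("template longer than the recording")
        if not (0 <= u.channel < cfg.n_channels):
            raise ValueError(f"unit channel {u.channel} out of range")

    # float32 keeps long 16-channel records ~1 GB; ~1e-7 relative rounding
    # is far below the uV noise floor
    V = np.zeros((cfg.n_channels, n_samp), dtype=np.float32)

    if cfg.noise_sd_uv > 0:
        low, high = cfg.band_hz
        sos = signal.butter(4, [low, high], btype="bandpass", fs=cfg.fs_hz,
                            output="sos")
        for c in range(cfg.n_channels):
            white = rng.standard_normal(n_samp)
            band = signal.sosfiltfilt(sos, white)
            band *= cfg.noise_sd_uv / np.sqrt(np.mean(band**2))
            V[c] += band
    else:
        # burn the same number of draws so planted times do not depend on
        # whether noise is enabled
        pass

    gt = EphysGroundTruth()
    for u in cfg.units:
        times = _poisson_times(rng, u.rate_hz, cfg.duration_s,
                               cfg.refractory_ms * 1e-3)
        tmpl = np.asarray(u.template, dtype=np.float64)
        peak_off = int(np.argmin(tmpl))  # trough index inside the template
        peak_times = []
        for t0 in times:
            start = int(round(t0 * cfg.fs_hz))
            stop = start + len(tmpl)
            if stop > n_samp:
                continue
            V[u.channel, start:stop] += tmpl
            peak_times.append((start + peak_off) / cfg.fs_hz)
        gt.units.append((u.channel, np.asarray(peak_times), tmpl))

    if cfg.common_mode is not None and cfg.common_mode.amplitude_uv != 0:
        t = np.arange(n_samp) / cfg.fs_hz
        cm = cfg.common_mode.amplitude_uv * np.sin(
            2 * np.pi * cfg.common_mode.freq_hz * t)
        V += cm[None, :]

    for art in cfg.motion_artifacts:
        n_pk = max(int(round(art.duration_ms * 1e-3 * cfg.fs_hz)), 8)
        tt = np.arange(n_pk) / cfg.fs_hz
        packet = -abs(art.amplitude_uv) * np.sin(
            2 * np.pi * art.carrier_hz * tt) * np.hanning(n_pk)
        chans = rng.choice(cfg.n_channels, size=min(art.n_channels_hit,
                                                    cfg.n_channels),
                           replace=False)
        delay = int(round(art.channel_delay_ms * 1e-3 * cfg.fs_hz))
        for k, c in enumerate(chans):
            start = int(round(art.time_s * cfg.fs_hz)) + k * delay
            stop = min(start + n_pk, n_samp)
            if start < n_samp:
                V[c, start:stop] += packet[: stop - start]
        gt.artifacts.append((art.time_s, frozenset(int(c) for c in chans)))

    for out in cfg.amplitude_outliers:
        tmpl = biphasic_template(cfg.fs_hz, 1.5 * abs(out.peak_uv))
        start = int(round(out.time_s * cfg.fs_hz))
        stop = min(start + len(tmpl), n_samp)
        V[out.channel, start:stop] += tmpl[: stop - start]
        gt.outliers.append((out.channel, out.time_s, out.peak_uv))

    rec = Recording(voltages=V, fs_hz=cfg.fs_hz,
                    channel_ids=list(range(cfg.n_channels)))
    return rec, gt


# --------------------------------------------------------------------------
# Radial histology simulator
# --------------------------------------------------------------------------

@dataclass
class HistoSimConfig:
    shape_px: tuple[int, int] = (1600, 1600)
    um_per_px: float = 1.0
    hole_center_px: tuple[float, float] = (800.0, 800.0)  # (row, col)
    hole_radius_um: float = 200.0
    marker_profile: Callable[[np.ndarray], np.ndarray] = lambda d: np.full_like(
        d, 1000.0)
    background_intensity: float = 1000.0
    neuron_density_profile: Callable[[np.ndarray], np.ndarray] | None = None
    artifact_regions: Sequence[tuple[slice, slice]] = ()
    noise_sd: float = 0.0
    hole_fill: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        r_px = self.hole_radius_um / self.um_per_px
        r0, c0 = self.hole_center_px
        h, w = self.shape_px
        if (r0 - r_px < 0 or c0 - r_px < 0 or r0 + r_px >= h
                or c0 + r_px >= w):
            raise ValueError("implant hole must lie fully inside the image")


def simulate_histology(
    cfg: HistoSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Synthesise (image, hole_mask, artifact_mask, neuron_centroids).

    Pixel mean intensity at edge-distance ``d`` um equals
    ``marker_profile(d)`` before noise; the hole interior is set to
    ``hole_fill``. Neuron centroids are an inhomogeneous Poisson process
    with per-pixel intensity ``neuron_density_profile(d)`` (neurons/mm^2),
    realised as independent per-pixel Poisson counts jittered uniformly
    inside each pixel. Centroids are returned as (x_px, y_px) columns.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape_px
    rr, cc = np.mgrid[0:h, 0:w]
    r0, c0 = cfg.hole_center_px
    dist_center_um = np.hypot(rr - r0, cc - c0) * cfg.um_per_px
    hole_mask = dist_center_um <= cfg.hole_radius_um
    d_um = np.maximum(dist_center_um - cfg.hole_radius_um, 0.0)

    img = np.asarray(cfg.marker_profile(d_um), dtype=np.float64)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img[hole_mask] = cfg.hole_fill
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    artifact_mask = np.zeros((h, w), dtype=bool)
    for sl in cfg.artifact_regions:
        artifact_mask[sl] = True

    if cfg.neuron_density_profile is None:
        centroids = np.empty((0, 2))
    else:
        px_area_mm2 = (cfg.um_per_px / 1000.0) ** 2
        lam = np.asarray(cfg.neuron_density_profile(d_um),
                         dtype=np.float64) * px_area_mm2
        lam[hole_mask] = 0.0
        counts = rng.poisson(lam)
        ys, xs = np.nonzero(counts)
        reps = counts[ys, xs]
        y_rep = np.repeat(ys, reps).astype(np.float64)
        x_rep = np.repeat(xs, reps).astype(np.float64)
        jitter = rng.uniform(-0.5, 0.5, size=(y_rep.size, 2))
        centroids = np.column_stack([x_rep + jitter[:, 0],
                                     y_rep + jitter[:, 1]])

    return img, hole_mask, artifact_mask, centroids


# --------------------------------------------------------------------------
# Dialysis release simulator
# --------------------------------------------------------------------------

_BIEXP_A = 0.63
_BIEXP_K1 = 0.15           # /h, burst component
_BIEXP_K2 = math.log(18.5) / 576.0  # /h, sustained component


def biexponential_release(t_h: np.ndarray | float, a: float = _BIEXP_A,
                          k1: float = _BIEXP_K1,
                          k2: float = _BIEXP_K2) -> np.ndarray:
    """Default cumulative release fraction F(t) = 1 - a e^{-k1 t} -
    (1-a) e^{-k2 t}. Defaults give F(24 h) ~ 0.655 and F(24 d) ~ 0.980,
    the burst-plus-sustained shape typical of drug-loaded liposomal
    particles."""
    t = np.asarray(t_h, dtype=np.float64)
    return 1.0 - a * np.exp(-k1 * t) - (1.0 - a) * np.exp(-k2 * t)


@dataclass
class ReleaseSimConfig:
    release_model: Callable[[np.ndarray], np.ndarray] = biexponential_release
    loaded_mass_mg: float = 4.0
    v_reservoir_ml: float = 14.0
    v_aliquot_ml: float = 1.0
    sample_times_h: Sequence[float] = (1, 2, 4, 8, 24, 48, 96, 192, 384, 576)
    measurement_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_aliquot_ml > self.v_reservoir_ml:
            raise ValueError("aliquot volume cannot exceed the reservoir")
        t = np.asarray(self.sample_times_h, dtype=np.float64)
        if np.any(t < 0):
            raise ValueError("sample times must be non-negative")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")


def simulate_release(cfg: ReleaseSimConfig):
    """Simulate sample-and-replace dialysis measurements.

    Released drug accumulates in the reservoir according to the cumulative
    fraction F(t). At each sample time the true reservoir concentration is
    mass/V_reservoir; an aliquot removes C*V_aliquot of mass and is
    replaced by drug-free buffer (volume constant). The reported
    concentration is the true one perturbed multiplicatively by
    ``measurement_cv``. Mass is conserved exactly: reservoir + removed +
    unreleased = loaded at every step.
    """
    from .release import ReleaseSeries  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.sample_times_h, dtype=np.float64)
    F = np.asarray(cfg.release_model(t), dtype=np.float64)
    if np.any(np.diff(np.concatenate(([0.0], F))) < -1e-12):
        raise ValueError("release model must be monotone non-decreasing")

    conc = np.empty_like(t)
    reservoir = 0.0
    prev_F = 0.0
    for i, (ti, Fi) in enumerate(zip(t, F)):
        reservoir += cfg.loaded_mass_mg * (Fi - prev_F)
        prev_F = Fi
        c_true = reservoir / cfg.v_reservoir_ml
        noise = rng.normal(0.0, cfg.measurement_cv) if cfg.measurement_cv > 0 else 0.0
        conc[i] = c_true * (1.0 + noise)
        reservoir -= c_true * cfg.v_aliquot_ml  # aliquot out, buffer in

    return ReleaseSeries(times_h=t, conc_mg_per_ml=conc,
                         v_reservoir_ml=cfg.v_reservoir_ml,
                         v_aliquot_ml=cfg.v_aliquot_ml,
                         loaded_mass_mg=cfg.loaded_mass_mg)
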