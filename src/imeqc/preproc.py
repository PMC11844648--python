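"""Referencing, filtering, spike detection, artifact screening, impedance QC.

The preprocessing chain mirrors standard chronic-recording practice:
common-median referencing across the 16 array channels, a 300-3000 Hz
zero-phase band-pass, threshold crossing at -k*sigma_hat per channel with
the robust noise estimate sigma_hat = median(|x|)/0.6745, then two artifact
rules — reject events whose snippet exceeds +/-500 uV anywhere, and reject
groups of near-simultaneous events spanning more than 14 distinct channels
(motion artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "SpikeEvent",
    "DetectionConfig",
    "ImpedanceReport",
    "robust_sigma",
    "common_median_reference",
    "bandpass",
    "detect_spikes",
    "reject_artifacts",
    "impedance_qc",
]


@dataclass
class Recording:
    """Channels x samples voltage matrix in microvolts."""

    voltages: np.ndarray
    fs_hz: float
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltages = np.atleast_2d(np.asarray(self.voltages))
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.voltages)):
            raise ValueError("voltages must be finite")
        if not self.channel_ids:
            self.channel_ids = list(range(self.voltages.shape[0]))
        if len(self.channel_ids) != self.voltages.shape[0]:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class SpikeEvent:
    channel: int
    peak_sample: int          # 0-based index of the trough
    peak_amplitude_uv: float  # signed
    waveform: np.ndarray      # snippet around the peak, uV
    window_ms: tuple[float, float]  # (pre, post)

    def time_s(self, fs_hz: float) -> float:
        return self.peak_sample / fs_hz


@dataclass
class DetectionConfig:
    k_sigma: float = 4.0
    band_hz: tuple[float, float] = (300.0, 3000.0)
    lockout_ms: float = 1.0
    snippet_pre_ms: float = 0.5
    snippet_post_ms: float = 1.0
    amp_limit_uv: float = 500.0
    coincidence_channels: int = 14   # motion if > this many channels
    coincidence_window_ms: float = 0.5

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if not (0 < self.band_hz[0] < self.band_hz[1]):
            raise ValueError("band must satisfy 0 < low < high")
        if self.amp_limit_uv <= 0:
            raise ValueError("amp_limit_uv must be positive")


@dataclass
class ImpedanceReport:
    impedances_ohm: np.ndarray
    site_pass: np.ndarray
    passed: bool


def robust_sigma(x: np.ndarray) -> float:
    """Median-absolute-deviation noise estimate sigma_hat = median(|x|)/0.6745,
    insensitive to the spikes riding on the noise floor."""
    return float(np.median(np.abs(x)) / 0.6745)


def common_median_reference(rec: Recording) -> Recording:
    """Subtract the per-sample median across channels from every channel.

    Removes common-mode signal (movement, line pickup) while a single
    deviant channel leaves the median untouched. Requires >= 2 channels;
    with an even channel count the median is the mean of the middle two.
    """
    if rec.n_channels < 2:
        raise ValueError("common-median reference needs at least 2 channels")
    med = np.median(rec.voltages, axis=0)
    return Recording(voltages=rec.voltages - med[None, :], fs_hz=rec.fs_hz,
                     channel_ids=list(rec.channel_ids))


def bandpass(rec: Recording, band_hz: tuple[float, float] | None = None,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward, so
    the effective magnitude response is the squared filter response)."""
    if band_hz is None:
        band_hz = (300.0, 3000.0)
    low, high = band_hz
    nyq = rec.fs_hz / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band_hz} must lie inside (0, {nyq}) Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs_hz,
                     output="sos")
    # channel-at-a-time in float64 keeps peak memory flat on long records
    out = np.empty_like(rec.voltages)
    for i in range(rec.n_channels):
        out[i] = sps.sosfiltfilt(sos, rec.voltages[i].astype(np.float64))
    return Recording(voltages=out, fs_hz=rec.fs_hz,
                     channel_ids=list(rec.channel_ids))


def _extract_snippet(x: np.ndarray, peak: int, pre: int, post: int) -> np.ndarray:
    """Window [peak-pre, peak+post] with edge-value padding when clipped."""
    lo, hi = peak - pre, peak + post + 1
    left = max(0, -lo)
    right = max(0, hi - x.size)
    core = x[max(lo, 0):min(hi, x.size)]
    if left or right:
        core = np.pad(core, (left, right), mode="edge")
    return core.copy()


def detect_spikes(rec: Recording, cfg: DetectionConfig | None = None,
                  sigma_override: dict[int, float] | None = None
                  ) -> list[SpikeEvent]:
    """Negative threshold-crossing detection per channel.

    For each channel, sigma_hat = median(|x|)/0.6745 and events are
    negative-going crossings of -k_sigma * sigma_hat. The event peak is the
    minimum within the lockout window after the crossing; at most one event
    per lockout window. Snippets span (pre, post) ms around the peak and
    are edge-padded when the peak is near a record boundary.
    """
    if cfg is None:
        cfg = DetectionConfig()
    fs = rec.fs_hz
    pre = int(round(cfg.snippet_pre_ms * 1e-3 * fs))
    post = int(round(cfg.snippet_post_ms * 1e-3 * fs))
    lockout = max(int(round(cfg.lockout_ms * 1e-3 * fs)), 1)
    if rec.n_samples < pre + post + 1:
        raise ValueError("recording shorter than the snippet window")

    events: list[SpikeEvent] = []
    for ci, chan in enumerate(rec.channel_ids):
        x = rec.voltages[ci]
        sigma = (sigma_override or {}).get(chan) or robust_sigma(x)
        if sigma == 0:
            continue
        thr = -cfg.k_sigma * sigma
        below = x < thr
        crossings = np.nonzero(below[1:] & ~below[:-1])[0] + 1
        last_peak = -lockout - 1
        for c in crossings:
            if c <= last_peak + lockout:
                continue
            stop = min(c + lockout, x.size)
            peak = c + int(np.argmin(x[c:stop]))
            if peak <= last_peak + lockout:
                continue
            last_peak = peak
            wf = _extract_snippet(x, peak, pre, post)
            events.append(SpikeEvent(channel=chan, peak_sample=int(peak),
                                     peak_amplitude_uv=float(x[peak]),
                                     waveform=wf,
                                     window_ms=(cfg.snippet_pre_ms,
                                                cfg.snippet_post_ms)))
    events.sort(key=lambda e: (e.peak_sample, e.channel))
    return events


def reject_artifacts(events: list[SpikeEvent], cfg: DetectionConfig,
                     fs_hz: float
                     ) -> tuple[list[SpikeEvent], list[SpikeEvent], list[SpikeEvent]]:
    """Partition events into (kept, removed_amplitude, removed_motion).

    Amplitude rule: any snippet sample beyond +/- amp_limit_uv marks the
    event abnormal. Motion rule: events are single-linkage grouped in time
    (gap <= coincidence_window_ms between successive peaks); a group whose
    members span strictly more than ``coincidence_channels`` distinct
    channels is removed wholesale. The three output lists are disjoint and
    exhaustive.
    """
    removed_amp = [e for e in events
                   if np.max(np.abs(e.waveform)) > cfg.amp_limit_uv]
    remaining = [e for e in events
                 if np.max(np.abs(e.waveform)) <= cfg.amp_limit_uv]

    window = cfg.coincidence_window_ms * 1e-3 * fs_hz
    remaining.sort(key=lambda e: e.peak_sample)
    kept: list[SpikeEvent] = []
    removed_motion: list[SpikeEvent] = []
    group: list[SpikeEvent] = []

    def _flush(g: list[SpikeEvent]) -> None:
        chans = {e.channel for e in g}
        if len(chans) > cfg.coincidence_channels:
            removed_motion.extend(g)
        else:
            kept.extend(g)

    for e in remaining:
        if group and e.peak_sample - group[-1].peak_sample > window:
            _flush(group)
            group = []
        group.append(e)
    if group:
        _flush(group)
    kept.sort(key=lambda e: (e.peak_sample, e.channel))
    return kept, removed_amp, removed_motion


def impedance_qc(site_impedances_ohm, low_ohm: float = 1e5,
                 high_ohm: float = 1e6) -> ImpedanceReport:
    """Site-level 1 kHz impedance check: every site must lie in
    [100 kOhm, 1 MOhm] (inclusive) for the device to pass."""
    z = np.asarray(site_impedances_ohm, dtype=np.float64)
    if np.any(z <= 0):
        raise ValueError("impedances must be positive")
    site_pass = (z >= low_ohm) & (z <= high_ohm)
    return ImpedanceReport(impedances_ohm=z, site_pass=site_pass,
                           passed=bool(np.all(site_pass)))
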