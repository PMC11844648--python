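"""Per-unit recording-quality metrics and channel x phase aggregation.

Definitions follow the conventions of chronic-microelectrode studies:

* Vpp — peak-to-peak voltage of the unit's mean waveform (max - min), uV.
* Noise — RMS of the referenced, filtered channel signal after excising
  every detected-spike snippet window.
* SNR — Vpp divided by the channel noise RMS.
* Spike rate — inverse of the median inter-spike interval.

Units with Vpp below 40 uV are non-putative and excluded; SNR outliers are
removed with the ROUT procedure at Q = 5% in one global pass across all
treatments and phases before aggregation. Surviving units are averaged at
the individual-channel level within two study phases (weeks 1-4 and 5-8),
and units-per-active-channel divides the per-channel unit count by the
four weeks in a phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sorting import Unit

__all__ = [
    "UnitMetrics",
    "PUTATIVE_VPP_FLOOR_UV",
    "unit_vpp",
    "channel_noise_rms",
    "unit_snr",
    "unit_spike_rate",
    "filter_putative",
    "rout_outliers",
    "compute_unit_metrics",
    "aggregate_channel_phase",
    "PHASES",
]

PUTATIVE_VPP_FLOOR_UV = 40.0
PHASES = {"W1_4": (1, 2, 3, 4), "W5_8": (5, 6, 7, 8)}
WEEKS_PER_PHASE = 4


@dataclass
class UnitMetrics:
    vpp_uv: float
    noise_rms_uv: float
    snr: float
    spike_rate_hz: float | None  # None when < 2 spikes
    putative: bool = False
    snr_outlier: bool = False


def unit_vpp(mean_waveform: np.ndarray) -> float:
    """Absolute voltage range of the mean waveform: max - min, uV."""
    w = np.asarray(mean_waveform, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty waveform")
    return float(w.max() - w.min())


def channel_noise_rms(signal: np.ndarray, peak_samples, fs_hz: float,
                      pre_ms: float = 0.5, post_ms: float = 1.0) -> float:
    """RMS of a channel's signal outside all spike snippet windows.

    ``peak_samples`` are the detected event peaks on this channel; each
    excises [peak - pre_ms, peak + post_ms]. Raises if exclusion empties
    the record.
    """
    x = np.asarray(signal, dtype=np.float64)
    keep = np.ones(x.size, dtype=bool)
    pre = int(round(pre_ms * 1e-3 * fs_hz))
    post = int(round(post_ms * 1e-3 * fs_hz))
    for p in np.asarray(peak_samples, dtype=int).ravel():
        keep[max(p - pre, 0):min(p + post + 1, x.size)] = False
    if not keep.any():
        raise ValueError("spike exclusion removed every sample")
    return float(np.sqrt(np.mean(x[keep] ** 2)))


def unit_snr(vpp_uv: float, noise_rms_uv: float) -> float:
    if noise_rms_uv <= 0:
        raise ValueError("noise RMS must be positive")
    return vpp_uv / noise_rms_uv


def unit_spike_rate(spike_times_s: np.ndarray) -> float | None:
    """Inverse of the median inter-spike interval, Hz. With an even number
    of ISIs the median is the mean of the middle two. Undefined (None)
    below 2 spikes."""
    t = np.asarray(spike_times_s, dtype=np.float64)
    if t.size < 2:
        return None
    return float(1.0 / np.median(np.diff(t)))


def filter_putative(vpps_uv) -> np.ndarray:
    """Putative iff Vpp >= 40 uV (units with Vpp less than 40 uV are
    excluded; exactly 40 is retained)."""
    v = np.asarray(vpps_uv, dtype=np.float64)
    return v >= PUTATIVE_VPP_FLOOR_UV


def rout_outliers(values, q: float = 0.05) -> np.ndarray:
    """ROUT outlier flags for a single metric column (constant model).

    The robust-regression-and-outlier-removal procedure specialised to a
    constant fit: the robust center is the median; the robust residual
    scale (RSDR) is the 68.27th percentile of |residuals| inflated by
    n/(n-1); residual t-ratios get two-sided P values from Student t with
    n-1 df and are tested outermost-first with the Benjamini-Hochberg
    step-up at rate ``q`` — the j-th outermost point is compared against
    q*j/n and every point at least as extreme as the largest passing rank
    is flagged. Flags are returned in input order.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    flags = np.zeros(n, dtype=bool)
    if n < 3:
        warnings.warn("ROUT needs n >= 3; returning no flags")
        return flags
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        return flags
    t_ratio = np.abs(resid) / rsdr
    order = np.argsort(t_ratio)[::-1]  # outermost first, ascending P
    pvals = 2.0 * stats.t.sf(t_ratio[order], df=n - 1)
    ranks = np.arange(1, n + 1)
    passing = np.nonzero(pvals <= q * ranks / n)[0]
    if passing.size:
        flags[order[: passing[-1] + 1]] = True
    return flags


def compute_unit_metrics(units: list[Unit], noise_by_channel: dict[int, float],
                         rout_q: float = 0.05) -> pd.DataFrame:
    """Per-unit metric table with putative and SNR-outlier flags.

    ``noise_by_channel`` maps channel id -> spike-excised noise RMS for the
    unit's session. The ROUT pass runs once over all units pooled (across
    channels, weeks, groups), matching a single global outlier screen.
    """
    rows = []
    for i, u in enumerate(units):
        vpp = unit_vpp(u.mean_waveform)
        noise = noise_by_channel[u.channel]
        rate = unit_spike_rate(u.spike_times_s)
        rows.append({
            "unit_id": i, "group": u.group, "animal": u.animal,
            "week": u.week, "channel": u.channel, "n_spikes": u.n_spikes,
            "vpp_uv": vpp, "noise_uv": noise,
            "snr": unit_snr(vpp, noise), "rate_hz": rate,
            "verified": u.verified,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["putative"] = filter_putative(df["vpp_uv"].to_numpy())
    df["snr_outlier"] = rout_outliers(df["snr"].to_numpy(), q=rout_q)
    return df


def _phase_of(week: int) -> str:
    for name, weeks in PHASES.items():
        if week in weeks:
            return name
    raise ValueError(f"week {week} outside the 8-week study")


def aggregate_channel_phase(metrics: pd.DataFrame) -> pd.DataFrame:
    """Average qualifying units at the individual-channel level per phase.

    Qualifying units are putative, verified, non-outlier. A channel with no
    qualifying units in a phase contributes no row (active-channel
    definition). units_per_active_channel = unit count / 4 weeks; the
    spike-rate mean skips units with undefined rate (< 2 spikes), which
    still count toward the unit total.
    """
    required = {"channel", "week", "vpp_uv", "noise_uv", "snr", "rate_hz",
                "putative", "snr_outlier", "verified"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    df = metrics.copy()
    df["phase"] = df["week"].map(_phase_of)
    qual = df[df["putative"] & df["verified"] & ~df["snr_outlier"]]
    group_keys = [k for k in ("group", "animal") if k in qual.columns
                  and qual[k].notna().any()]
    keys = group_keys + ["channel", "phase"]
    out = []
    for key, g in qual.groupby(keys, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        row.update({
            "mean_vpp_uv": g["vpp_uv"].mean(),
            "mean_noise_uv": g["noise_uv"].mean(),
            "mean_snr": g["snr"].mean(),
            "mean_rate_hz": g["rate_hz"].dropna().mean(),
            "n_units": len(g),
            "units_per_active_channel": len(g) / WEEKS_PER_PHASE,
        })
        out.append(row)
    return pd.DataFrame(out)
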