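"""Per-channel clustering of retained spikes into candidate single units.

The proprietary "K-Means Scan" of commercial offline sorters is
re-expressed here as a reproducible open procedure: project peak-aligned
snippets onto the leading principal components, run seeded k-means for
k = 2..k_max, pick the k with the best mean silhouette if that maximum
clears a floor, otherwise keep one cluster. Manual unit verification is
replaced by an explicit rule (minimum spike count and a cap on sub-1-ms
inter-spike-interval violations); the flag is recorded so downstream
metrics can be recomputed under different rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .preproc import SpikeEvent

__all__ = ["Unit", "SortConfig", "extract_features", "kmeans_scan",
           "verify_units", "sort_channel", "sort_events"]


@dataclass
class SortConfig:
    n_pcs: int = 2
    k_max: int = 5
    silhouette_floor: float = 0.5
    seed: int = 0
    verify_min_spikes: int = 30
    verify_max_isi_violation: float = 0.05  # fraction of ISIs < 1 ms
    isi_violation_ms: float = 1.0
    # a human verifier rejects clusters whose mean waveform hugs the
    # detection threshold (threshold-riding noise); enforced only when the
    # caller supplies the per-channel noise sigma
    verify_min_trough_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not (0 < self.silhouette_floor < 1):
            raise ValueError("silhouette_floor must be in (0, 1)")


@dataclass
class Unit:
    channel: int
    spike_times_s: np.ndarray      # sorted, strictly increasing
    waveforms: np.ndarray          # n_spikes x n_samples, uV
    verified: bool = False
    week: int | None = None        # session tag used by aggregation
    animal: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=np.float64)
        if self.spike_times_s.size > 1 and np.any(
                np.diff(self.spike_times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size

    @property
    def mean_waveform(self) -> np.ndarray:
        return self.waveforms.mean(axis=0)


def extract_features(waveforms: np.ndarray, n_pcs: int = 2) -> np.ndarray:
    """Project peak-aligned snippets onto the first ``n_pcs`` principal
    components. Rows of the feature matrix correspond 1:1 to input order."""
    W = np.asarray(waveforms, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need at least 2 equal-length waveforms")
    n_pcs = min(n_pcs, W.shape[0], W.shape[1])
    if np.allclose(W, W[0]):  # zero total variance: PCA is degenerate
        return np.zeros((W.shape[0], n_pcs))
    pca = PCA(n_components=n_pcs, svd_solver="full")
    return pca.fit_transform(W)


def kmeans_scan(features: np.ndarray, cfg: SortConfig | None = None
                ) -> tuple[np.ndarray, int]:
    """Silhouette-selected seeded k-means.

    Runs k-means (10 restarts, fixed seed) for k = 2..k_max, scores each
    partition by mean silhouette, and keeps the best k if its silhouette
    reaches ``silhouette_floor``; otherwise all points form one cluster.
    Deterministic given the seed.
    """
    if cfg is None:
        cfg = SortConfig()
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 feature points")
    n = X.shape[0]
    k_max = cfg.k_max
    if k_max > n - 1:
        warnings.warn(f"k_max={cfg.k_max} clamped to n-1={n - 1}")
        k_max = n - 1
    # degenerate cloud: every point identical -> a single unit
    if np.allclose(X, X[0]):
        return np.zeros(n, dtype=int), 1

    best_labels, best_score, best_k = None, -np.inf, 1
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=cfg.seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        # subsampled silhouette keeps the scan O(n) on long sessions;
        # seeded, so the scan stays deterministic
        score = silhouette_score(X, labels,
                                 sample_size=min(2000, n),
                                 random_state=cfg.seed)
        if score > best_score:
            best_labels, best_score, best_k = labels, score, k
    if best_labels is None or best_score < cfg.silhouette_floor:
        return np.zeros(n, dtype=int), 1
    return best_labels, best_k


def verify_units(units: list[Unit], cfg: SortConfig | None = None,
                 sigma_by_channel: dict[int, float] | None = None
                 ) -> list[Unit]:
    """Rule-based stand-in for manual verification.

    A unit is verified iff it has >= verify_min_spikes spikes and its
    fraction of ISIs shorter than ``isi_violation_ms`` is at most
    ``verify_max_isi_violation``. When the per-channel noise sigma is
    supplied, a third rule mimics the amplitude judgement of a human
    verifier: the mean-waveform trough must reach
    ``verify_min_trough_sigma`` noise SDs, rejecting clusters of
    threshold-riding noise crossings.
    """
    if cfg is None:
        cfg = SortConfig()
    for u in units:
        if u.n_spikes < cfg.verify_min_spikes:
            u.verified = False
            continue
        isis = np.diff(u.spike_times_s)
        viol = np.mean(isis < cfg.isi_violation_ms * 1e-3) if isis.size else 0.0
        ok = viol <= cfg.verify_max_isi_violation
        if ok and sigma_by_channel is not None:
            sigma = sigma_by_channel.get(u.channel)
            if sigma:
                ok = abs(float(u.mean_waveform.min())) \
                    >= cfg.verify_min_trough_sigma * sigma
        u.verified = ok
    return units


def sort_channel(events: list[SpikeEvent], fs_hz: float,
                 cfg: SortConfig | None = None,
                 sigma_by_channel: dict[int, float] | None = None
                 ) -> list[Unit]:
    """Cluster one channel's kept events into units and verify them."""
    if cfg is None:
        cfg = SortConfig()
    if not events:
        return []
    chan = events[0].channel
    events = sorted(events, key=lambda e: e.peak_sample)
    W = np.vstack([e.waveform for e in events])
    times = np.array([e.peak_sample for e in events], dtype=np.float64) / fs_hz
    if len(events) < 2:
        labels = np.zeros(len(events), dtype=int)
    else:
        feats = extract_features(W, cfg.n_pcs)
        labels, _ = kmeans_scan(feats, cfg)
    units = []
    for lab in np.unique(labels):
        sel = labels == lab
        t = times[sel]
        # duplicate peak times cannot occur within a channel (lockout), but
        # guard against exact ties from merged inputs
        order = np.argsort(t, kind="stable")
        units.append(Unit(channel=chan, spike_times_s=t[order],
                          waveforms=W[sel][order]))
    return verify_units(units, cfg, sigma_by_channel)


def sort_events(events: list[SpikeEvent], fs_hz: float,
                cfg: SortConfig | None = None,
                sigma_by_channel: dict[int, float] | None = None
                ) -> list[Unit]:
    """Sort each channel independently (unit counts and metrics are
    reported per channel downstream)."""
    by_chan: dict[int, list[SpikeEvent]] = {}
    for e in events:
        by_chan.setdefault(e.channel, []).append(e)
    units: list[Unit] = []
    for chan in sorted(by_chan):
        units.extend(sort_channel(by_chan[chan], fs_hz, cfg,
                                  sigma_by_channel))
    return units
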