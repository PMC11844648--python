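"""Scoring detected events and recovered metrics against planted ground
truth from the simulators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preproc import SpikeEvent
from .synth import EphysGroundTruth

__all__ = ["EventScore", "score_events"]


@dataclass
class EventScore:
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def precision(self) -> float:
        return (self.n_matched / self.n_detected if self.n_detected
                else float("nan"))


def score_events(events: list[SpikeEvent], gt: EphysGroundTruth,
                 fs_hz: float, tol_ms: float = 0.2) -> EventScore:
    """Match detected events to planted spike times, channel by channel.

    A detected event matches an unmatched planted spike on the same
    channel if their peak times differ by at most ``tol_ms``; matching is
    greedy in time order, each planted spike used at most once.
    """
    tol = tol_ms * 1e-3
    truth: dict[int, np.ndarray] = {}
    for chan, times, _ in gt.units:
        truth[chan] = (np.sort(np.concatenate([truth[chan], times]))
                       if chan in truth else np.sort(times))
    n_true = sum(t.size for t in truth.values())
    used = {c: np.zeros(t.size, dtype=bool) for c, t in truth.items()}
    n_matched = 0
    for e in sorted(events, key=lambda ev: ev.peak_sample):
        t = e.peak_sample / fs_hz
        tt = truth.get(e.channel)
        if tt is None or tt.size == 0:
            continue
        i = int(np.argmin(np.abs(tt - t)))
        lo, hi = max(i - 2, 0), min(i + 3, tt.size)
        cand = [j for j in range(lo, hi)
                if not used[e.channel][j] and abs(tt[j] - t) <= tol]
        if cand:
            j = min(cand, key=lambda k: abs(tt[k] - t))
            used[e.channel][j] = True
            n_matched += 1
    return EventScore(n_true=n_true, n_detected=len(events),
                      n_matched=n_matched)
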