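"""Evoked-response dynamics: time-to-peak, window means, grand averages.

Time-to-peak (TTP) is the latency of the extremum of an electrode's
trial-mean HFB response inside +200..+1500 ms post-onset: the maximum for
activating networks (DAN, SN), the minimum for the deactivating DMN.
Pre-stimulus (-400..0 ms) and post-stimulus (+400..+1200 ms) window means
summarize the envelope around behavioral errors.  Windows are closed at
both bounds; the sample at t = 0 belongs to the pre-window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .localize import EpochSet

__all__ = ["TTPRecord", "WindowStat", "time_to_peak", "window_mean",
           "grand_average", "PRE_WINDOW_MS", "POST_WINDOW_MS"]

PRE_WINDOW_MS = (-400.0, 0.0)
POST_WINDOW_MS = (400.0, 1200.0)
TTP_WINDOW_MS = (200.0, 1500.0)


@dataclass(frozen=True)
class TTPRecord:
    channel: str
    ttp_ms: float
    peak: float
    sign: int
    degenerate: bool = False       # flat response; earliest sample returned


@dataclass
class WindowStat:
    channel: str
    window_ms: tuple[float, float]
    per_trial: np.ndarray
    mean: float


def time_to_peak(mean_response: np.ndarray, times_ms: np.ndarray,
                 sign: int, window_ms: tuple[float, float] = TTP_WINDOW_MS,
                 channel: str = "") -> TTPRecord:
    """Latency of the signed extremum of a trial-mean response.

    ``sign=+1`` finds the maximum, ``sign=-1`` the minimum, inside the
    closed ``window_ms``.  Ties break to the earliest sample; a flat
    response returns the earliest sample with ``degenerate=True``.
    """
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    mean_response = np.asarray(mean_response, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not np.any(sel):
        raise ValueError("response does not cover the search window")
    seg = mean_response[sel]
    seg_t = times_ms[sel]
    idx = int(np.argmax(sign * seg))      # argmax returns the earliest tie
    degenerate = bool(np.all(seg == seg[0]))
    return TTPRecord(channel=channel, ttp_ms=float(seg_t[idx]),
                     peak=float(seg[idx]), sign=sign, degenerate=degenerate)


def window_mean(epochs: EpochSet,
                window_ms: tuple[float, float]) -> WindowStat:
    """Per-trial mean of the envelope over a closed time window."""
    sel = (epochs.times_ms >= window_ms[0]) & (epochs.times_ms <= window_ms[1])
    if not np.any(sel):
        raise ValueError("window contains no epoch samples")
    per_trial = epochs.data[:, sel].mean(axis=1)
    return WindowStat(channel=epochs.channel, window_ms=tuple(window_ms),
                      per_trial=per_trial, mean=float(per_trial.mean()))


def grand_average(trial_means: list[np.ndarray]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SEM across electrodes of per-electrode trial-mean traces.

    With a single electrode the SEM is returned as zeros (degenerate).
    """
    if len(trial_means) == 0:
        raise ValueError("need at least one electrode")
    stack = np.vstack(trial_means)
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        return mean, np.zeros_like(mean)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return mean, sem
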