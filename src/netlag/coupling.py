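"""Continuous inter-electrode coupling of slow HFB envelope fluctuations.

Two run-level metrics per electrode pair quantify coordination of the
0.1-1 Hz filtered HFB power envelope:

* **zero-lag correlation** — Pearson r with no time shift;
* **lag-minimum correlation** — the most negative Pearson r over
  inter-electrode shifts of -2..+2 s, capturing temporally delayed
  anticorrelation that a zero-lag measure misses.

Correlations at each lag are computed on the truncated overlap of the two
series (no padding or circular wrap-around), each lag using its own overlap
mean and SD; values are Fisher r-to-z transformed and, when a subject has
several runs, averaged on the z scale.  The first 20 s of every run (the
pre-task fixation baseline, or the start of a rest run) are discarded, and
the slow-band envelope is decimated to a few Hz before the lag scan —
well above twice the 1 Hz band edge — so that one envelope sample is the
lag resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["CouplingResult", "slow_bandpass", "lagged_crosscorr",
           "zero_lag", "lag_minimum", "fisher_z", "run_coupling",
           "average_runs"]

SLOW_BAND = (0.1, 1.0)
TRIM_S = 20.0
MAX_LAG_S = 2.0
COUPLING_ENVELOPE_HZ = 10.0


@dataclass
class CouplingResult:
    """Coupling metrics for one electrode pair in one run (or run average)."""

    ch_i: str
    ch_j: str
    condition: str
    run_id: str
    zero_lag_r: float
    zero_lag_z: float
    lag_min_r: float
    lag_min_z: float
    lag_at_min_s: float
    band: tuple[float, float] | None
    fs_env: float


def slow_bandpass(env: np.ndarray, fs: float,
                  band: tuple[float, float] = SLOW_BAND,
                  trim_s: float = TRIM_S,
                  decimate_to: float | None = COUPLING_ENVELOPE_HZ,
                  order: int = 4) -> tuple[np.ndarray, float]:
    """Trim the lead-in, band-pass the envelope, and decimate.

    Zero-phase 4th-order Butterworth band-pass (default 0.1-1 Hz) after
    removing the first ``trim_s`` seconds.  ``decimate_to`` picks the output
    rate (must exceed twice the upper band edge; ``None`` keeps the input
    rate).  Returns ``(filtered, fs_out)``.
    """
    env = np.asarray(env, dtype=float)
    if env.ndim != 1:
        raise ValueError("slow_bandpass expects a 1-D envelope")
    i0 = int(round(trim_s * fs))
    env = env[i0:]
    if len(env) < 30 * fs:
        raise ValueError("record shorter than 30 s after the lead-in trim")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, env)
    fs_out = fs
    if decimate_to is not None and decimate_to < fs:
        if decimate_to < 2 * band[1]:
            raise ValueError("decimate_to must exceed twice the upper band edge")
        step = int(round(fs / decimate_to))
        out = out[::step]
        fs_out = fs / step
    return out, fs_out


def lagged_crosscorr(x: np.ndarray, y: np.ndarray, fs: float,
                     max_lag_s: float = MAX_LAG_S
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of two series at every integer-sample shift.

    Positive lag means ``y`` is shifted later relative to ``x``
    (r(tau) = corr(x[t], y[t + tau])), so a process that reaches ``y`` a
    delay ``d`` after ``x`` produces a correlation extremum at ``tau = d``.
    Each lag's r is computed on the truncated overlap with that overlap's
    own mean and SD.  Zero-variance overlaps yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    n = len(x)
    lag_n = int(round(max_lag_s * fs))
    if lag_n >= n / 4:
        raise ValueError("max lag must be below a quarter of the duration")
    c = signal.correlate(y, x, mode="full", method="fft")  # c[n-1+tau]=sum x_i y_{i+tau}
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    lags = np.arange(-lag_n, lag_n + 1)
    r = np.empty(len(lags))
    for ii, tau in enumerate(lags):
        if tau >= 0:
            m = n - tau
            sx, sxx = cx[m], cx2[m]
            sy, syy = cy[n] - cy[tau], cy2[n] - cy2[tau]
        else:
            u = -tau
            m = n - u
            sx, sxx = cx[n] - cx[u], cx2[n] - cx2[u]
            sy, syy = cy[m], cy2[m]
        num = c[n - 1 + tau] - sx * sy / m
        var = (sxx - sx * sx / m) * (syy - sy * sy / m)
        r[ii] = num / np.sqrt(var) if var > 0 else np.nan
    return lags / fs, r


def zero_lag(lags_s: np.ndarray, r: np.ndarray) -> float:
    """r at lag zero."""
    idx = int(np.argmin(np.abs(lags_s)))
    if abs(lags_s[idx]) > 1e-12:
        raise ValueError("lag grid does not contain zero")
    return float(r[idx])


def lag_minimum(lags_s: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Global minimum of the correlation-by-lag curve.

    Ties (within 1e-12) break to the smallest |lag|, then to the negative
    lag.  Returns ``(r_min, lag_at_min)``.
    """
    finite = np.isfinite(r)
    if not finite.any():
        raise ValueError("correlation curve is entirely undefined")
    rmin = np.min(r[finite])
    cand = np.nonzero(finite & (r <= rmin + 1e-12))[0]
    # sort candidates by (|lag|, sign) with negative preferred at equal |lag|
    order = sorted(cand, key=lambda i: (abs(lags_s[i]), lags_s[i] > 0))
    i = order[0]
    return float(r[i]), float(lags_s[i])


def fisher_z(r: float) -> float:
    """Variance-stabilizing Fisher transform atanh(r); |r| at (or within
    numerical noise of) 1 is clipped to +/-(1 - 1e-6) with a warning."""
    if abs(r) >= 1.0 - 1e-9:
        warnings.warn("correlation at or beyond +/-1 clipped before Fisher z",
                      RuntimeWarning, stacklevel=2)
        r = np.sign(r) * (1.0 - 1e-6)
    return float(np.arctanh(r))


def run_coupling(env_i: np.ndarray, env_j: np.ndarray, fs: float,
                 ch_i: str = "i", ch_j: str = "j",
                 condition: str = "task", run_id: str = "run-01",
                 band: tuple[float, float] | None = SLOW_BAND,
                 trim_s: float = TRIM_S, max_lag_s: float = MAX_LAG_S,
                 decimate_to: float | None = COUPLING_ENVELOPE_HZ
                 ) -> CouplingResult:
    """Full per-pair, per-run coupling computation.

    ``band=None`` runs the unfiltered variant (trim and decimation still
    apply, using the default slow band's output rate).
    """
    if band is not None:
        xi, fs_env = slow_bandpass(env_i, fs, band, trim_s, decimate_to)
        xj, _ = slow_bandpass(env_j, fs, band, trim_s, decimate_to)
    else:
        i0 = int(round(trim_s * fs))
        xi, xj = env_i[i0:], env_j[i0:]
        fs_env = fs
        if decimate_to is not None and decimate_to < fs:
            step = int(round(fs / decimate_to))
            # guard aliasing of the raw envelope with a light low-pass
            sos = signal.butter(4, 0.4 * fs / step, btype="lowpass", fs=fs,
                                output="sos")
            xi = signal.sosfiltfilt(sos, xi)[::step]
            xj = signal.sosfiltfilt(sos, xj)[::step]
            fs_env = fs / step
        if len(xi) < 30 * fs_env:
            raise ValueError("record shorter than 30 s after the lead-in trim")
    lags, r = lagged_crosscorr(xi, xj, fs_env, max_lag_s)
    r0 = zero_lag(lags, r)
    rmin, lag_at_min = lag_minimum(lags, r)
    return CouplingResult(
        ch_i=ch_i, ch_j=ch_j, condition=condition, run_id=run_id,
        zero_lag_r=r0, zero_lag_z=fisher_z(r0),
        lag_min_r=rmin, lag_min_z=fisher_z(rmin),
        lag_at_min_s=lag_at_min, band=band, fs_env=fs_env)


def average_runs(results: list[CouplingResult]) -> CouplingResult:
    """Average coupling across runs of one pair on the Fisher-z scale."""
    if not results:
        raise ValueError("no runs to average")
    first = results[0]
    z0 = float(np.mean([r.zero_lag_z for r in results]))
    zmin = float(np.mean([r.lag_min_z for r in results]))
    return CouplingResult(
        ch_i=first.ch_i, ch_j=first.ch_j, condition=first.condition,
        run_id="average", zero_lag_r=float(np.tanh(z0)), zero_lag_z=z0,
        lag_min_r=float(np.tanh(zmin)), lag_min_z=zmin,
        lag_at_min_s=float(np.mean([r.lag_at_min_s for r in results])),
        band=first.band, fs_env=first.fs_env)
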