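"""Synthetic GradCPT sessions and intracranial recordings with known ground truth.

The generator emulates the study conditions of a gradual-onset continuous
performance task (GradCPT) recorded with intracranial EEG:

* stimulus streams of city/mountain scenes cross-fading every 800 ms, with
  rare (10%) mountain targets that never repeat on consecutive trials;
* button-press behavior with configurable lapse (commission-error) and
  omission probabilities;
* multichannel recordings containing a 1/f background, power-line noise,
  a 70-170 Hz high-frequency-broadband (HFB) carrier whose envelope carries
  signed task-evoked responses (increases in dorsal-attention / salience
  channels, decreases in default-mode channels) peaking at network-specific
  latencies, slow (0.1-1 Hz) envelope fluctuations with configurable lagged
  (anti)correlation between channel pairs, and injected artifacts
  (high-variance channels, sample-to-sample jump spikes).

Every stochastic quantity is a deterministic function of (config, seed), so
downstream stages can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "StimulusSequence",
    "ChannelEffect",
    "PairCoupling",
    "NoiseSpec",
    "GroundTruth",
    "Recording",
    "make_stimulus_sequence",
    "simulate_behavior",
    "simulate_recording",
    "band_limited_noise",
    "one_over_f_noise",
    "simulate_epoch_ensemble",
    "simulate_envelope_pair",
    "simulate_coupled_envelopes",
]

CITY = "city"
MOUNTAIN = "mountain"


@dataclass(frozen=True)
class StimulusSequence:
    """A GradCPT run: trial onsets and scene categories.

    Onsets are uniformly spaced at the transition duration (default 800 ms).
    Mountains (targets) are never adjacent.
    """

    run_id: str
    onsets: np.ndarray          # seconds, strictly increasing
    categories: np.ndarray      # "city" | "mountain" per trial
    transition_ms: float = 800.0
    mountain_rate: float = 0.1

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def duration(self) -> float:
        """Total run duration in seconds (one transition per trial)."""
        return float(self.onsets[-1] + self.transition_ms / 1000.0)

    def __post_init__(self):
        if len(self.onsets) != len(self.categories):
            raise ValueError("onsets and categories must have equal length")


@dataclass(frozen=True)
class ChannelEffect:
    """Ground-truth evoked response for one channel.

    The response is a Gaussian bump on the HFB envelope: ``sign * amplitude``
    (normalized power units) centered ``ttp_ms`` after target onset, with
    full-width-at-half-maximum ``width_ms``.  ``err_pre_amp`` adds a
    pre-onset bump (centered -200 ms) on commission-error trials only;
    ``err_post_gain`` scales the evoked bump on commission-error trials.
    """

    channel: str
    network: str                 # "DAN" | "SN" | "DMN" | "none"
    sign: int = 0                # +1 (activation), -1 (deactivation), 0 (null)
    amplitude: float = 0.0       # envelope modulation depth (fractional)
    ttp_ms: float = 500.0
    width_ms: float = 400.0      # FWHM of the evoked bump
    err_pre_amp: float = 0.0
    err_post_gain: float = 1.0

    def __post_init__(self):
        if self.sign not in (-1, 0, 1):
            raise ValueError("sign must be -1, 0 or +1")
        if self.sign != 0 and not (200.0 < self.ttp_ms < 1500.0):
            raise ValueError("ttp_ms must lie inside (200, 1500) ms")


@dataclass(frozen=True)
class PairCoupling:
    """Ground-truth slow-envelope coupling for one channel pair.

    The channels share a band-limited (``band`` Hz) latent envelope signal;
    the copy in ``ch_j`` is delayed by ``lag_s`` seconds and scaled so that
    the correlation between the two slow envelope components at the
    generative lag equals ``r_target`` (sign included).
    """

    ch_i: str
    ch_j: str
    r_target: float
    lag_s: float = 0.0
    band: tuple[float, float] = (0.1, 1.0)

    def __post_init__(self):
        if abs(self.r_target) > 1:
            raise ValueError("|r_target| must be <= 1")
        if abs(self.lag_s) > 2:
            raise ValueError("|lag_s| must be <= 2 s")


@dataclass(frozen=True)
class NoiseSpec:
    """Background and artifact model for synthetic recordings."""

    exponent: float = 2.0          # PSD ~ f**-exponent
    background_rms_uv: float = 20.0
    line_freq: float = 60.0
    line_amp_uv: float = 5.0
    bad_channels: tuple[str, ...] = ()
    bad_variance_multiplier: float = 30.0   # must exceed 5x to trip the QC rule
    spike_rate_per_min: float = 0.0
    spike_amp_uv: float = 150.0
    spike_channels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.exponent < 0:
            raise ValueError("1/f exponent must be >= 0")
        if self.spike_rate_per_min < 0:
            raise ValueError("spike rate must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows, for parameter-recovery testing."""

    seed: int | None = None
    outcomes: np.ndarray | None = None        # per trial, behavior-module labels
    rts: np.ndarray | None = None             # per trial, assigned true RT or nan
    channel_sign: dict[str, int] = field(default_factory=dict)
    channel_ttp_ms: dict[str, float] = field(default_factory=dict)
    pair_lag_s: dict[tuple[str, str], float] = field(default_factory=dict)
    pair_r: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class Recording:
    """A channel x sample recording with sampling-rate metadata."""

    data: np.ndarray               # (n_channels, n_samples), microvolts
    fs: float
    channels: list[str]
    condition: str = "task"        # "task" | "rest"
    run_id: str = "run-01"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.channels),
                         self.condition, self.run_id)


# ---------------------------------------------------------------------------
# stimulus sequence


def make_stimulus_sequence(n_trials: int, mountain_rate: float = 0.1,
                           transition_ms: float = 800.0, seed: int = 0,
                           run_id: str = "run-01") -> StimulusSequence:
    """Generate a GradCPT trial sequence.

    Mountain targets are placed uniformly at random among all subsets of
    ``round(n_trials * mountain_rate)`` non-adjacent positions, emulating the
    task rule that the same (rare) scene cannot repeat on consecutive trials.
    Onsets fall at ``k * transition_ms``.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if not 0.0 < mountain_rate < 0.5:
        raise ValueError("mountain_rate must lie in (0, 0.5)")
    n_mountain = int(round(n_trials * mountain_rate))
    if n_mountain > (n_trials + 1) // 2:
        raise ValueError("too many mountains to avoid adjacency")
    rng = np.random.default_rng(seed)
    # Uniform sample of k non-adjacent positions out of n via the standard
    # bijection with k-subsets of n-k+1.
    if n_mountain > 0:
        picks = np.sort(rng.choice(n_trials - n_mountain + 1, size=n_mountain,
                                   replace=False))
        positions = picks + np.arange(n_mountain)
    else:
        positions = np.array([], dtype=int)
    categories = np.full(n_trials, CITY, dtype=object)
    categories[positions] = MOUNTAIN
    onsets = np.arange(n_trials) * transition_ms / 1000.0
    return StimulusSequence(run_id=run_id, onsets=onsets,
                            categories=np.asarray(categories),
                            transition_ms=transition_ms,
                            mountain_rate=mountain_rate)


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(seq: StimulusSequence, rt_mean: float = 0.70,
                      rt_sd: float = 0.15, lapse_rate: float = 0.25,
                      omission_rate: float = 0.03,
                      seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Simulate button presses for a GradCPT run.

    Cities receive a press with probability ``1 - omission_rate``; mountains
    receive an (erroneous) press with probability ``lapse_rate``.  Lapses are
    independent Bernoulli events per mountain.  Reaction times are normal
    (``rt_mean``, ``rt_sd``) seconds from trial onset.  The defaults place
    the cohort near the observed error rates of clinical GradCPT sessions
    (~3% omissions, ~25% commissions) with a realistic RT distribution.

    Returns sorted press times and a :class:`GroundTruth` with per-trial
    outcome labels (behavior-module vocabulary).
    """
    if not (0.0 <= lapse_rate <= 1.0 and 0.0 <= omission_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    trial_window = seq.transition_ms / 1000.0 + 0.4 * 0.4  # fade-in is 400 ms
    from scipy.stats import norm
    inside = norm.cdf(trial_window, rt_mean, rt_sd) - norm.cdf(0.0, rt_mean, rt_sd)
    if inside < 0.5:
        raise ValueError(
            "RT distribution places more than half its mass outside the "
            f"[0, {trial_window:.2f}] s trial window")
    rng = np.random.default_rng(seed)
    n = seq.n_trials
    outcomes = np.empty(n, dtype=object)
    rts = np.full(n, np.nan)
    presses = []
    for k in range(n):
        rt = float(np.clip(rng.normal(rt_mean, rt_sd), 0.05, trial_window - 1e-3))
        if seq.categories[k] == CITY:
            if rng.random() < omission_rate:
                outcomes[k] = "omission_error"
            else:
                outcomes[k] = "correct_commission"
                rts[k] = rt
                presses.append(seq.onsets[k] + rt)
        else:
            if rng.random() < lapse_rate:
                outcomes[k] = "commission_error"
                rts[k] = rt
                presses.append(seq.onsets[k] + rt)
            else:
                outcomes[k] = "correct_omission"
    truth = GroundTruth(seed=seed, outcomes=outcomes, rts=rts)
    return np.sort(np.asarray(presses, dtype=float)), truth


# ---------------------------------------------------------------------------
# noise primitives


def _fft_band_noise(n: int, fs: float, lo: float, hi: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise whose spectrum is confined to [lo, hi] Hz."""
    spec = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    freqs = np.fft.fftfreq(n, 1.0 / fs)
    mask = (np.abs(freqs) >= lo) & (np.abs(freqs) <= hi)
    spec[~mask] = 0.0
    x = np.real(np.fft.ifft(spec))
    sd = x.std()
    if sd == 0:
        raise ValueError("band contains no FFT bins at this length/rate")
    return x / sd


def band_limited_noise(n: int, fs: float, lo: float, hi: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Public wrapper: unit-variance noise band-limited to [lo, hi] Hz."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _fft_band_noise(n, fs, lo, hi, rng)


def one_over_f_noise(n: int, fs: float, exponent: float,
                     seed: int | np.random.Generator = 0,
                     f_min: float = 0.05) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ f**-exponent.

    Below ``f_min`` the spectrum is flattened to keep the variance finite.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    freqs = np.abs(np.fft.fftfreq(n, 1.0 / fs))
    shaped = np.maximum(freqs, f_min) ** (-exponent / 2.0)
    shaped[freqs == 0] = 0.0
    x = np.real(np.fft.ifft(spec * shaped))
    return x / x.std()


def _hfb_carrier(n: int, fs: float, rng: np.random.Generator,
                 band: tuple[float, float] = (70.0, 170.0)) -> np.ndarray:
    return _fft_band_noise(n, fs, band[0], band[1], rng)


# ---------------------------------------------------------------------------
# recording synthesis


def _evoked_modulation(seq: StimulusSequence, outcomes: np.ndarray,
                       eff: ChannelEffect, t: np.ndarray) -> np.ndarray:
    """Fractional HFB-envelope modulation from task-evoked responses."""
    mod = np.zeros_like(t)
    if eff.sign == 0:
        return mod
    sigma = eff.width_ms / 1000.0 / 2.355  # FWHM -> SD
    for k in range(seq.n_trials):
        if seq.categories[k] != MOUNTAIN:
            continue
        onset = seq.onsets[k]
        amp = eff.sign * eff.amplitude
        is_err = outcomes is not None and outcomes[k] == "commission_error"
        if is_err:
            amp = amp * eff.err_post_gain
        # Gaussian bump at onset + ttp (evaluated on a local window only)
        center = onset + eff.ttp_ms / 1000.0
        win = np.abs(t - center) < 5 * sigma
        mod[win] += amp * np.exp(-0.5 * ((t[win] - center) / sigma) ** 2)
        if is_err and eff.err_pre_amp != 0.0:
            pre_center = onset - 0.2
            pre_sigma = 0.15
            winp = np.abs(t - pre_center) < 5 * pre_sigma
            mod[winp] += eff.err_pre_amp * np.exp(
                -0.5 * ((t[winp] - pre_center) / pre_sigma) ** 2)
    return mod


def simulate_recording(seq: StimulusSequence | None,
                       outcomes: GroundTruth | None,
                       effects: list[ChannelEffect],
                       coupling: list[PairCoupling] = (),
                       noise: NoiseSpec = NoiseSpec(),
                       fs: float = 1000.0,
                       seed: int = 0,
                       duration: float | None = None,
                       slow_mod_depth: float = 0.4,
                       hfb_base_uv: float = 8.0,
                       condition: str = "task",
                       run_id: str = "run-01",
                       pre_task_s: float = 0.0) -> tuple[Recording, GroundTruth]:
    """Synthesize a multichannel recording with known evoked and coupling truth.

    The signal model per channel is::

        x(t) = background_1/f(t) + line(t) + artifacts(t)
             + hfb_base * (1 + evoked(t) + slow_mod_depth * slow(t)) * carrier(t)

    where ``carrier`` is unit-variance 70-170 Hz noise, ``evoked`` the signed
    Gaussian bumps of the channel's :class:`ChannelEffect`, and ``slow`` a
    unit-variance 0.1-1 Hz process.  Channels named in a
    :class:`PairCoupling` share a latent slow process, one copy delayed by
    the generative lag and scaled/signed to reach the target correlation.

    ``pre_task_s`` prepends a stimulus-free baseline (the 20 s fixation
    period of real sessions) before the first trial onset; trial onsets in
    ``seq`` remain relative to task start, and the returned recording starts
    at ``-pre_task_s``.

    Returns the recording and a :class:`GroundTruth` carrying the channel
    signs/latencies and pair lags/correlations.
    """
    if fs < 500:
        raise ValueError("fs must be >= 500 Hz so the HFB band is below Nyquist")
    if seq is not None:
        task_dur = seq.duration + 1.0
    elif duration is not None:
        task_dur = duration
    else:
        raise ValueError("need a stimulus sequence or an explicit duration")
    total = task_dur + pre_task_s
    n = int(round(total * fs))
    t = np.arange(n) / fs - pre_task_s   # time relative to task start
    channels = [e.channel for e in effects]
    if len(set(channels)) != len(channels):
        raise ValueError("duplicate channel ids in effects")
    for pc in coupling:
        if pc.ch_i not in channels or pc.ch_j not in channels:
            raise ValueError(f"coupling pair ({pc.ch_i}, {pc.ch_j}) references "
                             "unknown channel")
    rng = np.random.default_rng(seed)
    out_labels = outcomes.outcomes if outcomes is not None else None

    # Slow (0.1-1 Hz) envelope processes, with shared latents for coupled pairs.
    slow = {ch: None for ch in channels}
    truth = GroundTruth(seed=seed,
                        outcomes=out_labels,
                        rts=outcomes.rts if outcomes is not None else None)
    for pc in coupling:
        latent = _fft_band_noise(n, fs, pc.band[0], pc.band[1], rng)
        a = np.sqrt(abs(pc.r_target))
        b = np.sqrt(1.0 - abs(pc.r_target))
        ni = _fft_band_noise(n, fs, pc.band[0], pc.band[1], rng)
        nj = _fft_band_noise(n, fs, pc.band[0], pc.band[1], rng)
        shift = int(round(pc.lag_s * fs))
        delayed = np.roll(latent, shift)
        s = np.sign(pc.r_target) if pc.r_target != 0 else 1.0
        slow[pc.ch_i] = a * latent + b * ni
        slow[pc.ch_j] = s * a * delayed + b * nj
        truth.pair_lag_s[(pc.ch_i, pc.ch_j)] = pc.lag_s
        truth.pair_r[(pc.ch_i, pc.ch_j)] = pc.r_target
    for ch in channels:
        if slow[ch] is None:
            slow[ch] = _fft_band_noise(n, fs, 0.1, 1.0, rng)

    data = np.empty((len(channels), n))
    for idx, eff in enumerate(effects):
        ch = eff.channel
        bg = noise.background_rms_uv * one_over_f_noise(n, fs, noise.exponent, rng)
        phase = rng.uniform(0, 2 * np.pi)
        line = noise.line_amp_uv * np.sin(2 * np.pi * noise.line_freq * t + phase)
        carrier = _hfb_carrier(n, fs, rng)
        if seq is not None and eff.sign != 0:
            evoked = _evoked_modulation(seq, out_labels, eff, t)
        else:
            evoked = 0.0
        envelope = 1.0 + evoked + slow_mod_depth * slow[ch]
        envelope = np.maximum(envelope, 0.05)
        x = bg + line + hfb_base_uv * envelope * carrier
        if ch in noise.spike_channels and noise.spike_rate_per_min > 0:
            n_spikes = rng.poisson(noise.spike_rate_per_min * total / 60.0)
            locs = rng.integers(1, n - 2, size=n_spikes)
            for loc in locs:
                pol = rng.choice([-1.0, 1.0])
                x[loc] += pol * noise.spike_amp_uv
                x[loc + 1] -= pol * noise.spike_amp_uv
        if ch in noise.bad_channels:
            x = x * np.sqrt(noise.bad_variance_multiplier)
        data[idx] = x
        truth.channel_sign[ch] = eff.sign
        truth.channel_ttp_ms[ch] = eff.ttp_ms if eff.sign != 0 else np.nan
    rec = Recording(data=data, fs=fs, channels=channels,
                    condition=condition, run_id=run_id)
    return rec, truth


# ---------------------------------------------------------------------------
# envelope-level generators (cohort-scale fast paths)


def simulate_epoch_ensemble(n_trials: int, fs_env: float, t_start: float,
                            t_stop: float, ttp_ms: float, sign: int,
                            amplitude: float, width_ms: float = 400.0,
                            noise_sd: float = 1.0, noise_tau_s: float = 0.15,
                            seed: int | np.random.Generator = 0,
                            err_pre_amp: float = 0.0,
                            n_err: int = 0) -> np.ndarray:
    """Trial x time epochs of a normalized HFB envelope, generated directly.

    Each epoch is a signed Gaussian bump (center ``ttp_ms`` post-onset, FWHM
    ``width_ms``) plus temporally smooth Gaussian noise (AR-like, correlation
    time ``noise_tau_s``), mimicking a wavelet HFB envelope without paying for
    the raw-signal synthesis; used for cohort-scale recovery studies.  The
    last ``n_err`` trials additionally receive a pre-onset bump of amplitude
    ``err_pre_amp`` (commission-error precursor).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_t = int(round((t_stop - t_start) * fs_env))
    tt = t_start + np.arange(n_t) / fs_env
    sigma = width_ms / 1000.0 / 2.355
    bump = sign * amplitude * np.exp(-0.5 * ((tt - ttp_ms / 1000.0) / sigma) ** 2)
    # smooth noise: white noise convolved with a Gaussian kernel, unit SD
    n_k = max(3, int(round(6 * noise_tau_s * fs_env)) | 1)
    k = signal.windows.gaussian(n_k, noise_tau_s * fs_env)
    k /= np.sqrt(np.sum(k ** 2))
    white = rng.standard_normal((n_trials, n_t + n_k))
    smooth = signal.fftconvolve(white, k[None, :], mode="same", axes=1)[:, n_k // 2:
                                                                        n_k // 2 + n_t]
    epochs = bump[None, :] + noise_sd * smooth
    if n_err > 0 and err_pre_amp != 0.0:
        pre = err_pre_amp * np.exp(-0.5 * ((tt + 0.2) / 0.15) ** 2)
        epochs[-n_err:] += pre[None, :]
    return epochs


def simulate_envelope_pair(duration: float, fs_env: float, r_target: float,
                           lag_s: float, band: tuple[float, float] = (0.1, 1.0),
                           noise_frac: float = 0.0,
                           seed: int | np.random.Generator = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Directly generate a pair of slow HFB envelopes with known lagged coupling.

    Equivalent in structure to the slow components injected by
    :func:`simulate_recording`, but skipping the carrier/wavelet round trip.
    ``noise_frac`` adds broadband envelope noise on top of the slow process
    (fraction of the slow process SD).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs_env))
    latent = _fft_band_noise(n, fs_env, band[0], band[1], rng)
    a = np.sqrt(abs(r_target))
    b = np.sqrt(1.0 - abs(r_target))
    s = np.sign(r_target) if r_target != 0 else 1.0
    x = a * latent + b * _fft_band_noise(n, fs_env, band[0], band[1], rng)
    y = s * a * np.roll(latent, int(round(lag_s * fs_env))) + \
        b * _fft_band_noise(n, fs_env, band[0], band[1], rng)
    if noise_frac > 0:
        x = x + noise_frac * rng.standard_normal(n)
        y = y + noise_frac * rng.standard_normal(n)
    return x, y


def simulate_coupled_envelopes(duration: float, fs_env: float,
                               zero_r: float, lag_r: float, lag_s: float,
                               band: tuple[float, float] = (0.1, 1.0),
                               seed: int | np.random.Generator = 0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Envelope pair with separately controlled zero-lag and lagged coupling.

    Two shared latents drive the pair: one aligned (contributing the
    zero-lag correlation ``zero_r``) and one delayed by ``lag_s`` in the
    second channel (contributing correlation ``lag_r`` at that lag).  The
    construction lets task-like and rest-like conditions differ in lagged
    coupling while keeping the instantaneous component fixed.
    Requires |zero_r| + |lag_r| <= 1.
    """
    c0, c1 = abs(zero_r), abs(lag_r)
    if c0 + c1 > 1:
        raise ValueError("|zero_r| + |lag_r| must be <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs_env))
    l0 = _fft_band_noise(n, fs_env, band[0], band[1], rng)
    l1 = _fft_band_noise(n, fs_env, band[0], band[1], rng)
    nx = _fft_band_noise(n, fs_env, band[0], band[1], rng)
    ny = _fft_band_noise(n, fs_env, band[0], band[1], rng)
    rest = np.sqrt(1.0 - c0 - c1)
    x = np.sqrt(c0) * l0 + np.sqrt(c1) * l1 + rest * nx
    y = np.sign(zero_r) * np.sqrt(c0) * l0 + \
        np.sign(lag_r) * np.sqrt(c1) * np.roll(l1, int(round(lag_s * fs_env))) + \
        rest * ny
    return x, y
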