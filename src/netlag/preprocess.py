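"""Raw recording -> normalized seven-band power-amplitude envelopes.

Pipeline order (enforced by :func:`preprocess_run`):

    crop -> notch -> channel QC / common-average reference -> Morlet
    wavelet decomposition -> log-ratio normalization -> band averaging ->
    (optional) Gaussian smoothing

The time-frequency decomposition uses Morlet wavelets at 38 log-spaced
center frequencies between 1 and 170 Hz.  Power amplitudes are normalized
*per frequency* by the log ratio against the whole-run mean (which removes
the 1/f spectral decline) before averaging into seven canonical bands:
delta 1-3, theta 4-7, alpha 8-12, beta1 13-29, beta2 30-39, gamma 40-70 and
high-frequency broadband (HFB) 70-170 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .synth import Recording

__all__ = [
    "BAND_TABLE", "BAND_ORDER", "ChannelQC", "BandEnvelope",
    "morlet_frequencies", "notch_filter", "qc_channels",
    "common_average_reference", "wavelet_power", "lognorm", "band_average",
    "smooth_envelope", "preprocess_run",
]

BAND_TABLE: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta1": (13.0, 29.0),
    "beta2": (30.0, 39.0),
    "gamma": (40.0, 70.0),
    "hfb": (70.0, 170.0),
}
BAND_ORDER = tuple(BAND_TABLE)

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))   # ~2.355


def morlet_frequencies(n: int = 38, f_min: float = 1.0,
                       f_max: float = 170.0) -> np.ndarray:
    """Log-spaced Morlet center frequencies (default 38 values, 1-170 Hz)."""
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


@dataclass
class ChannelQC:
    """Per-channel exclusion decisions for the common average.

    Rules: (a) clinician-listed pathological channels; (b) manually listed
    spectral outliers; (c) variance above 5x or below 1/5x the median
    channel variance; (d) more than 3x the median count of >100 microvolt
    sample-to-sample jumps.
    """

    channels: list[str]
    variance: np.ndarray
    jump_count: np.ndarray
    excluded: np.ndarray                    # bool per channel
    reasons: list[tuple[str, ...]] = field(default_factory=list)

    def included(self) -> np.ndarray:
        return ~self.excluded


@dataclass
class BandEnvelope:
    """Normalized power-amplitude time series per channel and band."""

    data: np.ndarray               # (n_channels, n_bands, n_samples)
    fs: float
    channels: list[str]
    bands: tuple[str, ...]
    valid: np.ndarray | None = None   # bool per sample; False near edges
    condition: str = "task"
    run_id: str = "run-01"

    def band(self, name: str) -> np.ndarray:
        """(n_channels, n_samples) envelope of one band."""
        return self.data[:, self.bands.index(name), :]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------


def notch_filter(rec: Recording, line_freq: float = 60.0,
                 n_harmonics: int = 3, half_width: float = 3.0,
                 order: int = 3) -> Recording:
    """Zero-phase Butterworth band-stop at the line frequency and harmonics.

    Defaults reproduce stops at 57-63, 117-123 and 177-183 Hz for 60 Hz
    mains (use ``line_freq=50`` for 50 Hz systems).
    """
    nyq = rec.fs / 2.0
    top = n_harmonics * line_freq + half_width
    if top >= nyq:
        raise ValueError(
            f"highest requested stop band ({top:g} Hz) reaches Nyquist "
            f"({nyq:g} Hz); lower n_harmonics or raise fs")
    out = rec.data.astype(float, copy=True)
    for h in range(1, n_harmonics + 1):
        f0 = h * line_freq
        sos = signal.butter(order, [f0 - half_width, f0 + half_width],
                            btype="bandstop", fs=rec.fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=1)
    return Recording(out, rec.fs, list(rec.channels), rec.condition, rec.run_id)


def qc_channels(rec: Recording, pathology_list: tuple[str, ...] = (),
                manual_list: tuple[str, ...] = (),
                jump_uv: float = 100.0) -> ChannelQC:
    """Flag channels to exclude from the common average reference."""
    if rec.n_channels < 3:
        raise ValueError("channel QC needs at least 3 channels")
    var = rec.data.var(axis=1)
    jumps = np.sum(np.abs(np.diff(rec.data, axis=1)) > jump_uv, axis=1)
    med_var = np.median(var)
    med_jump = np.median(jumps)
    excluded = np.zeros(rec.n_channels, dtype=bool)
    reasons: list[tuple[str, ...]] = []
    for i, ch in enumerate(rec.channels):
        why = []
        if ch in pathology_list:
            why.append("pathology")
        if ch in manual_list:
            why.append("manual")
        if var[i] > 5 * med_var or var[i] < med_var / 5:
            why.append("variance")
        if jumps[i] > 3 * med_jump:
            why.append("jumps")
        excluded[i] = bool(why)
        reasons.append(tuple(why))
    return ChannelQC(channels=list(rec.channels), variance=var,
                     jump_count=jumps, excluded=excluded, reasons=reasons)


def common_average_reference(rec: Recording, qc: ChannelQC) -> Recording:
    """Subtract the mean of non-excluded channels from every channel."""
    keep = qc.included()
    if not np.any(keep):
        raise ValueError("all channels excluded; no common average defined")
    car = rec.data[keep].mean(axis=0)
    return Recording(rec.data - car[None, :], rec.fs, list(rec.channels),
                     rec.condition, rec.run_id)


# ---------------------------------------------------------------------------


def _morlet_kernel(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized so a unit sinusoid at ``freq``
    yields amplitude ~1 (amplitude scaling applied by the caller)."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    kernel -= kernel.mean()            # zero-mean correction
    # normalize so |conv| equals the amplitude of a matching sinusoid
    kernel *= 2.0 / np.abs(np.sum(kernel * np.exp(-2j * np.pi * freq * t)))
    return kernel


def wavelet_power(rec: Recording, freqs: np.ndarray | None = None,
                  n_cycles: float = 7.0
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet power-amplitude tensor.

    Returns ``(amplitude, freqs, valid)`` where ``amplitude`` has shape
    (n_channels, n_freqs, n_samples), and ``valid`` flags samples farther
    than half the widest wavelet support from either record edge.  The
    convolution uses reflection padding, so edge samples are defined but
    flagged.
    """
    if freqs is None:
        freqs = morlet_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    f_lo = freqs.min()
    support = n_cycles / f_lo          # seconds, full nominal support
    if rec.duration <= support:
        raise ValueError(
            f"record ({rec.duration:.1f} s) is shorter than the widest "
            f"wavelet support ({support:.1f} s at {f_lo:g} Hz)")
    n = rec.n_samples
    pad = int(np.ceil(5 * n_cycles / (2 * np.pi * f_lo) * rec.fs))
    padded = np.pad(rec.data, ((0, 0), (pad, pad)), mode="reflect")
    amp = np.empty((rec.n_channels, len(freqs), n))
    valid = np.ones(n, dtype=bool)
    for fi, f in enumerate(freqs):
        k = _morlet_kernel(f, rec.fs, n_cycles)
        conv = signal.fftconvolve(padded, k[None, :], mode="same", axes=1)
        amp[:, fi, :] = np.abs(conv[:, pad:pad + n])
        half_support = int(np.ceil(0.5 * n_cycles / f * rec.fs))
        if half_support > 0:
            valid[:half_support] = False
            valid[-half_support:] = False
    return amp, freqs, valid


def lognorm(amplitude: np.ndarray, mode: str = "ratio") -> np.ndarray:
    """Per-frequency log-ratio normalization against the whole-run level.

    ``mode="ratio"`` (default): x -> log10(x / mean_t(x)); the time-mean of
    10**output is exactly 1 per frequency.  ``mode="log_mean"``: x ->
    log10(x) - mean_t(log10(x)); the time-mean of the output is exactly 0
    per frequency.  Both remove the 1/f level differences across
    frequencies; they differ by a per-frequency constant.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude <= 0):
        raise ValueError("power amplitudes must be strictly positive")
    if mode == "ratio":
        return np.log10(amplitude / amplitude.mean(axis=-1, keepdims=True))
    if mode == "log_mean":
        lg = np.log10(amplitude)
        return lg - lg.mean(axis=-1, keepdims=True)
    raise ValueError(f"unknown lognorm mode {mode!r}")


def band_average(tensor: np.ndarray, freqs: np.ndarray,
                 bands: dict[str, tuple[float, float]] | None = None
                 ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Average a per-frequency tensor into bands (closed intervals).

    A center frequency belongs to every band whose closed interval contains
    it (the default grid assigns each frequency to exactly one band; 170 Hz
    belongs to HFB).  Raises if a band has no member frequency.
    """
    if bands is None:
        bands = BAND_TABLE
    names = tuple(bands)
    out = np.empty(tensor.shape[:-2] + (len(names), tensor.shape[-1]))
    for bi, name in enumerate(names):
        lo, hi = bands[name]
        member = (freqs >= lo) & (freqs <= hi)
        if not np.any(member):
            raise ValueError(f"band {name!r} ({lo}-{hi} Hz) has no member "
                             "frequency on this grid")
        out[..., bi, :] = tensor[..., member, :].mean(axis=-2)
    return out, names


def smooth_envelope(env: BandEnvelope, width_ms: float = 50.0) -> BandEnvelope:
    """Zero-phase Gaussian smoothing of every band envelope.

    ``width_ms`` is the full width at half maximum of the Gaussian kernel;
    the kernel integrates to one, so constant envelopes are unchanged.
    """
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    sigma = width_ms / 1000.0 / _FWHM_TO_SD * env.fs
    data = gaussian_filter1d(env.data, sigma, axis=-1, mode="reflect")
    return BandEnvelope(data, env.fs, list(env.channels), env.bands,
                        None if env.valid is None else env.valid.copy(),
                        env.condition, env.run_id)


# ---------------------------------------------------------------------------


def preprocess_run(rec: Recording, line_freq: float = 60.0,
                   pathology_list: tuple[str, ...] = (),
                   manual_list: tuple[str, ...] = (),
                   n_cycles: float = 7.0,
                   lognorm_mode: str = "ratio",
                   smooth_ms: float | None = None,
                   bands: dict[str, tuple[float, float]] | None = None,
                   freqs: np.ndarray | None = None,
                   crop: tuple[float, float] | None = None
                   ) -> tuple[BandEnvelope, ChannelQC]:
    """Full preprocessing chain for one run.

    ``bands``/``freqs`` can restrict the decomposition (e.g. HFB only) when
    downstream analyses need a subset; ``crop`` is (start_s, stop_s) on the
    recording clock.  Returns the band envelopes (at the raw sampling rate)
    and the channel-QC record.
    """
    if crop is not None:
        i0, i1 = (int(round(c * rec.fs)) for c in crop)
        rec = Recording(rec.data[:, i0:i1], rec.fs, list(rec.channels),
                        rec.condition, rec.run_id)
    rec = notch_filter(rec, line_freq)
    qc = qc_channels(rec, pathology_list, manual_list)
    rec = common_average_reference(rec, qc)
    if freqs is None and bands is not None:
        grid = morlet_frequencies()
        lo = min(b[0] for b in bands.values())
        hi = max(b[1] for b in bands.values())
        freqs = grid[(grid >= lo) & (grid <= hi)]
    amp, freqs, valid = wavelet_power(rec, freqs=freqs, n_cycles=n_cycles)
    normed = lognorm(amp, mode=lognorm_mode)
    data, names = band_average(normed, freqs, bands)
    env = BandEnvelope(data, rec.fs, list(rec.channels), names, valid,
                       rec.condition, rec.run_id)
    if smooth_ms is not None:
        env = smooth_envelope(env, smooth_ms)
    return env, qc
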