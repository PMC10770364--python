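"""Per-chunk adaptive background-noise filtering.

Background noise on a forest floor varies strongly in space and time, so every
10-min chunk gets its own noise model. The steps are:

1. An amplitude threshold ``T = m + alpha * sigma`` from sigma clipping of the
   rectified signal (median ``m``, standard deviation ``sigma`` of ``|x|``).
2. ``alpha`` chosen on a 1.0–10.0 grid (step 0.3) by the elbow of the curve
   "number of samples above threshold" vs ``alpha``.
3. The longest stretch whose short-window loudness stays below ``T`` is taken
   as signal-free background, and its short-time spectrum becomes the noise
   profile.
4. Stationary spectral gating attenuates time–frequency cells below the
   per-bin gate ``mean + gate_k * std`` of the noise profile.

Chunks with no usable silent stretch are passed through unmodified and
flagged, so detection can still run on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter1d
from scipy.ndimage import label as ndi_label
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .audio_io import RecordingChunk, Waveform

__all__ = [
    "AmplitudeThreshold",
    "AlphaScan",
    "NoiseProfile",
    "NoUsableSilence",
    "alpha_grid",
    "amplitude_threshold",
    "select_alpha",
    "rms_envelope",
    "longest_silence",
    "noise_spectrum",
    "spectral_gate",
    "denoise_chunk",
]

#: Fallback multiplier when the count curve has no identifiable knee.
DEFAULT_ALPHA = 4.0


class NoUsableSilence(RuntimeError):
    """No signal-free stretch long enough to profile the background noise."""


@dataclass(frozen=True)
class AmplitudeThreshold:
    """Sigma-clipping amplitude threshold ``T = m + alpha * sigma`` (mV)."""

    m: float
    sigma: float
    alpha: float

    @property
    def T(self) -> float:
        return self.m + self.alpha * self.sigma


@dataclass(frozen=True)
class AlphaScan:
    """Result of scanning the alpha grid for the threshold multiplier.

    ``method`` records how ``selected_alpha`` was chosen: ``"knee"`` (maximum
    distance below the chord of the normalised count curve), ``"curvature"``
    (most negative second difference) or ``"default"``.
    """

    alphas: np.ndarray
    counts: np.ndarray
    selected_alpha: float
    method: str
    threshold: AmplitudeThreshold


@dataclass
class NoiseProfile:
    """Per-frequency-bin magnitude statistics of a background-noise segment.

    ``segment_samples`` optionally retains the raw noise segment so the gate
    can derive statistics of locally averaged energy (used by the hysteresis
    mask); profiles deserialized from JSON lack it and fall back to
    cell-level gating.
    """

    freqs: np.ndarray
    mean_mag: np.ndarray
    std_mag: np.ndarray
    sample_rate: int
    n_fft: int
    hop: int
    source_segment: tuple[float, float] | None = None
    segment_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.freqs) == len(self.mean_mag) == len(self.std_mag)):
            raise ValueError("freqs, mean_mag and std_mag must align")


@dataclass
class DenoiseResult:
    """Denoised chunk plus the noise model used (or the skip flag)."""

    chunk: RecordingChunk
    scan: AlphaScan
    profile: NoiseProfile | None
    skipped: bool = False
    notes: list[str] = field(default_factory=list)


def alpha_grid(start: float = 1.0, stop: float = 10.0, step: float = 0.3) -> np.ndarray:
    """The alpha candidate grid (default 1.0, 1.3, ..., 10.0; 31 values)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def amplitude_threshold(samples: np.ndarray, alpha: float) -> AmplitudeThreshold:
    """Single-pass sigma-clipping threshold on the rectified signal."""
    x = np.abs(np.asarray(samples, dtype=np.float64))
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    return AmplitudeThreshold(m=float(np.median(x)), sigma=float(np.std(x)), alpha=alpha)


def _knee_of_counts(alphas: np.ndarray, counts: np.ndarray) -> tuple[float, str]:
    """Elbow of a non-increasing count curve.

    Kneedle-style: normalise both axes to [0, 1] and take the point of maximum
    distance *below* the chord joining the endpoints. A flat or linear curve
    has no such point; fall back to the point of most negative discrete
    curvature, then to :data:`DEFAULT_ALPHA`.
    """
    c = counts.astype(np.float64)
    if c.max() == c.min():
        return DEFAULT_ALPHA, "default"
    x = (alphas - alphas[0]) / (alphas[-1] - alphas[0])
    y = (c - c.min()) / (c.max() - c.min())
    chord = y[0] + (y[-1] - y[0]) * x
    below = chord - y
    # interior points only; require a clearly convex deviation
    if below[1:-1].max() > 1e-9:
        return float(alphas[1 + int(np.argmax(below[1:-1]))]), "knee"
    d2 = np.diff(y, n=2)
    if d2.size and d2.min() < -1e-9:
        return float(alphas[1 + int(np.argmin(d2))]), "curvature"
    return DEFAULT_ALPHA, "default"


def select_alpha(samples: np.ndarray, alphas: np.ndarray | None = None) -> AlphaScan:
    """Choose the threshold multiplier by the elbow of counts-above-threshold.

    The count of samples exceeding ``m + alpha * sigma`` is non-increasing in
    ``alpha``; for a signal of sparse strong pulses over background noise it
    falls steeply while the threshold climbs through the noise and flattens
    once only pulse samples remain. The knee of that curve separates the two
    regimes. Selection is invariant under positive rescaling of the signal.
    """
    if alphas is None:
        alphas = alpha_grid()
    x = np.abs(np.asarray(samples, dtype=np.float64))
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    m = float(np.median(x))
    sigma = float(np.std(x))
    thresholds = m + alphas * sigma
    # one sort, then counts for every alpha by binary search
    xs = np.sort(x)
    counts = x.size - np.searchsorted(xs, thresholds, side="right")
    selected, method = _knee_of_counts(alphas, counts)
    return AlphaScan(
        alphas=np.asarray(alphas, dtype=np.float64),
        counts=counts.astype(np.int64),
        selected_alpha=selected,
        method=method,
        threshold=AmplitudeThreshold(m=m, sigma=sigma, alpha=selected),
    )


def rms_envelope(samples: np.ndarray, sample_rate: int, win_s: float = 0.02) -> np.ndarray:
    """Per-sample moving-RMS loudness envelope over a ``win_s`` window."""
    x = np.asarray(samples, dtype=np.float64)
    n = max(1, int(round(win_s * sample_rate)))
    # clip: the uniform filter can go fractionally negative on zero stretches
    return np.sqrt(np.maximum(uniform_filter1d(x * x, size=n, mode="nearest"),
                              0.0))


def longest_silence(
    samples: np.ndarray,
    sample_rate: int,
    T: float,
    min_silence_len: float = 1.0,
    envelope_win: float = 0.02,
) -> tuple[float, float]:
    """Longest stretch whose loudness envelope stays below ``T``, in seconds.

    Silence is judged on a short moving-RMS envelope rather than raw samples,
    so that isolated noise excursions do not break up genuinely signal-free
    stretches. Ties go to the earliest stretch. Raises
    :class:`NoUsableSilence` if no stretch reaches ``min_silence_len``.
    """
    env = rms_envelope(samples, sample_rate, envelope_win)
    below = env < T
    if not below.any():
        raise NoUsableSilence("no sample below the amplitude threshold")
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, below.size]
    run_is_silent = below[starts]
    lengths = np.where(run_is_silent, ends - starts, 0)
    best = int(np.argmax(lengths))  # argmax takes the first maximum: earliest run
    if lengths[best] < min_silence_len * sample_rate:
        raise NoUsableSilence(
            f"longest silent stretch {lengths[best] / sample_rate:.3f} s "
            f"< min_silence_len {min_silence_len} s"
        )
    return starts[best] / sample_rate, ends[best] / sample_rate


def _stft_transform(sample_rate: int, n_fft: int, hop: int) -> ShortTimeFFT:
    win = hann(n_fft, sym=False)
    return ShortTimeFFT(win, hop=hop, fs=sample_rate, fft_mode="onesided")


def noise_spectrum(
    segment_samples: np.ndarray,
    sample_rate: int,
    n_fft: int = 512,
    hop: int = 128,
) -> NoiseProfile:
    """Short-time magnitude statistics of a background-noise segment."""
    x = np.asarray(segment_samples, dtype=np.float64)
    if x.size < n_fft:
        raise ValueError(
            f"segment of {x.size} samples shorter than n_fft={n_fft}"
        )
    stf = _stft_transform(sample_rate, n_fft, hop)
    mag = np.abs(stf.stft(x))
    return NoiseProfile(
        freqs=stf.f.copy(),
        mean_mag=mag.mean(axis=1),
        std_mag=mag.std(axis=1),
        sample_rate=sample_rate,
        n_fft=n_fft,
        hop=hop,
        segment_samples=x,
    )


def _mask_sigmas(profile: NoiseProfile, mask_smooth_hz: float,
                 mask_smooth_s: float) -> tuple[float, float]:
    """Gaussian sigmas (bins, frames) from full-width smoothing extents."""
    df = profile.sample_rate / profile.n_fft
    dt = profile.hop / profile.sample_rate
    return (max((mask_smooth_hz / df) / 2.355, 0.3),
            max((mask_smooth_s / dt) / 2.355, 0.3))


def spectral_gate(
    samples: np.ndarray,
    profile: NoiseProfile,
    gate_k: float = 1.5,
    mask_smooth_hz: float = 100.0,
    mask_smooth_s: float = 0.008,
    seed_z: float = 22.0,
) -> np.ndarray:
    """Stationary spectral gating against a noise profile.

    The per-bin gate ``mean_mag + gate_k * std_mag`` defines the *support*:
    cells that may carry signal. Which supported regions survive is decided
    by hysteresis on a locally averaged energy field: energy is smoothed over
    ``mask_smooth_hz`` × ``mask_smooth_s``, standardized per bin against the
    same smoothed field of the noise segment, and connected support regions
    containing at least one cell ``seed_z`` noise standard deviations above
    the noise mean are kept whole (at unit gain, edges tapered); all other
    cells are zeroed. Keeping whole regions rather than independent cells is
    what preserves pulse amplitudes while removing the noise's own
    above-gate excursions, which otherwise reconstruct as impulsive residual
    bursts. When the profile lacks its raw segment, a cell-level Wiener-style
    gain against the gate is used instead. Output length equals input length.
    """
    x = np.asarray(samples, dtype=np.float64)
    n = x.size
    stf = _stft_transform(profile.sample_rate, profile.n_fft, profile.hop)
    S = stf.stft(x)
    mag = np.abs(S).astype(np.float32)
    gate = (profile.mean_mag + gate_k * profile.std_mag).astype(np.float32)
    sig = _mask_sigmas(profile, mask_smooth_hz, mask_smooth_s)
    support = mag > gate[:, None]
    if profile.segment_samples is not None and not np.all(
        profile.segment_samples == 0
    ):
        seg_mag2 = np.abs(stf.stft(profile.segment_samples)).astype(np.float32) ** 2
        En = gaussian_filter(seg_mag2, sigma=sig, mode="nearest")
        # median/quantile scale rather than mean/std: the reference segment may
        # contain sparse signal frames (silence-finding is loudness-based and
        # cannot exclude brief pulses), which would inflate a std estimate
        mu_s = np.median(En, axis=1)
        sd_s = np.maximum(np.quantile(En, 0.84, axis=1) - mu_s, 1e-30)
        del seg_mag2, En
        E = gaussian_filter(mag * mag, sigma=sig, mode="nearest")
        z = (E - mu_s[:, None]) / sd_s[:, None]
        del E
        seeds = (z >= seed_z) & support
        del z
        labels, n_regions = ndi_label(support, structure=np.ones((3, 3), dtype=bool))
        keep = np.zeros(n_regions + 1, dtype=bool)
        keep[np.unique(labels[seeds])] = True
        keep[0] = False
        region = keep[labels]
        del labels, seeds
        mask = np.clip(
            gaussian_filter(region.astype(np.float32), sigma=sig, mode="nearest")
            / 0.6, 0.0, 1.0,
        )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            wien = 1.0 - (gate[:, None] / np.maximum(mag, 1e-30)) ** 2
        mask = gaussian_filter(
            np.clip(np.where(support, wien, 0.0), 0.0, 1.0).astype(np.float32),
            sigma=sig, mode="nearest",
        )
    out = stf.istft(S * mask, k1=n)
    return np.asarray(out[:n], dtype=np.float64)


def denoise_chunk(
    chunk: RecordingChunk,
    alphas: np.ndarray | None = None,
    min_silence_len: float = 1.0,
    n_fft: int = 512,
    hop: int = 128,
    gate_k: float = 1.5,
    mask_smooth_hz: float = 100.0,
    mask_smooth_s: float = 0.008,
    seed_z: float = 22.0,
) -> DenoiseResult:
    """Adaptively denoise one chunk with its own background-noise profile.

    Composes :func:`select_alpha` → :func:`longest_silence` →
    :func:`noise_spectrum` → :func:`spectral_gate`. When no usable silent
    stretch exists the chunk is returned unchanged with ``skipped=True``.
    """
    w = chunk.waveform
    scan = select_alpha(w.samples, alphas)
    try:
        t0, t1 = longest_silence(
            w.samples, w.sample_rate, scan.threshold.T, min_silence_len
        )
    except NoUsableSilence as exc:
        return DenoiseResult(chunk=chunk, scan=scan, profile=None, skipped=True,
                             notes=[str(exc)])
    i0, i1 = int(t0 * w.sample_rate), int(t1 * w.sample_rate)
    profile = noise_spectrum(w.samples[i0:i1], w.sample_rate, n_fft=n_fft, hop=hop)
    profile.source_segment = (t0, t1)
    denoised = spectral_gate(
        w.samples, profile, gate_k=gate_k,
        mask_smooth_hz=mask_smooth_hz, mask_smooth_s=mask_smooth_s,
        seed_z=seed_z,
    )
    new_wave = Waveform(denoised, w.sample_rate, w.start_time)
    new_chunk = RecordingChunk(
        waveform=new_wave,
        unit_id=chunk.unit_id,
        plot_id=chunk.plot_id,
        substrate=chunk.substrate,
        chunk_index=chunk.chunk_index,
    )
    return DenoiseResult(chunk=new_chunk, scan=scan, profile=profile)
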