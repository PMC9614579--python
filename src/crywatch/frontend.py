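"""Frame-level acoustic parameter extraction.

Cry recordings are analyzed in short frames (12.5 ms by default, half-frame
hop, Hann taper). Two built-in analyzer profiles stand in for the two
analysis systems whose outputs are later stacked:

* ``cepstral`` — f0 via the real-cepstrum quefrency peak; reports f0 /
  hyperphonation, F1/F2, band-split energies, fricative score and the
  amplitude envelope.
* ``spectral`` — f0 via the autocorrelation computed from the power
  spectrum; reports f0, F1/F2, total energy, spectral entropy, spectral
  novelty, fricative score and the amplitude envelope.

Per-frame missingness is explicit: unvoiced frames carry NaN for f0 and the
formants, and every NaN f0 co-occurs with ``voiced = False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

from .audio import AudioSegment

__all__ = [
    "AnalyzerProfile",
    "FrameSeries",
    "CEPSTRAL",
    "SPECTRAL",
    "get_profile",
    "frame_signal",
    "estimate_f0_cepstral",
    "estimate_f0_autocorr",
    "estimate_formants",
    "frame_energy",
    "spectral_entropy",
    "fricative_score",
    "amplitude_envelope",
    "spectral_novelty",
    "analyze",
]

_NFFT = 1024  # zero-padded FFT length for spectra / cepstra
_EPS = 1e-12


@dataclass(frozen=True)
class AnalyzerProfile:
    """Configuration of one analyzer."""

    analyzer_id: str
    frame_ms: float = 12.5
    hop_ms: float = 6.25
    window: str = "hann"
    f0_range: tuple[float, float] = (150.0, 2500.0)
    hyperphonation_threshold: float = 1000.0
    f0_method: str = "cepstrum"  # or "autocorr"
    #: Voicing decision: cepstrum — band peak >= threshold × median absolute
    #: band level (noise frames sit near 5, voiced frames above 8);
    #: autocorr — normalized peak >= threshold.
    voicing_threshold: float = 7.5
    #: low LPC order: the sparse harmonic sampling of high-pitched cries
    #: (f0 300-600 Hz at a 10 kHz analysis rate) over-fits larger orders,
    #: pulling poles onto individual harmonics instead of formants
    lpc_order: int = 6
    formant_sr: int = 10000  # internal resample rate for LPC
    preemphasis: float = 0.97
    band_split: float = 2500.0
    novelty_kernel: int = 16
    feature_set: tuple[str, ...] = (
        "f0",
        "formants",
        "energy_bands",
        "fricative",
        "envelope",
    )

    def __post_init__(self) -> None:
        if self.frame_ms <= 0 or self.hop_ms <= 0:
            raise ValueError("frame_ms and hop_ms must be positive")
        if not self.f0_range[0] < self.f0_range[1]:
            raise ValueError("f0_range must be (min, max) with min < max")
        if self.f0_method not in ("cepstrum", "autocorr"):
            raise ValueError("f0_method must be 'cepstrum' or 'autocorr'")


CEPSTRAL = AnalyzerProfile(
    analyzer_id="cepstral",
    f0_method="cepstrum",
    voicing_threshold=7.5,
    feature_set=("f0", "formants", "energy_bands", "fricative", "envelope"),
)

SPECTRAL = AnalyzerProfile(
    analyzer_id="spectral",
    f0_method="autocorr",
    voicing_threshold=0.35,
    feature_set=("f0", "formants", "energy_total", "entropy", "novelty", "envelope", "fricative"),
)

_PROFILES = {"cepstral": CEPSTRAL, "spectral": SPECTRAL}


def get_profile(name: str) -> AnalyzerProfile:
    try:
        return _PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown analyzer profile {name!r}; choose from {sorted(_PROFILES)}")


@dataclass
class FrameSeries:
    """Per-frame acoustic parameters for one recording and one analyzer.

    ``table`` has one row per frame: ``frame_time`` (s, frame start) plus
    feature columns; NaN marks per-frame missingness.
    """

    analyzer_id: str
    table: pd.DataFrame
    frame_len_s: float
    hop_s: float
    infant_id: str = ""
    recording_id: str = ""
    profile: AnalyzerProfile | None = None

    _META = ("frame_time", "voiced")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def frame_times(self) -> np.ndarray:
        return self.table["frame_time"].to_numpy()

    def feature_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in self._META]

    def to_csv(self, path: str | Path) -> None:
        """Write the frame table as CSV (missing values as empty cells) with
        a JSON sidecar of the profile parameters."""
        path = Path(path)
        self.table.to_csv(path, index=False)
        if self.profile is not None:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(asdict(self.profile), indent=2))


# ---------------------------------------------------------------------------
# Framing
# ---------------------------------------------------------------------------


def frame_signal(audio: AudioSegment, profile: AnalyzerProfile) -> tuple[np.ndarray, np.ndarray]:
    """Slice ``audio`` into tapered frames.

    Returns ``(frames, times)`` where ``frames`` is (n_frames, frame_len)
    with the window applied and ``times`` are frame start times in seconds.
    Frame length is ``round(frame_ms·sr/1000)`` samples; the frame count is
    ``floor((N − frame_len)/hop) + 1``. Audio shorter than one frame yields
    an empty series.
    """
    sr = audio.sample_rate
    frame_len = int(round(profile.frame_ms * sr / 1000.0))
    hop = max(1, int(round(profile.hop_ms * sr / 1000.0)))
    x = audio.samples
    if x.size < frame_len:
        return np.empty((0, frame_len)), np.empty(0)
    n_frames = (x.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * sps.get_window(profile.window, frame_len, fftbins=True)
    times = hop * np.arange(n_frames) / sr
    return frames, times


def _power_spectra(frames: np.ndarray) -> np.ndarray:
    """Power spectra of windowed frames, zero-padded to ``_NFFT``."""
    spec = sfft.rfft(frames, n=_NFFT, axis=-1)
    return (spec.real**2 + spec.imag**2)


# ---------------------------------------------------------------------------
# f0 estimation
# ---------------------------------------------------------------------------


def _first_strong_peak(band: np.ndarray, rel: float) -> tuple[np.ndarray, np.ndarray]:
    """Per row: index and value of the lowest-index local maximum within
    ``rel`` of the row maximum.

    A periodic signal produces near-equal peaks at the fundamental quefrency
    (or lag) and its multiples (rahmonics / subharmonic lags); choosing the
    global maximum risks an octave-down error, so the earliest near-maximal
    peak is taken instead.
    """
    n_rows, n = band.shape
    peak_val = band.max(axis=-1)
    inner = band[:, 1:-1]
    is_peak = (inner >= band[:, :-2]) & (inner >= band[:, 2:]) & (
        inner >= rel * peak_val[:, None]
    )
    first = np.argmax(is_peak, axis=-1)  # 0 when no local peak qualifies
    has_peak = is_peak[np.arange(n_rows), first]
    idx = np.where(has_peak, first + 1, np.argmax(band, axis=-1))
    return idx, band[np.arange(n_rows), idx]


def _f0_cepstral_batch(
    power: np.ndarray, sr: int, profile: AnalyzerProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Cepstral f0 for a batch of frames given their power spectra."""
    cep = sfft.irfft(0.5 * np.log(power + _EPS), axis=-1)
    q_min = max(2, int(np.floor(sr / profile.f0_range[1])))
    q_max = min(cep.shape[-1] // 2 - 1, int(np.ceil(sr / profile.f0_range[0])))
    band = cep[:, q_min : q_max + 1]
    peak_idx, _ = _first_strong_peak(band, rel=0.7)
    level = np.median(np.abs(band), axis=-1) + _EPS
    voiced = band.max(axis=-1) >= profile.voicing_threshold * level
    f0 = sr / (peak_idx + q_min).astype(float)
    f0 = np.where(voiced, f0, np.nan)
    return f0, voiced


def _f0_autocorr_batch(
    power: np.ndarray, sr: int, profile: AnalyzerProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation f0 via the inverse transform of the power spectrum."""
    ac = sfft.irfft(power, axis=-1)
    lag0 = ac[:, 0] + _EPS
    q_min = max(2, int(np.floor(sr / profile.f0_range[1])))
    q_max = min(ac.shape[-1] // 2 - 1, int(np.ceil(sr / profile.f0_range[0])))
    band = ac[:, q_min : q_max + 1] / lag0[:, None]
    peak_idx, _ = _first_strong_peak(band, rel=0.85)
    voiced = band.max(axis=-1) >= profile.voicing_threshold
    f0 = sr / (peak_idx + q_min).astype(float)
    f0 = np.where(voiced, f0, np.nan)
    return f0, voiced


def estimate_f0_cepstral(
    frame: np.ndarray, sr: int, profile: AnalyzerProfile = CEPSTRAL
) -> tuple[float, bool]:
    """f0 of one windowed frame from the real-cepstrum quefrency peak.

    Voiced iff the peak exceeds ``voicing_threshold`` × the median absolute
    cepstrum level in the search band; unvoiced frames return (nan, False).
    """
    power = _power_spectra(np.atleast_2d(frame))
    f0, voiced = _f0_cepstral_batch(power, sr, profile)
    return float(f0[0]), bool(voiced[0])


def estimate_f0_autocorr(
    frame: np.ndarray, sr: int, profile: AnalyzerProfile = SPECTRAL
) -> tuple[float, bool]:
    """f0 of one windowed frame from the normalized autocorrelation peak."""
    power = _power_spectra(np.atleast_2d(frame))
    f0, voiced = _f0_autocorr_batch(power, sr, profile)
    return float(f0[0]), bool(voiced[0])


# ---------------------------------------------------------------------------
# Formants (LPC root-finding)
# ---------------------------------------------------------------------------


def _lpc(x: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method linear prediction coefficients (a_1..a_p)."""
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    if r[0] <= 0:
        return None
    r = r / r[0]
    r0 = r[:order] + np.concatenate(([1e-9], np.zeros(order - 1)))
    try:
        a = solve_toeplitz((r0, r0), r[1 : order + 1])
    except np.linalg.LinAlgError:
        return None
    return a


def estimate_formants(
    frame: np.ndarray, sr: int, profile: AnalyzerProfile = CEPSTRAL
) -> tuple[float, float]:
    """First and second formant of a voiced frame from the LPC envelope.

    The frame is resampled to ``formant_sr``, pre-emphasized and fitted with
    an order-``lpc_order`` all-pole model. Candidate formants are the local
    maxima of the all-pole spectral envelope within (200, 5000) Hz — peak
    picking on the envelope is markedly more robust to the sparse harmonic
    sampling of high-pitched cries than classifying raw pole bandwidths.
    The two lowest candidates are (F1, F2); missing slots are NaN.
    """
    sr_i = profile.formant_sr
    x = np.asarray(frame, dtype=float)
    if sr > sr_i:
        g = np.gcd(sr, sr_i)
        x = sps.resample_poly(x, sr_i // g, sr // g, padtype="line")
    if x.size <= profile.lpc_order + 2:
        return (np.nan, np.nan)
    x = np.append(x[0], x[1:] - profile.preemphasis * x[:-1])
    a = _lpc(x, profile.lpc_order)
    if a is None:
        return (np.nan, np.nan)
    w, h = sps.freqz(1.0, np.concatenate(([1.0], -a)), worN=1024, fs=sr_i)
    mag = np.abs(h)
    peaks, _ = sps.find_peaks(mag)
    freqs = w[peaks]
    cand = freqs[(freqs > 200.0) & (freqs < 5000.0)]
    f1 = float(cand[0]) if cand.size >= 1 else np.nan
    f2 = float(cand[1]) if cand.size >= 2 else np.nan
    return (f1, f2)


# ---------------------------------------------------------------------------
# Energy, entropy, fricatives
# ---------------------------------------------------------------------------

_DB_FLOOR = -120.0


def _energy_batch(
    power: np.ndarray, sr: int, band_split: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    freqs = np.arange(power.shape[-1]) * sr / _NFFT
    low = freqs < band_split
    def to_db(p):
        return np.maximum(10.0 * np.log10(np.maximum(p, _EPS)), _DB_FLOOR)
    total = to_db(power.sum(axis=-1))
    e_low = to_db(power[:, low].sum(axis=-1))
    e_high = to_db(power[:, ~low].sum(axis=-1))
    # an all-zero frame sums to 0 -> log floor; clamp exactly
    zero = power.sum(axis=-1) <= 0
    for arr in (total, e_low, e_high):
        arr[zero] = _DB_FLOOR
    return total, e_low, e_high


def frame_energy(
    frame: np.ndarray, sr: int, profile: AnalyzerProfile = CEPSTRAL
) -> tuple[float, float, float]:
    """(total, below band_split, above band_split) energies in dB.

    10·log10 of the summed power spectrum, floored at −120 dB.
    """
    power = _power_spectra(np.atleast_2d(frame))
    t, lo, hi = _energy_batch(power, sr, profile.band_split)
    return float(t[0]), float(lo[0]), float(hi[0])


_ENTROPY_BANDS = 32


def _entropy_batch(power: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy of the band-averaged power spectrum.

    Power is pooled into 32 equal-width bands before normalization: the raw
    periodogram of white noise has exponentially distributed bins whose
    expected normalized entropy plateaus near 0.91 regardless of the true
    flatness; band averaging stabilizes the estimate (noise ~0.97, pure
    tone < 0.05-0.2), keeping the 0 = tonal, 1 = noise-like reading.
    """
    nb = min(_ENTROPY_BANDS, power.shape[-1])
    edges = np.linspace(0, power.shape[-1], nb + 1).astype(int)
    banded = np.add.reduceat(power, edges[:-1], axis=-1)
    total = banded.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = banded / total
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=-1) / np.log(nb)
    h = np.where(total[:, 0] > _EPS, h, np.nan)
    return h


def spectral_entropy(frame: np.ndarray) -> float:
    """Shannon entropy of the normalized power spectrum, scaled to [0, 1].

    0 for a pure tone, approaching 1 for white noise; NaN for a zero frame.
    The spectrum is computed at the native frame length (no zero padding,
    which would correlate neighbouring bins and deflate the entropy).
    """
    frame = np.atleast_2d(np.asarray(frame, dtype=float))
    spec = sfft.rfft(frame, axis=-1)
    return float(_entropy_batch(spec.real**2 + spec.imag**2)[0])


def _zcr_batch(frames: np.ndarray) -> np.ndarray:
    s = np.signbit(frames)
    return np.mean(s[:, 1:] != s[:, :-1], axis=-1)


def _fricative_batch(power: np.ndarray, zcr: np.ndarray, sr: int, band_split: float) -> np.ndarray:
    freqs = np.arange(power.shape[-1]) * sr / _NFFT
    total = power.sum(axis=-1) + _EPS
    ratio = power[:, freqs >= band_split].sum(axis=-1) / total
    # logistic in the high-band energy ratio (midpoint 0.5) and the
    # normalized zero-crossing rate (midpoint 0.3); monotone in both
    z = 8.0 * (ratio - 0.5) + 8.0 * (zcr - 0.3)
    return 1.0 / (1.0 + np.exp(-z))


def fricative_score(
    frame: np.ndarray, sr: int, profile: AnalyzerProfile = CEPSTRAL
) -> float:
    """Frication likelihood in [0, 1]: logistic combination of the
    high-band/total energy ratio and the zero-crossing rate, monotone
    nondecreasing in both."""
    frames = np.atleast_2d(frame)
    power = _power_spectra(frames)
    return float(_fricative_batch(power, _zcr_batch(frames), sr, profile.band_split)[0])


# ---------------------------------------------------------------------------
# Series-level features
# ---------------------------------------------------------------------------


def amplitude_envelope(series: FrameSeries) -> tuple[np.ndarray, float]:
    """Per-frame RMS envelope and its dominant modulation frequency.

    The envelope frequency is the location of the maximum of the envelope's
    power spectrum after mean removal, reported as NaN when fewer than 8
    frames are available or when no peak rises above 5× the median
    (no discernible modulation).
    """
    env = series.table["amplitude_envelope"].to_numpy(dtype=float)
    if env.size < 8:
        return env, np.nan
    if np.std(env) < 1e-2 * (np.abs(np.mean(env)) + _EPS):
        return env, np.nan  # constant amplitude: no discernible modulation
    fs_env = 1.0 / series.hop_s
    x = env - np.mean(env)
    p = np.abs(sfft.rfft(x)) ** 2
    p[0] = 0.0
    if p.size < 3 or p.max() <= 0:
        return env, np.nan
    k = int(np.argmax(p))
    if p[k] < 5.0 * np.median(p[1:]):
        return env, np.nan
    return env, float(k * fs_env / (2 * (p.size - 1)))


def spectral_novelty(spectra: np.ndarray, kernel: int = 16) -> np.ndarray:
    """Novelty curve from the self-similarity of frame spectra.

    ``spectra`` is (n_frames, n_bins) of non-negative magnitudes. Frames are
    L2-normalized; local cosine self-similarity blocks are correlated with a
    Gaussian-tapered checkerboard kernel along the diagonal; the result is
    rectified at 0. Series shorter than the kernel return zeros.
    """
    n = spectra.shape[0]
    nov = np.zeros(n)
    if n < kernel:
        return nov
    norms = np.linalg.norm(spectra, axis=-1, keepdims=True)
    u = spectra / np.maximum(norms, _EPS)
    half = kernel // 2
    t = np.arange(-half, half) + 0.5
    taper = np.exp(-(t**2) / (2.0 * (half / 2.0) ** 2))
    kern = np.outer(np.sign(t) * taper, np.sign(t) * taper)
    for i in range(half, n - half):
        block = u[i - half : i + half] @ u[i - half : i + half].T
        nov[i] = max(0.0, float(np.sum(kern * block)))
    return nov


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------


def analyze(audio: AudioSegment, profile: AnalyzerProfile) -> FrameSeries:
    """Run every estimator in ``profile.feature_set`` over ``audio``.

    Returns a :class:`FrameSeries`; silence yields all-missing voiced
    features. ``energy_total`` and the RMS envelope are always computed
    (utterance segmentation depends on them).
    """
    frames, times = frame_signal(audio, profile)
    sr = audio.sample_rate
    frame_len = int(round(profile.frame_ms * sr / 1000.0))
    hop_s = profile.hop_ms / 1000.0
    cols: dict[str, np.ndarray] = {"frame_time": times}

    if frames.shape[0] == 0:
        table = pd.DataFrame({"frame_time": times})
        return FrameSeries(
            profile.analyzer_id, table, frame_len / sr, hop_s,
            audio.infant_id, audio.recording_id, profile,
        )

    power = _power_spectra(frames)
    total_db, low_db, high_db = _energy_batch(power, sr, profile.band_split)
    cols["energy_total"] = total_db
    if "energy_bands" in profile.feature_set:
        cols["energy_low"] = low_db
        cols["energy_high"] = high_db

    if "f0" in profile.feature_set:
        if profile.f0_method == "cepstrum":
            f0, voiced = _f0_cepstral_batch(power, sr, profile)
        else:
            f0, voiced = _f0_autocorr_batch(power, sr, profile)
        cols["f0"] = f0
        cols["voiced"] = voiced
        cols["hyperphonation"] = np.where(
            voiced, (np.nan_to_num(f0) > profile.hyperphonation_threshold), False
        ).astype(bool)
    else:
        voiced = np.zeros(frames.shape[0], dtype=bool)

    if "formants" in profile.feature_set:
        f1 = np.full(frames.shape[0], np.nan)
        f2 = np.full(frames.shape[0], np.nan)
        for i in np.flatnonzero(voiced):
            f1[i], f2[i] = estimate_formants(frames[i], sr, profile)
        cols["F1"], cols["F2"] = f1, f2

    if "entropy" in profile.feature_set:
        spec_raw = sfft.rfft(frames, axis=-1)
        cols["spectral_entropy"] = _entropy_batch(spec_raw.real**2 + spec_raw.imag**2)

    if "fricative" in profile.feature_set:
        cols["fricative_score"] = _fricative_batch(
            power, _zcr_batch(frames), sr, profile.band_split
        )

    cols["amplitude_envelope"] = np.sqrt(np.mean(frames**2, axis=-1))

    if "novelty" in profile.feature_set:
        cols["novelty"] = spectral_novelty(np.sqrt(power), profile.novelty_kernel)

    table = pd.DataFrame(cols)
    return FrameSeries(
        profile.analyzer_id, table, frame_len / sr, hop_s,
        audio.infant_id, audio.recording_id, profile,
    )
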