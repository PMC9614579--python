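"""Audio container and WAV input/output.

All analysis operates on mono waveforms with amplitudes in [-1, 1]. WAV
files are read through :mod:`scipy.io.wavfile`; integer PCM (16- or 32-bit,
including 24-bit payloads promoted to int32) and float formats are accepted,
stereo files are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioSegment", "read_wav", "write_wav"]


@dataclass
class AudioSegment:
    """Mono sampled waveform with recording identity.

    Attributes
    ----------
    samples : np.ndarray
        1-D float array of amplitudes, nominally in [-1, 1].
    sample_rate : int
        Sampling rate in Hz.
    infant_id, recording_id : str
        Identifiers carried through the pipeline; empty strings when unknown.
    """

    samples: np.ndarray
    sample_rate: int
    infant_id: str = ""
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment requires a mono (1-D) waveform")
        if self.samples.size == 0:
            raise ValueError("AudioSegment requires a non-empty waveform")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSegment samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path: str | Path, infant_id: str = "", recording_id: str = "") -> AudioSegment:
    """Read a mono WAV file into an :class:`AudioSegment`.

    Integer PCM is rescaled to [-1, 1]; stereo input raises ``ValueError``.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels; "
            "downmix before analysis"
        )
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64
        samples = data.astype(np.float64)
    rec_id = recording_id or Path(path).stem
    return AudioSegment(samples, int(rate), infant_id=infant_id, recording_id=rec_id)


def write_wav(path: str | Path, audio: AudioSegment) -> None:
    """Write an :class:`AudioSegment` as 16-bit PCM WAV."""
    clipped = np.clip(audio.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(audio.sample_rate), pcm)
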