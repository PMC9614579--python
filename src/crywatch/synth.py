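"""Synthetic cry-audio cohort generator.

Produces test cohorts that mirror the structure of a neonatal opioid
withdrawal (NOWS) cry study: a treated NOWS group, an opioid-exposed group
that did not develop NOWS, and an unexposed control group (19 / 7 / 39 by
default). Two output modes are supported:

* ``audio`` — source–filter synthesis of multi-utterance cry bouts: a
  glottal pulse train following a fundamental-frequency (f0) contour is
  shaped by second-order formant resonators, with optional hyperphonation
  episodes (f0 > 1 kHz), fricative noise segments, silence gaps that carry
  the background-noise floor, and ground-truth utterance boundaries.
* ``feature_table`` — infant-by-feature summary tables drawn directly from
  group-shifted Gaussians, bypassing signal processing, for fast tests of
  the selection/classification stages.

Group differences are controlled by an ``effect_map`` of standardized shifts
per acoustic feature family. The generator is fully determined by the seed
in :class:`CohortSpec`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .audio import AudioSegment, write_wav
from ._seeding import derive_seed

__all__ = [
    "CrySynthesisParams",
    "CohortSpec",
    "FnastSeries",
    "Cohort",
    "synthesize_utterance",
    "synthesize_recording",
    "generate_cohort",
    "simulate_fnast_series",
    "fnast_treated",
    "DEFAULT_EFFECT_MAP",
    "TABLE_KEYS",
]

#: The four (analyzer, utterance-stratum) model keys used throughout.
TABLE_KEYS = (
    ("cepstral", "short"),
    ("cepstral", "long"),
    ("spectral", "short"),
    ("spectral", "long"),
)

#: Default standardized group shifts per feature family (NOWS vs control).
#: Free parameters of the generator: the families mirror the acoustic
#: dimensions reported as discriminative for NOWS (hyperphonation, f0,
#: first formant, energy balance, fricatives, utterance counts), with
#: magnitudes chosen to give strong but imperfect separation at n = 65.
DEFAULT_EFFECT_MAP: dict[str, float] = {
    "hyperphonation": 1.2,
    "f0": 0.8,
    "formant_f1": 0.9,
    "energy": 0.8,
    "fricative": 0.7,
    "utterance_count": 1.0,
}


@dataclass(frozen=True)
class CrySynthesisParams:
    """Parameters of the source–filter cry synthesizer.

    Defaults approximate a healthy full-term newborn cry: f0 around 450 Hz
    with a rise–fall contour, first two formants near 1.1 and 3.3 kHz
    (short infant vocal tract), utterances of 0.15–0.9 s separated by
    0.1–0.4 s inspiratory gaps.
    """

    f0_base: float = 450.0
    #: Piecewise-linear f0 contour as (time fraction, multiplier) knots.
    f0_contour: tuple[tuple[float, float], ...] = (
        (0.0, 0.9),
        (0.3, 1.1),
        (0.7, 1.05),
        (1.0, 0.85),
    )
    hyperphonation_prob: float = 0.08
    hyperphonation_f0: float = 1400.0
    #: (center Hz, bandwidth Hz) for F1, F2[, F3].
    formants: tuple[tuple[float, float], ...] = ((1100.0, 150.0), (3300.0, 300.0))
    fricative_prob: float = 0.10
    utterance_dur_range_ms: tuple[float, float] = (150.0, 900.0)
    gap_dur_range_ms: tuple[float, float] = (100.0, 400.0)
    n_utterances_range: tuple[int, int] = (4, 12)
    noise_snr_db: float = 30.0
    sample_rate: int = 22050

    def __post_init__(self) -> None:
        if self.f0_base <= 0 or self.hyperphonation_f0 <= 1000:
            raise ValueError("f0_base must be > 0 and hyperphonation_f0 > 1000 Hz")
        for p in (self.hyperphonation_prob, self.fricative_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        centers = [c for c, _ in self.formants]
        if any(b <= 0 for _, b in self.formants) or centers != sorted(centers) or len(
            set(centers)
        ) != len(centers):
            raise ValueError("formant centers must be strictly increasing, bandwidths > 0")
        for lo, hi in (self.utterance_dur_range_ms, self.gap_dur_range_ms):
            if lo <= 0 or hi < lo:
                raise ValueError("duration ranges must be positive and ordered")
        if self.n_utterances_range[0] < 0 or self.n_utterances_range[1] < self.n_utterances_range[0]:
            raise ValueError("n_utterances_range must be ordered and non-negative")
        if self.sample_rate < 8000:
            raise ValueError("sample_rate must be at least 8000 Hz")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure and group effects for :func:`generate_cohort`."""

    n_nows: int = 19
    n_exposed_no_nows: int = 7
    n_unexposed: int = 39
    effect_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    seed: int = 0
    mode: str = "audio"  # or "feature_table"
    base_params: CrySynthesisParams = field(default_factory=CrySynthesisParams)
    #: Noise (uninformative) features added per table in feature_table mode.
    n_noise_features: int = 12

    def __post_init__(self) -> None:
        if min(self.n_nows, self.n_exposed_no_nows, self.n_unexposed) < 0:
            raise ValueError("group counts must be non-negative")
        if self.n_nows + self.n_exposed_no_nows + self.n_unexposed == 0:
            raise ValueError("cohort must contain at least one infant")
        if self.mode not in ("audio", "feature_table"):
            raise ValueError("mode must be 'audio' or 'feature_table'")


@dataclass
class FnastSeries:
    """Finnegan (FNAST) withdrawal scores at 3-hour intervals, range 0-46."""

    infant_id: str
    scores: list[int]

    def __post_init__(self) -> None:
        if any(not 0 <= s <= 46 for s in self.scores):
            raise ValueError("FNAST scores must lie in 0..46")


@dataclass
class Cohort:
    """A generated cohort: manifest plus recordings or feature tables."""

    manifest: "pd.DataFrame"
    recordings: dict[str, tuple[AudioSegment, list[tuple[float, float]]]] | None
    feature_tables: dict[tuple[str, str], "pd.DataFrame"] | None
    spec: CohortSpec

    def write(self, outdir: str | Path) -> Path:
        """Write WAVs + manifest + ground-truth boundaries (audio mode) or
        the four feature tables (feature_table mode) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        if self.recordings is not None:
            wav_paths, bounds_rows = [], []
            for infant_id, (audio, bounds) in self.recordings.items():
                wav = outdir / f"{infant_id}.wav"
                write_wav(wav, audio)
                wav_paths.append(str(wav))
                for s, e in bounds:
                    bounds_rows.append((infant_id, s, e))
            manifest["wav_path"] = wav_paths
            with open(outdir / "boundaries.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["infant_id", "start_s", "end_s"])
                w.writerows(bounds_rows)
        manifest.to_csv(outdir / "manifest.csv", index=False)
        if self.feature_tables is not None:
            for (analyzer, stratum), table in self.feature_tables.items():
                table.to_csv(outdir / f"table_{analyzer}_{stratum}.csv", index=False)
        return outdir


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------


def _glottal_pulse_train(f0_hz: np.ndarray, sr: int, rng: np.random.Generator) -> np.ndarray:
    """Impulse excitation whose instantaneous rate follows ``f0_hz`` (per sample)."""
    phase = np.cumsum(f0_hz / sr)
    pulses = np.zeros(f0_hz.size)
    idx = np.flatnonzero(np.diff(np.floor(phase), prepend=0.0) >= 1.0)
    # small shimmer on pulse amplitudes so the harmonic comb is not sterile
    pulses[idx] = 1.0 + 0.05 * rng.standard_normal(idx.size)
    return pulses


def _formant_filter(x: np.ndarray, formants: Sequence[tuple[float, float]], sr: int) -> np.ndarray:
    """Cascade of unit-peak-gain second-order resonators."""
    y = x
    for fc, bw in formants:
        r = np.exp(-np.pi * bw / sr)
        theta = 2.0 * np.pi * fc / sr
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [(1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2.0 * theta) + r * r)]
        y = sps.lfilter(b, a, y)
    return y


def _fricative_noise(n: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited turbulence noise (2.5 kHz up to 0.45·sr)."""
    hi = min(8000.0, 0.45 * sr)
    sos = sps.butter(4, [2500.0, hi], btype="bandpass", fs=sr, output="sos")
    return sps.sosfilt(sos, rng.standard_normal(n))


def _synth_clean(
    params: CrySynthesisParams,
    duration_ms: float,
    rng: np.random.Generator,
    hyperphonation: bool | None = None,
    fricative: bool | None = None,
) -> np.ndarray:
    """One utterance, no additive background noise, peak-normalized."""
    if duration_ms <= 0:
        raise ValueError("utterance duration must be positive")
    sr = params.sample_rate
    n = int(round(duration_ms / 1000.0 * sr))
    if hyperphonation is None:
        hyperphonation = bool(rng.random() < params.hyperphonation_prob)
    if fricative is None:
        fricative = bool(rng.random() < params.fricative_prob)

    base = params.hyperphonation_f0 if hyperphonation else params.f0_base
    knots = np.asarray(params.f0_contour, dtype=float)
    tfrac = np.arange(n) / max(n - 1, 1)
    f0 = base * np.interp(tfrac, knots[:, 0], knots[:, 1])
    # ~0.5% slow jitter so spectra are not perfectly stationary
    f0 = f0 * (1.0 + 0.005 * np.sin(2.0 * np.pi * 3.0 * tfrac + rng.uniform(0, 2 * np.pi)))

    voice = _formant_filter(_glottal_pulse_train(f0, sr, rng), params.formants, sr)

    if fricative and n > int(0.02 * sr):
        frac = rng.uniform(0.3, 0.6)
        seg = int(frac * n)
        start = int(rng.uniform(0.0, 1.0 - frac) * n)
        noise = _fricative_noise(seg, sr, rng)
        v_rms = np.sqrt(np.mean(voice**2)) or 1.0
        n_rms = np.sqrt(np.mean(noise**2)) or 1.0
        voice[start : start + seg] = noise * (v_rms / n_rms)

    # onset/offset ramps (15% of the utterance, at most 30 ms)
    ramp = min(int(0.15 * n), int(0.03 * sr), n // 2)
    if ramp > 0:
        env = np.ones(n)
        env[:ramp] = np.sin(0.5 * np.pi * np.arange(ramp) / ramp) ** 2
        env[-ramp:] = env[:ramp][::-1]
        voice *= env

    peak = np.max(np.abs(voice))
    return voice / peak * 0.9 if peak > 0 else voice


def synthesize_utterance(
    params: CrySynthesisParams,
    duration_ms: float,
    seed: int,
    hyperphonation: bool | None = None,
    fricative: bool | None = None,
    infant_id: str = "",
    recording_id: str = "",
) -> AudioSegment:
    """Synthesize a single cry utterance.

    A glottal pulse train following the f0 contour is filtered through the
    formant resonators; with probability ``fricative_prob`` a sub-segment is
    replaced by band-limited turbulence noise; Gaussian background noise is
    added at ``noise_snr_db``; the peak amplitude is normalized to 0.9.
    ``hyperphonation``/``fricative`` override the random draws (ground truth
    for tests).
    """
    rng = np.random.default_rng(seed)
    clean = _synth_clean(params, duration_ms, rng, hyperphonation, fricative)
    rms = np.sqrt(np.mean(clean**2))
    noise_rms = rms / (10.0 ** (params.noise_snr_db / 20.0))
    out = clean + noise_rms * rng.standard_normal(clean.size)
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out = out / peak
    return AudioSegment(out, params.sample_rate, infant_id, recording_id)


def synthesize_recording(
    params: CrySynthesisParams,
    n_utterances: int,
    seed: int,
    infant_id: str = "",
    recording_id: str = "",
) -> tuple[AudioSegment, list[tuple[float, float]]]:
    """Synthesize a cry bout: utterances separated by silence gaps.

    Returns the waveform and the ground-truth utterance boundaries in
    seconds. Gaps carry the same background-noise floor as the utterances
    (set by ``noise_snr_db`` relative to the mean utterance RMS), so
    segmentation thresholds are meaningfully tested.
    """
    if n_utterances < 0:
        raise ValueError("n_utterances must be non-negative")
    rng = np.random.default_rng(seed)
    sr = params.sample_rate
    lo_g, hi_g = params.gap_dur_range_ms
    lo_u, hi_u = params.utterance_dur_range_ms

    pieces: list[np.ndarray] = []
    bounds: list[tuple[float, float]] = []
    cursor = int(round(rng.uniform(lo_g, hi_g) / 1000.0 * sr))
    pieces.append(np.zeros(cursor))
    for _ in range(n_utterances):
        dur_ms = rng.uniform(lo_u, hi_u)
        utt = _synth_clean(params, dur_ms, rng)
        bounds.append((cursor / sr, (cursor + utt.size) / sr))
        pieces.append(utt)
        cursor += utt.size
        gap = int(round(rng.uniform(lo_g, hi_g) / 1000.0 * sr))
        pieces.append(np.zeros(gap))
        cursor += gap
    x = np.concatenate(pieces)

    if n_utterances > 0:
        mask = np.zeros(x.size, dtype=bool)
        for s, e in bounds:
            mask[int(s * sr) : int(e * sr)] = True
        sig_rms = np.sqrt(np.mean(x[mask] ** 2))
    else:
        sig_rms = 1e-3  # silent recording: nominal floor reference
    noise_rms = sig_rms / (10.0 ** (params.noise_snr_db / 20.0))
    x = x + noise_rms * rng.standard_normal(x.size)
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    audio = AudioSegment(x, sr, infant_id, recording_id or f"{infant_id}_rec")
    return audio, bounds


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Audio-mode mapping from feature family to synthesis-parameter shifts.
#: The shift applied is d × scale, where d is the effect_map entry.
_AUDIO_SHIFT_SCALES = {
    "hyperphonation": 0.12,  # added to hyperphonation_prob
    "f0": 0.04,  # relative shift of f0_base
    "formant_f1": 60.0,  # Hz added to F1 center
    "fricative": 0.10,  # added to fricative_prob
    "utterance_count": 2.0,  # added to both ends of n_utterances_range
}


def _infant_params(
    base: CrySynthesisParams,
    effects: dict[str, float],
    shifted: bool,
    rng: np.random.Generator,
) -> tuple[CrySynthesisParams, int]:
    """Per-infant synthesis parameters: biological scatter + group shifts."""
    d = {k: (effects.get(k, 0.0) if shifted else 0.0) for k in _AUDIO_SHIFT_SCALES}
    f0 = base.f0_base * (1.0 + _AUDIO_SHIFT_SCALES["f0"] * d["f0"]) + rng.normal(0.0, 25.0)
    hyp = float(
        np.clip(
            base.hyperphonation_prob
            + _AUDIO_SHIFT_SCALES["hyperphonation"] * d["hyperphonation"]
            + rng.normal(0.0, 0.03),
            0.0,
            1.0,
        )
    )
    fric = float(
        np.clip(
            base.fricative_prob
            + _AUDIO_SHIFT_SCALES["fricative"] * d["fricative"]
            + rng.normal(0.0, 0.03),
            0.0,
            1.0,
        )
    )
    formants = list(base.formants)
    f1c, f1b = formants[0]
    formants[0] = (f1c + _AUDIO_SHIFT_SCALES["formant_f1"] * d["formant_f1"] + rng.normal(0.0, 40.0), f1b)
    lo, hi = base.n_utterances_range
    shift = _AUDIO_SHIFT_SCALES["utterance_count"] * d["utterance_count"]
    lo_i = max(1, int(round(lo + shift + rng.normal(0.0, 1.0))))
    hi_i = max(lo_i, int(round(hi + shift)))
    params = replace(
        base,
        f0_base=max(200.0, f0),
        hyperphonation_prob=hyp,
        fricative_prob=fric,
        formants=tuple(formants),
    )
    n_utt = int(rng.integers(lo_i, hi_i + 1))
    return params, n_utt


#: feature_table mode: family → informative column names per analyzer.
_TABLE_FAMILY_COLUMNS = {
    "cepstral": {
        "hyperphonation": "hyperphonation_rate",
        "f0": "f0_mean",
        "formant_f1": "f1_mean",
        "energy": "energy_low_db",
        "fricative": "fricative_score_mean",
        "utterance_count": "utterance_count",
    },
    "spectral": {
        "f0": "f0_mean",
        "formant_f1": "f1_mean",
        "formant_f2": "f2_mean",
        "energy": "amp_envelope_mean",
        "entropy": "spectral_entropy_mean",
        "novelty": "novelty_mean",
        "utterance_count": "utterance_count",
    },
}


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a synthetic cohort per ``spec``.

    The NOWS group's synthesis parameters (audio mode) or informative
    feature columns (feature_table mode) are shifted by the standardized
    effects in ``spec.effect_map``; the two control subgroups are drawn from
    the unshifted distribution. Labels are 1 for the NOWS group, 0
    otherwise; subgroup tags are retained for sensitivity analyses. Output
    is fully determined by ``spec.seed``.
    """
    import pandas as pd

    subgroups = (
        ["nows"] * spec.n_nows
        + ["exposed_no_nows"] * spec.n_exposed_no_nows
        + ["unexposed"] * spec.n_unexposed
    )
    infant_ids = [f"inf{i:03d}" for i in range(len(subgroups))]
    labels = [1 if s == "nows" else 0 for s in subgroups]
    manifest = pd.DataFrame(
        {"infant_id": infant_ids, "subgroup": subgroups, "label": labels}
    )

    if spec.mode == "audio":
        recordings: dict[str, tuple[AudioSegment, list[tuple[float, float]]]] = {}
        for iid, sub in zip(infant_ids, subgroups):
            rng = np.random.default_rng(derive_seed(spec.seed, "params", iid))
            params, n_utt = _infant_params(
                spec.base_params, spec.effect_map, shifted=(sub == "nows"), rng=rng
            )
            recordings[iid] = synthesize_recording(
                params, n_utt, derive_seed(spec.seed, "audio", iid), infant_id=iid
            )
        return Cohort(manifest, recordings, None, spec)

    # feature_table mode
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    shift = np.asarray([1.0 if s == "nows" else 0.0 for s in subgroups])
    for analyzer, stratum in TABLE_KEYS:
        rng = np.random.default_rng(derive_seed(spec.seed, "table", analyzer, stratum))
        cols: dict[str, np.ndarray] = {}
        fam_cols = _TABLE_FAMILY_COLUMNS[analyzer]
        for family, col in fam_cols.items():
            d = spec.effect_map.get(family, 0.0)
            cols[col] = rng.standard_normal(len(subgroups)) + d * shift
        for j in range(spec.n_noise_features):
            cols[f"noise_{j:02d}"] = rng.standard_normal(len(subgroups))
        table = pd.DataFrame(cols)
        table.insert(0, "infant_id", infant_ids)
        table["label"] = labels
        table["subgroup"] = subgroups
        tables[(analyzer, stratum)] = table
    return Cohort(manifest, None, tables, spec)


# ---------------------------------------------------------------------------
# FNAST (Finnegan score) simulator
# ---------------------------------------------------------------------------


def fnast_treated(scores: Sequence[int]) -> bool:
    """Pharmacological-treatment rule: two consecutive scores >= 8, or any
    single score >= 12."""
    if any(s >= 12 for s in scores):
        return True
    return any(a >= 8 and b >= 8 for a, b in zip(scores, scores[1:]))


def simulate_fnast_series(
    withdrawal_severity: float,
    seed: int,
    infant_id: str = "",
    n_assessments: int = 16,
) -> tuple[FnastSeries, bool]:
    """Simulate FNAST scores at 3-hour intervals from a latent severity.

    Scores are drawn around a mean that increases with severity (severity 0
    gives a mean near 3, severity ~1.5 pushes repeated scores past the
    treatment thresholds). Returns the series and whether the treatment rule
    fires. Optional alternative to subgroup-membership labels.
    """
    if not np.isfinite(withdrawal_severity):
        raise ValueError("withdrawal_severity must be finite")
    rng = np.random.default_rng(seed)
    mean = 3.0 + 4.0 * withdrawal_severity
    scores = np.clip(np.round(rng.normal(mean, 1.5, size=n_assessments)), 0, 46)
    series = FnastSeries(infant_id, [int(s) for s in scores])
    return series, fnast_treated(series.scores)
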