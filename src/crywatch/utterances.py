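"""Utterance segmentation, duration stratification, and summarization.

A cry utterance is a vocalization during one expiratory phase. Utterances
are detected as maximal runs of frames whose total energy exceeds the
recording's noise floor by a threshold and that are sufficiently voiced
(the voicing requirement approximates the expiratory-phase restriction,
since inspiratory sounds are mostly unvoiced and short). Utterances are
stratified into short (< 500 ms) and long (>= 500 ms), summarized per
utterance (mean and missing-rate per feature), and aggregated per infant
(unweighted mean of utterance means, mean missing-rate, utterance count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .audio import AudioSegment, read_wav
from .frontend import CEPSTRAL, SPECTRAL, AnalyzerProfile, FrameSeries, analyze

__all__ = [
    "SegmentationConfig",
    "Utterance",
    "UtteranceFeatureRow",
    "segment_utterances",
    "classify_stratum",
    "summarize_utterance",
    "aggregate_infant",
    "build_feature_tables",
    "STRATUM_SPLIT_MS",
]

STRATUM_SPLIT_MS = 500.0

#: Feature columns that are frame-level metadata, not acoustic summaries.
_META_COLS = ("frame_time", "voiced")


@dataclass(frozen=True)
class SegmentationConfig:
    """Energy-based utterance detection parameters.

    The noise floor is the 10th percentile of frame energy over the
    recording; frames more than ``threshold_db`` above it are active. Active
    runs closer than ``merge_gap_ms`` are merged, runs shorter than
    ``min_dur_ms`` are dropped, and runs with a voiced-frame fraction below
    ``min_voiced_fraction`` are discarded as non-expiratory sounds.
    """

    threshold_db: float = 15.0
    min_dur_ms: float = 50.0
    merge_gap_ms: float = 50.0
    min_voiced_fraction: float = 0.3
    noise_floor_percentile: float = 10.0


@dataclass
class Utterance:
    start_s: float
    end_s: float
    stratum: str
    frame_start: int  # index into the FrameSeries, inclusive
    frame_end: int  # exclusive

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("utterance must have positive duration")

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass
class UtteranceFeatureRow:
    """Per-utterance summary: mean and missing-rate for each feature."""

    infant_id: str
    analyzer_id: str
    stratum: str
    duration_ms: float
    means: dict[str, float]
    missing: dict[str, float]


def classify_stratum(duration_ms: float) -> str:
    """'short' for durations < 500 ms, 'long' for >= 500 ms."""
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    return "short" if duration_ms < STRATUM_SPLIT_MS else "long"


def segment_utterances(
    series: FrameSeries, cfg: SegmentationConfig = SegmentationConfig()
) -> list[Utterance]:
    """Detect cry utterances in a frame series.

    Returns non-overlapping, time-ordered utterances; silence yields an
    empty list. Utterance end times extend one frame length past the last
    active frame's start.
    """
    if len(series) == 0 or "energy_total" not in series.table:
        return []
    energy = series.table["energy_total"].to_numpy(dtype=float)
    voiced = (
        series.table["voiced"].to_numpy(dtype=bool)
        if "voiced" in series.table
        else np.ones(len(series), dtype=bool)
    )
    floor = np.percentile(energy, cfg.noise_floor_percentile)
    active = energy > floor + cfg.threshold_db
    if not active.any():
        return []

    # maximal runs of active frames as (start, end) frame indices, end exclusive
    edges = np.flatnonzero(np.diff(active.astype(int), prepend=0, append=0))
    runs = list(zip(edges[::2], edges[1::2]))

    # merge runs separated by less than merge_gap_ms
    hop_ms = series.hop_s * 1000.0
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) * hop_ms < cfg.merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out: list[Utterance] = []
    times = series.frame_times
    for s, e in merged:
        start_s = times[s]
        end_s = times[e - 1] + series.frame_len_s
        dur_ms = (end_s - start_s) * 1000.0
        if dur_ms < cfg.min_dur_ms:
            continue
        if np.mean(voiced[s:e]) < cfg.min_voiced_fraction:
            continue
        out.append(Utterance(start_s, end_s, classify_stratum(dur_ms), s, e))
    return out


def summarize_utterance(series: FrameSeries, utt: Utterance) -> UtteranceFeatureRow:
    """Mean over non-missing frames and missing-rate per feature.

    The mean is NaN exactly when every frame is missing (missing-rate 1).
    Boolean frame flags (e.g. hyperphonation) summarize to rates.
    """
    if utt.frame_end <= utt.frame_start or utt.frame_end > len(series):
        raise ValueError("utterance frame range is empty or outside the series")
    chunk = series.table.iloc[utt.frame_start : utt.frame_end]
    means: dict[str, float] = {}
    missing: dict[str, float] = {}
    for col in series.feature_columns():
        vals = chunk[col].to_numpy(dtype=float)
        n_missing = int(np.isnan(vals).sum())
        missing[col] = n_missing / vals.size
        means[col] = float(np.nanmean(vals)) if n_missing < vals.size else np.nan
    return UtteranceFeatureRow(
        infant_id=series.infant_id,
        analyzer_id=series.analyzer_id,
        stratum=utt.stratum,
        duration_ms=utt.duration_ms,
        means=means,
        missing=missing,
    )


def aggregate_infant(
    rows: Sequence[UtteranceFeatureRow],
    infant_id: str,
    stratum: str,
    analyzer_id: str,
    feature_names: Sequence[str] | None = None,
) -> dict[str, float]:
    """One infant-level row: unweighted mean of utterance means, mean of
    utterance missing-rates, and the utterance count.

    With no utterances the count is 0 and every feature is NaN
    (``feature_names`` then supplies the schema).
    """
    if rows:
        if any(
            (r.infant_id, r.stratum, r.analyzer_id) != (infant_id, stratum, analyzer_id)
            for r in rows
        ):
            raise ValueError("rows must all belong to the same infant/stratum/analyzer")
        feats = list(rows[0].means)
    else:
        feats = list(feature_names or [])
    out: dict[str, float] = {"infant_id": infant_id}
    for f in feats:
        if rows:
            m = np.asarray([r.means[f] for r in rows], dtype=float)
            out[f"{f}_mean"] = float(np.nanmean(m)) if not np.isnan(m).all() else np.nan
            out[f"{f}_missing"] = float(np.mean([r.missing[f] for r in rows]))
        else:
            out[f"{f}_mean"] = np.nan
            out[f"{f}_missing"] = np.nan
    out["mean_utterance_dur_ms"] = (
        float(np.mean([r.duration_ms for r in rows])) if rows else np.nan
    )
    out["utterance_count"] = float(len(rows))
    return out


def build_feature_tables(
    manifest: pd.DataFrame,
    recordings: Mapping[str, AudioSegment] | None = None,
    profiles: Sequence[AnalyzerProfile] = (CEPSTRAL, SPECTRAL),
    seg_cfg: SegmentationConfig = SegmentationConfig(),
) -> dict[tuple[str, str], pd.DataFrame]:
    """Infant-by-feature tables for every (analyzer, stratum) pair.

    ``manifest`` needs columns infant_id, label, subgroup and (when
    ``recordings`` is not given) wav_path. Every analyzed infant must appear
    in the manifest; each table carries one row per manifest infant, aligned
    on infant_id, with utterance_count 0 and all-missing features for
    infants with no utterances in that stratum.
    """
    required = {"infant_id", "label", "subgroup"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    manifest_ids = list(manifest["infant_id"])
    if recordings is not None:
        missing = set(recordings) - set(manifest_ids)
        if missing:
            raise ValueError(f"infants missing from manifest: {sorted(missing)}")

    # per (analyzer, stratum, infant): list of utterance rows
    strata = ("short", "long")
    rows_by_key: dict[tuple[str, str, str], list[UtteranceFeatureRow]] = {}
    feature_names: dict[str, list[str]] = {}
    for _, rec in manifest.iterrows():
        iid = rec["infant_id"]
        if recordings is not None:
            audio = recordings[iid]
        else:
            audio = read_wav(rec["wav_path"], infant_id=iid)
        for profile in profiles:
            series = analyze(audio, profile)
            feature_names.setdefault(profile.analyzer_id, series.feature_columns())
            for utt in segment_utterances(series, seg_cfg):
                key = (profile.analyzer_id, utt.stratum, iid)
                rows_by_key.setdefault(key, []).append(summarize_utterance(series, utt))

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for profile in profiles:
        aid = profile.analyzer_id
        for stratum in strata:
            rows = [
                aggregate_infant(
                    rows_by_key.get((aid, stratum, iid), []),
                    iid,
                    stratum,
                    aid,
                    feature_names=feature_names.get(aid, []),
                )
                for iid in manifest_ids
            ]
            table = pd.DataFrame(rows)
            table = table.merge(
                manifest[["infant_id", "label", "subgroup"]], on="infant_id"
            )
            tables[(aid, stratum)] = table
    return tables


def utterance_rows_to_frame(rows: Iterable[UtteranceFeatureRow]) -> pd.DataFrame:
    """Flatten utterance summaries into a tidy per-utterance DataFrame."""
    records = []
    for r in rows:
        rec = {
            "infant_id": r.infant_id,
            "analyzer": r.analyzer_id,
            "stratum": r.stratum,
            "duration_ms": r.duration_ms,
        }
        rec.update({f"{k}_mean": v for k, v in r.means.items()})
        rec.update({f"{k}_missing": v for k, v in r.missing.items()})
        records.append(rec)
    return pd.DataFrame(records)
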