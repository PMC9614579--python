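"""End-to-end pipeline: configuration, seeding, staging, and reporting.

A single JSON-serializable :class:`RunConfig` drives the full analysis:
synthesize (or ingest) a cohort, extract frame features with both analyzer
profiles, segment and summarize utterances into the four infant-level
tables, filter features, run leave-one-out cross-validation with per-fold
ensemble selection and stacking, and write the diagnostic reports (primary
plus the two subgroup sensitivity variants), stability profiles, and a run
manifest with a config hash and per-file checksums. One master seed fans
out to every stochastic stage, so a fixed config reproduces every output
byte-for-byte (checksummed files are CSV/JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .audio import read_wav
from .boruta import stability_profile, plot_stability
from .metrics import plot_roc_pr, subgroup_analysis
from .prep import filter_features
from .stacking import LoocvResult, ModelConfig, loocv_stack
from .synth import Cohort, CohortSpec, generate_cohort, TABLE_KEYS
from .utterances import SegmentationConfig, build_feature_tables

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


_FILTER_DEFAULTS = {
    "max_missing": 0.60,
    "freq_ratio": 19.0,
    "unique_pct": 10.0,
    "corr_cutoff": 0.75,
    "within_folds": False,
}

_EVAL_DEFAULTS = {
    "level": 0.95,
    "subgroup_exclusions": ["unexposed", "exposed_no_nows"],
}


@dataclass
class RunConfig:
    """Validated run configuration; ``to_dict``/``validate_config`` round-trip."""

    seed: int = 0
    out_dir: str = "crywatch_run"
    #: path to a manifest CSV of real recordings; None -> synthesize
    input_manifest: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    filters: dict[str, Any] = field(default_factory=lambda: dict(_FILTER_DEFAULTS))
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: dict[str, Any] = field(default_factory=lambda: dict(_EVAL_DEFAULTS))

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "input_manifest": self.input_manifest,
            "cohort": dataclasses.asdict(self.cohort),
            "segmentation": dataclasses.asdict(self.segmentation),
            "filters": dict(self.filters),
            "model": dataclasses.asdict(self.model),
            "evaluation": dict(self.evaluation),
        }
        # synthesis params serialize as a nested dict
        d["cohort"]["base_params"] = dataclasses.asdict(self.cohort.base_params)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_dataclass(cls, raw: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid {where}: {exc}") from exc


def validate_config(raw: dict | None) -> RunConfig:
    """Validate a raw config dict, filling every default.

    An empty config yields the fully defaulted settings (12.5 ms frames,
    500 ms stratum split, 0.60/0.75 filter cutoffs, 100 selection runs with
    the >5 retention rule, 10 000-tree classifiers). Unknown keys and
    out-of-range values raise ``ValueError``.
    """
    raw = dict(raw or {})
    known = {"seed", "out_dir", "input_manifest", "cohort", "segmentation",
             "filters", "model", "evaluation"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    seed = int(raw.get("seed", 0))
    cohort_raw = dict(raw.get("cohort", {}))
    cohort_raw.setdefault("seed", seed)
    if "base_params" in cohort_raw and isinstance(cohort_raw["base_params"], dict):
        from .synth import CrySynthesisParams

        bp = dict(cohort_raw["base_params"])
        for key in ("f0_contour", "formants"):
            if key in bp:
                bp[key] = tuple(tuple(t) for t in bp[key])
        for key in ("utterance_dur_range_ms", "gap_dur_range_ms", "n_utterances_range"):
            if key in bp:
                bp[key] = tuple(bp[key])
        cohort_raw["base_params"] = _build_dataclass(
            CrySynthesisParams, bp, "cohort.base_params"
        )
    cohort = _build_dataclass(CohortSpec, cohort_raw, "cohort")

    seg = _build_dataclass(SegmentationConfig, dict(raw.get("segmentation", {})), "segmentation")
    if seg.threshold_db <= 0 or seg.min_dur_ms <= 0 or seg.merge_gap_ms < 0:
        raise ValueError("segmentation thresholds must be positive")

    filters = dict(_FILTER_DEFAULTS)
    fraw = dict(raw.get("filters", {}))
    unknown = set(fraw) - set(filters)
    if unknown:
        raise ValueError(f"unknown keys in filters: {sorted(unknown)}")
    filters.update(fraw)
    if not 0 <= filters["max_missing"] <= 1 or not 0 < filters["corr_cutoff"] <= 1:
        raise ValueError("filter cutoffs out of range")

    model_raw = dict(raw.get("model", {}))
    model_raw.setdefault("master_seed", seed)
    model = _build_dataclass(ModelConfig, model_raw, "model")

    evaluation = dict(_EVAL_DEFAULTS)
    eraw = dict(raw.get("evaluation", {}))
    unknown = set(eraw) - set(evaluation)
    if unknown:
        raise ValueError(f"unknown keys in evaluation: {sorted(unknown)}")
    evaluation.update(eraw)
    if not 0.5 < evaluation["level"] < 1:
        raise ValueError("evaluation.level must lie in (0.5, 1)")

    return RunConfig(
        seed=seed,
        out_dir=str(raw.get("out_dir", "crywatch_run")),
        input_manifest=raw.get("input_manifest"),
        cohort=cohort,
        segmentation=seg,
        filters=filters,
        model=model,
        evaluation=evaluation,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory.

    Writes: the four infant-level tables (raw and filtered), per-fold
    predictions, diagnostic reports (primary + subgroup variants) as JSON and
    text, stability profiles with plots, a JSONL stage log, and
    ``manifest.json`` with the config hash, seed, and checksums of every CSV
    and JSON output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    log_fh = open(log_path, "w")
    t_start = time.time()

    def log(stage: str, **info):
        log_fh.write(json.dumps({"stage": stage, "elapsed_s": round(time.time() - t_start, 3), **info}) + "\n")
        log_fh.flush()

    def run_stage(name: str, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            log_fh.close()
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        log(name)
        return result

    # 1. cohort: synthesize or ingest
    if config.input_manifest is not None:
        def ingest():
            manifest = pd.read_csv(config.input_manifest)
            for p in manifest.get("wav_path", []):
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing WAV: {p}")
            return Cohort(manifest, None, None, config.cohort)

        cohort = run_stage(f"ingest ({config.input_manifest})", ingest)
    else:
        cohort = run_stage("synthesize", generate_cohort, config.cohort)
    log("cohort", n_infants=len(cohort.manifest))

    # 2. frame extraction + utterance summarization into 4 tables
    if cohort.feature_tables is not None:
        tables = cohort.feature_tables
    else:
        recordings = (
            {iid: rec for iid, (rec, _) in cohort.recordings.items()}
            if cohort.recordings is not None
            else None
        )
        tables = run_stage(
            "extract+summarize",
            build_feature_tables,
            cohort.manifest,
            recordings=recordings,
            seg_cfg=config.segmentation,
        )
    tables_dir = out / "tables"
    tables_dir.mkdir(exist_ok=True)
    for (a, s), t in tables.items():
        t.to_csv(tables_dir / f"table_{a}_{s}.csv", index=False)
    log("tables", rows={f"{a}_{s}": len(t) for (a, s), t in tables.items()})

    # 3. pre-selection feature filters (once, on the full tables)
    fkw = {k: v for k, v in config.filters.items() if k != "within_folds"}
    filtered: dict = {}
    reports: dict[str, list] = {}
    for key, t in tables.items():
        ft, rep = run_stage(f"filter ({key[0]}/{key[1]})", filter_features, t, **fkw)
        filtered[key] = ft
        reports[f"{key[0]}_{key[1]}"] = rep.removed
        ft.to_csv(tables_dir / f"filtered_{key[0]}_{key[1]}.csv", index=False)
    (out / "filter_report.json").write_text(json.dumps(reports, indent=2, default=float))
    log("filter", kept={f"{a}_{s}": len(v.columns) for (a, s), v in filtered.items()})

    # 4. LOOCV with per-fold selection and stacking
    result: LoocvResult = run_stage("loocv", loocv_stack, filtered, config.model)
    pred_df = result.to_frame()
    pred_df.to_csv(out / "predictions.csv", index=False)
    log("loocv", n_predictions=len(pred_df))

    # per-table stability profiles across folds
    sel_dir = out / "selection"
    sel_dir.mkdir(exist_ok=True)
    if result.fold_selections:
        for key in TABLE_KEYS:
            per_fold = [
                folds[key] for folds in result.fold_selections.values() if key in folds
            ]
            if not per_fold:
                continue
            prof = stability_profile(per_fold)
            prof.to_frame().to_csv(sel_dir / f"stability_{key[0]}_{key[1]}.csv", index=False)
            plot_stability(prof, sel_dir / f"stability_{key[0]}_{key[1]}.svg")
    log("stability")

    # 5. evaluation: primary + subgroup sensitivity variants
    reports_dir = out / "reports"
    reports_dir.mkdir(exist_ok=True)
    variants = [None] + list(config.evaluation["subgroup_exclusions"])
    for exclude in variants:
        rep = run_stage(
            f"evaluate ({exclude or 'primary'})",
            subgroup_analysis,
            pred_df,
            exclude,
            config.evaluation["level"],
        )
        stem = "report_primary" if exclude is None else f"report_exclude_{exclude}"
        rep.write(reports_dir / f"{stem}.json")
        (reports_dir / f"{stem}.txt").write_text(rep.to_text() + "\n")
    plot_roc_pr(pred_df["label"], pred_df["p_stacked"], reports_dir / "roc_pr.svg")
    log("evaluate")

    # 6. manifest with config hash and checksums of deterministic outputs
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    }
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    log("done")
    log_fh.close()
    return out
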