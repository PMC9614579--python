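"""Stacked random-forest classification under leave-one-out cross-validation.

For every held-out infant, the remaining infants' rows in each of the four
feature tables (two analyzers × two utterance strata) go through ensemble
feature selection followed by a probability random forest; the held-out
infant's stacked prediction is the unweighted mean of the class-1
probabilities of the models for which the infant has usable data. Both the
selection and classification steps run inside every fold, so no statistic of
the held-out infant leaks into training.

Missing feature values are median-imputed from the training fold. A model
whose fold-level ensemble selection retains no feature is skipped for that
fold and stacking averages the rest; if every model is skipped (a realistic
outcome on uninformative data), the fold abstains with an uninformative
probability of 0.5 — under a null cohort every infant then ties, keeping the
cross-validated AUC at chance level rather than biasing it. (Predicting the
training prevalence instead would anti-correlate with the held-out label in
leave-one-out splits: removing a positive infant lowers the prevalence, so
positives would systematically receive lower scores than negatives.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._seeding import derive_seed
from .boruta import EnsembleSelectionResult, ensemble_select
from .prep import META_COLUMNS, feature_columns

__all__ = ["ModelConfig", "FoldPrediction", "FittedFold", "LoocvResult",
           "fit_fold", "predict_heldout", "loocv_stack"]

TableKey = tuple[str, str]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the per-fold selection + classification stage.

    Defaults follow common random-forest practice for probability forests:
    mtry = floor(sqrt(p)), minimum node size 10, 10 000 trees for the final
    classifiers. ``boruta_trees``/``n_runs``/``max_iter`` control the
    (cheaper) forests inside ensemble selection. Set ``selection=False`` to
    classify on all filtered features without per-fold selection.
    """

    n_trees: int = 10_000
    mtry: int | None = None
    min_node_size: int = 10
    master_seed: int = 0
    n_runs: int = 100
    retain_threshold: int = 5
    boruta_max_iter: int = 100
    boruta_trees: int = 300
    selection: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if not 0 <= self.retain_threshold <= self.n_runs:
            raise ValueError("retain_threshold must lie in [0, n_runs]")


@dataclass
class FoldPrediction:
    infant_id: str
    model_probs: dict[TableKey, float]
    stacked: float
    label: int
    subgroup: str


@dataclass
class FittedFold:
    """Per-table fitted models plus everything needed to predict unseen rows."""

    models: dict[TableKey, tuple[RandomForestClassifier, list[str], pd.Series]]
    skipped: list[TableKey]
    selections: dict[TableKey, EnsembleSelectionResult]
    fallback: float = 0.5  # stacked probability when every model is skipped


@dataclass
class LoocvResult:
    predictions: list[FoldPrediction]
    #: fold id -> per-table ensemble selection results (for stability profiles)
    fold_selections: dict[str, dict[TableKey, EnsembleSelectionResult]]

    def to_frame(self) -> pd.DataFrame:
        keys = sorted({k for p in self.predictions for k in p.model_probs})
        rows = []
        for p in self.predictions:
            row = {"infant_id": p.infant_id}
            for k in keys:
                row[f"p_{k[0]}_{k[1]}"] = p.model_probs.get(k, np.nan)
            row["p_stacked"] = p.stacked
            row["label"] = p.label
            row["subgroup"] = p.subgroup
            rows.append(row)
        return pd.DataFrame(rows)


def _usable(row: pd.Series, feats: list[str]) -> bool:
    """A row is usable when it has any observed feature (an infant with no
    utterances in a stratum carries an all-missing row)."""
    if "utterance_count" in row.index and row["utterance_count"] == 0:
        return False
    return bool(row[feats].notna().any())


def fit_fold(
    train_tables: Mapping[TableKey, pd.DataFrame],
    config: ModelConfig,
    fold_seed: int,
) -> FittedFold:
    """Fit the four per-table models on training rows only.

    Per table: median imputation from training rows, ensemble Boruta
    selection, then a probability forest on the retained features. Tables
    whose training rows hold a single class or whose retained set is empty
    are skipped.
    """
    models: dict[TableKey, tuple[RandomForestClassifier, list[str], pd.Series]] = {}
    skipped: list[TableKey] = []
    selections: dict[TableKey, EnsembleSelectionResult] = {}

    for key, table in train_tables.items():
        feats = feature_columns(table)
        rows = table[table.apply(lambda r: _usable(r, feats), axis=1)]
        y = rows["label"].to_numpy(dtype=int)
        if len(rows) < 2 or len(np.unique(y)) < 2 or len(feats) < 2:
            skipped.append(key)
            continue
        medians = rows[feats].median()
        X = rows[feats].fillna(medians)
        seed = derive_seed(fold_seed, "table", *key)
        if config.selection:
            sel = ensemble_select(
                X,
                y,
                seed=seed,
                n_runs=config.n_runs,
                retain_threshold=config.retain_threshold,
                fold_id=f"{key[0]}_{key[1]}",
                max_iter=config.boruta_max_iter,
                n_trees=config.boruta_trees,
            )
            selections[key] = sel
            retained = sel.retained
        else:
            retained = feats
        if not retained:
            skipped.append(key)
            continue
        mtry = config.mtry or max(1, int(np.sqrt(len(retained))))
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=min(mtry, len(retained)),
            min_samples_split=max(2, config.min_node_size),
            n_jobs=1,
            random_state=derive_seed(fold_seed, "forest", *key),
        )
        clf.fit(X[retained].to_numpy(), y)
        models[key] = (clf, retained, medians)

    return FittedFold(models, skipped, selections)


def predict_heldout(
    fold: FittedFold, heldout_rows: Mapping[TableKey, pd.Series | None]
) -> FoldPrediction | None:
    """Stacked prediction for one held-out infant.

    Each available model contributes its class-1 probability for the
    infant's row in that table (training-median imputation for missing
    values); the stacked probability is their unweighted mean. Returns None
    when the infant has no usable row in any table. When rows exist but all
    models were skipped, the uninformative fallback probability (0.5) is used.
    """
    probs: dict[TableKey, float] = {}
    any_usable = False
    infant_id, label, subgroup = "", 0, ""
    for key, row in heldout_rows.items():
        if row is None:
            continue
        infant_id = row.get("infant_id", infant_id)
        label = int(row.get("label", label))
        subgroup = row.get("subgroup", subgroup)
        feats = [c for c in row.index if c not in META_COLUMNS]
        if not _usable(row, feats):
            continue
        any_usable = True
        if key not in fold.models:
            continue
        clf, retained, medians = fold.models[key]
        x = row[retained].astype(float).fillna(medians[retained])
        probs[key] = float(clf.predict_proba(x.to_numpy()[None, :])[0, 1])
    if not any_usable:
        return None
    stacked = float(np.mean(list(probs.values()))) if probs else fold.fallback
    return FoldPrediction(infant_id, probs, stacked, label, subgroup)


def loocv_stack(
    tables: Mapping[TableKey, pd.DataFrame], config: ModelConfig
) -> LoocvResult:
    """Leave-one-out cross-validation of the stacked model.

    One fold per infant: the infant's rows are removed from all four tables,
    models are selected and fitted on the remainder, and the infant receives
    a stacked probability. Per-fold seeds derive from the master seed and
    the infant id, so a fixed configuration reproduces every probability
    exactly.
    """
    first = next(iter(tables.values()))
    infants = list(first["infant_id"])
    labels = first.set_index("infant_id")["label"]
    if min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise ValueError("LOOCV requires at least 2 infants per class")
    for key, t in tables.items():
        if list(t["infant_id"]) != infants:
            raise ValueError(f"table {key} is not aligned on infant_id")

    predictions: list[FoldPrediction] = []
    fold_selections: dict[str, dict[TableKey, EnsembleSelectionResult]] = {}
    for infant in infants:
        train = {k: t[t["infant_id"] != infant].reset_index(drop=True) for k, t in tables.items()}
        heldout = {
            k: t[t["infant_id"] == infant].iloc[0] for k, t in tables.items()
        }
        fold_seed = derive_seed(config.master_seed, "fold", infant)
        fold = fit_fold(train, config, fold_seed)
        if fold.selections:
            fold_selections[infant] = fold.selections
        pred = predict_heldout(fold, heldout)
        if pred is not None:
            predictions.append(pred)
    return LoocvResult(predictions, fold_selections)
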