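"""The information-free classifier experiment.

Extract a submatrix of the raw counts that is identically zero (rare-genus
filter, then drop any sample with a nonzero entry), populate it with the
corresponding normalized values, train one-vs-all gradient-boosted tree
classifiers with stratified cross-validation, and measure how accurate they
are. On honest normalization the answer must be chance; high accuracy here
is direct proof that the normalization wrote the class labels into the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from ._rng import stage_seed
from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "EvalConfig",
    "ClassifierEvaluation",
    "extract_empty_submatrix",
    "populate_from_normalized",
    "one_vs_all_evaluate",
    "run_fig6_experiment",
]

logger = logging.getLogger(__name__)


def extract_empty_submatrix(
    raw: CountMatrix, prevalence_cutoff: int = 50
) -> CountMatrix:
    """Keep genera nonzero in fewer than ``prevalence_cutoff`` samples, then
    drop every sample with a nonzero retained entry. The result is
    identically zero by construction (an empty result only warns)."""
    nnz = (raw.counts != 0).sum(axis=0)
    keep_features = nnz.index[nnz < prevalence_cutoff].tolist()
    sub = raw.counts[keep_features]
    keep_samples = sub.index[(sub != 0).sum(axis=1) == 0].tolist()
    if not keep_samples or not keep_features:
        logger.warning(
            "empty-submatrix extraction produced %d samples x %d features",
            len(keep_samples),
            len(keep_features),
        )
    out = raw.subset(sample_ids=keep_samples, genus_ids=keep_features)
    assert (out.counts.to_numpy() == 0).all()
    return out


def populate_from_normalized(
    empty: CountMatrix, normalized: NormalizedMatrix
) -> tuple[pd.DataFrame, int]:
    """Fill the empty matrix's cells from the normalized data, by id.

    Features of ``empty`` absent from the normalized matrix are dropped
    (their number is returned and logged); a missing sample is an error.
    The join is keyed on (sample_id, genus_id), so row order of the
    normalized matrix is irrelevant.
    """
    missing_samples = [
        s for s in empty.sample_ids if s not in normalized.values.index
    ]
    if missing_samples:
        raise ValueError(
            f"samples missing from normalized matrix: {missing_samples[:5]}"
        )
    features = [g for g in empty.genus_ids if g in normalized.values.columns]
    n_dropped = len(empty.genus_ids) - len(features)
    if n_dropped:
        logger.info("dropped %d features absent from normalized data", n_dropped)
    populated = normalized.values.loc[empty.sample_ids, features]
    return populated, n_dropped


@dataclass(frozen=True)
class EvalConfig:
    """One-vs-all evaluation settings (gradient-boosted shallow trees)."""

    n_folds: int = 10
    n_estimators: int = 150
    max_depth: int = 3
    learning_rate: float = 0.1
    seed: int = 0

    @classmethod
    def from_mapping(cls, m: Mapping | None) -> "EvalConfig":
        return cls(**dict(m)) if m else cls()

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "model": {
                "family": "gradient_boosted_trees",
                "n_estimators": self.n_estimators,
                "max_depth": self.max_depth,
                "learning_rate": self.learning_rate,
            },
            "seed": self.seed,
        }


@dataclass
class ClassifierEvaluation:
    """Per-class cross-validated metrics and their medians.

    ``per_class`` has one row per class: auc, sensitivity, specificity,
    ppv, npv (at probability threshold 0.5), n_pos, n_folds. Undefined
    metrics (0/0) are NaN and excluded from the medians.
    """

    per_class: pd.DataFrame
    medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.medians:
            self.medians = {
                m: float(np.nanmedian(self.per_class[m]))
                for m in ("auc", "sensitivity", "specificity", "ppv", "npv")
            }

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.round(6).to_dict(orient="index"),
            "medians": {k: round(v, 6) for k, v in self.medians.items()},
        }


def _safe_div(num: int, den: int) -> float:
    return num / den if den else float("nan")


def one_vs_all_evaluate(
    matrix: pd.DataFrame | NormalizedMatrix,
    class_labels: pd.Series,
    config: EvalConfig | Mapping | None = None,
) -> ClassifierEvaluation:
    """Cross-validated one-vs-all classifiers, one per class.

    For each class, a binary gradient-boosted tree model is evaluated with
    stratified k-fold cross-validation (folds reduced for classes smaller
    than ``n_folds``, and logged); out-of-fold probabilities give hard-call
    metrics at 0.5 and a trapezoidal ROC AUC.
    """
    cfg = config if isinstance(config, EvalConfig) else EvalConfig.from_mapping(config)
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    y_all = class_labels.loc[values.index]
    classes = sorted(pd.unique(y_all))
    if len(classes) < 2:
        raise ValueError("need at least two classes for one-vs-all evaluation")
    x = values.to_numpy(dtype=float)

    rows = {}
    for cls in classes:
        y = (y_all == cls).to_numpy()
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        n_folds = min(cfg.n_folds, n_pos, n_neg)
        if n_folds < cfg.n_folds:
            logger.info("class %s: folds reduced to %d", cls, n_folds)
        if n_folds < 2:
            rows[str(cls)] = dict.fromkeys(
                ("auc", "sensitivity", "specificity", "ppv", "npv"), float("nan")
            ) | {"n_pos": n_pos, "n_folds": n_folds}
            continue
        cls_seed = stage_seed(cfg.seed, f"ova:{cls}")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cls_seed)
        prob = np.empty(len(y))
        for train, test in skf.split(x, y):
            model = XGBClassifier(
                n_estimators=cfg.n_estimators,
                max_depth=cfg.max_depth,
                learning_rate=cfg.learning_rate,
                tree_method="hist",
                n_jobs=1,
                random_state=cls_seed,
                eval_metric="logloss",
            )
            model.fit(x[train], y[train])
            prob[test] = model.predict_proba(x[test])[:, 1]
        pred = prob >= 0.5
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        tn = int((~pred & ~y).sum())
        fn = int((~pred & y).sum())
        rows[str(cls)] = {
            "auc": float(roc_auc_score(y, prob)),
            "sensitivity": _safe_div(tp, tp + fn),
            "specificity": _safe_div(tn, tn + fp),
            "ppv": _safe_div(tp, tp + fp),
            "npv": _safe_div(tn, tn + fn),
            "n_pos": n_pos,
            "n_folds": n_folds,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    per_class.index.name = "class"
    return ClassifierEvaluation(per_class)


def run_fig6_experiment(
    raw: CountMatrix,
    normalized: NormalizedMatrix,
    config: EvalConfig | Mapping | None = None,
    prevalence_cutoff: int = 50,
    sample_type: str | None = "tumor",
) -> tuple[ClassifierEvaluation, dict]:
    """End-to-end leakage experiment on one raw/normalized matrix pair.

    Chains: empty-submatrix extraction -> population from normalized values
    -> restriction to primary-tumor samples -> one-vs-all evaluation. The
    provenance report certifies that every classified cell was zero in the
    raw counts, so any accuracy above chance is a normalization artifact.
    """
    cfg = config if isinstance(config, EvalConfig) else EvalConfig.from_mapping(config)
    empty = extract_empty_submatrix(raw, prevalence_cutoff=prevalence_cutoff)
    populated, n_dropped = populate_from_normalized(empty, normalized)
    meta = empty.metadata
    if sample_type is not None:
        keep = meta.index[meta["sample_type"] == sample_type]
        populated = populated.loc[keep]
        meta = meta.loc[keep]
    labels = meta["class_label"]
    evaluation = one_vs_all_evaluate(populated, labels, cfg)
    provenance = {
        "n_samples": int(populated.shape[0]),
        "n_features": int(populated.shape[1]),
        "n_features_dropped": n_dropped,
        "prevalence_cutoff": prevalence_cutoff,
        "sample_type_filter": sample_type,
        "raw_submatrix_all_zero": bool(
            (raw.counts.loc[populated.index, populated.columns].to_numpy() == 0).all()
        ),
        "n_classes": int(labels.nunique()),
        "config": cfg.to_dict(),
    }
    return evaluation, provenance
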