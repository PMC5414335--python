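"""Repeated cross-validated AUC for signature scores plus clinical covariates.

Evaluation design: a classifier (random forest at library defaults unless a
different estimator is supplied) is trained on clinical covariates with or
without per-sample signature scores, and judged by 10-fold cross-validation
repeated many times. Folds are stratified by response so every fold contains
both classes; one AUC is computed per repeat on the pooled out-of-fold class
scores, and repeats share fold assignments across feature-set variants so
comparisons are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import ClinicalTable
from .response import roc_auc

logger = logging.getLogger(__name__)

__all__ = ["FeatureTable", "CVResult", "CLINICAL_FEATURES", "build_feature_table",
           "repeated_cv_auc", "compare_feature_sets"]

#: The seven baseline clinical covariates.
CLINICAL_FEATURES = ("age", "stage", "grade", "er", "pr", "her2", "nodal")
_CATEGORICAL = ("er", "pr", "her2", "nodal", "subtype")


@dataclass
class FeatureTable:
    """Encoded design matrix, binary response labels, and provenance."""

    X: pd.DataFrame
    y: np.ndarray  # True = pCR
    provenance: dict[str, str]
    level_maps: dict[str, dict]
    n_dropped_missing_label: int = 0

    @property
    def feature_names(self) -> list[str]:
        return self.X.columns.tolist()

    def with_labels(self, y: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X, np.asarray(y, dtype=bool), self.provenance,
                            self.level_maps, self.n_dropped_missing_label)


@dataclass
class CVResult:
    """Per-repeat AUCs of one repeated cross-validation run."""

    aucs: np.ndarray
    folds: int
    repeats: int
    seed: object = None

    def __post_init__(self) -> None:
        self.aucs = np.asarray(self.aucs, dtype=float)

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.aucs) > 1 else 0.0


def build_feature_table(
    clinical: ClinicalTable,
    score_sets: dict[str, pd.Series] | None = None,
    include=("clinical",),
) -> FeatureTable:
    """Assemble the design matrix from clinical covariates and score vectors.

    ``include`` lists clinical feature names (``"clinical"`` expands to all
    seven baseline covariates) and/or keys of ``score_sets``. Categorical
    covariates are integer-encoded with the level maps stored; missing
    covariate values are imputed by the feature mode (categorical/ordinal)
    or median (numeric) with a missingness indicator column added. Samples
    with a missing response label are dropped and counted.
    """
    include = list(include)
    if not include:
        raise ValueError("include must name at least one feature")
    expanded: list[str] = []
    for f in include:
        expanded.extend(CLINICAL_FEATURES if f == "clinical" else [f])
    score_sets = score_sets or {}
    unknown = [f for f in expanded
               if f not in CLINICAL_FEATURES and f != "subtype" and f not in score_sets]
    if unknown:
        raise KeyError(f"unknown features requested: {unknown}")

    resp = clinical.data["response"]
    keep = resp.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_feature_table: dropped %d samples with missing response", n_dropped)
    data = clinical.data.loc[keep]
    y = (resp[keep] == "pCR").to_numpy()

    cols: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    level_maps: dict[str, dict] = {}
    for f in expanded:
        if f in score_sets:
            s = score_sets[f]
            missing = [i for i in data.index if i not in s.index]
            if missing:
                raise ValueError(f"score set {f!r} is missing samples: {missing[:5]}")
            cols[f] = s.loc[data.index].to_numpy(dtype=float)
            provenance[f] = "score"
            continue
        raw = data[f]
        if f in _CATEGORICAL:
            levels = sorted(raw.dropna().unique(), key=str)
            level_maps[f] = {lev: i for i, lev in enumerate(levels)}
            enc = raw.map(level_maps[f]).astype(float)
        else:
            enc = pd.to_numeric(raw, errors="coerce")
        if enc.isna().any():
            fill = enc.mode().iloc[0] if f in _CATEGORICAL or f in ("stage", "grade") else enc.median()
            cols[f + "_missing"] = enc.isna().to_numpy(dtype=float)
            provenance[f + "_missing"] = "indicator"
            enc = enc.fillna(fill)
        cols[f] = enc.to_numpy(dtype=float)
        provenance[f] = "clinical"
    X = pd.DataFrame(cols, index=data.index)
    if X.columns.has_duplicates:
        raise ValueError("duplicate feature names")
    return FeatureTable(X, y, provenance, level_maps, n_dropped)


def _default_model():
    return RandomForestClassifier()


def _seed_streams(seed, repeats: int, folds: int):
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    model_seeds = rng.integers(0, 2**31 - 1, size=(repeats, folds))
    return fold_seeds, model_seeds


def _one_repeat(ft: FeatureTable, splitter, model, model_seeds_r) -> float:
    oof = np.empty(len(ft.y))
    X = ft.X.to_numpy(dtype=float)
    for k, (tr, te) in enumerate(splitter.split(X, ft.y)):
        est = clone(model)
        if "random_state" in est.get_params():
            est.set_params(random_state=int(model_seeds_r[k]))
        est.fit(X[tr], ft.y[tr])
        if hasattr(est, "predict_proba"):
            oof[te] = est.predict_proba(X[te])[:, list(est.classes_).index(True)]
        else:
            oof[te] = est.decision_function(X[te])
    return roc_auc(oof, ft.y).auc


def repeated_cv_auc(
    ft: FeatureTable,
    folds: int = 10,
    repeats: int = 100,
    seed=None,
    model=None,
    stratified: bool = True,
) -> CVResult:
    """Mean/SD AUC over repeated k-fold cross-validation.

    Per repeat, samples are divided into ``folds`` random label-stratified
    subsets (``stratified=False`` gives plain random folds), out-of-fold
    class scores are pooled, and a single AUC is computed via the threshold
    sweep. Identical inputs and seed reproduce the AUC list exactly.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n_pos, n_neg = int(ft.y.sum()), int((~ft.y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if stratified and min(n_pos, n_neg) < folds:
        raise ValueError(
            f"minority class has {min(n_pos, n_neg)} samples; cannot stratify into {folds} folds"
        )
    model = model if model is not None else _default_model()
    fold_seeds, model_seeds = _seed_streams(seed, repeats, folds)
    cls = StratifiedKFold if stratified else KFold
    aucs = np.empty(repeats)
    for r in range(repeats):
        splitter = cls(n_splits=folds, shuffle=True, random_state=int(fold_seeds[r]))
        aucs[r] = _one_repeat(ft, splitter, model, model_seeds[r])
    return CVResult(aucs, folds=folds, repeats=repeats, seed=seed)


def compare_feature_sets(
    variants: dict[str, FeatureTable],
    folds: int = 10,
    repeats: int = 100,
    seed=None,
    model=None,
    stratified: bool = True,
) -> pd.DataFrame:
    """Paired repeated-CV comparison of feature-set variants.

    All variants must cover the same samples in the same order; fold
    assignments and per-fold model seeds are shared across variants within a
    repeat, so differences in mean AUC reflect the features alone. Returns a
    table with mean/sd AUC and the mean-AUC difference against the first
    variant.
    """
    names = list(variants)
    if not names:
        raise ValueError("no variants given")
    ref = variants[names[0]]
    for name in names[1:]:
        ft = variants[name]
        if list(ft.X.index) != list(ref.X.index) or not np.array_equal(ft.y, ref.y):
            raise ValueError(f"variant {name!r} covers different samples or labels")
    results = {name: repeated_cv_auc(variants[name], folds=folds, repeats=repeats,
                                     seed=seed, model=model, stratified=stratified)
               for name in names}
    base = results[names[0]].mean_auc
    table = pd.DataFrame(
        {
            "mean_auc": [results[n].mean_auc for n in names],
            "sd_auc": [results[n].sd_auc for n in names],
            "mean_auc_diff": [results[n].mean_auc - base for n in names],
        },
        index=pd.Index(names, name="variant"),
    )
    table.attrs["cv_results"] = results
    return table
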