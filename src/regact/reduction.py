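"""Distill a genome-wide activity score into a small control-normalized panel.

Workflow: select target genes whose expression correlates highly (Pearson
R > 0.8 by default) with the full-signature iRAS; express each panel gene
relative to the mean of five housekeeping control genes (ACTB, GAPDH, RPLP0,
GUSB, TFRC); fit the first principal component of the gene-wise-centered
relative-expression matrix; score new samples as

    score = sum_i beta_i * (e_i - c_i)

with ``beta_i`` the PC1 loading, ``e_i`` the control-relative log expression
and ``c_i`` the stored centering offset of panel gene ``i``. The centering
offsets shift the score by a sample-independent constant relative to the
uncentered linear form, leaving rankings, correlations and ROC curves
unchanged while making out-of-cohort scoring well defined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix, TargetSignature

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CONTROL_GENES",
    "ReducedSignatureModel",
    "select_correlated_genes",
    "relative_expression",
    "fit_reduced_model",
    "score_reduced",
    "ReducedSignaturePanel",
]

DEFAULT_CONTROL_GENES = ("ACTB", "GAPDH", "RPLP0", "GUSB", "TFRC")

_SCHEMA_VERSION = 1


@dataclass
class ReducedSignatureModel:
    """Serializable linear panel: genes, PC1 loadings, controls, offsets."""

    panel_genes: list[str]
    loadings: np.ndarray
    centering_offsets: np.ndarray
    control_genes: list[str]
    orientation: int = 1
    fit_metadata: dict = field(default_factory=dict)
    min_coverage: float = 0.8

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.centering_offsets = np.asarray(self.centering_offsets, dtype=float)
        if len(self.loadings) != len(self.panel_genes):
            raise ValueError("one loading per panel gene required")
        if len(self.centering_offsets) != len(self.panel_genes):
            raise ValueError("one centering offset per panel gene required")
        if not np.any(self.loadings):
            raise ValueError("loadings are all zero")
        clash = set(self.panel_genes) & set(self.control_genes)
        if clash:
            raise ValueError(f"control genes overlap the panel: {sorted(clash)}")

    @property
    def n_genes(self) -> int:
        return len(self.panel_genes)

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "panel_genes": list(self.panel_genes),
            "loadings": self.loadings.tolist(),
            "centering_offsets": self.centering_offsets.tolist(),
            "control_genes": list(self.control_genes),
            "orientation": int(self.orientation),
            "fit_metadata": self.fit_metadata,
            "min_coverage": self.min_coverage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedSignatureModel":
        if d.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {d.get('schema_version')!r}")
        return cls(
            panel_genes=list(d["panel_genes"]),
            loadings=np.asarray(d["loadings"], dtype=float),
            centering_offsets=np.asarray(d["centering_offsets"], dtype=float),
            control_genes=list(d["control_genes"]),
            orientation=int(d.get("orientation", 1)),
            fit_metadata=dict(d.get("fit_metadata", {})),
            min_coverage=float(d.get("min_coverage", 0.8)),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "ReducedSignatureModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def select_correlated_genes(
    m: ExpressionMatrix,
    scores,
    threshold: float = 0.8,
    candidates: TargetSignature | list[str] | None = None,
    method: str = "pearson",
) -> list[str]:
    """Target genes whose expression correlates with the score above ``threshold``.

    ``scores`` is an :class:`~regact.scoring.IRASVector`, Series or array
    aligned with the matrix samples. Candidates default to all matrix genes
    but are normally the target signature. Returns genes with correlation
    strictly greater than ``threshold``, sorted by descending correlation.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to correlate")
    s = _score_array(scores, m.sample_ids)
    cand = list(candidates.genes) if isinstance(candidates, TargetSignature) else (
        list(candidates) if candidates is not None else m.gene_symbols
    )
    present = [g for g in cand if g in m.values.index]
    if len(present) < len(cand):
        logger.info("select_correlated_genes: %d candidates absent from matrix", len(cand) - len(present))
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    selected: list[tuple[str, float]] = []
    X = m.values.loc[present].to_numpy(dtype=float)
    for g, row in zip(present, X):
        if np.std(row) == 0:
            continue
        r = float(corr_fn(row, s)[0])
        if r > threshold:
            selected.append((g, r))
    selected.sort(key=lambda gr: -gr[1])
    logger.info("select_correlated_genes: %d of %d candidates pass R > %g", len(selected), len(present), threshold)
    return [g for g, _ in selected]


def _score_array(scores, sample_ids) -> np.ndarray:
    from .scoring import IRASVector

    if isinstance(scores, IRASVector):
        scores = scores.as_series()
    if isinstance(scores, pd.Series):
        missing = [s for s in sample_ids if s not in scores.index]
        if missing:
            raise ValueError(f"scores missing for samples: {missing[:5]}")
        return scores.loc[list(sample_ids)].to_numpy(dtype=float)
    arr = np.asarray(scores, dtype=float)
    if len(arr) != len(sample_ids):
        raise ValueError("score vector length does not match number of samples")
    return arr


def relative_expression(
    m: ExpressionMatrix,
    panel: list[str],
    controls=DEFAULT_CONTROL_GENES,
) -> pd.DataFrame:
    """Panel expression relative to the mean of the control genes, per sample.

    Returns a samples x panel-genes DataFrame of ``e_i = x_i - mean(controls)``
    (log scale). Panel genes absent from the matrix appear as NaN columns;
    missing control genes are dropped with a warning, at least one required.
    """
    present_controls = [g for g in controls if g in m.values.index]
    if not present_controls:
        raise ValueError(f"none of the control genes {list(controls)} are in the matrix")
    if len(present_controls) < len(controls):
        logger.warning(
            "relative_expression: control genes missing from matrix: %s",
            sorted(set(controls) - set(present_controls)),
        )
    ctrl_mean = m.values.loc[present_controls].mean(axis=0)  # per sample
    out = pd.DataFrame(index=m.values.columns, columns=list(panel), dtype=float)
    for g in panel:
        if g in m.values.index:
            out[g] = (m.values.loc[g] - ctrl_mean).to_numpy()
    return out


def fit_reduced_model(
    rel: pd.DataFrame,
    reference_scores,
    controls=DEFAULT_CONTROL_GENES,
    explained_variance_floor: float = 0.2,
    dataset_id: str | None = None,
    selection_threshold: float | None = None,
) -> ReducedSignatureModel:
    """Fit PC1 loadings on a samples x panel-genes relative-expression matrix.

    Panel genes entirely missing from ``rel`` are dropped and the model refit
    on the remainder (mirroring a 34 -> 28 gene reduction when some panel
    genes are absent from the fitting dataset). PCA is on the gene-wise
    mean-centered covariance (no variance scaling); the PC1 sign is fixed so
    panel scores correlate positively with ``reference_scores``.
    """
    keep = [g for g in rel.columns if rel[g].notna().all()]
    dropped = [g for g in rel.columns if g not in keep]
    if dropped:
        logger.info("fit_reduced_model: dropping %d panel genes absent from fitting data: %s",
                    len(dropped), dropped[:8])
    if len(keep) < 2:
        raise ValueError("need at least 2 panel genes with complete data")
    if len(rel) < 3:
        raise ValueError("need at least 3 samples to fit PC1")
    X = rel[keep].to_numpy(dtype=float)
    offsets = X.mean(axis=0)
    Xc = X - offsets
    # PC1 via SVD of the centered matrix (covariance PCA).
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    beta = vt[0]
    ev = float(svals[0] ** 2 / np.sum(svals**2))
    if ev < explained_variance_floor:
        logger.warning("fit_reduced_model: PC1 explains only %.1f%% of panel variance", 100 * ev)
    ref = _score_array(reference_scores, list(rel.index))
    raw_scores = Xc @ beta
    orientation = 1
    if np.corrcoef(raw_scores, ref)[0, 1] < 0:
        beta = -beta
        orientation = -1
    return ReducedSignatureModel(
        panel_genes=list(keep),
        loadings=beta,
        centering_offsets=offsets,
        control_genes=list(controls),
        orientation=orientation,
        fit_metadata={
            "dataset_id": dataset_id,
            "selection_threshold": selection_threshold,
            "explained_variance_ratio": ev,
            "n_genes": len(keep),
            "n_samples": int(len(rel)),
            "n_dropped_at_fit": len(dropped),
        },
    )


def score_reduced(model: ReducedSignatureModel, rel) -> np.ndarray | float:
    """Linear panel score ``sum_i beta_i (e_i - c_i)`` for one or many samples.

    ``rel`` is a Series (one sample) or samples x genes DataFrame of
    control-relative expression. Missing panel genes contribute zero after
    centering (mean imputation in effect); a sample must cover at least
    ``model.min_coverage`` of the panel, else an error lists what is missing.
    """
    single = isinstance(rel, pd.Series)
    frame = rel.to_frame().T if single else rel
    vals = np.full((len(frame), model.n_genes), np.nan)
    for i, g in enumerate(model.panel_genes):
        if g in frame.columns:
            vals[:, i] = frame[g].to_numpy(dtype=float)
    covered = ~np.isnan(vals)
    frac = covered.mean(axis=1)
    if (frac < model.min_coverage).any():
        j = int(np.argmin(frac))
        missing = [g for g, c in zip(model.panel_genes, covered[j]) if not c]
        raise ValueError(
            f"sample {frame.index[j]!r} covers {frac[j]:.0%} of the panel "
            f"(< {model.min_coverage:.0%}); missing genes: {missing[:10]}"
        )
    n_missing = int((~covered).sum())
    if n_missing:
        logger.info("score_reduced: %d missing panel values imputed to the centering mean", n_missing)
    centered = np.where(covered, vals - model.centering_offsets, 0.0)
    scores = centered @ model.loadings
    return float(scores[0]) if single else scores


class ReducedSignaturePanel(BaseEstimator, TransformerMixin):
    """Scikit-learn estimator fitting and applying the reduced linear panel.

    ``fit(X, y)`` takes a samples x genes DataFrame of log expression
    (including the control genes) and the reference activity scores ``y``
    (full-signature iRAS); it selects panel genes among ``candidate_genes``
    by correlation with ``y`` (skipped if ``panel_genes`` is given), computes
    control-relative expression and fits PC1 loadings. ``transform(X)``
    returns the ``(n_samples, 1)`` panel scores.

    Selection and loading fits may use different cohorts: fit a selector on
    one matrix, then pass its ``model_.panel_genes`` as ``panel_genes`` to a
    second estimator fit on the other matrix.
    """

    def __init__(
        self,
        candidate_genes=None,
        panel_genes=None,
        threshold: float = 0.8,
        controls=DEFAULT_CONTROL_GENES,
        method: str = "pearson",
        min_coverage: float = 0.8,
        explained_variance_floor: float = 0.2,
        dataset_id: str | None = None,
    ):
        self.candidate_genes = candidate_genes
        self.panel_genes = panel_genes
        self.threshold = threshold
        self.controls = controls
        self.method = method
        self.min_coverage = min_coverage
        self.explained_variance_floor = explained_variance_floor
        self.dataset_id = dataset_id

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame")
        m = ExpressionMatrix(X.T)
        if self.panel_genes is not None:
            panel = [g for g in self.panel_genes if g not in set(self.controls)]
        else:
            cand = self.candidate_genes
            panel = select_correlated_genes(
                m, np.asarray(y, dtype=float), threshold=self.threshold,
                candidates=list(cand) if cand is not None else None, method=self.method,
            )
            panel = [g for g in panel if g not in set(self.controls)]
        if len(panel) < 2:
            raise ValueError(f"panel has {len(panel)} genes; need at least 2")
        rel = relative_expression(m, panel, controls=self.controls)
        model = fit_reduced_model(
            rel,
            np.asarray(y, dtype=float),
            controls=self.controls,
            explained_variance_floor=self.explained_variance_floor,
            dataset_id=self.dataset_id,
            selection_threshold=self.threshold if self.panel_genes is None else None,
        )
        model.min_coverage = self.min_coverage
        self.model_ = model
        self.panel_genes_ = list(model.panel_genes)
        self.loadings_ = model.loadings
        self.explained_variance_ratio_ = model.fit_metadata["explained_variance_ratio"]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame")
        rel = relative_expression(
            ExpressionMatrix(X.T), self.model_.panel_genes, controls=self.model_.control_genes
        )
        return np.asarray(score_reduced(self.model_, rel))[:, None]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["panel_score"], dtype=object)
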