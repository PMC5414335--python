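"""Activity-based patient stratification and pCR/RD prediction evaluation.

Stratification either cuts the score distribution at its two outer density
modes (the bimodal full-signature case) or into tertiles (the unimodal
reduced-panel case). Classification accuracy is evaluated by the threshold
sweep: every observed score serves as a cutoff, samples at or below it are
called residual disease (RD) and samples above it pathologic complete
response (pCR); the sweep traces the ROC curve and the AUC is its
trapezoidal area, which equals the Mann-Whitney concordance probability with
ties counted one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityStrata",
    "ROCCurve",
    "StratumResponseTable",
    "stratify_by_modes",
    "stratify_tertiles",
    "stratum_response_table",
    "roc_auc",
    "subgroup_report",
]

STRATA = ("low", "intermediate", "high")


@dataclass
class ActivityStrata:
    """Low/intermediate/high labels plus the thresholds that produced them."""

    method: str  # "modes", "tertiles" or "fixed"
    t_low: float
    t_high: float
    labels: pd.Series  # sample id -> "low"/"intermediate"/"high"

    def __post_init__(self) -> None:
        if self.t_low > self.t_high:
            raise ValueError("t_low must not exceed t_high")

    def counts(self) -> dict[str, int]:
        return {s: int((self.labels == s).sum()) for s in STRATA}


@dataclass
class ROCCurve:
    """Threshold-sweep ROC curve with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


@dataclass
class StratumResponseTable:
    """Per-stratum pCR counts/rates with chi-square and optional Fisher tests."""

    table: pd.DataFrame  # index strata, columns n, n_pcr, pcr_rate
    chi2: float | None
    chi2_p: float | None
    fisher_odds_ratio: float | None = None
    fisher_p: float | None = None
    n_missing_response: int = 0
    baseline_pcr_rate: float = float("nan")
    label: str = ""


def _scores_series(scores) -> pd.Series:
    from .scoring import IRASVector

    if isinstance(scores, IRASVector):
        return scores.as_series()
    if isinstance(scores, pd.Series):
        return scores.astype(float)
    arr = np.asarray(scores, dtype=float)
    return pd.Series(arr, index=pd.RangeIndex(len(arr)))


def _labels_from_thresholds(s: pd.Series, t_low: float, t_high: float) -> pd.Series:
    lab = pd.Series("intermediate", index=s.index, dtype=object)
    lab[s < t_low] = "low"
    lab[s > t_high] = "high"
    return lab


def stratify_by_modes(scores, bandwidth=None, grid_size: int = 512) -> ActivityStrata:
    """Stratify on the outermost local maxima of the score density.

    A Gaussian KDE (Silverman bandwidth by default; ``bandwidth`` overrides
    the scipy ``bw_method``) is evaluated on a ``grid_size``-point grid over
    the data range padded by three bandwidths. The low class is scores below
    the most negative mode, the high class scores above the most positive
    mode, the intermediate class everything between. Raises if fewer than
    two modes are found — use :func:`stratify_tertiles` for unimodal scores.
    """
    s = _scores_series(scores)
    if len(s) < 20:
        raise ValueError("mode-based stratification needs at least 20 samples")
    x = s.to_numpy()
    kde = stats.gaussian_kde(x, bw_method=bandwidth if bandwidth is not None else "silverman")
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])) + 1
    modes = grid[interior]
    if len(modes) < 2:
        raise ValueError(
            "fewer than two density modes detected; the score distribution looks "
            "unimodal — use stratify_tertiles instead"
        )
    t_low, t_high = float(modes.min()), float(modes.max())
    labels = _labels_from_thresholds(s, t_low, t_high)
    logger.info("stratify_by_modes: %d modes, thresholds %.3f / %.3f", len(modes), t_low, t_high)
    return ActivityStrata("modes", t_low, t_high, labels)


def stratify_tertiles(scores) -> ActivityStrata:
    """Sort and divide samples into equal low/intermediate/high thirds.

    The low stratum takes ceil(n/3) samples, the high stratum floor(n/3),
    the remainder is intermediate. Samples tied on a boundary score all go
    to the lower of the two straddled strata, so the labeling depends only
    on the score values.
    """
    s = _scores_series(scores)
    n = len(s)
    if n < 3:
        raise ValueError("tertile stratification needs at least 3 samples")
    n_low = -(-n // 3)
    n_high = n // 3
    order = np.argsort(s.to_numpy(), kind="stable")
    sorted_vals = s.to_numpy()[order]
    labels = pd.Series("intermediate", index=s.index, dtype=object)
    labels.iloc[order[:n_low]] = "low"
    labels.iloc[order[n - n_high:]] = "high"
    b_low = sorted_vals[n_low - 1]  # largest low score
    b_high = sorted_vals[n - n_high]  # smallest high score
    # Ties straddling a boundary drop to the lower stratum.
    labels[(labels == "high") & (s == b_high) & (b_high <= sorted_vals[n - n_high - 1])] = "intermediate"
    labels[(labels == "intermediate") & (s == b_low)] = "low"
    if (labels == "low").all():
        logger.warning("stratify_tertiles: all scores identical; every sample labeled low")
    return ActivityStrata("tertiles", float(b_low), float(b_high), labels)


def _response_labels(clinical: ClinicalTable | pd.Series, index) -> pd.Series:
    resp = clinical.data["response"] if isinstance(clinical, ClinicalTable) else clinical
    return resp.reindex(index)


def stratum_response_table(
    strata: ActivityStrata,
    clinical: ClinicalTable | pd.Series,
    fisher_low_vs_rest: bool = True,
    label: str = "",
) -> StratumResponseTable:
    """Cross-tabulate strata against pCR/RD with chi-square and Fisher tests.

    Samples with missing response are excluded listwise and counted. The
    chi-square is the 3x2 independence test without continuity correction;
    the optional Fisher exact test collapses intermediate+high against low.
    """
    resp = _response_labels(clinical, strata.labels.index)
    ok = resp.notna()
    n_missing = int((~ok).sum())
    resp = resp[ok]
    labels = strata.labels[ok]
    rows = []
    for stratum in STRATA:
        in_s = labels == stratum
        n = int(in_s.sum())
        n_pcr = int((resp[in_s] == "pCR").sum())
        rows.append({"n": n, "n_pcr": n_pcr, "pcr_rate": n_pcr / n if n else float("nan")})
    table = pd.DataFrame(rows, index=pd.Index(STRATA, name="stratum"))
    chi2 = chi2_p = None
    counts = table[table["n"] > 0]
    if (table["n"] == 0).any():
        logger.warning("stratum_response_table: empty stratum; chi-square skipped")
    else:
        cont = np.column_stack([table["n_pcr"], table["n"] - table["n_pcr"]])
        if cont.sum(axis=0).all():
            chi2, chi2_p, *_ = stats.chi2_contingency(cont, correction=False)
            chi2, chi2_p = float(chi2), float(chi2_p)
        else:
            logger.warning("stratum_response_table: degenerate margins; chi-square skipped")
    f_or = f_p = None
    if fisher_low_vs_rest and counts["n"].sum() > 0:
        low_pcr = int(table.loc["low", "n_pcr"])
        low_rd = int(table.loc["low", "n"] - low_pcr)
        rest_pcr = int(table["n_pcr"].sum() - low_pcr)
        rest_rd = int((table["n"] - table["n_pcr"]).sum() - low_rd)
        if (low_pcr + low_rd) and (rest_pcr + rest_rd):
            f_or, f_p = stats.fisher_exact(
                [[low_pcr, low_rd], [rest_pcr, rest_rd]], alternative="two-sided"
            )
            f_or, f_p = float(f_or), float(f_p)
    total = int(table["n"].sum())
    baseline = float(table["n_pcr"].sum() / total) if total else float("nan")
    return StratumResponseTable(
        table=table, chi2=chi2, chi2_p=chi2_p,
        fisher_odds_ratio=f_or, fisher_p=f_p,
        n_missing_response=n_missing, baseline_pcr_rate=baseline, label=label,
    )


def _binary_labels(labels) -> np.ndarray:
    y = pd.Series(labels)
    if y.dtype == bool:
        return y.to_numpy()
    vals = set(y.dropna().unique())
    if vals <= {"pCR", "RD"}:
        return (y == "pCR").to_numpy()
    if vals <= {0, 1}:
        return y.astype(bool).to_numpy()
    raise ValueError(f"labels must be pCR/RD, 0/1 or bool; got {sorted(map(str, vals))[:5]}")


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and AUC from the full threshold sweep.

    Every observed score is used as a cutoff (score <= cutoff predicts RD,
    above predicts pCR), tied scores collapse to one threshold step, and
    sentinel cutoffs anchor the curve at (0,0) and (1,1). The trapezoidal
    AUC equals the probability that a random pCR sample outscores a random
    RD sample, ties counted one half.
    """
    s = np.asarray(_scores_series(scores).to_numpy(), dtype=float)
    y = _binary_labels(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    keep = ~pd.isna(y)
    s, y = s[keep], y[keep].astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    thresholds = np.unique(s)[::-1]  # sweep from the highest cutoff down
    sp = np.sort(s[y])
    sn = np.sort(s[~y])
    tpr = (n_pos - np.searchsorted(sp, thresholds, side="right")) / n_pos
    fpr = (n_neg - np.searchsorted(sn, thresholds, side="right")) / n_neg
    fpr = np.r_[0.0, fpr, 1.0]
    tpr = np.r_[0.0, tpr, 1.0]
    thresholds = np.r_[np.inf, thresholds, -np.inf]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc, n_pos=n_pos, n_neg=n_neg)


def subgroup_report(
    strata: ActivityStrata,
    clinical: ClinicalTable,
    by: str,
) -> dict[str, StratumResponseTable]:
    """Per-level stratum response tables after splitting on a clinical variable.

    ``by`` names a clinical column (``er``, ``stage``, ``subtype``, ...).
    Levels with no samples are omitted; levels where fewer than two strata
    are populated keep their rates but skip the chi-square.
    """
    if by not in clinical.data.columns:
        raise KeyError(f"clinical variable {by!r} not found")
    common = strata.labels.index.intersection(clinical.data.index)
    groups = clinical.data.loc[common, by]
    out: dict[str, StratumResponseTable] = {}
    for level in sorted(groups.dropna().unique(), key=str):
        ids = groups.index[groups == level]
        if len(ids) == 0:
            logger.info("subgroup_report: level %r empty, omitted", level)
            continue
        sub = ActivityStrata(strata.method, strata.t_low, strata.t_high, strata.labels.loc[ids])
        tab = stratum_response_table(sub, clinical, label=f"{by}={level}")
        n_populated = int((tab.table["n"] > 0).sum())
        if n_populated < 2:
            tab.chi2 = tab.chi2_p = None
            logger.info("subgroup_report: level %r has <2 populated strata; test skipped", level)
        out[str(level)] = tab
    return out
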