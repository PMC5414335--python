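"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generative model plants a bimodal latent regulator activity ``a_s``
(mixture of two Gaussians), makes each target gene track it linearly with a
gene-specific positive slope, enriches ER-negative status in the high
activity mode, and couples the probability of pathologic complete response
(pCR) to the activity through a logistic link. Ground truth (per-sample
activity, per-gene slope, mixture component) is returned alongside the data
so recovery can be measured exactly.

Defaults emulate a neoadjuvant breast-cancer expression cohort at desk
scale: 500 samples, 5000 genes of which 199 are signature targets and five
are housekeeping controls, baseline pCR rate near 20%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import ClinicalTable, ExpressionMatrix, ProbesetMatrix, TargetSignature

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorParams",
    "SyntheticCohort",
    "generate_cohort",
    "generate_probeset_view",
    "make_toy_fixtures",
    "solve_baseline_intercept",
]

CONTROL_GENES = ("ACTB", "GAPDH", "RPLP0", "GUSB", "TFRC")


@dataclass
class GeneratorParams:
    """Knobs of the synthetic cohort generator (defaults = study conditions).

    ``mixture_weight`` is the probability of the low-activity mode;
    ``lambda_range`` bounds the per-target slope on latent activity;
    ``er_neg_given_high``/``er_neg_given_low`` give P(ER-negative | mode);
    ``gamma0=None`` solves the logistic intercept so the cohort-level pCR
    rate is ``baseline_pcr``.
    """

    n_samples: int = 500
    n_genes: int = 5000
    n_targets: int = 199
    mixture_weight: float = 0.5
    mu_low: float = -2.0
    mu_high: float = 2.0
    sigma: float = 0.7
    lambda_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 1.0
    er_neg_given_high: float = 0.55
    er_neg_given_low: float = 0.20
    gamma0: float | None = None
    gamma1: float = 1.0
    baseline_pcr: float = 0.2
    baseline_intensity: float = 8.0
    control_intensity: float = 10.0
    control_noise_sd: float = 0.2
    probesets_per_gene: int = 1
    emit_survival: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mixture_weight < 1:
            raise ValueError("mixture_weight must lie in (0, 1)")
        if self.mu_low >= self.mu_high:
            raise ValueError("mu_low must be below mu_high")
        if self.gamma1 < 0 or min(self.lambda_range) < 0:
            raise ValueError("gamma1 and lambda_range must be non-negative")
        if self.n_targets + len(CONTROL_GENES) >= self.n_genes:
            raise ValueError("n_targets (plus controls) must be below n_genes")


@dataclass
class SyntheticCohort:
    """Expression + clinical data with the generating ground truth attached."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    signature: TargetSignature
    truth: pd.DataFrame  # per sample: activity, component, pcr_prob
    gene_lambda: pd.Series  # per target gene: slope on latent activity
    params: GeneratorParams


def solve_baseline_intercept(p: GeneratorParams) -> float:
    """Logistic intercept giving the requested marginal pCR rate.

    Integrates expit(gamma0 + gamma1 * a) over the activity mixture with
    Gauss-Hermite quadrature and solves for gamma0 by bisection.
    """
    if p.gamma0 is not None:
        return float(p.gamma0)
    t, w = np.polynomial.hermite.hermgauss(64)
    w = w / np.sqrt(np.pi)

    def marginal(g0: float) -> float:
        lo = np.sum(w * expit(g0 + p.gamma1 * (p.mu_low + np.sqrt(2) * p.sigma * t)))
        hi = np.sum(w * expit(g0 + p.gamma1 * (p.mu_high + np.sqrt(2) * p.sigma * t)))
        return p.mixture_weight * lo + (1 - p.mixture_weight) * hi

    return float(brentq(lambda g: marginal(g) - p.baseline_pcr, -30.0, 30.0))


def _gene_names(p: GeneratorParams) -> tuple[list[str], list[str]]:
    targets = [f"TG{i:04d}" for i in range(1, p.n_targets + 1)]
    n_bg = p.n_genes - p.n_targets - len(CONTROL_GENES)
    background = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    return targets, background


def generate_cohort(p: GeneratorParams | None = None, **overrides) -> SyntheticCohort:
    """Draw one synthetic cohort; bitwise reproducible for identical params.

    Expression is emitted on a raw log-intensity scale (positive baseline,
    one-channel flavor) with normalization flags unset — run
    ``quantile_normalize`` and ``median_center`` before scoring, as for real
    data.
    """
    if p is None:
        p = GeneratorParams(**overrides)
    elif overrides:
        raise ValueError("pass either a GeneratorParams or keyword overrides, not both")
    rng = np.random.default_rng(p.seed)
    n = p.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    component = rng.random(n) >= p.mixture_weight  # True = high mode
    mu = np.where(component, p.mu_high, p.mu_low)
    activity = rng.normal(mu, p.sigma)

    targets, background = _gene_names(p)
    lam = rng.uniform(*p.lambda_range, size=p.n_targets)
    target_expr = lam[:, None] * activity[None, :] + rng.normal(
        0.0, p.noise_sd, size=(p.n_targets, n)
    )
    bg_expr = rng.normal(0.0, p.noise_sd, size=(len(background), n))
    ctrl_expr = rng.normal(0.0, p.control_noise_sd, size=(len(CONTROL_GENES), n))
    values = pd.DataFrame(
        np.vstack([
            target_expr + p.baseline_intensity,
            bg_expr + p.baseline_intensity,
            ctrl_expr + p.control_intensity,
        ]),
        index=list(targets) + list(background) + list(CONTROL_GENES),
        columns=sample_ids,
    )

    er_neg_p = np.where(component, p.er_neg_given_high, p.er_neg_given_low)
    er_negative = rng.random(n) < er_neg_p
    pr_pos_p = np.where(er_negative, 0.25, 0.80)
    pr_positive = rng.random(n) < pr_pos_p
    her2_positive = rng.random(n) < 0.20

    gamma0 = solve_baseline_intercept(p)
    pcr_prob = expit(gamma0 + p.gamma1 * activity)
    pcr = rng.random(n) < pcr_prob

    stage_latent = 0.3 * activity + rng.normal(0.0, 1.0, n)
    stage = 1 + (stage_latent > 0.4).astype(int) + (stage_latent > 1.4).astype(int)
    grade_latent = 0.5 * activity + rng.normal(0.0, 1.0, n)
    grade = 1 + (grade_latent > -0.3).astype(int) + (grade_latent > 0.9).astype(int)
    age = np.clip(rng.normal(52.0, 10.0, n), 25.0, 85.0).round(1)
    nodal_positive = rng.random(n) < 0.5

    # Residual cancer burden: pCR = RCB0; heavier burden favored at low activity.
    rcb_logits = np.stack([-0.5 * -activity, np.zeros(n), 0.5 * -activity])
    rcb_p = np.exp(rcb_logits) / np.exp(rcb_logits).sum(axis=0)
    rcb_draw = rng.random(n)
    rcb_idx = (rcb_draw[None, :] > np.cumsum(rcb_p, axis=0)).sum(axis=0)
    rcb = np.where(pcr, "RCB0", np.array(["RCB1", "RCB2", "RCB3"])[np.minimum(rcb_idx, 2)])

    subtype = np.where(
        her2_positive, "HER2",
        np.where(er_negative, "basal", np.where(grade >= 3, "luminal_B", "luminal_A")),
    )

    clin = pd.DataFrame(
        {
            "response": np.where(pcr, "pCR", "RD"),
            "rcb_class": rcb,
            "er": np.where(er_negative, "negative", "positive"),
            "pr": np.where(pr_positive, "positive", "negative"),
            "her2": np.where(her2_positive, "positive", "negative"),
            "stage": stage.astype(float),
            "grade": grade.astype(float),
            "age": age,
            "nodal": np.where(nodal_positive, "positive", "negative"),
            "subtype": subtype,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if p.emit_survival:
        hazard_scale = 8.0 * np.exp(-0.3 * activity)
        event_time = rng.exponential(hazard_scale)
        censor_time = rng.uniform(0.0, 15.0, n)
        clin["drfs_time"] = np.minimum(event_time, censor_time).round(3)
        clin["drfs_event"] = event_time <= censor_time
    truth = pd.DataFrame(
        {"activity": activity, "component": np.where(component, "high", "low"),
         "pcr_prob": pcr_prob},
        index=clin.index,
    )
    logger.info(
        "generate_cohort: n=%d, genes=%d, targets=%d, pCR rate %.3f",
        n, p.n_genes, p.n_targets, float(pcr.mean()),
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(values, channel="one_channel"),
        clinical=ClinicalTable(clin),
        signature=TargetSignature("planted_targets", targets),
        truth=truth,
        gene_lambda=pd.Series(lam, index=targets, name="lambda"),
        params=p,
    )


def generate_probeset_view(
    cohort: SyntheticCohort,
    probesets_per_gene: int | None = None,
    offset_scale: float = 2.0,
    noise_sd: float = 0.05,
) -> tuple[ProbesetMatrix, pd.Series]:
    """Expand each gene into several probesets to exercise the collapse rule.

    Each probeset is the gene value plus a per-probeset offset (drawn once,
    continuous, so exactly one probeset per gene has the highest mean) plus
    measurement noise. Returns the probeset matrix and the per-gene best
    probeset ids; with ``offset_scale`` well above ``noise_sd`` the collapse
    rule must recover them exactly.
    """
    k = probesets_per_gene if probesets_per_gene is not None else max(
        1, cohort.params.probesets_per_gene
    )
    if k < 1:
        raise ValueError("probesets_per_gene must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([cohort.params.seed, 1]))
    genes = cohort.expression.values.index
    n = cohort.expression.n_samples
    rows, ids, mapping, best = [], [], {}, {}
    base = cohort.expression.values.to_numpy()
    for gi, g in enumerate(genes):
        offsets = rng.uniform(-offset_scale, 0.0, size=k)
        if k == 1:
            offsets[:] = 0.0
        noise = rng.normal(0.0, noise_sd, size=(k, n)) if noise_sd > 0 else np.zeros((k, n))
        for j in range(k):
            pid = f"{g}_p{j + 1}"
            ids.append(pid)
            mapping[pid] = g
            rows.append(base[gi] + offsets[j] + noise[j])
        best[g] = f"{g}_p{int(np.argmax(offsets)) + 1}"
    values = pd.DataFrame(np.vstack(rows), index=ids, columns=cohort.expression.sample_ids)
    return (
        ProbesetMatrix(values, mapping, channel=cohort.expression.channel),
        pd.Series(best, name="best_probeset"),
    )


_TOY_PROFILES = (
    "gene\tS1\tS2\tS3\n"
    "T1\t10\t3\t10\n"
    "T2\t9\t2\t7\n"
    "T3\t8\t1\t2\n"
    "G1\t7\t10\t9\n"
    "G2\t6\t9\t8\n"
    "G3\t5\t8\t6\n"
    "G4\t4\t7\t5\n"
    "G5\t3\t6\t4\n"
    "G6\t2\t5\t3\n"
    "G7\t1\t4\t1\n"
)
_TOY_GMT = (
    "TOY3\ttargets at known ranks\tT1\tT2\tT3\n"
    "TOP2\ttop two genes of S1\tT1\tT2\n"
    "MIX4\ta mixed set\tT1\tG1\tG4\tG7\n"
)
_TOY_QN = (
    "gene\tS1\tS2\tS3\n"
    "A\t2\t8\t5\n"
    "B\t4\t6\t7\n"
    "C\t6\t4\t9\n"
    "D\t8\t2\t11\n"
)
_TOY_FISHER = "pcr,rd\n1,9\n11,3\n"
_TOY_TERTILE = "sample_id,score\n" + "".join(
    f"K{i},{v}\n" for i, v in enumerate([-4, -3, -2, -1, 0, 1, 2, 3, 4], start=1)
)
_TOY_CLINICAL = (
    "sample_id,response,er,pr,her2,stage,grade,age,nodal\n"
    "S1,pCR,negative,negative,negative,2,3,48,positive\n"
    "S2,RD,positive,positive,negative,1,2,61,negative\n"
    "S3,RD,positive,negative,positive,3,3,55,positive\n"
)


def make_toy_fixtures(outdir) -> dict[str, Path]:
    """Write the tiny deterministic fixture bundle; returns name -> path.

    Contents are fixed strings, hence byte-stable across runs: a 10-gene
    x 3-sample profile matrix whose ``TOY3`` targets occupy ranks 1-3 of S1
    (preliminary score 1.0) and the bottom ranks of S2 (-1.0), a 4x3
    quantile-normalization example, the 2x2 Fisher table [[1,9],[11,3]], a
    9-score tertile case, a 3-signature GMT and a 3-sample clinical CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contents = {
        "profiles.tsv": _TOY_PROFILES,
        "signatures.gmt": _TOY_GMT,
        "qn_example.tsv": _TOY_QN,
        "fisher_2x2.csv": _TOY_FISHER,
        "tertile_scores.csv": _TOY_TERTILE,
        "clinical.csv": _TOY_CLINICAL,
    }
    paths = {}
    for name, text in contents.items():
        path = outdir / name
        path.write_text(text)
        paths[name.split(".")[0]] = path
    return paths
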