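# regact

Single-sample transcription-factor regulatory activity scoring and panel
reduction for bulk expression cohorts, built around the question that
motivates neoadjuvant genomic assays in breast cancer: can a tumor's
proliferative drive — read out through the activity of a cell-cycle
regulator such as E2F4 — predict whether chemotherapy before surgery will
achieve a pathologic complete response (pCR) or leave residual disease (RD)?

`regact` implements the full analysis as a reusable library plus CLI:

1. **BASE/iRAS scoring.** For each sample, genes are ranked from high to low
   normalized expression and two CDFs are walked down the ranking — the
   foreground `F_fg(k)` (fraction of signature target genes in the top *k*)
   and background `F_bg(k)` (fraction of all other genes). The preliminary
   score is the signed maximal deviation

       d(k*) where |F_fg(k) − F_bg(k)| is maximal over k,

   in [−1, 1], positive when targets crowd the top of the profile. It is
   normalized against the mean of 1000 same-sign preliminary scores of
   random equal-size gene sets, giving the individual Regulatory Activity
   Score (iRAS).
2. **Stratification and evaluation.** Cohorts are cut at the outer modes of
   the (typically bimodal) iRAS density — or into tertiles when unimodal —
   and pCR rates are compared across strata (χ², Fisher). Any per-sample
   score is evaluated as a pCR/RD classifier by the full threshold sweep;
   the trapezoidal AUC equals the Mann–Whitney concordance.
3. **Panel reduction.** Target genes whose expression correlates with the
   iRAS at R > 0.8 are normalized against five housekeeping controls
   (ACTB, GAPDH, RPLP0, GUSB, TFRC) and combined with first-principal-
   component loadings into a portable linear score
   `Σ βᵢ eᵢ` — a small RT-PCR-friendly panel that mirrors the genome-wide
   score.
4. **Clinical integration.** Repeated stratified 10-fold cross-validation
   of a random-forest classifier measures how much a signature score adds
   to age, stage, grade, ER/PR/HER2 and nodal status.
5. **Synthetic cohorts.** A generator plants a bimodal latent activity,
   target genes tracking it, ER-negative enrichment in the high mode and
   an activity-coupled pCR probability, so every stage is testable against
   known ground truth.

The scoring and reduction steps are scikit-learn estimators
(`BASEScorer`, `ReducedSignaturePanel`) and compose with sklearn pipelines;
module-level functions mirror them for script use.

## Worked example

```python
from regact import (GeneratorParams, generate_cohort, quantile_normalize,
                    median_center, compute_iras, stratify_by_modes,
                    stratum_response_table, roc_auc)

cohort = generate_cohort(GeneratorParams(n_samples=120, n_genes=1000,
                                         n_targets=60, seed=42))
m = median_center(quantile_normalize(cohort.expression))
iras = compute_iras(m, cohort.signature, B=1000, seed=0)
print(iras.to_frame().head(3).round(3))

strata = stratify_by_modes(iras.as_series())
tab = stratum_response_table(strata, cohort.clinical)
print(tab.table.round(3))
print(f"chi2 p = {tab.chi2_p:.2e}   Fisher (low vs rest) p = {tab.fisher_p:.2e}")
roc = roc_auc(iras.as_series(), cohort.clinical.data["response"])
print(f"AUC = {roc.auc:.3f}  ({roc.n_pos} pCR vs {roc.n_neg} RD)")
```

prints

```
           preliminary   iras  n_targets_used
sample_id
S0001            0.895  7.858              60
S0002           -0.659 -5.785              60
S0003            0.484  4.322              60
               n  n_pcr  pcr_rate
stratum
low           32      0     0.000
intermediate  62     12     0.194
high          26     13     0.500
chi2 p = 1.74e-05   Fisher (low vs rest) p = 2.15e-04
AUC = 0.855  (25 pCR vs 95 RD)
```

Sample S0001's target genes sit near the top of its expression ranking
(preliminary 0.895, iRAS ≈ 7.9 — about eight times the mean positive score
of random gene sets), S0002's near the bottom. The pCR rate climbs from 0%
in the low-activity stratum to 50% in the high stratum, and the iRAS alone
separates pCR from RD with AUC 0.855 on this synthetic cohort.

The same workflow is available from the shell:

```bash
regact simulate --outdir cohort/
regact score --expr cohort/expression.tsv --gmt cohort/signature.gmt --out iras.csv
regact evaluate --scores iras.csv --clinical cohort/clinical.csv --stratify modes --out report/
regact reduce --expr cohort/expression.tsv --iras iras.csv --gmt cohort/signature.gmt --out model.json
regact score-panel --model model.json --expr cohort/expression.tsv --out panel.csv
regact integrate --clinical cohort/clinical.csv --scores e2f4=iras.csv --out cv.json
```

## Layout

- `src/regact/io.py` — TSV/GMT/clinical-CSV readers, probeset collapse,
  quantile normalization, median centering
- `src/regact/scoring.py` — BASE statistic, permutation null, `BASEScorer`
- `src/regact/reduction.py` — gene selection, control-gene normalization,
  PC1 panel, `ReducedSignaturePanel`
- `src/regact/response.py` — stratification, response tables, ROC/AUC
- `src/regact/cv.py` — repeated stratified CV with paired fold reuse
- `src/regact/simulate.py` — synthetic cohort generator and toy fixtures
- `docs/methods.md` — model, assumptions, parameter choices, limitations
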