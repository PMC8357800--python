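"""Delivery-age regressions and confound screens.

Ordinary least squares relates gestational age at delivery to the NAS
score, to each enriched network pair's mean stress-related connectivity,
and to the WQS index; the per-pair family is Holm-Bonferroni adjusted.
Confound screens report Pearson correlations of the NAS residual with
demographics and data-quality summaries, and of the WQS index with motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class RegressionResult:
    predictor: str
    beta: float          # standardized coefficient
    beta_raw: float
    se: float
    t: float             # t statistic ("B" column analogue)
    p: float
    n: int
    holm_p: float | None = None

    def to_dict(self) -> dict:
        return {"predictor": self.predictor, "beta": self.beta,
                "beta_raw": self.beta_raw, "se": self.se, "t": self.t,
                "p": self.p, "n": self.n, "holm_p": self.holm_p}


def regress_delivery(outcome, predictor, covariates=None,
                     label: str = "predictor") -> RegressionResult:
    """OLS of gestational age at delivery on one predictor (plus optional
    covariates).  Reports raw and standardized coefficients; with no
    covariates the standardized beta equals the Pearson correlation."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and predictor lengths differ")
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    ok = np.isfinite(y) & np.isfinite(x)
    if C is not None:
        ok &= np.isfinite(C).all(axis=1)
    n = int(ok.sum())
    if n < 20:
        raise ValueError(f"need >= 20 subjects, got {n}")
    xo, yo = x[ok], y[ok]
    if xo.std(ddof=1) == 0:
        raise ValueError("constant predictor")
    cols = xo[:, None] if C is None else np.column_stack([xo, C[ok]])
    D = sm.add_constant(cols)
    model = sm.OLS(yo, D).fit()
    beta_raw = float(model.params[1])
    beta_std = beta_raw * xo.std(ddof=1) / yo.std(ddof=1)
    return RegressionResult(predictor=label, beta=beta_std, beta_raw=beta_raw,
                            se=float(model.bse[1]), t=float(model.tvalues[1]),
                            p=float(model.pvalues[1]), n=n)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Bonferroni adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def delivery_table(outcome, predictors: pd.DataFrame,
                   holm_family=None) -> pd.DataFrame:
    """Regression of delivery age on each predictor column; the columns named
    in ``holm_family`` (default: all) form one Holm-adjusted family."""
    results = [regress_delivery(outcome, predictors[c], label=c)
               for c in predictors.columns]
    fam = list(predictors.columns) if holm_family is None else list(holm_family)
    fam_idx = [i for i, r in enumerate(results) if r.predictor in fam]
    adj = holm_adjust([results[i].p for i in fam_idx])
    for i, a in zip(fam_idx, adj):
        results[i].holm_p = float(a)
    return pd.DataFrame([r.to_dict() for r in results])


def confound_screen(cohort: pd.DataFrame, nas_resid, wqs_index=None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlations of the NAS residual with maternal age, income,
    motion and frame count (and of the WQS index with motion); constant
    columns are reported as not computable rather than raising."""
    nas = np.asarray(nas_resid, dtype=float)
    checks = [("nas_resid", nas, c) for c in
              ("maternal_age", "income", "motion_xyz", "motion_pyr", "frame_count")]
    if wqs_index is not None:
        wqs = np.asarray(wqs_index, dtype=float)
        checks += [("wqs_index", wqs, c) for c in ("motion_xyz", "motion_pyr")]
    rows = []
    for score_name, score, col in checks:
        v = cohort[col].to_numpy(dtype=float)
        ok = np.isfinite(v) & np.isfinite(score)
        if ok.sum() < 3 or v[ok].std() == 0 or score[ok].std() == 0:
            rows.append({"score": score_name, "variable": col, "r": np.nan,
                         "p": np.nan, "n": int(ok.sum()), "flagged": False,
                         "note": "not computable (constant or missing)"})
            continue
        r, p = stats.pearsonr(score[ok], v[ok])
        rows.append({"score": score_name, "variable": col, "r": float(r),
                     "p": float(p), "n": int(ok.sum()),
                     "flagged": bool(p < alpha), "note": ""})
    return pd.DataFrame(rows)


__all__ = ["RegressionResult", "regress_delivery", "holm_adjust",
           "delivery_table", "confound_screen"]
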