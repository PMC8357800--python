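"""Latent negative-affect/stress (NAS) factor.

Five maternal self-report scales (depression, trait anxiety, worry,
perceived stress, and reverse-keyed life satisfaction) are summarised by a
single maximum-likelihood factor.  The workflow mirrors a split-half
validation: exploratory fits with one and two factors on a random half of
the sample choose the dimensionality, a confirmatory one-factor fit on the
full sample yields fit indices and regression-method (Thomson) factor
scores, and the scores are residualised on gestational age at scan before
any connectivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._factor import (FactorConvergenceError, fit_indices, ml_factor, model_df)
from .synthetic import SCALE_COLUMNS

REVERSE_KEYED = ("swls",)


@dataclass
class FactorSolution:
    loadings: np.ndarray      # 5 standardized loadings
    uniquenesses: np.ndarray
    fit: dict                 # chi2, df, p, CFI, TLI, RMSEA, SRMR
    scores: np.ndarray        # one per input row (NaN if no indicator observed)
    n_used: int

    def to_dict(self) -> dict:
        return {"loadings": self.loadings.tolist(),
                "uniquenesses": self.uniquenesses.tolist(),
                "fit": self.fit, "n_used": self.n_used}


def _as_scale_matrix(scale_table) -> np.ndarray:
    if isinstance(scale_table, pd.DataFrame):
        cols = [c for c in SCALE_COLUMNS if c in scale_table.columns]
        if len(cols) == 5:
            X = scale_table[cols].to_numpy(dtype=float)
            rev = [cols.index(c) for c in REVERSE_KEYED]
        else:
            X = scale_table.to_numpy(dtype=float)
            rev = []
        X = X.copy()
        X[:, rev] *= -1.0  # reverse-key so all indicators track stress positively
        return X
    return np.array(scale_table, dtype=float, copy=True)


def fit_one_factor(scale_table) -> FactorSolution:
    """Confirmatory single-factor ML fit of the five-scale battery.

    Fitting uses the correlation matrix of complete rows (listwise); factor
    scores are computed for every row from whatever indicators it has, via
    regression-method weights restricted to the available indicators.  The
    factor sign is chosen so the majority of loadings are positive.
    """
    X = _as_scale_matrix(scale_table)
    if X.ndim != 2 or X.shape[1] != 5:
        raise ValueError("scale_table must be n x 5")
    complete = ~np.isnan(X).any(axis=1)
    n_used = int(complete.sum())
    if n_used < 20:
        raise ValueError(f"need >= 20 complete subjects, got {n_used}")
    Xc = X[complete]
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError(f"constant scale column at index {int(np.argmin(sd))}")
    S = np.corrcoef(Xc, rowvar=False)
    loadings, psi, f_min = ml_factor(S, 1)
    loadings = loadings.ravel()
    if np.sum(loadings >= 0) < 3:
        loadings = -loadings
    fit = fit_indices(S, loadings[:, None], psi, f_min, n_used)

    # Thomson regression scores on standardized indicators; rows with missing
    # indicators get weights from the corresponding submatrix of the
    # model-implied correlation matrix.
    mu = Xc.mean(axis=0)
    Z = (X - mu) / sd
    sigma = np.outer(loadings, loadings) + np.diag(psi)
    scores = np.full(X.shape[0], np.nan)
    avail_patterns = {}
    for i in range(X.shape[0]):
        mask = ~np.isnan(Z[i])
        if not mask.any():
            continue
        key = tuple(mask)
        if key not in avail_patterns:
            sub = sigma[np.ix_(mask, mask)]
            avail_patterns[key] = np.linalg.solve(sub, loadings[mask])
        scores[i] = Z[i, mask] @ avail_patterns[key]
    return FactorSolution(loadings=loadings, uniquenesses=psi, fit=fit,
                          scores=scores, n_used=n_used)


def split_half_efa(scale_table, seed: int = 0) -> dict:
    """Seeded random half-split; ML EFA with one and two factors on the half.

    Dimensionality is chosen from fit indices: one factor if it already fits
    well (CFI >= 0.95 and RMSEA <= 0.08), otherwise the model with the higher
    CFI, with one factor preferred on ties.  If the two-factor model cannot
    be estimated it is reported absent and one factor is chosen.
    """
    X = _as_scale_matrix(scale_table)
    X = X[~np.isnan(X).any(axis=1)]
    n = X.shape[0]
    if n < 40:
        raise ValueError(f"need >= 40 complete subjects for a split-half EFA, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    half = X[idx[: n // 2]]
    S = np.corrcoef(half, rowvar=False)
    m = half.shape[0]

    def _efa(k):
        L, psi, f = ml_factor(S, k, n_restarts=15, seed=seed)
        return {"loadings": L, "uniquenesses": psi, **fit_indices(S, L, psi, f, m)}

    fit1 = _efa(1)
    try:
        fit2 = _efa(2)
    except (FactorConvergenceError, np.linalg.LinAlgError):
        fit2 = None
    if fit1["CFI"] >= 0.95 and fit1["RMSEA"] <= 0.08:
        chosen = 1
    elif fit2 is not None and fit2["CFI"] > fit1["CFI"]:
        chosen = 2
    else:
        chosen = 1
    return {"efa_fit_1factor": fit1, "efa_fit_2factor": fit2, "chosen_k": chosen,
            "half_indices": idx[: n // 2], "n_half": m}


def residualize_on_ga(scores, ga_scan) -> np.ndarray:
    """Residuals of factor scores after OLS on gestational age at scan."""
    scores = np.asarray(scores, dtype=float)
    ga = np.asarray(ga_scan, dtype=float)
    if scores.shape != ga.shape:
        raise ValueError("scores and ga_scan must have equal length")
    if not np.all(np.isfinite(ga)):
        raise ValueError("ga_scan must be finite")
    if np.ptp(ga) == 0:
        warnings.warn("ga_scan is constant; returning mean-centered scores",
                      RuntimeWarning)
        return scores - np.nanmean(scores)
    ok = np.isfinite(scores)
    A = np.column_stack([np.ones(ok.sum()), ga[ok]])
    coef, *_ = np.linalg.lstsq(A, scores[ok], rcond=None)
    resid = np.full_like(scores, np.nan)
    resid[ok] = scores[ok] - A @ coef
    return resid


__all__ = ["FactorSolution", "fit_one_factor", "split_half_efa",
           "residualize_on_ga", "model_df", "SCALE_COLUMNS"]
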