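"""Maximum-likelihood factor analysis primitives.

Implements the classic profile-likelihood (Joreskog) formulation: for fixed
uniquenesses Psi the loadings maximising the likelihood are available in
closed form from the eigendecomposition of Psi^{-1/2} S Psi^{-1/2}, so the
discrepancy function is minimised over log-uniquenesses only.  Everything
operates on the correlation matrix, so loadings are standardized.

Also holds the fit-index formulas (CFI/TLI/RMSEA/SRMR against the
zero-correlation baseline), varimax/promax rotation, Bartlett's sphericity
test and Horn's parallel analysis, shared by the stress-factor and
health/support-factor modules.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats

HEYWOOD_FLOOR = 1e-4


class FactorConvergenceError(RuntimeError):
    def __init__(self, msg, last_objective=None):
        super().__init__(msg)
        self.last_objective = last_objective


def _profile_objective(log_psi: np.ndarray, S: np.ndarray, k: int) -> float:
    psi = np.exp(log_psi)
    d = 1.0 / np.sqrt(psi)
    theta = np.linalg.eigvalsh(d[:, None] * S * d[None, :])  # ascending
    tail = theta[: len(psi) - k]
    tail = np.maximum(tail, 1e-12)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _loadings_given_psi(psi: np.ndarray, S: np.ndarray, k: int) -> np.ndarray:
    d = 1.0 / np.sqrt(psi)
    theta, v = np.linalg.eigh(d[:, None] * S * d[None, :])
    idx = np.argsort(theta)[::-1][:k]
    lam = np.sqrt(np.maximum(theta[idx] - 1.0, 0.0))
    return np.sqrt(psi)[:, None] * v[:, idx] * lam[None, :]


def ml_factor(S: np.ndarray, k: int, n_restarts: int = 10, seed: int = 0):
    """ML common-factor fit of a correlation matrix.

    Returns (loadings p x k, uniquenesses p, F_ML at the optimum).
    Heywood cases are clamped at ``HEYWOOD_FLOOR`` with a warning.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if k < 1 or ((p - k) ** 2 - (p + k)) < 0:
        raise ValueError(f"{k}-factor model not identified for {p} indicators")
    inv_diag = np.diag(np.linalg.pinv(S))
    start = np.clip((1.0 - 0.5 * k / p) / np.maximum(inv_diag, 1e-8), 0.05, 0.95)
    rng = np.random.default_rng(seed)
    bounds = [(np.log(HEYWOOD_FLOOR), 0.0)] * p
    best = None
    last_obj = None
    for attempt in range(n_restarts):
        x0 = np.log(start) if attempt == 0 else np.log(
            np.clip(start * np.exp(rng.uniform(-0.7, 0.7, p)), HEYWOOD_FLOOR, 1.0))
        res = optimize.minimize(_profile_objective, x0, args=(S, k),
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12})
        last_obj = float(res.fun)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best is not None and attempt >= 2 and best.fun < 1e-10:
            break
    if best is None or not np.isfinite(best.fun):
        raise FactorConvergenceError("ML factor fit failed to converge",
                                     last_objective=last_obj)
    psi = np.exp(best.x)
    if np.any(psi <= HEYWOOD_FLOOR * (1 + 1e-6)):
        warnings.warn("Heywood case: uniqueness clamped at 1e-4", RuntimeWarning)
        psi = np.maximum(psi, HEYWOOD_FLOOR)
    return _loadings_given_psi(psi, S, k), psi, float(best.fun)


def model_df(p: int, k: int) -> int:
    """Degrees of freedom of the k-factor model on p indicators."""
    return ((p - k) ** 2 - (p + k)) // 2


def fit_indices(S: np.ndarray, loadings: np.ndarray, psi: np.ndarray,
                f_min: float, n: int) -> dict:
    """chi2/CFI/TLI/RMSEA/SRMR for an ML factor fit of a correlation matrix.

    Baseline model: all correlations zero (df = p(p-1)/2). CFI and TLI are
    clamped to [0, 1]; a degenerate baseline (already-diagonal S) yields
    CFI = TLI = 1.
    """
    p, k = loadings.shape
    df = model_df(p, k)
    chi2 = max((n - 1) * f_min, 0.0)
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    f_base = -float(np.linalg.slogdet(S)[1])
    chi2_b = max((n - 1) * f_base, 0.0)
    df_b = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, num, 0.0)
    cfi = 1.0 if den <= 0 else 1.0 - num / den
    if chi2_b / df_b > 1.0 and df > 0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = 1.0
    cfi = float(np.clip(cfi, 0.0, 1.0))
    tli = float(np.clip(tli, 0.0, 1.0))
    rmsea = float(np.sqrt(num / (df * (n - 1)))) if df > 0 else 0.0
    sigma = loadings @ loadings.T + np.diag(psi)
    resid = (S - sigma)[np.tril_indices(p, k=-1)]
    srmr = float(np.sqrt(np.mean(resid ** 2)))
    return {"chi2": float(chi2), "df": int(df), "p": pval,
            "CFI": cfi, "TLI": tli, "RMSEA": rmsea, "SRMR": srmr,
            "chi2_baseline": float(chi2_b), "df_baseline": int(df_b)}


# --- rotation -------------------------------------------------------------

def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser-normalised)."""
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy()
    h = np.sqrt((L ** 2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        B = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p))
        R = u @ vt
        var_new = s.sum()
        if var_new <= var_old * (1 + tol):
            break
        var_old = var_new
    return (A @ R) * h[:, None]


def promax(loadings: np.ndarray, power: int = 4):
    """Oblique promax rotation: varimax followed by an oblique Procrustes fit
    to the powered target.  Returns (pattern, factor correlation Phi)."""
    V = varimax(loadings)
    k = V.shape[1]
    if k < 2:
        return V.copy(), np.eye(k)
    target = np.abs(V) ** power * np.sign(V)
    X = np.linalg.lstsq(V, target, rcond=None)[0]
    d = np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
    X = X * d[None, :]
    pattern = V @ X
    t_inv = np.linalg.inv(X)
    phi = t_inv @ t_inv.T
    dd = np.sqrt(np.diag(phi))
    phi = phi / np.outer(dd, dd)
    return pattern, phi


# --- adequacy / retention diagnostics -------------------------------------

def bartlett_sphericity(S: np.ndarray, n: int) -> dict:
    """Bartlett's test that the correlation matrix is the identity."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("correlation matrix is singular")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return {"chi2": float(chi2), "df": int(df), "p": float(stats.chi2.sf(chi2, df))}


def parallel_analysis(X: np.ndarray, n_resamples: int = 1000, quantile: float = 0.95,
                      seed: int = 0) -> dict:
    """Horn's parallel analysis: retain factors whose observed correlation
    eigenvalues exceed the given quantile of eigenvalues from standard-normal
    data of the same shape."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_resamples, p))
    for b in range(n_resamples):
        Z = rng.standard_normal((n, p))
        sims[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    ref = np.quantile(sims, quantile, axis=0)
    keep = obs > ref
    n_keep = int(np.argmin(keep)) if not keep.all() else p
    return {"n_factors": n_keep, "eigenvalues": obs, "reference": ref}
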