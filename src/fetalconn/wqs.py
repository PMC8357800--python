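"""Weighted quantile sum (WQS) stress-connectivity index and moderation.

The mixture components are per-subject mean FC(z) values over each enriched
network pair's significant edges.  Components are scored into within-sample
quantiles (quartiles by default); non-negative weights summing to one are
estimated on a training split (40% of subjects) by maximising the
index-outcome association over bootstrap resamples, combined as a
signal-weighted (|t|) ensemble average, and the resulting index is
validated by linear regression in the held-out 60%.  Moderation by the
health/social-support factors (HE, FS, HAR) is tested with
index x factor interaction terms in the validation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from ._factor import (bartlett_sphericity, fit_indices, ml_factor,
                      parallel_analysis, promax)
from .enrichment import EdgeStats
from .synthetic import HEALTH_COLUMNS

# measures that define each health/support factor, used to name and sign
# recovered factors; substance use and attachment avoidance are
# reverse-indicators of HAR, family conflict of FS
FACTOR_MARKERS = {
    "HE": ("diet", "exercise", "ecr_anxiety"),
    "FS": ("fes_cohesion", "fes_expressiveness", "fes_conflict"),
    "HAR": ("sleep", "medical_adherence", "substance_use", "ecr_avoidance"),
}

# measures keyed opposite to their factor's healthy/positive pole
REVERSE_MARKERS = frozenset({"fes_conflict", "substance_use", "ecr_avoidance"})


@dataclass
class WQSFit:
    weights: np.ndarray
    component_names: list
    beta: float                   # standardized validation coefficient
    beta_raw: float
    se: float
    p: float
    index: np.ndarray             # WQS index for all subjects
    train_mask: np.ndarray        # True = training subject
    bootstrap_weights: np.ndarray  # ensemble archive (n_boot x K)
    bootstrap_t: np.ndarray
    n_quantiles: int
    quantized: np.ndarray         # quantile scores (n x K)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(),
                "component_names": list(self.component_names),
                "beta": self.beta, "beta_raw": self.beta_raw,
                "se": self.se, "p": self.p,
                "n_quantiles": self.n_quantiles, "config": self.config}


# --- components -----------------------------------------------------------

def pair_summaries(fc_edges: np.ndarray, edge_stats: EdgeStats,
                   partition_labels, enriched_pairs,
                   network_names=None) -> pd.DataFrame:
    """Per-subject mean FC(z) over each enriched pair's significant edges.

    ``fc_edges`` is the (subjects x eligible edges) stack used for the
    enrichment analysis; ``enriched_pairs`` is a list of (net_a, net_b)
    integer pairs.
    """
    labels = np.asarray(partition_labels, dtype=int)
    a = labels[edge_stats.edge_i]
    b = labels[edge_stats.edge_j]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    cols = {}
    for pa, pb in enriched_pairs:
        mask = (lo == pa) & (hi == pb) & edge_stats.significant
        if not mask.any():
            raise ValueError(f"pair ({pa},{pb}) has no significant edges")
        name = (f"{network_names[pa]}-{network_names[pb]}" if network_names
                else f"{pa}-{pb}")
        cols[name] = fc_edges[:, mask].mean(axis=1)
    return pd.DataFrame(cols)


# --- health/support factors ----------------------------------------------

def support_factor_analysis(health_table, seed: int = 0, n_resamples: int = 1000,
                            n_factors: int | None = None) -> dict:
    """Three-factor (by default: data-driven) EFA of the ten health and
    social-support measures with oblique (promax) rotation.

    Factor count is chosen by Horn's parallel analysis; Bartlett's
    sphericity test guards against unstructured input.  Scores use the
    regression method and are standardized; factors are named HE/FS/HAR by
    their strongest marker measures when the input has the canonical
    columns, and signed so the strongest marker loads positively.
    """
    if isinstance(health_table, pd.DataFrame):
        cols = [c for c in HEALTH_COLUMNS if c in health_table.columns]
        measure_names = cols if len(cols) == len(health_table.columns) else list(health_table.columns)
        X = health_table[measure_names].to_numpy(dtype=float)
    else:
        X = np.asarray(health_table, dtype=float)
        measure_names = [f"m{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n < 50:
        raise ValueError(f"need >= 50 subjects, got {n}")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant measure column")
    S = np.corrcoef(X, rowvar=False)
    if np.linalg.matrix_rank(S) < p or np.linalg.cond(S) > 1e10:
        corr_pairs = [(measure_names[i], measure_names[j])
                      for i in range(p) for j in range(i + 1, p)
                      if abs(S[i, j]) > 0.999]
        raise ValueError(f"singular correlation matrix; collinear measures: {corr_pairs}")
    bartlett = bartlett_sphericity(S, n)
    pa = parallel_analysis(X, n_resamples=n_resamples, seed=seed)
    k = n_factors if n_factors is not None else pa["n_factors"]
    if k == 0:
        raise ValueError("parallel analysis retains 0 factors; the measures "
                         "appear unstructured (pass n_factors to override)")
    loadings, psi, f_min = ml_factor(S, k, seed=seed)
    fit = fit_indices(S, loadings, psi, f_min, n)
    pattern, phi = promax(loadings)
    structure = pattern @ phi
    Z = (X - X.mean(axis=0)) / sd
    scores = Z @ np.linalg.solve(S, structure)

    # name + sign factors by marker measures; the healthy/positive pole is
    # defined by the marker keying (conflict, substance use, avoidance are
    # reverse-indicators)
    factor_names = [f"F{j + 1}" for j in range(k)]
    canonical = set(HEALTH_COLUMNS) == set(measure_names) and k == len(FACTOR_MARKERS)
    if canonical:
        assign = {}
        for fname, markers in FACTOR_MARKERS.items():
            rows = [measure_names.index(m) for m in markers]
            strengths = np.abs(pattern[rows]).sum(axis=0)
            assign[fname] = int(np.argmax(strengths))
        if len(set(assign.values())) == k:
            order = [assign[f] for f in ("HE", "FS", "HAR")]
            pattern = pattern[:, order]
            structure = structure[:, order]
            scores = scores[:, order]
            phi = phi[np.ix_(order, order)]
            factor_names = ["HE", "FS", "HAR"]
        else:
            canonical = False
    for j in range(k):
        if canonical and factor_names[j] in FACTOR_MARKERS:
            keyed = sum((-1 if m in REVERSE_MARKERS else 1)
                        * pattern[measure_names.index(m), j]
                        for m in FACTOR_MARKERS[factor_names[j]])
            flip = keyed < 0
        else:
            flip = pattern[int(np.argmax(np.abs(pattern[:, j]))), j] < 0
        if flip:
            pattern[:, j] *= -1
            structure[:, j] *= -1
            scores[:, j] *= -1
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    return {"scores": pd.DataFrame(scores, columns=factor_names),
            "pattern": pd.DataFrame(pattern, index=measure_names, columns=factor_names),
            "phi": phi, "fit": fit, "bartlett": bartlett,
            "parallel": pa, "n_factors": k}


# --- WQS ------------------------------------------------------------------

def quantize(components: np.ndarray, q: int = 4) -> np.ndarray:
    """Within-sample quantile scores 0..q-1 per component.

    Components with fewer than q distinct values fall back to a coarser
    scoring over their distinct values, with a warning.
    """
    X = np.asarray(components, dtype=float)
    out = np.empty_like(X)
    for k in range(X.shape[1]):
        x = X[:, k]
        if len(np.unique(x)) < q:
            warnings.warn(f"component {k} has < {q} distinct values; "
                          "using coarser scoring", RuntimeWarning)
        cuts = np.unique(np.quantile(x, np.linspace(0, 1, q + 1)[1:-1]))
        out[:, k] = np.searchsorted(cuts, x, side="left")
    return out


def _fit_weights_one(Qb: np.ndarray, yb: np.ndarray, w0: np.ndarray):
    """Maximise the signed t-statistic of the index-outcome slope over the
    weight simplex (positive-direction WQS)."""
    m, K = Qb.shape

    def neg_t(w):
        idx = Qb @ w
        sx = idx.std(ddof=1)
        if sx < 1e-12:
            return 0.0
        r = np.corrcoef(idx, yb)[0, 1]
        r = np.clip(r, -0.999999, 0.999999)
        return -r * np.sqrt((m - 2) / (1 - r ** 2))

    res = optimize.minimize(neg_t, w0, method="SLSQP",
                            bounds=[(0.0, 1.0)] * K,
                            constraints=[{"type": "eq",
                                          "fun": lambda w: w.sum() - 1.0}],
                            options={"maxiter": 200, "ftol": 1e-9})
    w = np.clip(res.x, 0.0, None)
    s = w.sum()
    w = w / s if s > 0 else np.full(K, 1.0 / K)
    return w, -float(res.fun)


def wqs_fit(components, outcome, q: int = 4, n_boot: int = 100,
            split: float = 0.4, seed: int = 0) -> WQSFit:
    """Train/validate a positive-direction WQS index.

    Weights are estimated per bootstrap resample of the training split and
    combined as a |t|-weighted average over resamples with a positive
    association; the index is evaluated against the outcome by OLS in the
    validation split (standardized and raw coefficients reported).
    """
    if isinstance(components, pd.DataFrame):
        names = list(components.columns)
        X = components.to_numpy(dtype=float)
    else:
        X = np.asarray(components, dtype=float)
        names = [f"c{k}" for k in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    n, K = X.shape
    if K < 1:
        raise ValueError("need >= 1 component")
    if n < 30:
        raise ValueError(f"need >= 30 subjects, got {n}")
    rng = np.random.default_rng(seed)
    Q = quantize(X, q=q)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    train_mask = np.zeros(n, dtype=bool)
    train_mask[perm[:n_train]] = True

    if K == 1:
        weights = np.array([1.0])
        boot_w = np.ones((n_boot, 1))
        boot_t = np.full(n_boot, np.nan)
    else:
        Qt, yt = Q[train_mask], y[train_mask]
        boot_w = np.empty((n_boot, K))
        boot_t = np.empty(n_boot)
        w0 = np.full(K, 1.0 / K)
        m = len(yt)
        for b in range(n_boot):
            take = rng.integers(0, m, size=m)
            boot_w[b], boot_t[b] = _fit_weights_one(Qt[take], yt[take], w0)
        pos = boot_t > 0
        if not pos.any():
            raise ValueError("no positive-direction signal in any bootstrap resample")
        wsum = (np.abs(boot_t[pos, None]) * boot_w[pos]).sum(axis=0)
        weights = wsum / wsum.sum()

    index = Q @ weights
    val = ~train_mask
    xv, yv = index[val], y[val]
    model = sm.OLS(yv, sm.add_constant(xv)).fit()
    beta_raw = float(model.params[1])
    se = float(model.bse[1])
    p = float(model.pvalues[1])
    sx, sy = xv.std(ddof=1), yv.std(ddof=1)
    beta_std = beta_raw * sx / sy if sy > 0 and sx > 0 else float("nan")
    return WQSFit(weights=weights, component_names=names, beta=beta_std,
                  beta_raw=beta_raw, se=se, p=p, index=index,
                  train_mask=train_mask, bootstrap_weights=boot_w,
                  bootstrap_t=boot_t, n_quantiles=q, quantized=Q,
                  config={"q": q, "n_boot": n_boot, "split": split,
                          "seed": seed, "direction": "positive"})


def wqs_moderation(fit: WQSFit, support: pd.DataFrame, outcome) -> pd.DataFrame:
    """Validation-set interaction models outcome ~ index * factor.

    One row per support factor with the interaction coefficient and simple
    slopes of the index at +/-1 SD of the moderator.  Index and moderator
    are standardized within the validation set.
    """
    y = np.asarray(outcome, dtype=float)
    val = ~fit.train_mask
    idx = fit.index[val]
    if idx.std(ddof=1) == 0:
        raise ValueError("degenerate index (zero variance) in validation set")
    zi = (idx - idx.mean()) / idx.std(ddof=1)
    yv = y[val]
    rows = []
    for fname in support.columns:
        mod = support[fname].to_numpy(dtype=float)[val]
        if mod.std(ddof=1) == 0:
            raise ValueError(f"moderator {fname!r} is constant (rank-deficient design)")
        zm = (mod - mod.mean()) / mod.std(ddof=1)
        D = sm.add_constant(np.column_stack([zi, zm, zi * zm]))
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError(f"rank-deficient design for moderator {fname!r}")
        m = sm.OLS(yv, D).fit()
        b_idx, b_mod, b_int = m.params[1:4]
        rows.append({"factor": fname,
                     "beta_index": float(b_idx), "beta_moderator": float(b_mod),
                     "beta_interaction": float(b_int),
                     "se_interaction": float(m.bse[3]),
                     "p_interaction": float(m.pvalues[3]),
                     "simple_slope_low": float(b_idx - b_int),
                     "simple_slope_high": float(b_idx + b_int)})
    return pd.DataFrame(rows)


__all__ = ["WQSFit", "pair_summaries", "support_factor_analysis", "quantize",
           "wqs_fit", "wqs_moderation", "FACTOR_MARKERS"]
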