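"""Network-pair enrichment of stress-connectivity correlations.

For every distance-eligible ROI pair, the Fisher-z connectivity values
across subjects are correlated with the gestational-age-adjusted NAS score.
Edges with two-sided p below ``edge_alpha`` (default 0.05) are "significant";
a 2x2 chi-square (df = 1, no continuity correction) per network pair tests
whether significant edges cluster inside that pair.  Empirical significance
comes from permuting the subject pairing of connectivity and NAS values,
recomputing every pair's chi-square per permutation, and applying the
add-one rule p = (1 + #{perm >= observed}) / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EDGE_ALPHA = 0.05


@dataclass
class EdgeStats:
    """Per-eligible-edge FC-NAS correlation statistics."""

    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    edge_i: np.ndarray          # ROI row index of each edge
    edge_j: np.ndarray
    roi_ids: list
    n_subjects: int
    edge_alpha: float = DEFAULT_EDGE_ALPHA

    @property
    def n_edges(self) -> int:
        return len(self.r)


def eligible_edge_index(n_roi: int, eligible_mask: np.ndarray | None):
    """Upper-triangle indices of eligible ROI pairs."""
    iu = np.triu_indices(n_roi, k=1)
    if eligible_mask is None:
        return iu
    keep = eligible_mask[iu]
    return iu[0][keep], iu[1][keep]


def stack_fc(fc_list, eligible_mask: np.ndarray | None = None) -> tuple:
    """Flatten per-subject FC matrices to a (subjects x eligible-edges) array."""
    if len(fc_list) == 0:
        raise ValueError("no FC matrices")
    ref = fc_list[0].roi_ids
    for fc in fc_list:
        if fc.roi_ids != ref:
            raise ValueError("incongruent roi_ids across subjects")
    n = fc_list[0].n_roi
    ei, ej = eligible_edge_index(n, eligible_mask)
    X = np.stack([fc.matrix[ei, ej] for fc in fc_list])
    return X, ei, ej, list(ref)


def _r_critical(alpha: float, n: int) -> float:
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit ** 2))


def _resolve_edges(X: np.ndarray, eligible_mask):
    """Edge index bookkeeping for a pre-stacked (subjects x edges) array."""
    if eligible_mask is None:
        n_roi = int(round((1 + np.sqrt(1 + 8 * X.shape[1])) / 2))
        if n_roi * (n_roi - 1) // 2 != X.shape[1]:
            raise ValueError("edge array is not a full upper triangle; "
                             "pass eligible_mask=(edge_i, edge_j, roi_ids)")
        iu = np.triu_indices(n_roi, k=1)
        return iu[0], iu[1], [f"roi{j:03d}" for j in range(n_roi)]
    return eligible_mask


def edgewise_correlation(fc_per_subject, nas_resid, eligible_mask=None,
                         edge_alpha: float = DEFAULT_EDGE_ALPHA) -> EdgeStats:
    """Pearson r (and two-sided t-distribution p) of each eligible edge's
    FC(z) with the NAS residual across subjects.

    ``fc_per_subject`` may be a list of :class:`FCMatrix` or a pre-stacked
    (subjects x edges) array together with ``eligible_mask`` = (edge_i,
    edge_j, roi_ids).  Zero-variance edges get r = 0, p = 1 with a warning.
    """
    if isinstance(fc_per_subject, np.ndarray):
        X = fc_per_subject
        ei, ej, roi_ids = _resolve_edges(X, eligible_mask)
    else:
        X, ei, ej, roi_ids = stack_fc(fc_per_subject, eligible_mask)
    y = np.asarray(nas_resid, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need >= 10 subjects, got {n}")
    if len(y) != n:
        raise ValueError("nas_resid length mismatch")
    y_sd = y.std(ddof=1)
    x_sd = X.std(axis=0, ddof=1)
    zero_var = x_sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    if y_sd <= 1e-12 * max(1.0, np.abs(y).max()):
        y_sd = 0.0
    if y_sd == 0:
        warnings.warn("NAS residual is constant; all edge correlations set to 0",
                      RuntimeWarning)
        r = np.zeros(X.shape[1])
    else:
        if zero_var.any():
            warnings.warn(f"{int(zero_var.sum())} zero-variance edges set to r=0",
                          RuntimeWarning)
        xc = X - X.mean(axis=0)
        denom = np.where(zero_var, 1.0, x_sd) * y_sd * (n - 1)
        r = (xc.T @ (y - y.mean())) / denom
        r[zero_var] = 0.0
        r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    if y_sd == 0:
        p = np.ones_like(p)
    p[zero_var] = 1.0
    sig = p < edge_alpha
    return EdgeStats(r=r, p=p, significant=sig, edge_i=np.asarray(ei),
                     edge_j=np.asarray(ej), roi_ids=roi_ids, n_subjects=n,
                     edge_alpha=edge_alpha)


def _edge_pair_keys(edge_stats: EdgeStats, labels: np.ndarray):
    """Unordered network-pair key per edge, plus the sorted unique key list."""
    a = labels[edge_stats.edge_i]
    b = labels[edge_stats.edge_j]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    n_com = int(labels.max()) + 1
    code = lo * n_com + hi
    uniq = np.unique(code)
    return code, uniq, n_com


def _chi2_2x2(a, n_in, s_tot, e_tot):
    """Vectorised chi-square (df=1, no Yates) of the 2x2 table
    {in-pair, out-of-pair} x {significant, not}."""
    a = np.asarray(a, dtype=float)
    b = n_in - a
    c = s_tot - a
    d = e_tot - n_in - c
    denom = n_in * (e_tot - n_in) * s_tot * (e_tot - s_tot)
    num = e_tot * (a * d - b * c) ** 2
    return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)


def pair_chi2(edge_stats: EdgeStats, partition_labels, network_names=None) -> pd.DataFrame:
    """Per-network-pair enrichment chi-square table (no permutation p yet).

    Rows cover every network pair with at least one eligible edge; pairs
    with zero edges are absent.  ``over_represented`` records whether the
    in-pair significant fraction exceeds the global rate.
    """
    labels = np.asarray(partition_labels, dtype=int)
    code, uniq, n_com = _edge_pair_keys(edge_stats, labels)
    sig = edge_stats.significant.astype(float)
    E = edge_stats.n_edges
    S = float(sig.sum())
    rows = []
    for c in uniq:
        mask = code == c
        n_in = int(mask.sum())
        a = float(sig[mask].sum())
        chi2 = float(_chi2_2x2(a, n_in, S, E))
        lo, hi = divmod(int(c), n_com)
        name = (f"{network_names[lo]}-{network_names[hi]}" if network_names
                else f"{lo}-{hi}")
        rows.append({"network_pair": name, "net_a": lo, "net_b": hi,
                     "n_edges": n_in, "n_significant": int(a),
                     "chi2": chi2,
                     "over_represented": (a / n_in) > (S / E) if S > 0 else False})
    return pd.DataFrame(rows)


def significant_edge_lists(edge_stats: EdgeStats, partition_labels) -> dict:
    """Map network pair (lo, hi) -> list of significant (roi_i, roi_j, r)."""
    labels = np.asarray(partition_labels, dtype=int)
    code, uniq, n_com = _edge_pair_keys(edge_stats, labels)
    out = {}
    for c in uniq:
        mask = (code == c) & edge_stats.significant
        lo, hi = divmod(int(c), n_com)
        out[(lo, hi)] = [(edge_stats.roi_ids[i], edge_stats.roi_ids[j], float(r))
                         for i, j, r in zip(edge_stats.edge_i[mask],
                                            edge_stats.edge_j[mask],
                                            edge_stats.r[mask])]
    return out


def permutation_null(fc_per_subject, nas_resid, partition_labels, B: int = 10000,
                     seed: int = 0, edge_alpha: float = DEFAULT_EDGE_ALPHA,
                     eligible_mask=None, network_names=None, block: int = 500,
                     max_work: float = 1e12, force: bool = False) -> pd.DataFrame:
    """Enrichment table with empirical permutation p-values.

    Permutations shuffle the subject pairing of NAS residuals against the FC
    matrix stack, preserving the across-edge covariance of connectivity.
    ``p_perm = (1 + #{permuted chi2 >= observed}) / (B + 1)``; a pair is
    ``enriched`` when p_perm < 0.05 and significant edges are
    over-represented in it.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if isinstance(fc_per_subject, np.ndarray):
        X = fc_per_subject
        ei, ej, roi_ids = _resolve_edges(X, eligible_mask)
    else:
        X, ei, ej, roi_ids = stack_fc(fc_per_subject, eligible_mask)
    y = np.asarray(nas_resid, dtype=float)
    n, E = X.shape
    work = float(B) * E * n
    if work > max_work and not force:
        raise ValueError(f"estimated work {work:.2e} exceeds budget {max_work:.2e}; "
                         "pass force=True to override")
    obs = edgewise_correlation(X, y, (ei, ej, roi_ids), edge_alpha=edge_alpha)
    labels = np.asarray(partition_labels, dtype=int)
    table = pair_chi2(obs, labels, network_names=network_names)
    code, uniq, n_com = _edge_pair_keys(obs, labels)
    pair_of_edge = np.searchsorted(uniq, code)
    n_pairs = len(uniq)
    P = np.zeros((n_pairs, E))
    P[pair_of_edge, np.arange(E)] = 1.0
    n_in = P.sum(axis=1)

    # standardized design for fast blocked permutation correlations
    xc = X - X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    zero_var = x_sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    xn = xc / (np.where(zero_var, 1.0, x_sd) * np.sqrt(n - 1))
    xn[:, zero_var] = 0.0
    r_crit = _r_critical(edge_alpha, n)

    rng = np.random.default_rng(seed)
    obs_chi2 = table.sort_values(["net_a", "net_b"])["chi2"].to_numpy()
    exceed = np.zeros(n_pairs)
    done = 0
    while done < B:
        nb = min(block, B - done)
        Y = np.empty((n, nb))
        for b in range(nb):
            Y[:, b] = rng.permutation(y)
        Y = Y - Y.mean(axis=0)
        Y /= np.sqrt((Y ** 2).sum(axis=0))
        R = xn.T @ Y                          # E x nb permuted correlations
        sig = (np.abs(R) > r_crit).astype(float)
        a = P @ sig                           # pairs x nb significant counts
        s_tot = sig.sum(axis=0)
        chi2 = _chi2_2x2(a, n_in[:, None], s_tot[None, :], float(E))
        exceed += (chi2 >= obs_chi2[:, None] - 1e-12).sum(axis=1)
        done += nb
    p_perm = (1.0 + exceed) / (B + 1.0)
    table = table.sort_values(["net_a", "net_b"]).reset_index(drop=True)
    table["p_perm"] = p_perm
    table["enriched"] = (table["p_perm"] < 0.05) & table["over_represented"]
    table.attrs["B"] = B
    table.attrs["edge_alpha"] = edge_alpha
    return table


__all__ = ["EdgeStats", "edgewise_correlation", "pair_chi2", "permutation_null",
           "significant_edge_lists", "stack_fc", "eligible_edge_index",
           "DEFAULT_EDGE_ALPHA"]
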