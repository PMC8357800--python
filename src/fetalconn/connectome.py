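"""Connectivity matrices and multi-threshold binarized graphs.

Per-subject functional connectivity is the Fisher-z transform of pairwise
Pearson correlations between ROI timeseries.  The group matrix is the
element-wise mean across subjects.  ROI pairs whose centres-of-mass are
closer than 10 mm are excluded from all edge statistics (a guard against
spatial blurring), and the group matrix is binarized at a grid of edge
densities from 1% to 10% in steps of 0.1% (91 thresholds), keeping the
top-ranked eligible edges by signed z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z_CLIP = 1.0 - 1e-12


@dataclass
class FCMatrix:
    """Symmetric ROI x ROI Fisher-z connectivity matrix (diagonal = 0)."""

    matrix: np.ndarray
    roi_ids: list
    subject_id: str | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal values must be finite")
        self.matrix = m

    @property
    def n_roi(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AdjacencyStack:
    thresholds: list                 # edge densities, ascending
    matrices: list                   # boolean n_roi x n_roi per threshold
    excluded_edges: list             # (roi_id_i, roi_id_j) removed by distance rule
    roi_ids: list
    eligible_mask: np.ndarray = None  # boolean upper-triangle eligibility

    @property
    def n_eligible(self) -> int:
        return int(np.triu(self.eligible_mask, 1).sum())


def fc_from_timeseries(ts: np.ndarray, roi_ids=None, subject_id=None) -> FCMatrix:
    """Pairwise Pearson correlation of ROI columns, Fisher-z transformed.

    r is clipped to +/-(1 - 1e-12) before atanh so perfectly correlated
    series yield a large finite z rather than infinity.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be frames x roi")
    frames, p = ts.shape
    if frames < 10:
        raise ValueError(f"need >= 10 frames, got {frames}")
    if roi_ids is None:
        roi_ids = [f"roi{j:03d}" for j in range(p)]
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = roi_ids[int(np.argmin(sd))]
        raise ValueError(f"constant timeseries for ROI {bad!r}")
    r = np.corrcoef(ts, rowvar=False)
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    np.fill_diagonal(z, 0.0)
    return FCMatrix(matrix=z, roi_ids=list(roi_ids), subject_id=subject_id)


def group_average(fc_list) -> FCMatrix:
    """Element-wise mean of Fisher-z matrices across subjects."""
    if len(fc_list) < 2:
        raise ValueError("need >= 2 matrices to average")
    ref = fc_list[0].roi_ids
    for fc in fc_list[1:]:
        if fc.roi_ids != ref:
            raise ValueError("incongruent roi_ids across subjects")
    mean = np.mean([fc.matrix for fc in fc_list], axis=0)
    return FCMatrix(matrix=mean, roi_ids=list(ref), subject_id="group")


def roi_distances(roi_meta: pd.DataFrame) -> np.ndarray:
    coords = roi_meta[["x", "y", "z"]].to_numpy(dtype=float)
    if np.isnan(coords).any():
        raise ValueError("missing ROI coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def exclude_short_edges(fc: FCMatrix, roi_meta: pd.DataFrame, min_mm: float = 10.0):
    """Flag ROI pairs closer than ``min_mm`` (strict <) as ineligible.

    Returns (eligible_mask, excluded_list).  The mask is symmetric boolean
    with False on the diagonal and on excluded pairs.
    """
    meta = roi_meta.set_index("roi_id").loc[fc.roi_ids].reset_index()
    dist = roi_distances(meta)
    eligible = dist >= min_mm
    np.fill_diagonal(eligible, False)
    iu = np.triu_indices(fc.n_roi, k=1)
    short = ~eligible[iu]
    excluded = [(fc.roi_ids[i], fc.roi_ids[j])
                for i, j in zip(iu[0][short], iu[1][short])]
    return eligible, excluded


def default_density_grid() -> list:
    """Edge densities 1.0% .. 10.0% in 0.1% steps, computed over integers."""
    return [i / 1000.0 for i in range(10, 101)]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def threshold_stack(group_fc: FCMatrix, eligible_mask: np.ndarray | None = None,
                    densities=None, excluded_edges=None) -> AdjacencyStack:
    """Binarize the group matrix at each density.

    For density d, the top ``round(d * E)`` eligible edges by signed z are
    kept (E = eligible pair count).  Ties at the cut rank are broken by
    (z descending, i ascending, j ascending) for determinism.
    """
    n = group_fc.n_roi
    if eligible_mask is None:
        eligible_mask = ~np.eye(n, dtype=bool)
    if densities is None:
        densities = default_density_grid()
    densities = list(densities)
    for d in densities:
        if not (0 < d <= 1):
            raise ValueError(f"density {d} outside (0, 1]")
    iu = np.triu_indices(n, k=1)
    elig = eligible_mask[iu]
    if not elig.any():
        raise ValueError("eligible edge set is empty")
    zi, ii, jj = group_fc.matrix[iu][elig], iu[0][elig], iu[1][elig]
    order = np.lexsort((jj, ii, -zi))  # z desc, then i asc, j asc
    E = len(zi)
    matrices = []
    for d in densities:
        k = min(_round_half_away(d * E), E)
        adj = np.zeros((n, n), dtype=bool)
        sel = order[:k]
        adj[ii[sel], jj[sel]] = True
        adj |= adj.T
        matrices.append(adj)
    return AdjacencyStack(thresholds=densities, matrices=matrices,
                          excluded_edges=list(excluded_edges or []),
                          roi_ids=list(group_fc.roi_ids),
                          eligible_mask=eligible_mask)


__all__ = ["FCMatrix", "AdjacencyStack", "fc_from_timeseries", "group_average",
           "exclude_short_edges", "threshold_stack", "default_density_grid",
           "roi_distances"]
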