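"""Fisher-z connectivity, distance exclusion, and density thresholding."""

import numpy as np
import pandas as pd
import pytest

from fetalconn import (fc_from_timeseries, group_average, exclude_short_edges,
                       threshold_stack, default_density_grid, FCMatrix)
from fetalconn.connectome import Z_CLIP


def _roi_meta(coords):
    coords = np.asarray(coords, dtype=float)
    return pd.DataFrame({"roi_id": [f"roi{j:03d}" for j in range(len(coords))],
                         "hemisphere": "L", "lobe": "frontal",
                         "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2]})


def test_identical_series_clipped():
    rng = np.random.default_rng(0)
    a = rng.standard_normal(50)
    fc = fc_from_timeseries(np.column_stack([a, a, rng.standard_normal(50)]))
    assert fc.matrix[0, 1] == pytest.approx(np.arctanh(Z_CLIP))


def test_white_noise_z_near_zero():
    """At 10,000 frames the sampling sd of z is ~0.01, so |z| stays < 0.05."""
    rng = np.random.default_rng(1)
    fc = fc_from_timeseries(rng.standard_normal((10000, 6)))
    off = fc.matrix[~np.eye(6, dtype=bool)]
    assert np.abs(off).max() < 0.05


def test_197_rois_give_19306_pairs():
    rng = np.random.default_rng(2)
    fc = fc_from_timeseries(rng.standard_normal((12, 197)))
    iu = np.triu_indices(197, k=1)
    assert len(iu[0]) == 19306
    stack = threshold_stack(fc, densities=[0.05])
    assert stack.n_eligible == 19306


@pytest.mark.parametrize("frames", [5, 9])
def test_too_few_frames_rejected(frames):
    with pytest.raises(ValueError, match="frames"):
        fc_from_timeseries(np.random.default_rng(0).standard_normal((frames, 4)))


def test_constant_column_names_roi():
    ts = np.random.default_rng(0).standard_normal((30, 3))
    ts[:, 1] = 7.0
    with pytest.raises(ValueError, match="roi001"):
        fc_from_timeseries(ts)


def test_column_permutation_equivariance():
    rng = np.random.default_rng(3)
    ts = rng.standard_normal((60, 8))
    perm = rng.permutation(8)
    a = fc_from_timeseries(ts).matrix
    b = fc_from_timeseries(ts[:, perm]).matrix
    assert np.allclose(a[np.ix_(perm, perm)], b, atol=1e-12)


def test_group_average_matches_bruteforce_and_order_invariant(rng):
    mats = []
    for s in range(12):
        m = rng.standard_normal((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        mats.append(FCMatrix(matrix=m, roi_ids=[f"r{i}" for i in range(6)]))
    avg = group_average(mats).matrix
    brute = np.zeros((6, 6))
    for m in mats:
        brute += m.matrix
    brute /= len(mats)
    assert np.allclose(avg, brute, atol=1e-12)
    shuffled = [mats[i] for i in rng.permutation(12)]
    assert np.allclose(group_average(shuffled).matrix, avg, atol=1e-12)


def test_group_average_of_matrix_and_negation_is_zero():
    m = np.array([[0, 0.4], [0.4, 0]])
    a = FCMatrix(matrix=m, roi_ids=["a", "b"])
    b = FCMatrix(matrix=-m, roi_ids=["a", "b"])
    assert np.allclose(group_average([a, b]).matrix, 0)
    assert np.allclose(group_average([a, a]).matrix, m)


def test_distance_exclusion_strict_boundary():
    """9.99 mm is excluded; exactly 10.0 mm is retained (strict <)."""
    meta = _roi_meta([[0, 0, 0], [9.99, 0, 0], [0, 10.0, 0]])
    fc = FCMatrix(matrix=np.zeros((3, 3)), roi_ids=list(meta["roi_id"]))
    eligible, excluded = exclude_short_edges(fc, meta)
    assert excluded == [("roi000", "roi001")]
    assert eligible[0, 2] and eligible[1, 2] and not eligible[0, 1]


def test_missing_coordinates_rejected():
    meta = _roi_meta([[0, 0, 0], [20, 0, 0]])
    meta.loc[1, "x"] = np.nan
    fc = FCMatrix(matrix=np.zeros((2, 2)), roi_ids=list(meta["roi_id"]))
    with pytest.raises(ValueError, match="coordinates"):
        exclude_short_edges(fc, meta)


def test_default_grid_has_91_densities():
    grid = default_density_grid()
    assert len(grid) == 91
    assert grid[0] == 0.01 and grid[-1] == 0.10
    rng = np.random.default_rng(4)
    fc = fc_from_timeseries(rng.standard_normal((40, 20)))
    stack = threshold_stack(fc)
    assert len(stack.matrices) == 91
    E = stack.n_eligible
    for d, m in zip(stack.thresholds, stack.matrices):
        assert int(np.triu(m, 1).sum()) == int(np.floor(d * E + 0.5))


def test_saturation_density_keeps_all_edges():
    rng = np.random.default_rng(5)
    fc = fc_from_timeseries(rng.standard_normal((30, 8)))
    stack = threshold_stack(fc, densities=[1.0])
    assert int(np.triu(stack.matrices[0], 1).sum()) == stack.n_eligible


@pytest.mark.parametrize("d", [0.0, -0.1, 1.5])
def test_invalid_density_rejected(d):
    fc = FCMatrix(matrix=np.zeros((4, 4)), roi_ids=list("abcd"))
    with pytest.raises(ValueError, match="density"):
        threshold_stack(fc, densities=[d])


def test_tie_break_matches_sort_oracle():
    """Ties at the cut rank resolve by (z desc, i asc, j asc), exactly as an
    independent full-sort oracle predicts."""
    n = 6
    m = np.zeros((n, n))
    vals = {(0, 1): 0.9, (0, 2): 0.5, (1, 2): 0.5, (3, 4): 0.5, (0, 3): 0.2,
            (2, 3): 0.1, (4, 5): 0.05, (1, 3): 0.0, (2, 4): -0.1, (0, 4): -0.2,
            (1, 4): -0.3, (2, 5): -0.4, (0, 5): -0.5, (1, 5): -0.6, (3, 5): -0.7}
    for (i, j), v in vals.items():
        m[i, j] = m[j, i] = v
    fc = FCMatrix(matrix=m, roi_ids=[f"r{i}" for i in range(n)])
    # oracle: sorted edge list, keep first k
    oracle = sorted(vals.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    for d in (0.2, 0.25, 0.3):
        k = int(np.floor(d * 15 + 0.5))
        stack = threshold_stack(fc, densities=[d])
        kept = {tuple(sorted((i, j))) for i, j in zip(*np.nonzero(np.triu(stack.matrices[0], 1)))}
        assert kept == {e for e, _ in oracle[:k]}


def test_nested_edge_sets_with_unique_z():
    rng = np.random.default_rng(6)
    n = 15
    m = rng.standard_normal((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)  # continuous values: unique with probability 1
    fc = FCMatrix(matrix=m, roi_ids=[f"r{i}" for i in range(n)])
    stack = threshold_stack(fc)
    prev = None
    for mat in stack.matrices:
        cur = {tuple(e) for e in zip(*np.nonzero(np.triu(mat, 1)))}
        if prev is not None:
            assert prev <= cur
        prev = cur
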