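"""WQS index estimation, support factors, and moderation."""

import numpy as np
import pandas as pd
import pytest

from fetalconn import (generate_cohort, GeneratorConfig, fc_from_timeseries,
                       group_average, exclude_short_edges, wqs_fit,
                       wqs_moderation, support_factor_analysis, quantize,
                       pair_summaries, edgewise_correlation)
from fetalconn.enrichment import stack_fc
from fetalconn.synthetic import HEALTH_COLUMNS, HEALTH_LOADINGS
from conftest import truth_codes


def test_quantize_invariant_to_monotone_transform():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 3))
    q1 = quantize(X, 4)
    q2 = quantize(np.exp(X * 2) + 5, 4)  # strictly increasing transform
    assert np.array_equal(q1, q2)


def test_quantize_coarse_fallback_warns():
    X = np.repeat([[0.0], [1.0]], 50, axis=0)
    with pytest.warns(RuntimeWarning, match="coarser"):
        q = quantize(X, 4)
    assert set(np.unique(q)) <= {0.0, 1.0, 2.0, 3.0}


def test_single_component_weight_is_one():
    rng = np.random.default_rng(1)
    fit = wqs_fit(rng.standard_normal((60, 1)), rng.standard_normal(60),
                  n_boot=10, seed=0)
    assert fit.weights == pytest.approx([1.0])


def test_planted_weight_recovery():
    rng = np.random.default_rng(2)
    n = 500
    true_w = np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0])
    X = rng.standard_normal((n, 6))
    y = 2.0 * (quantize(X, 4) @ true_w) + rng.standard_normal(n)
    fit = wqs_fit(X, y, q=4, n_boot=100, seed=3)
    assert np.abs(fit.weights - true_w).max() <= 0.1
    assert fit.beta > 0 and fit.p < 0.01
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(fit.weights >= 0)


def test_split_is_reproducible_and_disjoint():
    rng = np.random.default_rng(3)
    X, y = rng.standard_normal((100, 4)), rng.standard_normal(100)
    f1 = wqs_fit(X, y, n_boot=10, seed=11)
    f2 = wqs_fit(X, y, n_boot=10, seed=11)
    assert np.array_equal(f1.train_mask, f2.train_mask)
    assert np.array_equal(f1.weights, f2.weights)
    assert f1.train_mask.sum() == 40  # 40% train
    assert (~f1.train_mask).sum() == 60


def test_null_outcome_rarely_significant():
    hits = 0
    for s in range(12):
        rng = np.random.default_rng(400 + s)
        fit = wqs_fit(rng.standard_normal((200, 5)), rng.standard_normal(200),
                      n_boot=30, seed=s)
        hits += fit.p < 0.05
    assert hits <= 3


def test_no_positive_signal_raises():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((100, 3))
    y = -quantize(X, 4).sum(axis=1)  # noiseless negative-direction outcome
    with pytest.raises(ValueError, match="positive-direction"):
        wqs_fit(X, y, n_boot=20, seed=0)


def test_preconditions():
    rng = np.random.default_rng(6)
    with pytest.raises(ValueError, match="subjects"):
        wqs_fit(rng.standard_normal((20, 3)), rng.standard_normal(20))


# --- support factors ------------------------------------------------------

def _health_data(n, seed):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, 3))
    uniq = np.sqrt(1 - (HEALTH_LOADINGS ** 2).sum(axis=1))
    X = F @ HEALTH_LOADINGS.T + uniq * rng.standard_normal((n, 10))
    return pd.DataFrame(X, columns=HEALTH_COLUMNS), F


def test_parallel_analysis_retains_three_factors():
    correct = 0
    for s in range(20):
        X, _ = _health_data(300, 50 + s)
        res = support_factor_analysis(X, seed=s, n_resamples=100)
        correct += res["n_factors"] == 3
    assert correct >= 18


def test_support_factor_scores_track_truth():
    X, F = _health_data(600, 7)
    res = support_factor_analysis(X, seed=1, n_resamples=100)
    assert list(res["scores"].columns) == ["HE", "FS", "HAR"]
    for j, name in enumerate(["HE", "FS", "HAR"]):
        r = np.corrcoef(res["scores"][name], F[:, j])[0, 1]
        assert r > 0.8, f"{name}: r={r}"
    sc = res["scores"].to_numpy()
    assert np.allclose(sc.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(sc.std(axis=0, ddof=1), 1, atol=1e-9)


def test_pure_noise_retains_zero_factors():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.standard_normal((200, 10)), columns=HEALTH_COLUMNS)
    with pytest.raises(ValueError, match="0 factors"):
        support_factor_analysis(X, seed=0, n_resamples=100)


def test_duplicate_columns_singular():
    X, _ = _health_data(200, 9)
    X["exercise"] = X["diet"]
    with pytest.raises(ValueError, match="collinear"):
        support_factor_analysis(X, seed=0, n_resamples=50)


def test_small_sample_rejected():
    X, _ = _health_data(40, 10)
    with pytest.raises(ValueError, match="subjects"):
        support_factor_analysis(X, seed=0)


# --- components and moderation -------------------------------------------

def _cohort_components(seed, n=400, har_slope=0.5):
    cfg = GeneratorConfig(n_subjects=n, n_roi=30, n_networks=6,
                          frames_mean=120, frames_sd=10,
                          stress_coupled_pairs=(("N01", "N02"), ("N03", "N03")),
                          coupling_slope=0.03, har_moderation_slope=har_slope,
                          seed=seed)
    coh = generate_cohort(cfg)
    nas = coh.truth["latent_nas"].to_numpy()
    fcs = [fc_from_timeseries(coh.timeseries[s], roi_ids=list(coh.roi_meta["roi_id"]))
           for s in coh.subjects["id"]]
    grp = group_average(fcs)
    elig, _ = exclude_short_edges(grp, coh.roi_meta)
    X, ei, ej, rids = stack_fc(fcs, elig)
    labels = truth_codes(coh)
    es = edgewise_correlation(X, nas, (ei, ej, rids))
    comps = pair_summaries(X, es, labels, [(0, 1), (2, 2)])
    return coh, comps, nas, es, X, labels


def test_pair_summaries_mean_over_significant_edges():
    coh, comps, nas, es, X, labels = _cohort_components(0, n=100)
    assert list(comps.columns) == ["0-1", "2-2"]
    a, b = labels[es.edge_i], labels[es.edge_j]
    mask = (np.minimum(a, b) == 0) & (np.maximum(a, b) == 1) & es.significant
    assert np.allclose(comps["0-1"], X[:, mask].mean(axis=1))
    with pytest.raises(ValueError, match="no significant"):
        pair_summaries(X, es, labels, [(4, 5)])


def test_moderation_sign_recovery():
    """HAR is planted to amplify the stress-connectivity coupling, so the
    index x HAR interaction on NAS should be positive in most replicates."""
    signs = []
    for s in range(15):
        coh, comps, nas, *_ = _cohort_components(900 + s)
        fit = wqs_fit(comps, nas, n_boot=40, seed=s)
        sup = support_factor_analysis(coh.subjects[HEALTH_COLUMNS], seed=s,
                                      n_resamples=80)
        mod = wqs_moderation(fit, sup["scores"], nas).set_index("factor")
        signs.append(mod.loc["HAR", "beta_interaction"] > 0)
    assert sum(signs) >= 13


def test_moderation_constant_moderator_raises():
    coh, comps, nas, *_ = _cohort_components(1, n=100)
    fit = wqs_fit(comps, nas, n_boot=10, seed=0)
    sup = pd.DataFrame({"HAR": np.ones(100)})
    with pytest.raises(ValueError, match="constant"):
        wqs_moderation(fit, sup, nas)


def test_moderation_reports_simple_slopes():
    coh, comps, nas, *_ = _cohort_components(2, n=150)
    fit = wqs_fit(comps, nas, n_boot=15, seed=1)
    sup = support_factor_analysis(coh.subjects[HEALTH_COLUMNS], seed=2,
                                  n_resamples=50)
    mod = wqs_moderation(fit, sup["scores"], nas)
    assert set(mod["factor"]) == {"HE", "FS", "HAR"}
    row = mod.set_index("factor").loc["HAR"]
    assert row["simple_slope_high"] == pytest.approx(
        row["beta_index"] + row["beta_interaction"])
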