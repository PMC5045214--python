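"""Feature-channel computations against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from neuromkl import (CohortConfig, VoxelMap, bandpass, compute_alff,
                      compute_reho, compute_rfcs, connectivity,
                      extract_features, global_mean_scale, make_atlas,
                      regional_means, regress_nuisance, roi_timeseries,
                      simulate_cohort)


# ---------------------------------------------------------------- oracles

def alff_oracle(x, tr, low, high):
    """Direct-DFT mean in-band amplitude of a single demeaned series."""
    x = np.asarray(x, float)
    x = x - x.mean()
    T = len(x)
    t = np.arange(T)
    vals = []
    for k in range(T // 2 + 1):
        f = k / (T * tr)
        if low <= f <= high and f > 0:
            Xk = np.sum(x * np.exp(-2j * np.pi * k * t / T))
            vals.append(2.0 * abs(Xk) / T)
    return float(np.mean(vals))


def kendalls_w_oracle(series):
    """Rank-sum Kendall's W of a list of series (midranks for ties)."""
    R = np.array([stats.rankdata(s) for s in series])
    K, T = R.shape
    Rt = R.sum(axis=0)
    S = np.sum((Rt - Rt.mean()) ** 2)
    return 12.0 * S / (K ** 2 * (T ** 3 - T))


def rfcs_oracle(roi_ts):
    """Double-loop Pearson + absolute-mean regional correlation strength."""
    n = len(roi_ts)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i == j:
                continue
            acc += abs(stats.pearsonr(roi_ts[i], roi_ts[j])[0])
        out[i] = acc / (n - 1)
    return out


# --------------------------------------------------------------- bandpass

def test_bandpass_rejects_out_of_band_and_keeps_in_band():
    t = np.arange(128) * 2.0
    fast = np.sin(2 * np.pi * 0.2 * t)
    slow = np.sin(2 * np.pi * 0.05 * t)
    out_fast = bandpass(fast, 2.0, 0.01, 0.08)
    out_slow = bandpass(slow, 2.0, 0.01, 0.08)
    assert np.var(out_fast) < 0.01 * np.var(fast)
    assert np.var(out_slow) >= 0.95 * np.var(slow)


def test_bandpass_recovers_in_band_component_of_mixture():
    t = np.arange(150) * 2.0
    slow = np.sin(2 * np.pi * 0.05 * t + 0.3)
    mixed = slow + np.sin(2 * np.pi * 0.2 * t)
    out = bandpass(mixed, 2.0, 0.01, 0.08)
    r = np.corrcoef(out, slow)[0, 1]
    assert r > 0.99


def test_bandpass_is_linear_and_validates_band():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(64)
    np.testing.assert_allclose(bandpass(3.0 * x, 2.0, 0.01, 0.08),
                               3.0 * bandpass(x, 2.0, 0.01, 0.08), atol=1e-12)
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(x, 2.0, 0.01, 0.3)


# ------------------------------------------------------------------- ALFF

def test_alff_matches_direct_dft_oracle_and_scales_linearly():
    rng = np.random.default_rng(7)
    vol = rng.standard_normal((2, 2, 1, 150))
    vmap = compute_alff(vol, tr=2.0)
    for idx in np.ndindex(2, 2, 1):
        expect = alff_oracle(vol[idx], 2.0, 0.01, 0.08)
        assert abs(vmap.values[idx] - expect) <= 1e-10 * max(expect, 1)
    np.testing.assert_allclose(compute_alff(2.0 * vol, tr=2.0).values,
                               2.0 * vmap.values, rtol=1e-12)


def test_alff_zero_for_constant_series_and_sinusoid_amplitude_ratio():
    vol = np.ones((1, 1, 1, 64)) * 5.0
    assert compute_alff(vol, tr=2.0).values[0, 0, 0] == 0.0
    t = np.arange(200) * 2.0
    s = np.sin(2 * np.pi * 0.05 * t)
    vol = np.stack([s, 2 * s]).reshape(2, 1, 1, 200)
    vals = compute_alff(vol, tr=2.0).values[:, 0, 0]
    assert abs(vals[1] / vals[0] - 2.0) < 0.01


# ------------------------------------------------------ global mean scale

def test_global_mean_scale_examples_and_unit_mean():
    m = VoxelMap(values=np.full((2, 1, 1), 7.0), mask=np.ones((2, 1, 1), bool))
    np.testing.assert_allclose(global_mean_scale(m).values, 1.0)
    m = VoxelMap(values=np.array([1.0, 3.0]).reshape(2, 1, 1),
                 mask=np.ones((2, 1, 1), bool))
    np.testing.assert_allclose(global_mean_scale(m).values.ravel(), [0.5, 1.5])


@given(st.integers(0, 2 ** 31 - 1))
def test_global_mean_scale_mean_is_one_for_random_maps(seed):
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(size=(3, 3, 3))
    mask = rng.random((3, 3, 3)) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    out = global_mean_scale(VoxelMap(values=vals, mask=mask))
    assert abs(out.values[mask].mean() - 1.0) < 1e-12


# ------------------------------------------------------------------- ReHo

def test_reho_is_one_for_identical_series_and_matches_rank_oracle():
    rng = np.random.default_rng(1)
    base = rng.standard_normal(50)
    vol = np.tile(base, (3, 3, 3, 1))
    w = compute_reho(vol)
    assert w.mask.sum() == 1  # only the centre voxel has a full cluster
    assert abs(w.values[1, 1, 1] - 1.0) < 1e-12

    vol = rng.standard_normal((3, 3, 3, 50))
    w = compute_reho(vol)
    expect = kendalls_w_oracle(vol.reshape(27, 50))
    assert abs(w.values[1, 1, 1] - expect) < 1e-10


def test_reho_bounded_and_boundary_masked():
    rng = np.random.default_rng(2)
    vol = rng.standard_normal((5, 4, 4, 20))
    w = compute_reho(vol)
    interior = np.zeros((5, 4, 4), bool)
    interior[1:-1, 1:-1, 1:-1] = True
    assert np.array_equal(w.mask, interior)
    assert np.all((w.values[w.mask] >= 0) & (w.values[w.mask] <= 1))


def test_reho_constant_cluster_flagged_and_masked():
    import warnings

    vol = np.zeros((3, 3, 3, 20))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        with pytest.raises(ValueError, match="no voxel"):
            compute_reho(vol)
    assert any("constant" in str(w.message) for w in caught)


# ------------------------------------------------------------- regression

def test_nuisance_regression_matches_ols_and_orthogonalizes():
    rng = np.random.default_rng(3)
    T = 60
    cov = rng.standard_normal((2, T))
    Y = rng.standard_normal((4, T))
    res = regress_nuisance(Y, cov)
    X = np.column_stack([np.ones(T), cov.T])
    beta = np.linalg.solve(X.T @ X, X.T @ Y.T)
    np.testing.assert_allclose(res, Y - (X @ beta).T, atol=1e-8)
    for r in res:
        for c in cov:
            cr = r / np.linalg.norm(r)
            cc = c / np.linalg.norm(c)
            assert abs(cr @ cc) < 1e-8
    # perfect confound -> residual ~ 0
    res = regress_nuisance(cov[0][None, :], cov[0][None, :])
    assert np.max(np.abs(res)) < 1e-10


def test_rank_deficient_covariates_rejected():
    cov = np.vstack([np.ones(20), np.ones(20)])
    with pytest.raises(ValueError, match="rank deficient"):
        regress_nuisance(np.random.default_rng(0).standard_normal((2, 20)), cov)


# ------------------------------------------------------------ ROI series

def test_roi_timeseries_hand_example_and_loop_oracle():
    atlas = make_atlas((2, 1, 1), 1)
    vol = np.array([[0.0, 2.0, 4.0], [2.0, 2.0, 2.0]]).reshape(2, 1, 1, 3)
    np.testing.assert_allclose(roi_timeseries(vol, atlas)[0], [1.0, 2.0, 3.0])

    atlas = make_atlas((4, 3, 2), 5)
    rng = np.random.default_rng(4)
    vol = rng.standard_normal((4, 3, 2, 10))
    ts = roi_timeseries(vol, atlas)
    for i, rid in enumerate(atlas.roi_ids):
        acc = np.zeros(10)
        cnt = 0
        for idx in np.ndindex(4, 3, 2):
            if atlas.labels[idx] == rid:
                acc += vol[idx]
                cnt += 1
        np.testing.assert_allclose(ts[i], acc / cnt, atol=1e-12)


# ------------------------------------------------------------------- RFCS

def test_rfcs_trivial_cases_and_bruteforce_oracle():
    # identical series everywhere -> S(i) = 1
    base = np.sin(np.linspace(0, 7, 40))
    conn = connectivity(np.tile(base, (4, 1)) + 0, (1, 2, 3, 4))
    np.testing.assert_allclose(compute_rfcs(conn), 1.0)
    # N=2, r=-0.4 -> S = 0.4
    rng = np.random.default_rng(5)
    x = rng.standard_normal(200)
    y = -0.4 * x + np.sqrt(1 - 0.16) * rng.standard_normal(200)
    r = np.corrcoef(x, y)[0, 1]
    conn = connectivity(np.vstack([x, y]), (1, 2))
    np.testing.assert_allclose(compute_rfcs(conn), abs(r), atol=1e-12)
    # seeded 5-ROI oracle
    ts = rng.standard_normal((5, 60))
    conn = connectivity(ts, tuple(range(1, 6)))
    np.testing.assert_allclose(compute_rfcs(conn), rfcs_oracle(ts), atol=1e-12)


# --------------------------------------------------------- regional means

def test_regional_means_constant_and_masked():
    atlas = make_atlas((4, 2, 2), 4)
    vmap = VoxelMap(values=np.full((4, 2, 2), 3.5), mask=np.ones((4, 2, 2), bool))
    np.testing.assert_allclose(regional_means(vmap, atlas), 3.5)
    mask = np.ones((4, 2, 2), bool)
    mask[atlas.roi_mask(2)] = False
    vmap = VoxelMap(values=np.ones((4, 2, 2)), mask=mask)
    out = regional_means(vmap, atlas)
    assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()


# -------------------------------------------------------------- extraction

def test_extract_features_shapes_and_label_permutation_equivariance():
    import warnings

    cfg = CohortConfig(n_patients=3, n_controls=3, n_timepoints=40,
                       volume_shape=(6, 6, 6), n_rois=8, seed=2)
    cohort = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = extract_features(cohort)
    assert set(tables) == {"ALFF", "ReHo", "RFCS", "GM"}
    for tab in tables.values():
        assert tab.matrix.shape[0] == 6
        assert len(tab.roi_ids) <= 8

    # permuting atlas labels permutes feature entries identically
    from dataclasses import replace

    from neuromkl.atlas import AtlasParcellation

    atlas = cohort.atlas
    perm = {1: 4, 4: 1, 2: 7, 7: 2, 3: 3, 5: 5, 6: 6, 8: 8}
    relabeled = np.vectorize(perm.get)(atlas.labels).astype(np.int32)
    atlas2 = AtlasParcellation(labels=relabeled, roi_ids=atlas.roi_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables2 = extract_features(cohort, atlas=atlas2)
    for ch in tables:
        t1, t2 = tables[ch], tables2[ch]
        common = [r for r in t1.roi_ids if perm[r] in t2.roi_ids]
        for r in common:
            c1 = t1.matrix[:, t1.roi_ids.index(r)]
            c2 = t2.matrix[:, t2.roi_ids.index(perm[r])]
            np.testing.assert_allclose(c1, c2, atol=1e-12)
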