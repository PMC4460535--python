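"""Searchlight, GLM t-maps, and percent coverage."""

import numpy as np
import pytest

from blockdecode import VoxelMap, glm_map, percent_coverage, searchlight
from blockdecode.evaluate import CHANCE_LEVEL


def _volume_session(rng, shape=(4, 4, 3), n_runs=2, signal_region=None,
                    effect=2.0):
    """Small 4-D volume with balanced six-class blocks; optional planted
    signal inside ``signal_region`` (a boolean volume)."""
    n_frames = n_runs * 72
    y = np.tile(np.repeat(np.tile(np.arange(1, 7), 2), 6), n_runs)
    block = np.repeat(np.arange(12 * n_runs), 6)
    run = np.repeat(np.arange(n_runs), 72)
    data = rng.standard_normal(shape + (n_frames,))
    if signal_region is not None:
        patterns = rng.standard_normal((6, int(signal_region.sum())))
        sig = effect * patterns[y - 1].T          # voxels x frames
        data[signal_region] += sig
    return data, y, block, run


def test_searchlight_one_value_per_in_mask_voxel():
    rng = np.random.default_rng(0)
    data, y, block, run = _volume_session(rng, shape=(3, 3, 1))
    mask = np.ones((3, 3, 1), bool)
    mask[0, 0, 0] = False
    vmap = searchlight(data, y, block, run, mask=mask, seed=0)
    assert len(vmap.values) == mask.sum()
    assert vmap.kind == "searchlight_accuracy"
    assert vmap.threshold == pytest.approx(2 * CHANCE_LEVEL)


def test_searchlight_pure_noise_sits_at_chance():
    rng = np.random.default_rng(1)
    data, y, block, run = _volume_session(rng, shape=(3, 3, 1))
    vmap = searchlight(data, y, block, run, seed=1)
    n_dec = len(vmap.values) * 144
    band = 3 * np.sqrt(CHANCE_LEVEL * (1 - CHANCE_LEVEL) / n_dec)
    assert abs(np.nanmean(vmap.values) - CHANCE_LEVEL) < band + 0.02


def test_searchlight_finds_planted_region():
    hits = 0
    for seed in range(3):
        rng = np.random.default_rng(seed + 10)
        region = np.zeros((4, 4, 1), bool)
        region[:2, :2, 0] = True
        data, y, block, run = _volume_session(rng, shape=(4, 4, 1),
                                              signal_region=region)
        vmap = searchlight(data, y, block, run, seed=seed)
        vol = vmap.to_volume()[..., ]
        inside = np.nanmean(vol[region])
        outside = np.nanmean(vol[~region])
        hits += inside > outside
    assert hits >= 2


def test_glm_recovers_noise_free_regressor_exactly():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 3))
    Y = np.outer(np.ones(5), X[:, 1])          # 5 voxels = regressor 1
    vmap = glm_map(Y, X)
    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0]
    assert np.allclose(beta[1], 1.0) and np.allclose(beta[[0, 2]], 0.0, atol=1e-10)
    assert np.all(vmap.values > 1e3)           # near-zero residual -> huge t


def test_glm_betas_match_normal_equations_oracle():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((50, 4))
    Y = rng.standard_normal((7, 50))
    beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y.T).T
    pinv = np.linalg.pinv(X)
    assert np.allclose(Y @ pinv.T, beta_oracle, atol=1e-8)
    vmap = glm_map(Y, X)
    assert len(vmap.values) == 7


def test_glm_null_t_pvalues_roughly_uniform():
    from scipy import stats
    rng = np.random.default_rng(4)
    n, p = 60, 3
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((1000, n))
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T
    resid = Y - beta @ X.T
    sigma2 = (resid ** 2).sum(axis=1) / (n - p)
    t = beta[:, 0] / np.sqrt(sigma2 * np.diag(pinv @ pinv.T)[0])
    pvals = 2 * stats.t.sf(np.abs(t), df=n - p)
    ks = stats.kstest(pvals, "uniform").statistic
    assert ks < 0.1


def test_glm_rank_deficient_design_rejected():
    X = np.ones((10, 2))
    with pytest.raises(ValueError):
        glm_map(np.random.default_rng(5).standard_normal((3, 10)), X)


def _toy_map(values, threshold=0.5):
    coords = np.column_stack([np.arange(len(values)),
                              np.zeros(len(values), int),
                              np.zeros(len(values), int)])
    return VoxelMap(np.asarray(values, float), coords, threshold, "glm_t",
                    (len(values), 1, 1))


def test_coverage_all_in_one_label():
    vmap = _toy_map([1.0, 1.0, 0.1])
    cov = dict(percent_coverage(vmap, np.array(["A", "A", "B"], object)))
    assert cov["A"] == pytest.approx(1.0)
    assert cov["B"] == 0.0


def test_coverage_fractions_sum_to_one():
    vmap = _toy_map([1, 1, 1, 0.2, 0.9])
    cov = percent_coverage(vmap, np.array(["A", "A", "B", "B", "C"], object))
    assert sum(f for _, f in cov) == pytest.approx(1.0, abs=1e-9)


def test_coverage_two_thirds_one_third():
    vmap = _toy_map([1, 1, 1])
    cov = dict(percent_coverage(vmap, np.array(["A", "A", "B"], object)))
    assert cov["A"] == pytest.approx(2 / 3)
    assert cov["B"] == pytest.approx(1 / 3)


def test_coverage_empty_supra_threshold_flagged():
    vmap = _toy_map([0.1, 0.2], threshold=0.9)
    with pytest.warns(UserWarning):
        cov = percent_coverage(vmap, np.array(["A", "B"], object))
    assert all(f == 0.0 for _, f in cov)


def test_distributed_signal_beats_best_searchlight():
    """When class information is split across two distant, individually
    weak voxels (a 3x2 factorial code of the six counts), the whole-volume
    decoder with nested ANOVA selection outperforms the best single
    searchlight neighborhood, which can never see both regions at once."""
    from blockdecode import cross_validate
    from blockdecode.dataset import ExampleSet

    whole, best_local = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed + 40)
        n_frames = 2 * 72
        y = np.tile(np.repeat(np.tile(np.arange(1, 7), 2), 6), 2)
        block = np.repeat(np.arange(24), 6)
        run = np.repeat(np.arange(2), 72)
        data = rng.standard_normal((5, 5, 1, n_frames))
        data[0, 0, 0] += 2.5 * ((y - 1) // 2)   # coarse count level
        data[4, 4, 0] += 2.5 * ((y - 1) % 2)    # fine count level
        vmap = searchlight(data, y, block, run, seed=seed, cv_args={"k": 4})
        best_local.append(np.nanmax(vmap.values))
        ex = ExampleSet(data.reshape(-1, n_frames).T, y, block, run)
        whole.append(cross_validate(
            ex, "block", k=4, selection_k=4,
            classifier_spec={"name": "nn", "hidden_grid": [8],
                             "n_restarts": 1, "max_epochs": 150},
            seed=seed).mean_accuracy)
    assert np.mean(whole) > np.mean(best_local)
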