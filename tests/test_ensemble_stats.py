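import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gik import synthetic_data as sd
from gik.ensemble_stats import (
    block_stats,
    cluster_frames,
    population_percentages,
    representative,
    rmsd,
    rmsd_series,
)
from gik.errors import CongruenceError, GikError, ParameterError


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def test_rmsd_identity_and_rigid_invariance(rng):
    a = rng.normal(size=(30, 3)) * 5
    assert rmsd(a, a) == pytest.approx(0.0, abs=1e-9)
    R = Rotation.random(random_state=1).as_matrix()
    moved = a @ R.T + [3.0, -7.0, 1.0]
    assert rmsd(a, moved, superpose=True) == pytest.approx(0.0, abs=1e-6)
    assert rmsd(a, moved, superpose=False) > 1.0


def test_rmsd_known_value():
    a = np.zeros((4, 3))
    b = np.zeros((4, 3))
    b[:, 0] = [1.0, -1.0, 1.0, -1.0]  # centered, no rotation improves it
    assert rmsd(a, b, superpose=False) == pytest.approx(1.0)
    with pytest.raises(CongruenceError):
        rmsd(a, np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# block averaging
# ---------------------------------------------------------------------------

def test_block_stats_hand_computed():
    # two replicates of 6 frames, block size 3 -> 2 blocks each
    s1 = [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]   # block means 2, 4 -> mean 3, sem 1
    s2 = [2.0, 2.0, 2.0, 4.0, 4.0, 4.0]   # block means 2, 4 -> mean 3, sem 1
    bs = block_stats([s1, s2], block_size=3)
    assert [r.mean for r in bs.per_replicate] == [3.0, 3.0]
    assert bs.per_replicate[0].sem == pytest.approx(1.0)
    assert bs.ensemble_mean == 3.0
    assert bs.ensemble_sem == 0.0  # identical replicate means
    assert bs.dropped_frames == 0


def test_block_stats_partial_block_dropped():
    bs = block_stats([[1.0] * 7], block_size=3)
    assert bs.dropped_frames == 1
    assert bs.per_replicate[0].block_means.size == 2
    with pytest.raises(ParameterError):
        block_stats([[1.0, 2.0]], block_size=5)
    with pytest.raises(ParameterError):
        block_stats([[1.0, 2.0]], block_size=0)


def test_across_replicate_estimator_uses_sample_sd():
    means = [2.0, 2.5, 3.0]
    bs = block_stats([[m] * 4 for m in means], block_size=2)
    assert bs.ensemble_mean == pytest.approx(np.mean(means))
    assert bs.ensemble_sem == pytest.approx(np.std(means, ddof=1) / np.sqrt(3))


def test_population_percentage_inference():
    percentages, total = population_percentages(
        [3525, 1162, 1117], anchor_count=1162, anchor_percent=15.5)
    assert total == 7497
    assert percentages == [47.0, 15.5, 14.9]
    with pytest.raises(ParameterError):
        population_percentages([1], 0, 15.5)


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

def _gromos_oracle(frames, cutoff):
    """Independent GROMOS reimplementation (naive, O(F^3))."""
    F = frames.shape[0]
    D = np.zeros((F, F))
    for i in range(F):
        for j in range(F):
            D[i, j] = np.sqrt(((frames[i] - frames[j]) ** 2).sum(1).mean())
    active = set(range(F))
    assign = {}
    cid = 0
    while active:
        cid += 1
        best, best_n = None, -1
        for i in sorted(active):
            n = sum(1 for j in active if D[i, j] <= cutoff)
            if n > best_n:
                best, best_n = i, n
        members = sorted(j for j in active if D[best, j] <= cutoff)
        for j in members:
            assign[j] = cid
        active -= set(members)
    return assign


@pytest.mark.parametrize("seed", [0, 3])
def test_clustering_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-10, 10, size=(3, 5, 3))
    frames = np.concatenate([
        c + rng.normal(scale=0.4, size=(15, 5, 3)) for c in centers])
    res = cluster_frames(frames, cutoff=1.5)
    oracle = _gromos_oracle(frames, 1.5)
    assert [res.assignments[i] for i in range(len(frames))] == \
        [oracle[i] for i in range(len(frames))]
    assert sum(n for n, _ in res.populations.values()) == len(frames)


def test_clustering_deterministic_and_tiebreak():
    # two isolated singleton frames with equal neighbor counts: the lower
    # frame index becomes the first cluster
    frames = np.zeros((2, 3, 3))
    frames[1] += 100.0
    res = cluster_frames(frames, cutoff=1.0)
    assert res.assignments.tolist() == [1, 2]
    res2 = cluster_frames(frames, cutoff=1.0)
    assert np.array_equal(res.assignments, res2.assignments)
    with pytest.raises(ParameterError):
        cluster_frames(frames, cutoff=0.0)


def test_medoid_is_min_mean_rmsd_member(rng):
    frames = rng.normal(scale=0.3, size=(12, 4, 3))
    res = cluster_frames(frames, cutoff=10.0)  # one cluster
    assert res.sorted_ids() == [1]
    med = representative(res, 1)
    D = np.array([[np.sqrt(((a - b) ** 2).sum(1).mean()) for b in frames]
                  for a in frames])
    assert med == int(D.mean(axis=1).argmin())
    with pytest.raises(GikError):
        representative(res, 99)


def test_planted_basin_recovery_small(small_scenario, small_ensemble,
                                      small_ensemble_record):
    rec = small_ensemble_record
    res = cluster_frames(small_ensemble, selection_idx=sd.h5_ca_indices(rec),
                         cutoff=1.5, fit_idx=sd.receptor_ca_indices(rec))
    planted = sorted((b.fraction for b in small_scenario.basins), reverse=True)
    top = [res.populations[c][1] for c in res.sorted_ids()[:3]]
    assert np.abs(np.array(top) - np.array(planted)).max() < 0.1  # n=80 frames


def test_rmsd_series_shapes(small_ensemble):
    sel = np.arange(10)
    ref = small_ensemble.topology.coords()
    series = rmsd_series(small_ensemble, ref, sel)
    assert len(series) == small_ensemble.n_replicates
    assert all(s.values.size == 40 for s in series)  # 80 frames, 50% discard
    assert all((s.values >= 0).all() for s in series)
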