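"""Co-clustering, Binder point partitions, articulation and agreement summaries."""

import itertools

import numpy as np
import pytest

import delphilearn as dl
from delphilearn.summaries import binder_loss, enumerate_partitions

from conftest import make_draws


# ---------------------------------------------------------------------------
# co-clustering matrix
# ---------------------------------------------------------------------------

def test_coclustering_counting():
    s = np.array(   # rows are draws, columns participants
        [
            [1, 1, 3],
            [1, 1, 3],
            [1, 1, 3],
            [2, 1, 3],
        ]
    )
    C = dl.coclustering_matrix(s)
    assert C[0, 1] == pytest.approx(0.75)   # share a label in 3 of 4 draws
    assert C[0, 2] == pytest.approx(0.0)    # never share
    assert np.allclose(np.diag(C), 1.0)
    assert np.allclose(C, C.T)


def test_coclustering_invariant_to_label_permutation():
    rng = np.random.default_rng(0)
    s = rng.integers(1, 5, size=(50, 8))
    perm = np.array([0, 3, 1, 4, 2])        # permutation of labels 1..4 (+pad)
    s_perm = perm[s]
    assert np.allclose(dl.coclustering_matrix(s), dl.coclustering_matrix(s_perm))


# ---------------------------------------------------------------------------
# Binder point partition
# ---------------------------------------------------------------------------

def _bruteforce_binder(C):
    """Independent exhaustive minimiser over all set partitions."""
    n = C.shape[0]
    best, best_loss, best_k = None, np.inf, None
    count = 0
    for labels in _all_partitions(n):
        count += 1
        loss = 0.0
        for i, j in itertools.combinations(range(n), 2):
            loss += abs(float(labels[i] == labels[j]) - C[i, j])
        key = (loss, len(set(labels)), labels)
        if best is None or key < (best_loss, best_k, best):
            best, best_loss, best_k = labels, loss, len(set(labels))
    return best, best_loss, count


def _all_partitions(n):
    """Recursive set-partition enumeration (independent of the package's)."""
    if n == 1:
        yield (0,)
        return
    for smaller in _all_partitions(n - 1):
        k = max(smaller) + 1
        for lab in range(k + 1):
            yield smaller + (lab,)


def test_point_partition_all_ones_matrix():
    part = dl.point_partition(np.ones((5, 5)))
    assert part.n_clusters == 1 and part.sizes == [5]


def test_point_partition_exact_blocks():
    C = np.zeros((6, 6))
    C[:3, :3] = 1.0
    C[3:, 3:] = 1.0
    part = dl.point_partition(C)
    assert part.n_clusters == 2 and part.sizes == [3, 3]
    assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1


@pytest.mark.parametrize("n,n_partitions,seed", [(6, 203, 0), (8, 4140, 1)])
def test_point_partition_matches_exhaustive_minimiser(n, n_partitions, seed):
    """Oracle equivalence against brute-force Binder minimisation."""
    rng = np.random.default_rng(seed)
    A = rng.random((n, n))
    C = (A + A.T) / 2
    np.fill_diagonal(C, 1.0)
    part = dl.point_partition(C)
    oracle, oracle_loss, count = _bruteforce_binder(C)
    assert count == n_partitions   # Bell numbers B(6), B(8)
    assert binder_loss(part.labels, C) == pytest.approx(oracle_loss, abs=1e-12)
    # identical partition, not merely identical loss
    got = tuple(part.labels)
    assert _canon(got) == _canon(oracle)


def _canon(labels):
    seen = {}
    return tuple(seen.setdefault(x, len(seen)) for x in labels)


def test_enumerate_partitions_counts():
    assert sum(1 for _ in enumerate_partitions(6)) == 203


def test_point_partition_rejects_bad_matrix():
    bad = np.array([[1.0, 0.2], [0.4, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        dl.point_partition(bad)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        dl.point_partition(np.array([[1.0, 1.4], [1.4, 1.0]]))


def test_partition_labels_ordered_by_size():
    labels = np.array([2, 2, 1, 1, 1, 3])
    part = dl.Partition(["a", "b", "c", "d", "e", "f"], np.array([1, 1, 2, 2, 2, 3]))
    assert part.sizes == [2, 3, 1]  # as given; ordering is point_partition's job
    C = np.eye(6)
    C[2:5, 2:5] = 1.0
    C[:2, :2] = 1.0
    ordered = dl.point_partition(C)
    assert ordered.sizes == sorted(ordered.sizes, reverse=True)


def test_partition_rejects_noncontiguous_labels():
    with pytest.raises(ValueError, match="contiguous"):
        dl.Partition(["a", "b"], np.array([1, 3]))


# ---------------------------------------------------------------------------
# articulation summaries (on hand-built draws)
# ---------------------------------------------------------------------------

def _doubling_draws(rng, n=10, draws=400):
    """Cluster-average articulation doubling between rounds."""
    v = np.empty((draws, n, 2))
    v[:, :, 0] = rng.lognormal(np.log(2.0), 0.1, size=(draws, n))
    v[:, :, 1] = rng.lognormal(np.log(4.0), 0.1, size=(draws, n))
    theta = rng.normal(5, 1, size=(draws, n, 4, 2))
    s = np.ones((draws, n))
    return make_draws(v, theta, s)


def test_articulation_doubling_detected():
    draws = _doubling_draws(np.random.default_rng(0))
    part = dl.Partition(draws.participant_ids, np.ones(10, int))
    art = dl.articulation_summary(draws, part)
    assert art.loc[1, "p_delta_positive"] >= 0.95
    assert art.loc[1, "v_lo_R1"] < art.loc[1, "v_mean_R1"] < art.loc[1, "v_hi_R1"]


def test_articulation_flat_interval_contains_zero():
    rng = np.random.default_rng(1)
    v = rng.lognormal(np.log(2.0), 0.15, size=(400, 10, 2))
    theta = rng.normal(5, 1, size=(400, 10, 4, 2))
    draws = make_draws(v, theta, np.ones((400, 10)))
    part = dl.Partition(draws.participant_ids, np.ones(10, int))
    art = dl.articulation_summary(draws, part)
    assert art.loc[1, "delta_lo"] <= 0 <= art.loc[1, "delta_hi"]


def test_articulation_invariant_to_participant_order():
    draws = _doubling_draws(np.random.default_rng(2))
    part = dl.Partition(draws.participant_ids, np.ones(10, int))
    art1 = dl.articulation_summary(draws, part)
    perm = np.random.default_rng(3).permutation(10)
    draws2 = make_draws(draws.v[:, perm], draws.theta[:, perm], draws.s[:, perm])
    draws2.participant_ids = [draws.participant_ids[i] for i in perm]
    part2 = dl.Partition(draws2.participant_ids, np.ones(10, int))
    art2 = dl.articulation_summary(draws2, part2)
    assert np.allclose(art1.to_numpy(), art2.to_numpy())


def test_articulation_rejects_foreign_partition():
    draws = _doubling_draws(np.random.default_rng(4))
    with pytest.raises(ValueError, match="partition"):
        dl.articulation_summary(draws, dl.Partition(["x", "y"], np.array([1, 2])))


# ---------------------------------------------------------------------------
# agreement change (on hand-built draws)
# ---------------------------------------------------------------------------

def _contraction_draws(rng, sd_r1=1.5, sd_r3=0.5, n=12, draws=400, q=4):
    """Member beliefs contract around the cluster mean between rounds."""
    theta = np.empty((draws, n, q, 2))
    offsets_r1 = rng.normal(0, sd_r1, size=(draws, n))
    offsets_r3 = rng.normal(0, sd_r3, size=(draws, n))
    theta[:, :, :, 0] = 5 + offsets_r1[:, :, None]
    theta[:, :, :, 1] = 5 + offsets_r3[:, :, None]
    v = np.ones((draws, n, 2))
    return make_draws(v, theta, np.ones((draws, n)))


def test_agreement_contraction_detected():
    draws = _contraction_draws(np.random.default_rng(0))
    part = dl.Partition(draws.participant_ids, np.ones(12, int))
    _, summary = dl.agreement_change(draws, part)
    assert summary.loc[1, "avg_delta_var_mean"] < 0
    assert summary.loc[1, "p_meaningful_negative"] >= 0.95


def test_agreement_null_probability_near_half():
    draws = _contraction_draws(np.random.default_rng(1), sd_r1=1.0, sd_r3=1.0)
    part = dl.Partition(draws.participant_ids, np.ones(12, int))
    _, summary = dl.agreement_change(draws, part, margin=0.0)
    assert 0.2 <= summary.loc[1, "p_avg_negative"] <= 0.8
    assert abs(summary.loc[1, "avg_delta_var_mean"]) < 0.3


def test_agreement_identical_members_zero_variance():
    theta = np.full((50, 5, 3, 2), 6.0)
    draws = make_draws(np.ones((50, 5, 2)), theta, np.ones((50, 5)))
    part = dl.Partition(draws.participant_ids, np.ones(5, int))
    per_item, summary = dl.agreement_change(draws, part)
    assert np.allclose(per_item["delta_var_mean"], 0.0)
    assert summary.loc[1, "avg_delta_var_mean"] == 0.0


def test_agreement_singleton_flagged_not_error():
    draws = _contraction_draws(np.random.default_rng(2), n=3)
    part = dl.Partition(draws.participant_ids, np.array([1, 1, 2]))
    _, summary = dl.agreement_change(draws, part)
    assert summary.loc[2, "available"] == False  # noqa: E712
    assert np.isnan(summary.loc[2, "avg_delta_var_mean"])


def test_per_item_entries_cover_all_items():
    draws = _contraction_draws(np.random.default_rng(3))
    part = dl.Partition(draws.participant_ids, np.ones(12, int))
    per_item, _ = dl.agreement_change(draws, part)
    assert len(per_item.loc[1]) == draws.theta.shape[2]


# ---------------------------------------------------------------------------
# full profiles
# ---------------------------------------------------------------------------

def test_cluster_change_profiles_carry_metadata(fitted_small):
    panel, draws = fitted_small
    part = dl.point_partition(
        dl.coclustering_matrix(draws), panel.participant_ids, sampled_labels=draws.s
    )
    profiles = dl.cluster_change_profiles(draws, part, panel)
    assert sum(p.n_members for p in profiles) == panel.n_participants
    assert all(set(p.articulation) == {"R1", "R3"} for p in profiles)
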