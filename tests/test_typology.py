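"""Learning-style classification, dominance, weighting, weighted judgments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import delphilearn as dl
from delphilearn import LearningStyle
from delphilearn.summaries import ClusterChangeProfile


def profile(cluster, n, p_art, p_agr):
    return ClusterChangeProfile(
        cluster=cluster,
        n_members=n,
        articulation={"R1": (1, 0.5, 1.5), "R3": (2, 1.5, 2.5)},
        delta_articulation=(1.0, 0.5, 1.5),
        p_articulation_increase=p_art,
        agreement_per_item=np.zeros(4),
        delta_agreement=(-0.1, -0.2, 0.0),
        p_agreement_increase=p_agr,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "art,agr,expected",
    [
        (True, True, LearningStyle.LEARNING_TOWARDS_CONSENSUS),
        (True, False, LearningStyle.LEARNING_BY_CONTRAST),
        (False, True, LearningStyle.GROUPTHINK),
        (False, False, LearningStyle.NO_LEARNING),
    ],
)
def test_style_mapping_covers_indicator_space(art, agr, expected):
    assert dl.style_from_indicators(art, agr) is expected


@pytest.mark.parametrize(
    "p_art,p_agr,expected",
    [
        (0.95, 0.99, LearningStyle.LEARNING_TOWARDS_CONSENSUS),
        (0.95, 0.50, LearningStyle.LEARNING_BY_CONTRAST),
        (0.79, 0.81, LearningStyle.GROUPTHINK),     # just below / above cutoff
        (0.50, 0.50, LearningStyle.NO_LEARNING),
        (0.80, 0.80, LearningStyle.LEARNING_TOWARDS_CONSENSUS),  # cutoff inclusive
    ],
)
def test_classify_cluster_thresholding(p_art, p_agr, expected):
    assert dl.classify_cluster(profile(1, 10, p_art, p_agr)) is expected


def test_classify_cluster_missing_indicator_errors():
    with pytest.raises(ValueError, match="missing change indicators"):
        dl.classify_cluster(profile(3, 1, 0.9, np.nan))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(p_art=st.floats(0, 1), p_agr=st.floats(0, 1))
def test_classification_exhaustive_and_exclusive(p_art, p_agr):
    style = dl.classify_cluster(profile(1, 5, p_art, p_agr))
    assert style in set(LearningStyle)


# ---------------------------------------------------------------------------
# dominant style
# ---------------------------------------------------------------------------

def _partition(sizes):
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    return dl.Partition([f"p{i}" for i in range(labels.size)], labels)


def test_dominant_style_worked_example():
    """Six clusters sized 50/38/32/18/18/16 with three contrast clusters:
    learning by contrast dominates with 3 clusters and 120 members."""
    part = _partition([50, 38, 32, 18, 18, 16])
    styles = {
        1: LearningStyle.LEARNING_BY_CONTRAST,
        2: LearningStyle.LEARNING_BY_CONTRAST,
        3: LearningStyle.LEARNING_BY_CONTRAST,
        4: LearningStyle.LEARNING_TOWARDS_CONSENSUS,
        5: LearningStyle.GROUPTHINK,
        6: LearningStyle.LEARNING_TOWARDS_CONSENSUS,
    }
    dom, n_clusters, n_members = dl.dominant_style(part, styles)
    assert dom is LearningStyle.LEARNING_BY_CONTRAST
    assert (n_clusters, n_members) == (3, 120)


def test_dominant_style_single_cluster():
    part = _partition([9])
    dom, n_c, n_m = dl.dominant_style(part, {1: LearningStyle.GROUPTHINK})
    assert (dom, n_c, n_m) == (LearningStyle.GROUPTHINK, 1, 9)


def test_dominant_style_tie_broken_by_cluster_count():
    part = _partition([15, 15, 30])
    styles = {
        1: LearningStyle.GROUPTHINK,
        2: LearningStyle.GROUPTHINK,
        3: LearningStyle.LEARNING_TOWARDS_CONSENSUS,
    }
    dom, n_c, n_m = dl.dominant_style(part, styles)
    assert dom is LearningStyle.GROUPTHINK and (n_c, n_m) == (2, 30)


def test_dominant_style_member_counts_conserved():
    part = _partition([10, 20, 5, 7])
    styles = {
        1: LearningStyle.NO_LEARNING,
        2: LearningStyle.LEARNING_BY_CONTRAST,
        3: LearningStyle.LEARNING_BY_CONTRAST,
        4: LearningStyle.GROUPTHINK,
    }
    from collections import Counter

    members = Counter()
    for k, st_ in styles.items():
        members[st_] += part.sizes[k - 1]
    assert sum(members.values()) == sum(part.sizes) == 42


def test_dominant_style_requires_full_coverage():
    part = _partition([5, 5])
    with pytest.raises(ValueError, match="cover"):
        dl.dominant_style(part, {1: LearningStyle.NO_LEARNING})


# ---------------------------------------------------------------------------
# participant weights
# ---------------------------------------------------------------------------

def test_uniform_weights():
    part = _partition([4, 4])
    styles = {1: LearningStyle.GROUPTHINK, 2: LearningStyle.GROUPTHINK}
    w = dl.participant_weights(part, styles, "uniform")
    assert np.allclose(w, 1 / 8) and w.sum() == pytest.approx(1.0)


def test_drop_no_learning_weights():
    part = _partition([15, 5])
    styles = {1: LearningStyle.LEARNING_BY_CONTRAST, 2: LearningStyle.NO_LEARNING}
    w = dl.participant_weights(part, styles, "drop_no_learning")
    assert np.allclose(w.iloc[:15], 1 / 15) and np.allclose(w.iloc[15:], 0.0)


def test_dominant_style_weight_ratio():
    part = _partition([10, 10])
    styles = {
        1: LearningStyle.LEARNING_BY_CONTRAST,
        2: LearningStyle.LEARNING_TOWARDS_CONSENSUS,
    }
    w = dl.participant_weights(part, styles, "dominant_style", dominant_ratio=2.0)
    assert np.allclose(w.iloc[:10], 2 / 30) and np.allclose(w.iloc[10:], 1 / 30)


def test_engagement_weights_proportional_and_zeroed():
    part = _partition([2, 1])
    styles = {1: LearningStyle.LEARNING_BY_CONTRAST, 2: LearningStyle.NO_LEARNING}
    eng = {"p0": 6.0, "p1": 3.0, "p2": 7.0}
    w = dl.participant_weights(part, styles, "engagement", engagement=eng)
    assert w["p0"] == pytest.approx(6 / 9) and w["p1"] == pytest.approx(3 / 9)
    assert w["p2"] == 0.0


def test_engagement_scheme_requires_engagement():
    part = _partition([2])
    styles = {1: LearningStyle.GROUPTHINK}
    with pytest.raises(ValueError, match="engagement"):
        dl.participant_weights(part, styles, "engagement")


def test_all_zero_weights_error():
    part = _partition([3])
    styles = {1: LearningStyle.NO_LEARNING}
    with pytest.raises(ValueError, match="no engaged participants"):
        dl.participant_weights(part, styles, "drop_no_learning")


def test_unknown_scheme_errors():
    part = _partition([2])
    with pytest.raises(ValueError, match="scheme"):
        dl.participant_weights(part, {1: LearningStyle.GROUPTHINK}, "magic")


# ---------------------------------------------------------------------------
# weighted group judgment
# ---------------------------------------------------------------------------

def _complete_panel(scores):
    scores = np.asarray(scores, float)
    P, Q = scores.shape
    full = np.stack([scores, scores], axis=2)
    return dl.RatingPanel(
        [f"p{i}" for i in range(P)], [f"G{j}" for j in range(Q)], ["C1"], full
    )


def test_uniform_weights_reproduce_plain_mean():
    panel = _complete_panel([[4, 7], [8, 3], [6, 5]])
    w = pd.Series(1 / 3, index=panel.participant_ids)
    out = dl.weighted_group_judgment(panel, w)
    assert np.allclose(out["weighted_mean"], panel.scores[:, :, 1].mean(axis=0))


def test_single_participant_weight():
    panel = _complete_panel([[4, 7], [8, 3]])
    w = pd.Series([1.0, 0.0], index=panel.participant_ids)
    out = dl.weighted_group_judgment(panel, w)
    assert np.allclose(out["weighted_mean"], [4, 7])
    assert np.allclose(out["weighted_sd"], 0.0)


def test_weighted_mean_arithmetic():
    panel = _complete_panel([[4], [8]])
    w = pd.Series([0.25, 0.75], index=panel.participant_ids)
    out = dl.weighted_group_judgment(panel, w)
    assert out["weighted_mean"].iloc[0] == pytest.approx(7.0)


def test_weighted_judgment_rejects_missing_cells():
    scores = np.array([[[4.0, np.nan]], [[5.0, 6.0]]])
    panel = dl.RatingPanel(["a", "b"], ["G1"], ["C1"], scores)
    w = pd.Series([0.5, 0.5], index=["a", "b"])
    with pytest.raises(ValueError, match="imput"):
        dl.weighted_group_judgment(panel, w)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    bump=st.integers(1, 5),
    who=st.integers(0, 2),
)
def test_weighted_mean_monotone_in_scores(bump, who):
    base = np.array([[3, 5], [4, 4], [5, 2]], dtype=float)
    raised = base.copy()
    raised[who, 0] = min(10, raised[who, 0] + bump)
    w = pd.Series([0.2, 0.5, 0.3], index=["p0", "p1", "p2"])
    m0 = dl.weighted_group_judgment(_complete_panel(base), w)["weighted_mean"].iloc[0]
    m1 = dl.weighted_group_judgment(_complete_panel(raised), w)["weighted_mean"].iloc[0]
    assert m1 >= m0
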