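"""Learning-style typology, dominant style, and learning-weighted judgments.

Crossing the two learning indicators — did the cluster's individual
articulation increase between rounds, and did its group agreement increase
(member belief variance fall)? — yields four collaborative-learning styles:

====================  =====================  ======================
                      articulation increased  articulation not
====================  =====================  ======================
agreement increased   learning towards        groupthink
                      consensus
agreement not         learning by contrast    no learning
====================  =====================  ======================

"Increased" is operationalised as a posterior probability exceeding a
configurable cutoff (default 0.8).  The dominant style is the one covering
the most participants (ties: most clusters, then a fixed style order), and
participant weights for the final group judgment can up-weight dominant-style
clusters, drop or down-weight no-learning participants, or scale with online
engagement (mean satisfaction).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .panel_data import RatingPanel
from .summaries import ClusterChangeProfile, Partition

__all__ = [
    "LearningStyle",
    "TypologyResult",
    "style_from_indicators",
    "classify_cluster",
    "dominant_style",
    "participant_weights",
    "weighted_group_judgment",
]

DEFAULT_THRESHOLD = 0.8


class LearningStyle(str, Enum):
    LEARNING_TOWARDS_CONSENSUS = "learning_towards_consensus"
    LEARNING_BY_CONTRAST = "learning_by_contrast"
    GROUPTHINK = "groupthink"
    NO_LEARNING = "no_learning"


#: fixed order used for tie-breaking the dominant style
STYLE_ORDER = (
    LearningStyle.LEARNING_BY_CONTRAST,
    LearningStyle.LEARNING_TOWARDS_CONSENSUS,
    LearningStyle.GROUPTHINK,
    LearningStyle.NO_LEARNING,
)


def style_from_indicators(articulation_increased: bool, agreement_increased: bool) -> LearningStyle:
    """Map the 2×2 qualitative indicator space to a learning style."""
    if articulation_increased and agreement_increased:
        return LearningStyle.LEARNING_TOWARDS_CONSENSUS
    if articulation_increased:
        return LearningStyle.LEARNING_BY_CONTRAST
    if agreement_increased:
        return LearningStyle.GROUPTHINK
    return LearningStyle.NO_LEARNING


def classify_cluster(
    profile: ClusterChangeProfile,
    threshold: float = DEFAULT_THRESHOLD,
) -> LearningStyle:
    """Classify one cluster from its posterior change profile.

    Articulation counts as increased iff P(Δv̄ > 0) ≥ ``threshold``;
    agreement counts as increased iff P(across-item average ΔVar < 0) ≥
    ``threshold``.  A singleton cluster (agreement indicator not available)
    is an error: the caller must decide how to handle it.
    """
    p_art = profile.p_articulation_increase
    p_agr = profile.p_agreement_increase
    if p_art is None or np.isnan(p_art) or p_agr is None or np.isnan(p_agr):
        raise ValueError(
            f"cluster {profile.cluster}: missing change indicators "
            "(singleton clusters have no agreement measure)"
        )
    return style_from_indicators(p_art >= threshold, p_agr >= threshold)


@dataclass
class TypologyResult:
    """Per-cluster styles, the dominant style, and participant weights."""

    styles: dict[int, LearningStyle]
    dominant: LearningStyle
    dominant_n_clusters: int
    dominant_n_members: int
    weights: pd.Series | None = None
    scheme: str | None = None

    def to_frame(self, partition: Partition) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": list(self.styles),
                "n_members": [partition.sizes[k - 1] for k in self.styles],
                "style": [s.value for s in self.styles.values()],
                "is_dominant_style": [
                    s == self.dominant for s in self.styles.values()
                ],
            }
        ).set_index("cluster")


def dominant_style(
    partition: Partition, styles: dict[int, LearningStyle]
) -> tuple[LearningStyle, int, int]:
    """Dominant style: most member participants; ties by cluster count, then
    by the fixed style order (contrast, consensus, groupthink, no-learning).

    Returns ``(style, n_clusters, n_members)``.
    """
    if set(styles) != set(range(1, partition.n_clusters + 1)):
        raise ValueError("styles must cover every cluster of the partition")
    sizes = partition.sizes
    members: dict[LearningStyle, int] = {}
    clusters: dict[LearningStyle, int] = {}
    for k, st in styles.items():
        members[st] = members.get(st, 0) + sizes[k - 1]
        clusters[st] = clusters.get(st, 0) + 1
    best = min(
        members,
        key=lambda st: (-members[st], -clusters[st], STYLE_ORDER.index(st)),
    )
    return best, clusters[best], members[best]


def participant_weights(
    partition: Partition,
    styles: dict[int, LearningStyle],
    scheme: str = "uniform",
    engagement: dict[str, float] | pd.Series | None = None,
    dominant_ratio: float = 2.0,
) -> pd.Series:
    """Per-participant weights for the final group judgment.

    Schemes:

    - ``uniform``: 1/n each;
    - ``drop_no_learning``: zero for members of no-learning clusters,
      uniform otherwise;
    - ``dominant_style``: members of dominant-style clusters weighted
      ``dominant_ratio`` : 1 against other learners; no-learning members 0;
    - ``engagement``: weight proportional to mean satisfaction; no-learning
      members 0 (requires ``engagement``).

    Weights are renormalised to sum to one; an all-zero weight vector ("no
    engaged participants") is an error.
    """
    ids = partition.participant_ids
    n = len(ids)
    style_of = np.array([styles[k].value for k in partition.labels], dtype=object)
    no_learning = style_of == LearningStyle.NO_LEARNING.value

    if scheme == "uniform":
        w = np.ones(n)
    elif scheme == "drop_no_learning":
        w = np.where(no_learning, 0.0, 1.0)
    elif scheme == "dominant_style":
        dom, _, _ = dominant_style(partition, styles)
        w = np.where(style_of == dom.value, float(dominant_ratio), 1.0)
        w[no_learning] = 0.0
    elif scheme == "engagement":
        if engagement is None:
            raise ValueError("engagement scheme requires per-participant satisfaction")
        eng = pd.Series(engagement, dtype=float)
        w = eng.reindex(ids).to_numpy()
        if np.any(np.isnan(w)) or np.any(w < 0):
            raise ValueError("engagement values must be non-negative and cover all participants")
        w = np.where(no_learning, 0.0, w)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")

    total = w.sum()
    if total <= 0:
        raise ValueError("no engaged participants: all weights are zero")
    return pd.Series(w / total, index=pd.Index(ids, name="participant"), name="weight")


def weighted_group_judgment(
    completed: RatingPanel,
    weights: pd.Series,
    round_label: str | None = None,
) -> pd.DataFrame:
    """Per-item weighted mean and weighted SD of final-round scores.

    ``completed`` must have no missing cells in the aggregated round (run
    posterior-predictive imputation first).  Uniform weights reproduce the
    plain mean exactly; the weighted SD is ``sqrt(Σ w (x − x̄_w)²)`` with
    weights summing to one.
    """
    r = completed.rounds.index(round_label) if round_label else 1
    x = completed.scores[:, :, r]
    if np.isnan(x).any():
        raise ValueError(
            "completed panel still has missing cells in the aggregated round; "
            "impute them first (impute_missing)"
        )
    w = weights.reindex(completed.participant_ids).to_numpy()
    if np.any(np.isnan(w)):
        raise ValueError("weights must cover every participant in the panel")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    mean = w @ x
    sd = np.sqrt(np.maximum(w @ (x - mean) ** 2, 0.0))
    return pd.DataFrame(
        {"weighted_mean": mean, "weighted_sd": sd},
        index=completed.item_index(),
    )
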