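"""Synthetic two-round rating panels with known cluster structure.

Generates panels by running the latent-belief model forward: cluster-level
item means ``m*`` plus participant position offsets with precision ``τ*``
(whose between-round rise is a planted agreement gain) give latent beliefs;
articulation precisions ``v*`` (rise = planted articulation gain) add
per-question readout noise; the resulting latent responses are discretised
through the fixed cutpoints into 1–10 scores.  Missingness is
assigned participant-level first (which round(s) are affected, with the
study-like default pattern 10% round-1-only / 15% round-3-only / 3% both) and
then item-level within affected participants.

:func:`paper_like_scenario` is a preset emulating the structure of a large
online stakeholder panel on suicide-prevention research priorities: six
clusters of sizes 50/38/32/18/18/16 (172 participants), 12 goals × 4
criteria, four stakeholder groups, and planted learning styles — three
learning-by-contrast clusters, two learning-towards-consensus, one
groupthink.  Effect sizes are the generator's own choice, set for clear
separability between clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import default_cutpoints, N_CATEGORIES
from .panel_data import RatingPanel
from .typology import LearningStyle

__all__ = ["GeneratorConfig", "GroundTruth", "generate_panel", "paper_like_scenario"]

SATISFACTION_QUESTIONS = (
    "divergent_views",
    "debated_viewpoints",
    "interesting",
    "easy_to_use",
)

STAKEHOLDER_GROUPS = ("survivor", "researcher", "provider", "policymaker")


@dataclass
class GeneratorConfig:
    """Forward-simulation configuration.

    ``v_star`` and ``tau_star`` are (n_clusters, 2) arrays of per-round
    articulation and belief precisions.  Cluster belief means are built by a
    rule — common item base means (uniform in ``base_mean_range``) plus a
    per-cluster offset plus per-item cluster jitter, with round-3 means
    drifting slightly from round 1 — unless ``item_means`` (n_clusters, Q, 2)
    is given explicitly.  Missingness probabilities are per participant
    (affected exclusively in round 1 / exclusively round 3 / both), with
    ``item_missing_prob`` applied item-wise inside affected rounds.
    """

    cluster_sizes: list[int]
    v_star: np.ndarray
    tau_star: np.ndarray
    styles: list[LearningStyle] | None = None
    item_means: np.ndarray | None = None
    n_goals: int = 12
    n_criteria: int = 4
    base_mean_range: tuple[float, float] = (4.0, 7.0)
    cluster_offsets: np.ndarray | None = None
    item_jitter_sd: float = 0.8
    r3_drift_sd: float = 0.05
    group_labels: tuple[str, ...] = STAKEHOLDER_GROUPS
    group_mixture: np.ndarray | None = None
    missing_r1: float = 0.10
    missing_r3: float = 0.15
    missing_both: float = 0.03
    item_missing_prob: float = 0.3
    satisfaction_means: np.ndarray | None = None
    satisfaction_sd: float = 1.0
    satisfaction_questions: tuple[str, ...] = SATISFACTION_QUESTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        self.v_star = np.asarray(self.v_star, dtype=float)
        self.tau_star = np.asarray(self.tau_star, dtype=float)
        self.validate()

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_items(self) -> int:
        return self.n_goals * self.n_criteria

    def validate(self) -> None:
        k = self.n_clusters
        if k == 0 or any(int(s) < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be a non-empty list of sizes >= 1")
        if self.v_star.shape != (k, 2):
            raise ValueError(f"v_star must have shape ({k}, 2)")
        if self.tau_star.shape != (k, 2):
            raise ValueError(f"tau_star must have shape ({k}, 2)")
        if np.any(self.v_star <= 0) or np.any(self.tau_star <= 0):
            raise ValueError("v_star and tau_star precisions must be > 0")
        probs = (self.missing_r1, self.missing_r3, self.missing_both)
        if any(p < 0 or p > 1 for p in probs) or sum(probs) > 1:
            raise ValueError(
                "missing_r1/missing_r3/missing_both must lie in [0,1] and sum to <= 1"
            )
        if not (0 <= self.item_missing_prob <= 1):
            raise ValueError("item_missing_prob must lie in [0,1]")
        if self.n_goals < 1 or self.n_criteria < 1:
            raise ValueError("n_goals and n_criteria must be >= 1")
        if self.styles is not None and len(self.styles) != k:
            raise ValueError("styles must give one learning style per cluster")
        if self.item_means is not None:
            im = np.asarray(self.item_means, dtype=float)
            if im.shape != (k, self.n_items, 2):
                raise ValueError(f"item_means must have shape ({k}, {self.n_items}, 2)")
        if self.group_mixture is not None:
            gm = np.asarray(self.group_mixture, dtype=float)
            if gm.shape != (k, len(self.group_labels)) or np.any(gm < 0):
                raise ValueError("group_mixture must be (n_clusters, n_groups) non-negative")
        if self.satisfaction_means is not None:
            sm = np.asarray(self.satisfaction_means, dtype=float)
            if sm.shape != (k, len(self.satisfaction_questions)):
                raise ValueError(
                    "satisfaction_means must be (n_clusters, n_questions)"
                )


@dataclass
class GroundTruth:
    """Generating quantities of a synthetic panel."""

    labels: np.ndarray            # (P,) 1-based cluster assignment
    theta_star: np.ndarray        # (P, Q, 2) latent beliefs
    v_star: np.ndarray            # (K, 2) articulation precisions
    tau_star: np.ndarray          # (K, 2) belief precisions
    item_means: np.ndarray        # (K, Q, 2)
    styles: list[LearningStyle] | None
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "participant_index": np.arange(len(self.labels)),
                "cluster": self.labels,
                "style": [
                    self.styles[k - 1].value if self.styles else ""
                    for k in self.labels
                ],
            }
        )


def _build_item_means(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.item_means is not None:
        return np.asarray(cfg.item_means, dtype=float)
    K, Q = cfg.n_clusters, cfg.n_items
    base = rng.uniform(*cfg.base_mean_range, size=Q)
    if cfg.cluster_offsets is not None:
        offsets = np.asarray(cfg.cluster_offsets, dtype=float)
    elif K == 1:
        offsets = np.zeros(1)
    else:
        offsets = np.linspace(-1.5, 1.5, K)
    jitter = rng.normal(0.0, cfg.item_jitter_sd, size=(K, Q))
    m = np.empty((K, Q, 2))
    m[:, :, 0] = base[None, :] + offsets[:, None] + jitter
    m[:, :, 1] = m[:, :, 0] + rng.normal(0.0, cfg.r3_drift_sd, size=(K, Q))
    return m


def generate_panel(config: GeneratorConfig) -> tuple[RatingPanel, GroundTruth]:
    """Draw one panel from the generative model (identical seed → identical output)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, Q = config.n_clusters, config.n_items
    sizes = [int(s) for s in config.cluster_sizes]
    P = sum(sizes)
    labels = np.repeat(np.arange(1, K + 1), sizes)

    m_star = _build_item_means(config, rng)
    gamma = default_cutpoints()

    v_p = config.v_star[labels - 1][:, None, :]       # (P, 1, 2)
    # participant position offsets: truncated normal draws standardised
    # within each cluster-round so the realised member-belief variance
    # equals the planted 1/tau* exactly (the agreement level is a planted
    # condition, not a sampled one; truncation avoids lone extreme members)
    delta = np.empty((P, 2))
    for k in range(1, K + 1):
        mem = np.flatnonzero(labels == k)
        raw = np.clip(rng.standard_normal((len(mem), 2)), -2.5, 2.5)
        if len(mem) > 1:
            raw = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
        else:
            raw[:] = 0.0
        delta[mem] = raw / np.sqrt(config.tau_star[k - 1])
    theta = m_star[labels - 1] + delta[:, None, :]
    z = theta + rng.standard_normal((P, Q, 2)) / np.sqrt(v_p)
    y = np.clip(np.digitize(z, gamma) + 1, 1, N_CATEGORIES).astype(float)

    # participant-level missingness category, then item-level inside it
    cat_probs = [
        config.missing_r1,
        config.missing_r3,
        config.missing_both,
    ]
    cat_probs.append(1.0 - sum(cat_probs))
    cats = rng.choice(4, size=P, p=cat_probs)  # 0: R1 only, 1: R3 only, 2: both, 3: none
    item_mask = rng.random((P, Q, 2)) < config.item_missing_prob
    affected = np.zeros((P, Q, 2), dtype=bool)
    affected[cats == 0, :, 0] = True
    affected[cats == 1, :, 1] = True
    affected[cats == 2, :, :] = True
    y[affected & item_mask] = np.nan

    ids = [f"P{i:03d}" for i in range(P)]
    groups: dict[str, str | None] = {}
    if config.group_mixture is not None:
        gm = np.asarray(config.group_mixture, dtype=float)
        gm = gm / gm.sum(axis=1, keepdims=True)
        for i, pid in enumerate(ids):
            gi = rng.choice(len(config.group_labels), p=gm[labels[i] - 1])
            groups[pid] = config.group_labels[gi]
    else:
        groups = {pid: None for pid in ids}

    satisfaction: dict[str, dict[str, int]] = {}
    if config.satisfaction_means is not None:
        sm = np.asarray(config.satisfaction_means, dtype=float)
        raw = sm[labels - 1] + rng.normal(
            0.0, config.satisfaction_sd, size=(P, sm.shape[1])
        )
        vals = np.clip(np.round(raw), 1, 7).astype(int)
        satisfaction = {
            pid: dict(zip(config.satisfaction_questions, row))
            for pid, row in zip(ids, vals)
        }

    panel = RatingPanel(
        participant_ids=ids,
        goals=[f"G{g + 1:02d}" for g in range(config.n_goals)],
        criteria=[f"C{c + 1}" for c in range(config.n_criteria)],
        scores=y,
        groups=groups,
        satisfaction=satisfaction,
    )
    truth = GroundTruth(
        labels=labels,
        theta_star=theta,
        v_star=config.v_star.copy(),
        tau_star=config.tau_star.copy(),
        item_means=m_star,
        styles=list(config.styles) if config.styles else None,
        seed=config.seed,
    )
    return panel, truth


def paper_like_scenario(seed: int = 0) -> GeneratorConfig:
    """Preset emulating the study-like panel structure.

    Six clusters, sizes 50/38/32/18/18/16; planted styles: three
    learning-by-contrast (articulation rises, agreement flat), two
    learning-towards-consensus (both rise), one groupthink (agreement rises
    only).  Articulation/belief precisions per round realise each style;
    stakeholder-group mixtures make cluster 1 the most diverse and cluster 2
    researcher-dominated; satisfaction means follow an engagement gradient
    with cluster 1 most and cluster 6 least engaged.
    """
    C = LearningStyle.LEARNING_BY_CONTRAST
    S = LearningStyle.LEARNING_TOWARDS_CONSENSUS
    G = LearningStyle.GROUPTHINK
    return GeneratorConfig(
        cluster_sizes=[50, 38, 32, 18, 18, 16],
        styles=[C, C, C, S, G, S],
        #               R1    R3
        v_star=np.array(
            [
                [1.0, 5.0],   # cluster 1: largest articulation gain
                [1.0, 4.0],
                [1.2, 4.0],
                [1.0, 4.0],
                [1.0, 1.0],   # groupthink: articulation flat
                [1.4, 2.8],   # cluster 6: smallest articulation gain
            ]
        ),
        tau_star=np.array(
            [
                [0.8, 0.8],   # contrast clusters: agreement flat
                [0.8, 0.8],
                [0.8, 0.8],
                [0.8, 2.5],   # consensus: belief variance contracts
                [0.8, 2.5],   # groupthink: same contraction
                [0.6, 3.0],   # cluster 6: largest agreement gain
            ]
        ),
        group_mixture=np.array(
            [
                [0.22, 0.26, 0.26, 0.26],  # most diverse
                [0.10, 0.64, 0.16, 0.10],  # researcher-dominated
                [0.40, 0.20, 0.22, 0.18],
                [0.40, 0.20, 0.22, 0.18],
                [0.40, 0.20, 0.22, 0.18],
                [0.40, 0.20, 0.22, 0.18],
            ]
        ),
        satisfaction_means=np.array(
            [
                [5.2, 4.4, 5.8, 4.7],
                [4.6, 3.4, 5.3, 4.8],
                [4.6, 4.2, 5.3, 4.8],
                [4.7, 3.9, 5.3, 4.7],
                [4.5, 3.9, 5.5, 4.6],
                [4.3, 3.7, 4.9, 3.8],
            ]
        ),
        seed=int(seed),
    )
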