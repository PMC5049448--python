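"""Data model and I/O for two-round ordinal rating panels.

A modified-Delphi engagement panel asks every participant to rate each of
``n_goals × n_criteria`` questions on a 1–10 ordinal scale in a first rating
round, discuss the group feedback, and re-rate the same questions in a final
round.  This module holds the observed panel — scores, explicit missingness,
participant metadata (stakeholder group, satisfaction survey) — and the
descriptive between-round change statistics computed directly on raw scores.

The canonical in-memory container is :class:`RatingPanel`; on disk a panel is
a long-format ("tidy") delimited table with one row per
(participant, goal, criterion, round) cell, empty score cells marking explicit
missings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RatingPanel",
    "MissingnessSummary",
    "DEFAULT_SCHEMA",
    "read_panel",
    "write_panel",
    "read_satisfaction",
    "write_satisfaction",
    "changed_answer_counts",
    "group_stats",
    "missingness_summary",
]

SCORE_MIN = 1
SCORE_MAX = 10

#: logical field -> default column name in delimited panel files
DEFAULT_SCHEMA: dict[str, str] = {
    "participant": "participant",
    "goal": "goal",
    "criterion": "criterion",
    "round": "round",
    "score": "score",
    "group": "group",
}


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel data."""


@dataclass
class RatingPanel:
    """Observed two-round ordinal rating panel.

    Parameters
    ----------
    participant_ids
        Unique participant identifiers, in display order.
    goals, criteria
        Goal and criterion identifiers; the item set is their full cross
        product, ordered goal-major (item ``q`` = goal ``q // n_criteria``,
        criterion ``q % n_criteria``).
    rounds
        The two rating-round labels, in chronological order.  Default
        ``("R1", "R3")`` — the middle round of a modified Delphi is a
        discussion round with no ratings.
    scores
        Float array of shape ``(n_participants, n_items, 2)`` holding integer
        scores in 1..10, with ``NaN`` for explicit missings.
    groups
        Optional stakeholder-group label per participant (``None`` entries
        allowed).
    satisfaction
        Optional per-participant satisfaction responses: mapping
        participant id -> {question label: integer 1..7}.
    """

    participant_ids: list[str]
    goals: list[str]
    criteria: list[str]
    scores: np.ndarray
    rounds: tuple[str, str] = ("R1", "R3")
    groups: dict[str, str | None] = field(default_factory=dict)
    satisfaction: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.participant_ids = [str(p) for p in self.participant_ids]
        self.goals = [str(g) for g in self.goals]
        self.criteria = [str(c) for c in self.criteria]
        self.rounds = (str(self.rounds[0]), str(self.rounds[1]))
        if len(self.rounds) != 2 or self.rounds[0] == self.rounds[1]:
            raise PanelError("exactly two distinct rounds are required")
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise PanelError("participant ids must be unique")
        if not self.participant_ids:
            raise PanelError("panel has no participants")
        if not self.goals or not self.criteria:
            raise PanelError("panel needs at least one goal and one criterion")
        self.scores = np.asarray(self.scores, dtype=float)
        expect = (self.n_participants, self.n_items, 2)
        if self.scores.shape != expect:
            raise PanelError(
                f"scores shape {self.scores.shape} != expected {expect}"
            )
        obs = self.scores[~np.isnan(self.scores)]
        if obs.size and (
            np.any(obs != np.round(obs))
            or np.any(obs < SCORE_MIN)
            or np.any(obs > SCORE_MAX)
        ):
            raise PanelError("observed scores must be integers in 1..10")
        for q, vals in self.satisfaction.items():
            for label, v in vals.items():
                if not (1 <= int(v) <= 7):
                    raise PanelError(
                        f"satisfaction response {label}={v} for {q} outside 1..7"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_items(self) -> int:
        return len(self.goals) * len(self.criteria)

    @property
    def items(self) -> list[tuple[str, str]]:
        return [(g, c) for g in self.goals for c in self.criteria]

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.scores).sum())

    def item_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_tuples(self.items, names=["goal", "criterion"])

    def copy(self) -> "RatingPanel":
        return RatingPanel(
            participant_ids=list(self.participant_ids),
            goals=list(self.goals),
            criteria=list(self.criteria),
            scores=self.scores.copy(),
            rounds=self.rounds,
            groups=dict(self.groups),
            satisfaction={p: dict(v) for p, v in self.satisfaction.items()},
        )

    def equals(self, other: "RatingPanel") -> bool:
        return (
            self.participant_ids == other.participant_ids
            and self.goals == other.goals
            and self.criteria == other.criteria
            and self.rounds == other.rounds
            and np.array_equal(self.scores, other.scores, equal_nan=True)
            and self.groups == other.groups
            and self.satisfaction == other.satisfaction
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (participant, goal, criterion, round)."""
        P, Q = self.n_participants, self.n_items
        items = self.items
        rows = {
            "participant": np.repeat(self.participant_ids, Q * 2),
            "goal": np.tile(np.repeat([g for g, _ in items], 2), P),
            "criterion": np.tile(np.repeat([c for _, c in items], 2), P),
            "round": np.tile(list(self.rounds), P * Q),
            "score": self.scores.reshape(-1),
        }
        df = pd.DataFrame(rows)
        if any(v is not None for v in self.groups.values()):
            df["group"] = df["participant"].map(self.groups)
        return df


@dataclass(frozen=True)
class MissingnessSummary:
    """Participant-level missingness pattern of a two-round panel.

    ``n_r1_only`` / ``n_r3_only`` / ``n_both`` count participants with at
    least one missing answer exclusively in round 1, exclusively in round 3,
    or in both rounds; the categories are disjoint and exclude fully complete
    participants.  ``missing_fraction`` is the per-cell missing fraction per
    round label.
    """

    n_r1_only: int
    n_r3_only: int
    n_both: int
    n_complete: int
    missing_fraction: dict[str, float]

    @property
    def n_participants(self) -> int:
        return self.n_r1_only + self.n_r3_only + self.n_both + self.n_complete


def missingness_summary(panel: RatingPanel) -> MissingnessSummary:
    miss = np.isnan(panel.scores)  # (P, Q, 2)
    any_r1 = miss[:, :, 0].any(axis=1)
    any_r3 = miss[:, :, 1].any(axis=1)
    n_both = int((any_r1 & any_r3).sum())
    n_r1_only = int((any_r1 & ~any_r3).sum())
    n_r3_only = int((~any_r1 & any_r3).sum())
    n_complete = panel.n_participants - n_both - n_r1_only - n_r3_only
    frac = {
        panel.rounds[r]: float(miss[:, :, r].mean()) for r in range(2)
    }
    return MissingnessSummary(n_r1_only, n_r3_only, n_both, n_complete, frac)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _resolve_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_panel(
    path,
    schema: dict[str, str] | None = None,
    rounds: tuple[str, str] = ("R1", "R3"),
    sep: str | None = None,
    satisfaction_path=None,
) -> RatingPanel:
    """Read a long-format delimited panel file into a :class:`RatingPanel`.

    Every (participant, goal, criterion, round) key must occur at most once;
    cells absent from the file, and rows with an empty score cell, become
    explicit missings.  Scores outside 1..10 and round labels outside
    ``rounds`` are hard errors (with the offending row number / key named).
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep=_resolve_sep(path, sep), dtype=str)
    required = ["participant", "goal", "criterion", "round", "score"]
    for logical in required:
        if colmap[logical] not in df.columns:
            raise PanelError(f"missing column {colmap[logical]!r} in {path}")

    part_c, goal_c, crit_c = colmap["participant"], colmap["goal"], colmap["criterion"]
    round_c, score_c = colmap["round"], colmap["score"]

    bad_round = ~df[round_c].isin(list(rounds))
    if bad_round.any():
        label = df.loc[bad_round, round_c].iloc[0]
        raise PanelError(
            f"unknown round label {label!r} (expected one of {rounds})"
        )

    score = pd.to_numeric(df[score_c], errors="raise")
    observed = score.notna()
    bad = observed & ((score < SCORE_MIN) | (score > SCORE_MAX) | (score != score.round()))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PanelError(
            f"score {score.iloc[row]} outside 1..10 at data row {row + 2} "
            f"(participant={df[part_c].iloc[row]!r})"
        )

    keys = df[[part_c, goal_c, crit_c, round_c]]
    dup = keys.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        k = tuple(keys.iloc[row])
        raise PanelError(f"duplicate (participant, goal, criterion, round) key {k}")

    participants = list(pd.unique(df[part_c]))
    goals = list(pd.unique(df[goal_c]))
    criteria = list(pd.unique(df[crit_c]))
    p_idx = {p: i for i, p in enumerate(participants)}
    g_idx = {g: i for i, g in enumerate(goals)}
    c_idx = {c: i for i, c in enumerate(criteria)}
    r_idx = {r: i for i, r in enumerate(rounds)}

    scores = np.full((len(participants), len(goals) * len(criteria), 2), np.nan)
    qi = (
        df[goal_c].map(g_idx).to_numpy() * len(criteria)
        + df[crit_c].map(c_idx).to_numpy()
    )
    pi = df[part_c].map(p_idx).to_numpy()
    ri = df[round_c].map(r_idx).to_numpy()
    scores[pi, qi, ri] = score.to_numpy()

    groups: dict[str, str | None] = {p: None for p in participants}
    if colmap["group"] in df.columns:
        for p, g in zip(df[part_c], df[colmap["group"]]):
            if isinstance(g, str) and g:
                groups[p] = g

    satisfaction: dict[str, dict[str, int]] = {}
    if satisfaction_path is not None:
        satisfaction = read_satisfaction(
            satisfaction_path, participant_col=part_c, sep=sep
        )

    return RatingPanel(
        participant_ids=participants,
        goals=goals,
        criteria=criteria,
        scores=scores,
        rounds=rounds,
        groups=groups,
        satisfaction=satisfaction,
    )


def write_panel(panel: RatingPanel, path, sep: str = ",", satisfaction_path=None) -> None:
    """Write a panel as a long-format delimited file (empty cells = missing).

    ``read_panel(write_panel(p))`` reproduces ``p`` exactly.  Satisfaction
    responses, if present and ``satisfaction_path`` is given, go to a second
    table keyed by participant.
    """
    df = panel.to_frame()
    df["score"] = df["score"].map(lambda v: "" if math.isnan(v) else str(int(v)))
    df.to_csv(path, sep=sep, index=False)
    if satisfaction_path is not None and panel.satisfaction:
        write_satisfaction(panel.satisfaction, satisfaction_path, sep=sep)


def read_satisfaction(path, participant_col: str = "participant", sep: str | None = None) -> dict[str, dict[str, int]]:
    """Read a wide satisfaction table (participant + one column per question)."""
    df = pd.read_csv(path, sep=_resolve_sep(path, sep))
    out: dict[str, dict[str, int]] = {}
    qcols = [c for c in df.columns if c != participant_col]
    for _, row in df.iterrows():
        vals = {q: int(row[q]) for q in qcols if pd.notna(row[q])}
        out[str(row[participant_col])] = vals
    return out


def write_satisfaction(satisfaction: dict[str, dict[str, int]], path, sep: str = ",") -> None:
    questions = sorted({q for v in satisfaction.values() for q in v})
    rows = [
        {"participant": p, **{q: v.get(q, "") for q in questions}}
        for p, v in satisfaction.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Descriptive change statistics
# ---------------------------------------------------------------------------

def changed_answer_counts(panel: RatingPanel) -> pd.DataFrame:
    """Per-participant between-round answer changes.

    Returns a frame indexed by participant with

    - ``n_changed``: number of items observed in both rounds whose scores
      differ;
    - ``n_compared``: number of items observed in both rounds (items missing
      in either round are excluded pairwise);
    - ``mean_abs_change``: mean |R3 − R1| over the compared items (``NaN``
      when nothing is comparable).
    """
    s = panel.scores
    both = ~np.isnan(s).any(axis=2)  # (P, Q)
    diff = np.abs(s[:, :, 1] - s[:, :, 0])
    n_compared = both.sum(axis=1)
    n_changed = np.where(both, diff > 0, False).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_abs = np.where(
            n_compared > 0,
            np.where(both, diff, 0.0).sum(axis=1) / np.maximum(n_compared, 1),
            np.nan,
        )
    return pd.DataFrame(
        {
            "n_changed": n_changed.astype(int),
            "n_compared": n_compared.astype(int),
            "mean_abs_change": mean_abs,
        },
        index=pd.Index(panel.participant_ids, name="participant"),
    )


def group_stats(panel: RatingPanel) -> pd.DataFrame:
    """Per-item per-round sample mean and SD of observed scores, with deltas.

    Cells with fewer than two observed scores are flagged not-available
    (``NaN``).  ``delta_sd < 0`` indicates movement toward group agreement
    between rounds.
    """
    s = panel.scores
    out = {}
    for r, label in enumerate(panel.rounds):
        x = s[:, :, r]
        n = (~np.isnan(x)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            sd = np.full(x.shape[1], np.nan)
            ok = n >= 2
            if ok.any():
                sd[ok] = np.nanstd(x[:, ok], axis=0, ddof=1)
        mean[n < 2] = np.nan
        out[f"mean_{label}"] = mean
        out[f"sd_{label}"] = sd
        out[f"n_{label}"] = n
    r1, r3 = panel.rounds
    df = pd.DataFrame(out, index=panel.item_index())
    df["delta_mean"] = df[f"mean_{r3}"] - df[f"mean_{r1}"]
    df["delta_sd"] = df[f"sd_{r3}"] - df[f"sd_{r1}"]
    return df
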