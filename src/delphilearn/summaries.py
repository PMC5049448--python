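"""Label-invariant posterior summaries: point partition, articulation, agreement.

The Dirichlet-process mixture posterior is summarised without reference to
raw cluster labels (which switch freely along the chain):

- :func:`coclustering_matrix` — posterior probability that two participants
  share a cluster;
- :func:`point_partition` — a single partition of the participants minimising
  Binder loss against the co-clustering probabilities (exhaustive for small
  panels, candidate-set search otherwise);
- :func:`articulation_summary` — per-cluster, per-round posterior mean and
  95% interval of member-averaged articulation ``v``, with the between-round
  change Δ and its posterior probability of being positive;
- :func:`agreement_change` — per-cluster, per-item posterior mean of the
  round-3 minus round-1 variance of member beliefs (negative values = shift
  toward agreement), with the across-item average and P(average < 0);
- :func:`cluster_change_profiles` — everything a cluster needs for typology
  classification, plus engagement (satisfaction means) and stakeholder-group
  composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .model import PosteriorDraws
from .panel_data import RatingPanel

__all__ = [
    "Partition",
    "ClusterChangeProfile",
    "coclustering_matrix",
    "point_partition",
    "binder_loss",
    "articulation_summary",
    "agreement_change",
    "cluster_change_profiles",
    "enumerate_partitions",
]

EXHAUSTIVE_LIMIT = 10  # Bell(10) = 115975 candidate partitions


@dataclass
class Partition:
    """Point-estimate cluster assignment of participants.

    Cluster indices are contiguous from 1, ordered by decreasing size (ties
    broken by the lowest member participant index).  ``labels`` is aligned
    with ``participant_ids``.
    """

    participant_ids: list[str]
    labels: np.ndarray  # 1-based, contiguous
    source: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.participant_ids):
            raise ValueError("labels must cover all participants")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("cluster indices must be contiguous from 1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    @property
    def sizes(self) -> list[int]:
        return [int((self.labels == k).sum()) for k in range(1, self.n_clusters + 1)]

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"participant": self.participant_ids, "cluster": self.labels}
        )


@dataclass
class ClusterChangeProfile:
    """Per-cluster posterior change profile feeding the learning typology.

    ``articulation``: round label -> (mean, lo95, hi95) of member-averaged v;
    ``delta_articulation``: (mean, lo95, hi95) of the R3−R1 change;
    ``p_articulation_increase``: posterior P(Δ > 0).
    ``agreement_per_item``: per-item posterior mean of the change in member
    belief variance (R3 − R1; negative = toward agreement);
    ``delta_agreement``: (mean, lo95, hi95) of the across-item average;
    ``p_agreement_increase``: posterior probability that the across-item
    average variance drop is meaningful (beyond the little-to-no-change
    margin); ``NaN`` for singleton clusters (variance undefined — flagged,
    not an error).
    """

    cluster: int
    n_members: int
    articulation: dict[str, tuple[float, float, float]]
    delta_articulation: tuple[float, float, float]
    p_articulation_increase: float
    agreement_per_item: np.ndarray
    delta_agreement: tuple[float, float, float]
    p_agreement_increase: float
    engagement: dict[str, float] = field(default_factory=dict)
    composition: dict[str, int] = field(default_factory=dict)

    @property
    def singleton(self) -> bool:
        return self.n_members < 2


# ---------------------------------------------------------------------------
# Co-clustering and point partition
# ---------------------------------------------------------------------------

def coclustering_matrix(draws: PosteriorDraws | np.ndarray) -> np.ndarray:
    """Posterior co-assignment probability matrix (symmetric, unit diagonal)."""
    s = draws.s if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if s.ndim != 2:
        raise ValueError("label draws must have shape (n_draws, n_participants)")
    eq = s[:, :, None] == s[:, None, :]
    C = eq.mean(axis=0)
    np.fill_diagonal(C, 1.0)
    return C


def binder_loss(labels: np.ndarray, coclust: np.ndarray) -> float:
    """Binder loss Σ_{p<p'} |1[same cluster] − coclust[p,p']| of a partition."""
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    return float(np.abs(same[iu].astype(float) - coclust[iu]).sum())


def _canonical(labels: np.ndarray) -> tuple[int, ...]:
    """Relabel clusters by order of first appearance (restricted-growth form)."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


def enumerate_partitions(n: int):
    """Yield all set partitions of range(n) as restricted-growth label tuples."""
    labels = [0] * n

    def rec(i: int, k: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(k + 1):
            labels[i] = lab
            yield from rec(i + 1, max(k, lab + 1))

    yield from rec(1, 1) if n > 1 else iter([(0,) * max(n, 1)])


def _validate_coclust(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("co-clustering matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("co-clustering matrix must be symmetric")
    if C.min() < -1e-12 or C.max() > 1 + 1e-12:
        raise ValueError("co-clustering entries must lie in [0, 1]")
    return C


def point_partition(
    coclust: np.ndarray,
    participant_ids: list[str] | None = None,
    sampled_labels: np.ndarray | None = None,
    loss: str = "binder",
) -> Partition:
    """Point-estimate partition minimising Binder loss against co-clustering.

    For panels of at most 10 participants the minimiser is found by
    exhaustive enumeration of all set partitions; above that, the candidate
    set is the unique sampled partitions (if given) plus all average-linkage
    cuts of ``1 − coclust``.  Ties are broken by fewer clusters, then by the
    lexicographically smallest canonical label vector.
    """
    if loss != "binder":
        raise ValueError(f"unsupported loss {loss!r}")
    C = _validate_coclust(coclust)
    n = C.shape[0]
    if participant_ids is None:
        participant_ids = [f"P{i:03d}" for i in range(n)]

    candidates: set[tuple[int, ...]] = set()
    n_sampled = 0
    if n <= EXHAUSTIVE_LIMIT:
        candidates.update(enumerate_partitions(n))
        source = f"binder/exhaustive(Bell({n}))"
    else:
        if sampled_labels is not None:
            sl = np.asarray(sampled_labels)
            n_sampled = sl.shape[0]
            for row in sl:
                candidates.add(_canonical(row))
        d = 1.0 - C
        np.fill_diagonal(d, 0.0)
        link = average(squareform(d, checks=False))
        for k in range(1, min(n, 30) + 1):
            candidates.add(_canonical(fcluster(link, k, criterion="maxclust")))
        source = f"binder/candidates({len(candidates)};{n_sampled} sampled)"

    best = min(
        candidates,
        key=lambda lab: (binder_loss(np.array(lab), C), len(set(lab)), lab),
    )
    return Partition(
        participant_ids=list(participant_ids),
        labels=_order_by_size(np.array(best)),
        source=source,
    )


def _order_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel 1..K by decreasing size; ties by lowest member index."""
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda k: (-(labels == k).sum(), int(np.flatnonzero(labels == k)[0])),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[k] for k in labels])


# ---------------------------------------------------------------------------
# Articulation and agreement summaries
# ---------------------------------------------------------------------------

def _check_partition(draws: PosteriorDraws, partition: Partition) -> None:
    if partition.participant_ids != draws.participant_ids:
        raise ValueError("partition does not cover the fitted participants")
    if min(partition.sizes) < 1:
        raise ValueError("partition contains an empty cluster")


def _interval(x: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.mean(x)),
        float(np.quantile(x, 0.025)),
        float(np.quantile(x, 0.975)),
    )


def articulation_summary(draws: PosteriorDraws, partition: Partition) -> pd.DataFrame:
    """Per-cluster posterior summary of member-averaged articulation by round.

    The cluster average ``v̄`` is taken over members within each draw; Δ =
    v̄(R3) − v̄(R1) is computed draw-wise before summarising.  Columns:
    per-round mean/lo95/hi95, ``delta_mean``/``delta_lo``/``delta_hi`` and
    ``p_delta_positive`` = posterior P(Δ > 0).
    """
    _check_partition(draws, partition)
    r1, r3 = draws.rounds
    rows = []
    for k in range(1, partition.n_clusters + 1):
        mem = partition.members(k)
        vbar = draws.v[:, mem, :].mean(axis=1)  # (D, 2)
        delta = vbar[:, 1] - vbar[:, 0]
        m1, lo1, hi1 = _interval(vbar[:, 0])
        m3, lo3, hi3 = _interval(vbar[:, 1])
        dm, dlo, dhi = _interval(delta)
        rows.append(
            {
                "cluster": k,
                "n_members": len(mem),
                f"v_mean_{r1}": m1, f"v_lo_{r1}": lo1, f"v_hi_{r1}": hi1,
                f"v_mean_{r3}": m3, f"v_lo_{r3}": lo3, f"v_hi_{r3}": hi3,
                "delta_mean": dm, "delta_lo": dlo, "delta_hi": dhi,
                "p_delta_positive": float(np.mean(delta > 0)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


DEFAULT_AGREEMENT_MARGIN = 0.25


def agreement_change(
    draws: PosteriorDraws,
    partition: Partition,
    items: list[tuple[str, str]] | None = None,
    margin: float = DEFAULT_AGREEMENT_MARGIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster change in between-member belief variance (R3 − R1).

    Within each draw and cluster, the sample variance of member beliefs
    ``θ[·,q,r]`` is computed per item; the per-item change and its across-item
    average are then summarised over draws.  Negative values indicate a shift
    toward agreement.  Singleton clusters are flagged not-available (``NaN``).

    A shift only counts as a *meaningful* move toward agreement when the
    variance drops by more than ``margin`` times the first-round level —
    trivial reductions are "little-to-no change" in the learning typology,
    not increased agreement.

    Returns ``(per_item, summary)`` frames; ``summary`` has the across-item
    average (mean/lo95/hi95), ``p_avg_negative`` = P(average < 0) and
    ``p_meaningful_negative`` = P(average < −margin × first-round variance).
    """
    _check_partition(draws, partition)
    D, P, Q, R = draws.theta.shape
    per_item_rows = []
    summary_rows = []
    item_labels = items if items is not None else [(f"item{q}", "") for q in range(Q)]
    for k in range(1, partition.n_clusters + 1):
        mem = partition.members(k)
        if len(mem) < 2:
            per_item_rows.extend(
                {
                    "cluster": k, "goal": g, "criterion": c,
                    "delta_var_mean": np.nan,
                }
                for g, c in item_labels
            )
            summary_rows.append(
                {
                    "cluster": k, "n_members": len(mem),
                    "avg_delta_var_mean": np.nan, "avg_delta_var_lo": np.nan,
                    "avg_delta_var_hi": np.nan, "p_avg_negative": np.nan,
                    "p_meaningful_negative": np.nan,
                    "available": False,
                }
            )
            continue
        th = draws.theta[:, mem, :, :].astype(float)  # (D, n_k, Q, 2)
        var = th.var(axis=1, ddof=1)                  # (D, Q, 2)
        dvar = var[:, :, 1] - var[:, :, 0]            # (D, Q)
        per_item_mean = dvar.mean(axis=0)
        avg = dvar.mean(axis=1)                       # (D,)
        base = var[:, :, 0].mean(axis=1)              # (D,) round-1 level
        am, alo, ahi = _interval(avg)
        per_item_rows.extend(
            {
                "cluster": k, "goal": g, "criterion": c,
                "delta_var_mean": float(per_item_mean[q]),
            }
            for q, (g, c) in enumerate(item_labels)
        )
        summary_rows.append(
            {
                "cluster": k, "n_members": len(mem),
                "avg_delta_var_mean": am, "avg_delta_var_lo": alo,
                "avg_delta_var_hi": ahi,
                "p_avg_negative": float(np.mean(avg < 0)),
                "p_meaningful_negative": float(np.mean(avg < -margin * base)),
                "available": True,
            }
        )
    per_item = pd.DataFrame(per_item_rows).set_index(["cluster", "goal", "criterion"])
    summary = pd.DataFrame(summary_rows).set_index("cluster")
    return per_item, summary


def cluster_change_profiles(
    draws: PosteriorDraws,
    partition: Partition,
    panel: RatingPanel | None = None,
    agreement_margin: float = DEFAULT_AGREEMENT_MARGIN,
) -> list[ClusterChangeProfile]:
    """Assemble the full per-cluster change profile for typology classification."""
    r1, r3 = draws.rounds
    art = articulation_summary(draws, partition)
    per_item, agr = agreement_change(
        draws,
        partition,
        items=panel.items if panel is not None else None,
        margin=agreement_margin,
    )
    profiles = []
    for k in range(1, partition.n_clusters + 1):
        a = art.loc[k]
        g = agr.loc[k]
        engagement: dict[str, float] = {}
        composition: dict[str, int] = {}
        if panel is not None:
            mem_ids = [partition.participant_ids[i] for i in partition.members(k)]
            qs = sorted({q for pid in mem_ids for q in panel.satisfaction.get(pid, {})})
            for ql in qs:
                vals = [
                    panel.satisfaction[pid][ql]
                    for pid in mem_ids
                    if ql in panel.satisfaction.get(pid, {})
                ]
                if vals:
                    engagement[ql] = float(np.mean(vals))
            for pid in mem_ids:
                grp = panel.groups.get(pid)
                if grp is not None:
                    composition[grp] = composition.get(grp, 0) + 1
        profiles.append(
            ClusterChangeProfile(
                cluster=k,
                n_members=int(a["n_members"]),
                articulation={
                    r1: (a[f"v_mean_{r1}"], a[f"v_lo_{r1}"], a[f"v_hi_{r1}"]),
                    r3: (a[f"v_mean_{r3}"], a[f"v_lo_{r3}"], a[f"v_hi_{r3}"]),
                },
                delta_articulation=(a["delta_mean"], a["delta_lo"], a["delta_hi"]),
                p_articulation_increase=float(a["p_delta_positive"]),
                agreement_per_item=per_item.loc[k, "delta_var_mean"].to_numpy(),
                delta_agreement=(
                    g["avg_delta_var_mean"], g["avg_delta_var_lo"], g["avg_delta_var_hi"],
                ),
                p_agreement_increase=float(g["p_meaningful_negative"]),
                engagement=engagement,
                composition=composition,
            )
        )
    return profiles
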