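"""Bayesian latent-belief model for two-round ordinal rating panels.

Each observed score ``y[p,q,r]`` (participant p, question q, round r, on a
1..10 scale) is an ordinal-probit readout of a latent continuous response
centred on the participant's latent belief:

.. math::

    z_{pqr} \\sim \\mathcal N(\\theta_{pqr},\\ 1/v_{pr}), \\qquad
    y_{pqr} = k \\iff \\gamma_{k-1} < z_{pqr} \\le \\gamma_k ,

with fixed, strictly increasing cutpoints ``γ`` (default: category midpoints
``k + 0.5``, anchoring the latent scale so the precisions are identified).
``v[p,r]`` is the *articulation* of participant p in round r — the
concentration of their answers around their own latent beliefs — and its
between-round increase is one of the two learning indicators.

Latent beliefs decompose into cluster-level item means and a participant-level
position offset shared across items within a round,

.. math::

    \\theta_{pqr} = m_{s_p qr} + \\delta_{pr}, \\qquad
    \\delta_{pr} \\sim \\mathcal N(0,\\ 1/\\tau_{s_p r}), \\qquad
    \\log v_{pr} \\sim \\mathcal N(\\mu_{s_p r},\\ \\sigma_v^2), \\qquad
    s_p \\sim \\mathrm{DP}(\\alpha),

with cluster memberships from a Dirichlet process (truncated
stick-breaking).  Each data-revealed cluster thus carries its own trajectory
of belief means ``m``, belief concentration ``τ`` (whose between-round rise —
member positions contracting around the cluster mean — is the group
*agreement* indicator) and articulation location ``μ_v``.  The decomposition
is what makes the two learning indicators identifiable from a single rating
per cell: articulation is read off each participant's residual spread across
the whole question battery within a round, agreement off the spread of member
positions.  Missing scores are missing-at-random latent variables, sampled
along the chain and usable for posterior-predictive imputation.

Inference is by partially collapsed blocked Gibbs sampling with data
augmentation: cluster labels are updated with ``δ`` integrated out (the
marginal of a participant's latent response vector is compound-symmetric
normal), then truncated normal draws for ``z``, conjugate normal/gamma
updates for ``δ``, ``m``, ``τ``, ``μ_v``, sticks and DP concentration ``α``,
and an adaptive Metropolis-within-Gibbs step for ``log v``.  All downstream
reporting is label-invariant (co-clustering based), so label switching is
harmless.
"""

from __future__ import annotations

import contextlib
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .panel_data import RatingPanel, PanelError

__all__ = [
    "ModelConfig",
    "PosteriorDraws",
    "ImputationResult",
    "ordinal_category_prob",
    "log_likelihood",
    "fit_clf",
    "impute_missing",
    "default_cutpoints",
]

N_CATEGORIES = 10

_EPS = 1e-12


def default_cutpoints() -> np.ndarray:
    """Fixed latent-scale cutpoints at category midpoints: 1.5, 2.5, …, 9.5."""
    return np.arange(1, N_CATEGORIES) + 0.5


@dataclass
class ModelConfig:
    """Sampler and prior configuration.

    Priors (all on the latent 1–10 scale):

    - cluster belief means ``m ~ N(mean_loc, mean_scale²)``;
    - within-cluster belief precisions ``τ ~ Gamma(tau_shape, tau_rate)``;
    - cluster log-articulation locations ``μ_v ~ N(logv_loc, logv_scale²)``
      with fixed within-cluster spread ``sigma_logv``;
    - DP concentration ``α ~ Gamma(alpha_shape, alpha_rate)``, stick-breaking
      truncated at ``k_max`` components.
    """

    cutpoints: np.ndarray = field(default_factory=default_cutpoints)
    k_max: int = 20
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    thin: int = 1
    seed: int = 0
    # priors
    mean_loc: float = 5.5
    mean_scale: float = 3.0
    tau_shape: float = 2.0
    tau_rate: float = 2.0
    logv_loc: float = 0.0
    logv_scale: float = 1.5
    sigma_logv: float = 0.4
    alpha_shape: float = 1.0
    alpha_rate: float = 1.0
    # sampler tuning
    mh_steps: int = 3
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.cutpoints.ndim != 1 or len(self.cutpoints) != N_CATEGORIES - 1:
            raise ValueError("cutpoints must be a length-9 vector")
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.warmup < 0 or self.draws <= 0 or self.thin < 1 or self.chains < 1:
            raise ValueError("iteration counts must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutpoints"] = [float(c) for c in self.cutpoints]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Ordinal-probit likelihood primitives
# ---------------------------------------------------------------------------

def _edges(cutpoints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = np.concatenate(([-np.inf], cutpoints))
    hi = np.concatenate((cutpoints, [np.inf]))
    return lo, hi


def ordinal_category_prob(theta, v, k: int | None = None, cutpoints=None):
    """P(y = k | θ, v) under the ordinal-probit readout.

    ``P(y=k) = Φ((γ_k − θ)√v) − Φ((γ_{k−1} − θ)√v)`` with ``γ_0 = −∞`` and
    ``γ_10 = +∞``.  With ``k=None`` returns the full length-10 probability
    vector along a trailing axis; probabilities sum to one.
    """
    cut = default_cutpoints() if cutpoints is None else np.asarray(cutpoints, float)
    if np.any(np.diff(cut) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    theta = np.asarray(theta, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("articulation precision v must be > 0")
    sqv = np.sqrt(v)
    lo, hi = _edges(cut)
    if k is not None:
        if not (1 <= int(k) <= N_CATEGORIES):
            raise ValueError(f"category k={k} outside 1..{N_CATEGORIES}")
        k = int(k)
        return ndtr((hi[k - 1] - theta) * sqv) - ndtr((lo[k - 1] - theta) * sqv)
    t = theta[..., None]
    s = sqv[..., None]
    return ndtr((hi - t) * s) - ndtr((lo - t) * s)


def log_likelihood(panel: RatingPanel, theta, v, cutpoints=None) -> float:
    """Total log probability of the observed scores at the given parameters.

    ``theta`` has shape (P, Q, 2), ``v`` shape (P, 2); missing cells
    contribute nothing.  Returns ``-inf`` if some observed cell has
    probability zero.
    """
    theta = np.asarray(theta, float)
    v = np.asarray(v, float)
    P, Q = panel.n_participants, panel.n_items
    if theta.shape != (P, Q, 2) or v.shape != (P, 2):
        raise ValueError(
            f"parameter shapes {theta.shape}/{v.shape} inconsistent with panel "
            f"({P} participants, {Q} items, 2 rounds)"
        )
    obs = panel.observed_mask
    if not obs.any():
        return 0.0
    y = panel.scores[obs].astype(int)
    th = theta[obs]
    vv = np.broadcast_to(v[:, None, :], (P, Q, 2))[obs]
    cut = default_cutpoints() if cutpoints is None else np.asarray(cutpoints, float)
    lo, hi = _edges(cut)
    sqv = np.sqrt(vv)
    p = ndtr((hi[y - 1] - th) * sqv) - ndtr((lo[y - 1] - th) * sqv)
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(p)))


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC draws from the hierarchical model, concatenated across chains.

    Dimensions: D total draws, P participants, Q items, R=2 rounds, K
    truncation level.  ``s`` holds 1-based cluster labels; all reported
    quantities downstream are label-invariant.  ``theta`` is the latent
    belief ``m[s_p,q,r] + δ[p,r]``; ``tau`` the cluster-round belief
    precision governing the spread of member positions.  ``y_imputed`` holds
    one posterior-predictive score draw per missing cell per draw
    (``missing_cells`` gives the (p, q, r) index of each column).
    """

    theta: np.ndarray          # (D, P, Q, R) float32
    v: np.ndarray              # (D, P, R)
    s: np.ndarray              # (D, P) int16, 1-based
    m: np.ndarray              # (D, K, Q, R) float32
    tau: np.ndarray            # (D, K, R)
    mu_v: np.ndarray           # (D, K, R)
    alpha: np.ndarray          # (D,)
    log_lik: np.ndarray        # (D,)
    y_imputed: np.ndarray      # (D, n_missing) int16
    missing_cells: np.ndarray  # (n_missing, 3) int
    participant_ids: list[str]
    rounds: tuple[str, str]
    config: ModelConfig
    n_chains: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.s.shape[0]

    @property
    def n_participants(self) -> int:
        return self.s.shape[1]

    def __post_init__(self) -> None:
        if np.any(self.v <= 0) or np.any(self.tau <= 0) or np.any(self.alpha <= 0):
            raise ValueError("v, tau and alpha draws must be strictly positive")
        if self.s.min(initial=1) < 1 or self.s.max(initial=1) > self.config.k_max:
            raise ValueError("cluster labels outside 1..k_max")
        if self.y_imputed.size and (
            self.y_imputed.min() < 1 or self.y_imputed.max() > N_CATEGORIES
        ):
            raise ValueError("imputed scores outside 1..10")


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _truncnorm_draw(mean, sd, lo, hi, rng) -> np.ndarray:
    """Inverse-CDF truncated normal draws, vectorised (lo/hi may be ±inf)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + (b - a) * rng.random(mean.shape)
    u = np.clip(u, _EPS, 1 - _EPS)
    return mean + sd * ndtri(u)


def _init_labels(scores: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """K-means initial clustering on per-participant summary features."""
    from sklearn.cluster import KMeans

    feats = []
    for r in range(2):
        x = scores[:, :, r]
        feats.append(np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1))
        feats.append(np.nanstd(np.where(np.isnan(x), np.nan, x), axis=1))
    X = np.column_stack(feats)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(
        n_clusters=min(k, X.shape[0]),
        n_init=4,
        random_state=int(rng.integers(2**31 - 1)),
    )
    with _quiet_kmeans():
        return km.fit_predict(X)


@contextlib.contextmanager
def _quiet_kmeans():
    """Silence the duplicate-points ConvergenceWarning on degenerate panels."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


def _cs_loglik_at(z, m_occ, se2, sd2, Q):
    """Compound-symmetric round log-likelihood for given noise/offset variances.

    ``z`` (P, Q) latent responses for one round, ``m_occ`` (C, Q) cluster item
    means, ``se2`` (C,) articulation noise variance per cluster, ``sd2`` (C,)
    offset variance per cluster.  Returns (P, C).
    """
    S = (
        (z**2).sum(axis=1)[:, None]
        - 2.0 * z @ m_occ.T
        + (m_occ**2).sum(axis=1)[None, :]
    )
    T = (z.sum(axis=1)[:, None] - m_occ.sum(axis=1)[None, :]) ** 2
    tot = se2[None, :] + Q * sd2[None, :]
    return -0.5 * (
        (Q - 1) * np.log(se2)[None, :]
        + np.log(tot)
        + S / se2[None, :]
        - (sd2 / se2)[None, :] * T / tot
    )


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(9)


def _marginal_loglik(z, m_occ, tau_occ, mu_v_occ, sigma_logv, Q):
    """Participant × cluster log-likelihood with both the position offset δ
    and the articulation precision v integrated out (δ analytically via the
    compound-symmetric marginal, log v by Gauss-Hermite quadrature over its
    cluster-level log-normal).  Used for warmup partition refinement, where
    assignments must not be anchored by a stuck per-participant v."""
    P = z.shape[0]
    C = m_occ.shape[0]
    ll = np.zeros((P, C))
    logw = np.log(_GH_WEIGHTS / np.sqrt(np.pi))
    for r in range(2):
        per_node = np.empty((len(_GH_NODES), P, C))
        sd2 = 1.0 / tau_occ[:, r]
        for j, x in enumerate(_GH_NODES):
            w_kr = mu_v_occ[:, r] + np.sqrt(2.0) * sigma_logv * x
            se2 = np.exp(-w_kr)
            per_node[j] = _cs_loglik_at(z[:, :, r], m_occ[:, :, r], se2, sd2, Q)
        mx = per_node.max(axis=0)
        ll += mx + np.log(
            np.exp(per_node - mx[None] + logw[:, None, None]).sum(axis=0)
        )
    return ll


def _plugin_params(z, labels, occ, Q, cfg):
    """Moment-based cluster parameter estimates for refinement scoring."""
    C = len(occ)
    P = z.shape[0]
    m = np.empty((C, Q, 2))
    tau = np.empty((C, 2))
    mu_v = np.empty((C, 2))
    w_hat = np.empty((P, 2))
    d_hat = np.empty((P, 2))
    for c, k in enumerate(occ):
        mem = np.flatnonzero(labels == k)
        zc = z[mem]
        m[c] = zc.mean(axis=0)
        d = (zc - m[c][None]).mean(axis=1)             # (n, 2) offsets
        d_hat[mem] = d
        resid = zc - m[c][None] - d[:, None, :]
        ssr = (resid**2).sum(axis=1)                   # (n, 2)
        # clip keeps overfit small clusters (ssr -> 0) from dominating scores;
        # precision beyond ~10 is sub-category resolution on a unit-spaced
        # ordinal scale, so the cap discards no real articulation signal
        w_mem = np.clip(
            np.log(np.maximum(Q - 1, 1) / np.maximum(ssr, 1e-8)),
            np.log(0.02), np.log(10.0),
        )
        w_hat[mem] = w_mem
        mu_v[c] = w_mem.mean(axis=0)
        var_d = d.var(axis=0) + 1.0 / np.exp(w_mem).mean(axis=0) / Q
        tau[c] = np.clip(1.0 / np.maximum(var_d, 1e-6), 1e-3, 1e2)
    return m, tau, mu_v, w_hat, d_hat


def _cluster_score(z, mem, alpha, Q, cfg):
    """Score contribution of one cluster to the plug-in partition posterior:
    marginal data likelihood of its members at moment-fitted parameters, plus
    the Chinese-restaurant prior mass and a BIC-style charge for the
    cluster's free parameters (item means, belief precision, articulation
    location per round)."""
    from scipy.special import gammaln

    lab = np.zeros(len(mem), dtype=int)
    m, tau, mu_v, _, _ = _plugin_params(z[mem], lab, np.array([0]), Q, cfg)
    ll = _marginal_loglik(z[mem], m, tau, mu_v, cfg.sigma_logv, Q)[:, 0].sum()
    prior = np.log(max(alpha, 1e-8)) + gammaln(len(mem))
    complexity = 0.5 * (2 * Q + 4) * np.log(z.shape[0])
    return ll + prior - complexity


def _refine_partition(z, labels0, alpha, Q, cfg, rng, max_rounds=8):
    """Greedy split / merge / reassign search improving the plug-in partition
    posterior.  Used during warmup only — it is an initialisation device, not
    part of the MCMC kernel, which stays pure Gibbs after warmup."""
    from sklearn.cluster import KMeans

    labels = labels0.copy()
    K = cfg.k_max
    scores: dict[int, float] = {}

    def score(k):
        if k not in scores:
            scores[k] = _cluster_score(
                z, np.flatnonzero(labels == k), alpha, Q, cfg
            )
        return scores[k]

    for _ in range(max_rounds):
        changed = False

        # merge pass (first improvement, rescanning after each merge)
        merged = True
        while merged:
            merged = False
            occ = sorted(np.unique(labels), key=lambda k: (labels == k).sum())
            for i in range(len(occ)):
                for j in range(i + 1, len(occ)):
                    a, b = occ[i], occ[j]
                    mem = np.flatnonzero((labels == a) | (labels == b))
                    gain = (
                        _cluster_score(z, mem, alpha, Q, cfg)
                        - score(a)
                        - score(b)
                    )
                    if gain > 1e-6:
                        labels[labels == a] = b
                        scores.pop(a, None)
                        scores.pop(b, None)
                        changed = merged = True
                        break
                if merged:
                    break

        # split pass: 2-means on offset-removed profiles + articulation
        occ = np.unique(labels)
        _, _, _, w_hat, d_hat = _plugin_params(z, labels, occ, Q, cfg)
        for k in occ:
            free = [x for x in range(K) if x not in set(np.unique(labels).tolist())]
            mem = np.flatnonzero(labels == k)
            if len(mem) < 4 or not free:
                continue
            feats = np.column_stack(
                [
                    (z[mem] - d_hat[mem][:, None, :]).reshape(len(mem), -1),
                    10.0 * w_hat[mem],
                ]
            )
            km = KMeans(2, n_init=2, random_state=int(rng.integers(2**31 - 1)))
            with _quiet_kmeans():
                half = km.fit_predict(feats)
            if half.min() == half.max():
                continue
            gain = (
                _cluster_score(z, mem[half == 0], alpha, Q, cfg)
                + _cluster_score(z, mem[half == 1], alpha, Q, cfg)
                - score(k)
            )
            if gain > 1e-6:
                labels[mem[half == 1]] = free[0]
                scores.pop(k, None)
                changed = True

        # reassignment pass at current plug-in parameters
        occ = np.unique(labels)
        if len(occ) > 1:
            m, tau, mu_v, _, _ = _plugin_params(z, labels, occ, Q, cfg)
            ll = _marginal_loglik(z, m, tau, mu_v, cfg.sigma_logv, Q)
            sizes = np.array([(labels == k).sum() for k in occ], dtype=float)
            new = occ[np.argmax(ll + np.log(sizes)[None, :], axis=1)]
            # never empty a cluster through reassignment alone
            if np.any(new != labels) and len(np.unique(new)) == len(occ):
                old_total = sum(score(k) for k in occ)
                new_total = sum(
                    _cluster_score(z, np.flatnonzero(new == k), alpha, Q, cfg)
                    for k in np.unique(new)
                )
                if new_total > old_total + 1e-6:
                    labels = new.copy()
                    scores.clear()
                    changed = True

        if not changed:
            break
    return labels


def _run_chain(panel: RatingPanel, cfg: ModelConfig, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    P, Q = panel.n_participants, panel.n_items
    K = cfg.k_max
    gamma = cfg.cutpoints
    lo_e, hi_e = _edges(gamma)
    obs = panel.observed_mask
    y = np.nan_to_num(panel.scores, nan=1.0).astype(int)
    lo = np.where(obs, lo_e[y - 1], -np.inf)
    hi = np.where(obs, hi_e[y - 1], np.inf)
    miss_idx = np.argwhere(~obs)

    # --- state ------------------------------------------------------------
    z = np.where(obs, panel.scores, np.nanmean(panel.scores[obs]) if obs.any() else 5.5)
    delta = np.zeros((P, 2))                  # participant position offsets
    w = np.zeros((P, 2))                      # log articulation
    s = _init_labels(panel.scores, min(K, max(2, P // 8)), rng).astype(int)
    # empty clusters start (and stay) at prior draws, so they are never a
    # better fit than a participant's own cluster; occupied clusters start
    # at their member means
    m = cfg.mean_loc + cfg.mean_scale * rng.standard_normal((K, Q, 2))
    for k in np.unique(s):
        m[k] = z[s == k].mean(axis=0)
    tau = rng.gamma(cfg.tau_shape, 1.0 / cfg.tau_rate, (K, 2))
    mu_v = np.zeros((K, 2))
    alpha = 1.0
    log_pi = np.full(K, -np.log(K))
    eps = np.full((P, 2), 0.3)                # MH step sizes for log v
    prior_mprec = 1.0 / cfg.mean_scale**2
    s0sq = cfg.logv_scale**2
    svsq = cfg.sigma_logv**2

    n_keep = cfg.draws
    keep_every = cfg.thin
    total = cfg.warmup + n_keep * keep_every

    out = {
        "theta": np.empty((n_keep, P, Q, 2), np.float32),
        "v": np.empty((n_keep, P, 2)),
        "s": np.empty((n_keep, P), np.int16),
        "m": np.empty((n_keep, K, Q, 2), np.float32),
        "tau": np.empty((n_keep, K, 2)),
        "mu_v": np.empty((n_keep, K, 2)),
        "alpha": np.empty(n_keep),
        "log_lik": np.empty(n_keep),
        "y_imp": np.empty((n_keep, len(miss_idx)), np.int16),
    }
    kept = 0
    refine_at = (
        {0, cfg.warmup // 3, (2 * cfg.warmup) // 3, cfg.warmup - 1}
        if cfg.warmup > 0
        else set()
    )

    for it in range(total):
        v = np.exp(w)                         # (P, 2)

        # -- s | z, w, cluster params (delta integrated out: marginally a
        # participant's round-r response vector is compound-symmetric normal,
        # Cov = I/v + J/tau, so whole participants can move between clusters
        # instead of being anchored by an offset drawn under their current
        # label; Sherman-Morrison gives the O(1)-per-item quadratic form)
        ll = np.zeros((P, K))
        for r in range(2):
            zr, mr = z[:, :, r], m[:, :, r]
            se2 = (1.0 / v[:, r])[:, None]                     # (P, 1)
            sd2 = (1.0 / tau[:, r])[None, :]                   # (1, K)
            S = (
                (zr**2).sum(axis=1)[:, None]
                - 2.0 * zr @ mr.T
                + (mr**2).sum(axis=1)[None, :]
            )
            T = (zr.sum(axis=1)[:, None] - mr.sum(axis=1)[None, :]) ** 2
            tot = se2 + Q * sd2
            ll += -0.5 * (
                (Q - 1) * np.log(se2)
                + np.log(tot)
                + S / se2
                - (sd2 / se2) * T / tot
            )
        ll -= ((w[:, None, :] - mu_v[None, :, :]) ** 2).sum(axis=2) / (2 * svsq)
        g = rng.gumbel(size=ll.shape)
        s = np.argmax(log_pi[None, :] + ll + g, axis=1)

        # -- delta | s, z, v, m, tau
        resid_sum = (z - m[s]).sum(axis=1)    # (P, 2)
        prec_d = tau[s] + Q * v
        mean_d = v * resid_sum / prec_d
        delta = mean_d + rng.standard_normal(delta.shape) / np.sqrt(prec_d)

        # -- z | delta, v, m, s, y (truncated normal; free where missing)
        center = m[s] + delta[:, None, :]
        sd_z = 1.0 / np.sqrt(v)[:, None, :]
        z = _truncnorm_draw(center, np.broadcast_to(sd_z, center.shape), lo, hi, rng)

        # -- log v | z, m, delta (adaptive MH)
        ssr = ((z - center) ** 2).sum(axis=1)  # (P, 2)
        mu_w = mu_v[s]                         # (P, 2)
        logp = 0.5 * Q * w - 0.5 * np.exp(w) * ssr - (w - mu_w) ** 2 / (2 * svsq)
        for _ in range(cfg.mh_steps):
            prop = w + eps * rng.standard_normal(w.shape)
            logp_prop = (
                0.5 * Q * prop - 0.5 * np.exp(prop) * ssr
                - (prop - mu_w) ** 2 / (2 * svsq)
            )
            acc = np.log(rng.random(w.shape)) < logp_prop - logp
            w = np.where(acc, prop, w)
            logp = np.where(acc, logp_prop, logp)
            if it < cfg.warmup:
                eps *= np.exp(0.08 * (acc.astype(float) - 0.44))
        v = np.exp(w)

        # -- cluster-level parameters | z, delta, w, s
        Z = np.zeros((P, K))
        Z[np.arange(P), s] = 1.0
        n_k = Z.sum(axis=0)                   # (K,)
        # m: members' (z - delta) weighted by their articulation precision
        zd = z - delta[:, None, :]            # (P, Q, 2)
        for r in range(2):
            wts = Z * v[:, r][:, None]        # (P, K)
            prec_m = prior_mprec + wts.sum(axis=0)[:, None]          # (K, 1)
            num = prior_mprec * cfg.mean_loc + wts.T @ zd[:, :, r]   # (K, Q)
            m[:, :, r] = num / prec_m + rng.standard_normal((K, Q)) / np.sqrt(prec_m)
        # tau | delta
        d2 = Z.T @ delta**2                   # (K, 2)
        tau = rng.gamma(
            cfg.tau_shape + 0.5 * n_k[:, None], 1.0 / (cfg.tau_rate + 0.5 * d2)
        )
        tau = np.maximum(tau, 1e-8)
        # mu_v | w
        sw = Z.T @ w                          # (K, 2)
        pv = 1.0 / s0sq + n_k[:, None] / svsq
        mv = (cfg.logv_loc / s0sq + sw / svsq) / pv
        mu_v = mv + rng.standard_normal(mu_v.shape) / np.sqrt(pv)

        # -- joint (m, z) translation per cluster-item-round: when
        # articulation is high, z hugs the belief and the two random-walk in
        # lockstep inside one category interval; shifting both together is a
        # valid Metropolis move (likelihood invariant) whose acceptance needs
        # only the m-prior ratio and the category bounds on the shifted z
        for _ in range(2):
            shift = 0.4 * rng.standard_normal((K, Q, 2))
            lo_gap = np.full((K, Q, 2), -np.inf)
            hi_gap = np.full((K, Q, 2), np.inf)
            for k in np.unique(s):
                mem = s == k
                lo_gap[k] = (lo[mem] - z[mem]).max(axis=0)
                hi_gap[k] = (hi[mem] - z[mem]).min(axis=0)
            dprior = (
                (m - cfg.mean_loc) ** 2 - (m + shift - cfg.mean_loc) ** 2
            ) * (0.5 * prior_mprec)
            ok = (
                (shift > lo_gap)
                & (shift < hi_gap)
                & (np.log(rng.random(shift.shape)) < dprior)
            )
            shift = np.where(ok, shift, 0.0)
            m = m + shift
            z = z + shift[s]

        # -- joint (delta, z) translation per participant-round (same
        # lockstep cure at the individual level: acceptance needs only the
        # delta-prior ratio and the category bounds)
        for _ in range(2):
            shift_d = 0.3 * rng.standard_normal((P, 2))
            lo_gap_d = (lo - z).max(axis=1)            # (P, 2)
            hi_gap_d = (hi - z).min(axis=1)
            tau_p = tau[s]                             # (P, 2)
            dprior_d = 0.5 * tau_p * (delta**2 - (delta + shift_d) ** 2)
            ok_d = (
                (shift_d > lo_gap_d)
                & (shift_d < hi_gap_d)
                & (np.log(rng.random(shift_d.shape)) < dprior_d)
            )
            shift_d = np.where(ok_d, shift_d, 0.0)
            delta = delta + shift_d
            z = z + shift_d[:, None, :]

        # -- sticks and alpha | s
        tail = np.concatenate((np.cumsum(n_k[::-1])[::-1][1:], [0.0]))
        V = rng.beta(1.0 + n_k[:-1], alpha + tail[:-1])
        V = np.clip(V, 1e-10, 1 - 1e-10)
        log1mV = np.log1p(-V)
        log_pi = np.concatenate(([0.0], np.cumsum(log1mV)))
        log_pi[:-1] += np.log(V)
        alpha = rng.gamma(cfg.alpha_shape + K - 1, 1.0 / (cfg.alpha_rate - log1mV.sum()))
        alpha = max(alpha, 1e-8)

        # -- warmup-only partition refinement (initialisation device: greedy
        # split/merge/reassign moves escape the merge-only dynamics of
        # incremental label updates; the sampling phase is pure Gibbs)
        if it in refine_at:
            labels = _refine_partition(z, s.copy(), alpha, Q, cfg, rng)
            occ = np.unique(labels)
            mm, tt, mv_hat, w_hat, d_hat = _plugin_params(z, labels, occ, Q, cfg)
            s = labels
            w = w_hat
            delta = d_hat
            for c, k in enumerate(occ):
                m[k] = mm[c]
                tau[k] = tt[c]
                mu_v[k] = mv_hat[c]

        # -- store --------------------------------------------------------
        if it >= cfg.warmup and (it - cfg.warmup) % keep_every == 0 and kept < n_keep:
            theta = m[s] + delta[:, None, :]
            out["theta"][kept] = theta
            out["v"][kept] = v
            out["s"][kept] = s + 1
            out["m"][kept] = m
            out["tau"][kept] = tau
            out["mu_v"][kept] = mu_v
            out["alpha"][kept] = alpha
            if len(miss_idx):
                zm = z[miss_idx[:, 0], miss_idx[:, 1], miss_idx[:, 2]]
                out["y_imp"][kept] = np.clip(
                    np.digitize(zm, gamma) + 1, 1, N_CATEGORIES
                )
            out["log_lik"][kept] = log_likelihood(panel, theta, v, gamma)
            kept += 1

    out["missing_cells"] = miss_idx
    return out


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Reshape (chains, draws, ...) into split half-chains for diagnostics."""
    c, d = x.shape[:2]
    h = d // 2
    return x[:, : 2 * h].reshape(c * 2, h, *x.shape[2:])


def _diagnostics(per_chain: list[dict], cfg: ModelConfig) -> dict:
    import arviz as az

    diags: dict = {"warnings": []}
    for name in ("v", "m", "tau"):
        x = np.stack([c[name] for c in per_chain]).astype(float)
        xs = _split_chains(x.reshape(x.shape[0], x.shape[1], -1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rh = np.asarray(az.rhat(az.convert_to_dataset(xs)).x)
            es = np.asarray(az.ess(az.convert_to_dataset(xs)).x)
        rh = rh[np.isfinite(rh)]
        es = es[np.isfinite(es)]
        diags[f"rhat_{name}_max"] = float(rh.max()) if rh.size else float("nan")
        diags[f"ess_{name}_min"] = float(es.min()) if es.size else float("nan")
    rv = diags["rhat_v_max"]
    diags["converged"] = bool(np.isfinite(rv) and rv <= cfg.rhat_threshold)
    if not diags["converged"]:
        diags["warnings"].append(
            f"split-Rhat for articulation v exceeds {cfg.rhat_threshold}: {rv:.3f}"
        )
    return diags


def fit_clf(panel: RatingPanel, config: ModelConfig | None = None) -> PosteriorDraws:
    """Fit the collaborative-learning model by blocked Gibbs sampling.

    Runs ``config.chains`` independent chains (seeds spawned deterministically
    from ``config.seed``), concatenates post-warmup draws, and attaches
    convergence diagnostics (split-R̂ and effective sample size for ``v``,
    ``m``, ``τ``).  Non-convergence is recorded as a warning in
    ``result.diagnostics``, not raised.  Identical panel + config + seed give
    identical draws.
    """
    if config is None:
        config = ModelConfig()
    if panel.n_participants < 2:
        raise PanelError("model requires at least 2 participants")
    seeds = np.random.SeedSequence(config.seed).generate_state(config.chains) % (
        2**31 - 1
    )
    per_chain = [_run_chain(panel, config, int(s)) for s in seeds]
    cat = {
        k: np.concatenate([c[k] for c in per_chain])
        for k in ("theta", "v", "s", "m", "tau", "mu_v", "alpha", "log_lik", "y_imp")
    }
    diags = _diagnostics(per_chain, config)
    return PosteriorDraws(
        theta=cat["theta"],
        v=cat["v"],
        s=cat["s"],
        m=cat["m"],
        tau=cat["tau"],
        mu_v=cat["mu_v"],
        alpha=cat["alpha"],
        log_lik=cat["log_lik"],
        y_imputed=cat["y_imp"].astype(np.int16),
        missing_cells=per_chain[0]["missing_cells"],
        participant_ids=list(panel.participant_ids),
        rounds=panel.rounds,
        config=config,
        n_chains=config.chains,
        diagnostics=diags,
    )


# ---------------------------------------------------------------------------
# Posterior-predictive imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    """Posterior-predictive distributions for missing cells and a completed panel.

    ``distributions`` is indexed by (participant, goal, criterion, round) with
    ten probability columns ``p1..p10`` (each row sums to one; observed cells
    queried through :meth:`cell_distribution` return a degenerate
    distribution).  ``completed`` is the input panel with every missing score
    replaced by its posterior-predictive mode (ties to the smaller category).
    """

    distributions: pd.DataFrame
    completed: RatingPanel
    _panel: RatingPanel

    def cell_distribution(self, participant: str, goal: str, criterion: str, rnd: str) -> np.ndarray:
        key = (participant, goal, criterion, rnd)
        if key in self.distributions.index:
            return self.distributions.loc[key].to_numpy(dtype=float)
        p = self._panel.participant_ids.index(participant)
        q = self._panel.items.index((goal, criterion))
        r = self._panel.rounds.index(rnd)
        val = self._panel.scores[p, q, r]
        if np.isnan(val):  # pragma: no cover - all missing cells are indexed
            raise KeyError(key)
        dist = np.zeros(N_CATEGORIES)
        dist[int(val) - 1] = 1.0
        return dist


def impute_missing(draws: PosteriorDraws, panel: RatingPanel) -> ImputationResult:
    """Posterior-predictive imputation of every missing cell.

    Distributions are relative frequencies of the per-draw predictive score
    draws stored along the chain; the completed panel takes the modal
    category.  Observed cells are returned untouched.
    """
    if list(panel.participant_ids) != draws.participant_ids:
        raise ValueError("draws were not fitted on this panel (participant mismatch)")
    cells = draws.missing_cells
    probs = np.zeros((len(cells), N_CATEGORIES))
    if len(cells):
        for k in range(1, N_CATEGORIES + 1):
            probs[:, k - 1] = (draws.y_imputed == k).mean(axis=0)
    items = panel.items
    index = pd.MultiIndex.from_tuples(
        [
            (
                panel.participant_ids[p],
                items[q][0],
                items[q][1],
                panel.rounds[r],
            )
            for p, q, r in cells
        ],
        names=["participant", "goal", "criterion", "round"],
    )
    dist = pd.DataFrame(
        probs, index=index, columns=[f"p{k}" for k in range(1, N_CATEGORIES + 1)]
    )
    completed = panel.copy()
    if len(cells):
        modes = np.argmax(probs, axis=1) + 1  # argmax ties -> smaller category
        completed.scores[cells[:, 0], cells[:, 1], cells[:, 2]] = modes
    return ImputationResult(distributions=dist, completed=completed, _panel=panel)
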