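"""Shared fixtures: tiny hand-built panels and small fitted posteriors."""

import numpy as np
import pytest

import delphilearn as dl


@pytest.fixture()
def tiny_panel():
    """2 participants x (1 goal x 1 criterion) x 2 rounds, fully observed."""
    scores = np.array(
        [
            [[3.0, 4.0]],
            [[5.0, 5.0]],
        ]
    )
    return dl.RatingPanel(
        participant_ids=["a", "b"],
        goals=["G1"],
        criteria=["C1"],
        scores=scores,
    )


@pytest.fixture()
def small_panel():
    """A small complete panel with groups and satisfaction metadata."""
    rng = np.random.default_rng(0)
    scores = rng.integers(1, 11, size=(5, 6, 2)).astype(float)
    scores[0, 1, 0] = np.nan
    scores[3, 4, 1] = np.nan
    return dl.RatingPanel(
        participant_ids=[f"p{i}" for i in range(5)],
        goals=["G1", "G2", "G3"],
        criteria=["C1", "C2"],
        scores=scores,
        groups={f"p{i}": ["survivor", "researcher"][i % 2] for i in range(5)},
        satisfaction={f"p{i}": {"interesting": 5, "easy": 4} for i in range(5)},
    )


def make_draws(v, theta, s, rounds=("R1", "R3")):
    """Hand-built PosteriorDraws for summary tests (no MCMC involved).

    v: (D, P, 2); theta: (D, P, Q, 2); s: (D, P) 1-based labels.
    """
    v = np.asarray(v, float)
    theta = np.asarray(theta, np.float32)
    s = np.asarray(s, np.int16)
    D, P, Q, _ = theta.shape
    K = max(2, int(s.max()))
    cfg = dl.ModelConfig(k_max=K, chains=1, warmup=1, draws=D, seed=0)
    return dl.PosteriorDraws(
        theta=theta,
        v=v,
        s=s,
        m=np.zeros((D, K, Q, 2), np.float32),
        tau=np.ones((D, K, 2)),
        mu_v=np.zeros((D, K, 2)),
        alpha=np.ones(D),
        log_lik=np.zeros(D),
        y_imputed=np.zeros((D, 0), np.int16),
        missing_cells=np.zeros((0, 3), int),
        participant_ids=[f"P{i:03d}" for i in range(P)],
        rounds=rounds,
        config=cfg,
        n_chains=1,
    )


@pytest.fixture(scope="session")
def fitted_small():
    """One small fitted model shared by imputation / contract tests."""
    scores = np.full((6, 6, 2), 8.0)
    scores[0, 0, 0] = np.nan
    panel = dl.RatingPanel(
        participant_ids=[f"P{i}" for i in range(6)],
        goals=["G1", "G2", "G3"],
        criteria=["C1", "C2"],
        scores=scores,
    )
    cfg = dl.ModelConfig(seed=11, chains=1, warmup=200, draws=200, k_max=3)
    return panel, dl.fit_clf(panel, cfg)
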