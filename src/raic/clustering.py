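"""Clustering of per-participant HMMs into viewing strategies.

All individual HMMs for one image share the same fixed ROI state space and
emissions, so the divergence between two models reduces to the divergence
between their Markov-chain parameters. Clustering is a hard-assignment EM
specialisation for this shared-state-space case: each model is scored
against a candidate representative by its expected log transition
probability (weighted by the model's own state occupancy) plus a 1/T-weighted
initial-state term; representatives are occupancy-weighted averages of
member rows. With K = 2 the clusters are labelled focused (high mean
self-transition) versus explorative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import GazeHMM

__all__ = ["StrategyClustering", "cluster_hmms", "label_strategies"]

_EPS = 1e-12


@dataclass
class StrategyClustering:
    K: int
    representatives: list[GazeHMM]
    assignments: np.ndarray  # model index -> cluster
    objective: float
    labels: dict[int, str] = field(default_factory=dict)  # cluster -> strategy
    n_restarts: int = 1
    degenerate: bool = False


def _occupancy(model: GazeHMM) -> np.ndarray:
    if model.occupancy is not None:
        return model.occupancy
    # fall back to the stationary distribution of A
    evals, evecs = np.linalg.eig(model.A.T)
    v = np.real(evecs[:, np.argmax(np.real(evals))])
    v = np.abs(v)
    return v / v.sum()


def _score(model: GazeHMM, rep_pi: np.ndarray, rep_A: np.ndarray) -> float:
    nu = _occupancy(model)
    w = 1.0 / max(model.n_obs, 1)
    trans = float(np.sum(nu[:, None] * model.A * np.log(rep_A + _EPS)))
    init = float(np.dot(model.pi, np.log(rep_pi + _EPS)))
    return trans + w * init


def _m_step(models: list[GazeHMM], members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy-weighted average of member transition rows and priors."""
    n = models[0].n_states
    num_A = np.zeros((n, n))
    den_A = np.zeros(n)
    pi_acc = np.zeros(n)
    for i in members:
        nu = _occupancy(models[i])
        num_A += nu[:, None] * models[i].A
        den_A += nu
        pi_acc += models[i].pi
    rep_A = num_A / np.maximum(den_A, _EPS)[:, None]
    # a state no member ever occupies contributes nothing to any score;
    # give its row the uniform reference instead of 0/0
    empty_rows = rep_A.sum(axis=1) <= 0
    rep_A[empty_rows] = 1.0 / n
    rep_A /= rep_A.sum(axis=1, keepdims=True)
    rep_pi = pi_acc / pi_acc.sum()
    return rep_pi, rep_A


def cluster_hmms(
    models: list[GazeHMM],
    K: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 100,
) -> StrategyClustering:
    """Hard-assignment EM over shared-state-space HMMs, best of restarts.

    E-step assigns each model to the representative maximising its expected
    log score; M-step recomputes representatives from members. An emptied
    cluster is re-seeded from the currently worst-fitting model. The run
    (over ``n_restarts`` random initialisations) with the highest total
    objective wins; output is invariant to input order up to relabelling.
    """
    n_models = len(models)
    if K > n_models:
        raise ValueError(f"K={K} exceeds number of models ({n_models})")
    if len({m.n_states for m in models}) != 1:
        raise ValueError("all models must share one state space")

    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        assign = rng.integers(0, K, n_models)
        # guarantee non-empty start
        assign[rng.permutation(n_models)[:K]] = np.arange(K)
        prev = None
        obj = -np.inf
        for _ in range(max_iter):
            reps = []
            for c in range(K):
                members = np.flatnonzero(assign == c)
                if len(members) == 0:
                    # re-seed from the worst-fitting model
                    scores = np.array(
                        [_score(models[i], *reps_cache[assign[i]]) for i in range(n_models)]
                    )
                    worst = int(np.argmin(scores))
                    assign[worst] = c
                    members = np.array([worst])
                reps.append(_m_step(models, members))
            reps_cache = reps
            score_mat = np.array(
                [[_score(m, *reps[c]) for c in range(K)] for m in models]
            )
            new_assign = score_mat.argmax(axis=1)
            obj = float(score_mat[np.arange(n_models), new_assign].sum())
            if prev is not None and np.array_equal(new_assign, assign):
                break
            prev = assign
            assign = new_assign
        if best is None or obj > best[0]:
            best = (obj, assign.copy(), reps)

    obj, assign, reps = best
    template = models[0]
    representatives = [
        GazeHMM(
            means=template.means,
            covs=template.covs,
            alpha=rep_pi * 1000.0 + _EPS,  # point mass encoded as strong Dirichlet
            beta=rep_A * 1000.0 + _EPS,
            prior_strength=template.prior_strength,
            occupancy=None,
            n_obs=int(np.mean([m.n_obs for m in models])),
        )
        for rep_pi, rep_A in reps
    ]
    degenerate = len(np.unique(assign)) < K and n_models >= K
    return StrategyClustering(
        K=K,
        representatives=representatives,
        assignments=assign,
        objective=obj,
        n_restarts=n_restarts,
        degenerate=degenerate,
    )


def _row_entropy(A: np.ndarray) -> float:
    p = np.clip(A, _EPS, None)
    return float(-(p * np.log(p)).sum(axis=1).mean())


def label_strategies(clustering: StrategyClustering) -> StrategyClustering:
    """Label the K=2 clusters as focused vs explorative.

    The cluster whose representative has the higher mean self-transition
    probability (trace(A)/n) is focused; on a tie the lower mean row entropy
    wins the focused label.
    """
    if clustering.K != 2:
        raise ValueError("strategy labelling is defined for K=2")
    diags = [float(np.trace(r.A) / r.n_states) for r in clustering.representatives]
    if not np.isclose(diags[0], diags[1]):
        focused = int(np.argmax(diags))
    else:
        ents = [_row_entropy(r.A) for r in clustering.representatives]
        focused = int(np.argmin(ents))
    clustering.labels = {focused: "focused", 1 - focused: "explorative"}
    return clustering
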