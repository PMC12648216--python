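"""Variational-Bayes scanpath HMMs over a fixed expert ROI state space.

Each participant's fixation sequence in a cumulative window is modelled by a
hidden Markov chain whose states are the expert-annotated ROIs. The Gaussian
emission of each state is fixed in advance from the ROI ellipse (mean at the
centroid, covariance from the axes and orientation), so inference reduces to
the initial-state distribution ``pi`` and the transition matrix ``A``. Both
carry symmetric Dirichlet priors; the variational posterior is again Dirichlet
and the E-step runs forward-backward under the expected-log parameters
(digammas of the Dirichlet posteriors). The evidence lower bound is
non-decreasing across iterations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

from .types import ExpertGazePattern, FixationSequence, GazeHMM

__all__ = [
    "exclude_trials",
    "window_sequence",
    "build_emissions",
    "fit_vb_hmm",
    "sequence_loglik",
]


# ---------------------------------------------------------------------------
# trial exclusion and windowing
# ---------------------------------------------------------------------------

def max_fixation_gap_s(seq: FixationSequence) -> float:
    """Longest span of the trial (s) not covered by any fixation.

    Covers the leading span before the first fixation, gaps between the end
    of one fixation and the onset of the next, and the trailing span after
    the last fixation ends.
    """
    if len(seq) == 0:
        return seq.trial_length_ms / 1000.0
    ends = seq.onset_ms + seq.duration_ms
    gaps = [seq.onset_ms[0]]
    gaps.extend(np.maximum(seq.onset_ms[1:] - ends[:-1], 0.0))
    gaps.append(max(seq.trial_length_ms - ends[-1], 0.0))
    return float(max(gaps)) / 1000.0


def exclude_trials(
    seqs: list[FixationSequence],
    gap_threshold_s: float = 2.0,
    drop_grayscale: bool = True,
) -> tuple[list[FixationSequence], list[dict]]:
    """Apply the trial-exclusion rules.

    A trial is excluded when any span longer than ``gap_threshold_s`` lacks
    fixations; grayscale-condition trials are dropped from the analysis set.
    Returns the kept trials and a log of exclusions with the rule that fired.
    """
    kept: list[FixationSequence] = []
    log: list[dict] = []
    for seq in seqs:
        if drop_grayscale and seq.condition == "grayscale":
            log.append(
                {
                    "participant_id": seq.participant_id,
                    "image_id": seq.image_id,
                    "rule": "grayscale",
                    "max_gap_s": np.nan,
                }
            )
            continue
        gap = max_fixation_gap_s(seq)
        if gap > gap_threshold_s:
            log.append(
                {
                    "participant_id": seq.participant_id,
                    "image_id": seq.image_id,
                    "rule": "fixation_gap",
                    "max_gap_s": gap,
                }
            )
            continue
        kept.append(seq)
    return kept, log


def window_sequence(seq: FixationSequence, t_end: float) -> FixationSequence:
    """Cumulative window [0, t_end): fixations with onset < t_end seconds.

    Half-open on the right, so a fixation starting at exactly ``t_end``
    belongs to the next window. Idempotent for fixed ``t_end`` and monotone:
    window(6) contains window(3).
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    keep = seq.onset_ms < t_end * 1000.0
    return FixationSequence(
        participant_id=seq.participant_id,
        image_id=seq.image_id,
        condition=seq.condition,
        x=seq.x[keep],
        y=seq.y[keep],
        onset_ms=seq.onset_ms[keep],
        duration_ms=seq.duration_ms[keep],
        trial_length_ms=seq.trial_length_ms,
    )


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def build_emissions(
    egp: ExpertGazePattern, axis_sigma_divisor: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed Gaussian emission parameters from ROI ellipse geometry.

    Mean = ROI centroid; covariance = R(theta) diag((major/d)^2, (minor/d)^2)
    R(theta)^T with d = ``axis_sigma_divisor``, so the drawn ellipse outline
    sits at about the 2-sigma contour for the default d = 4. Covariances are
    jittered to symmetric positive definite if rasterisation noise made them
    borderline.
    """
    n = egp.n_states
    means = np.empty((n, 2))
    covs = np.empty((n, 2, 2))
    for i, roi in enumerate(egp.rois):
        means[i] = (roi.cx, roi.cy)
        sa = roi.major_axis_length / axis_sigma_divisor
        sb = roi.minor_axis_length / axis_sigma_divisor
        c, s = np.cos(roi.orientation), np.sin(roi.orientation)
        rot = np.array([[c, -s], [s, c]])
        cov = rot @ np.diag([sa**2, sb**2]) @ rot.T
        cov = 0.5 * (cov + cov.T)
        if np.linalg.eigvalsh(cov)[0] <= 0:
            cov += 1e-6 * np.eye(2)
        covs[i] = cov
    return means, covs


def _log_emission_matrix(
    coords: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> np.ndarray:
    """log N(x_t; mu_j, Sigma_j) for all t, j -> (T, n)."""
    T = len(coords)
    n = len(means)
    logB = np.empty((T, n))
    for j in range(n):
        diff = coords - means[j]
        chol = np.linalg.cholesky(covs[j])
        z = np.linalg.solve(chol, diff.T)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        logB[:, j] = -0.5 * (np.sum(z**2, axis=0) + logdet + 2 * np.log(2 * np.pi))
    if not np.all(np.isfinite(logB)):
        raise ValueError("non-finite emission log-density; check data range")
    return logB


# ---------------------------------------------------------------------------
# forward-backward (scaled)
# ---------------------------------------------------------------------------

def _forward_backward(
    log_pi: np.ndarray, log_A: np.ndarray, logB: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaled forward-backward.

    Parameters may be sub-normalised (exp of expected logs). Returns
    (log-normaliser, gamma (T,n), xi_sum (n,n)).
    """
    T, n = logB.shape
    pi = np.exp(log_pi)
    A = np.exp(log_A)
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])

    alpha_f = np.empty((T, n))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha_f[0] = a / c[0]
    for t in range(1, T):
        a = (alpha_f[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha_f[t] = a / c[t]

    beta_b = np.empty((T, n))
    beta_b[-1] = 1.0
    xi_sum = np.zeros((n, n))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta_b[t + 1]
        beta_b[t] = (A @ bb) / c[t + 1]
        xi = alpha_f[t][:, None] * A * bb[None, :] / c[t + 1]
        xi_sum += xi

    gamma = alpha_f * beta_b
    gamma /= gamma.sum(axis=1, keepdims=True)
    log_z = float(np.log(c).sum() + shift.sum())
    return log_z, gamma, xi_sum


def _dirichlet_kl(post: np.ndarray, prior: np.ndarray) -> float:
    """KL(Dir(post) || Dir(prior)) for 1-D parameter vectors."""
    s_post = post.sum()
    return float(
        gammaln(s_post)
        - gammaln(post).sum()
        - gammaln(prior.sum())
        + gammaln(prior).sum()
        + np.dot(post - prior, digamma(post) - digamma(s_post))
    )


def fit_vb_hmm(
    seq: FixationSequence,
    emissions: tuple[np.ndarray, np.ndarray],
    prior_strength: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    window_s: tuple[float, float] | None = None,
) -> GazeHMM:
    """Variational Bayes over ``pi`` and ``A`` with fixed Gaussian emissions.

    E-step: forward-backward with exp(E[log pi]), exp(E[log A]) (digammas of
    the current Dirichlet posteriors) and the fixed emission densities at the
    fixation coordinates. M-step: posterior = symmetric prior + expected
    initial-state / transition counts. Iterates until the bound improves by
    less than ``tol`` or ``max_iter`` is reached; point estimates are the
    posterior means.
    """
    if len(seq) == 0:
        raise ValueError("cannot fit an HMM to a window with 0 fixations")
    means, covs = emissions
    n = len(means)
    logB = _log_emission_matrix(seq.coords, means, covs)

    prior_pi = np.full(n, prior_strength, dtype=float)
    prior_A = np.full((n, n), prior_strength, dtype=float)
    alpha = prior_pi.copy()
    beta = prior_A.copy()

    elbo_trace: list[float] = []
    converged = False
    gamma = np.ones((len(seq), n)) / n
    for _ in range(max_iter):
        # E-step under the current Dirichlet posteriors; the bound
        # F = log Z~ - KL(q(pi)||prior) - sum_j KL(q(A_j)||prior)
        # with q(Z) optimal for exp(E[log params]) is non-decreasing
        # across alternating E/M updates.
        log_pi = digamma(alpha) - digamma(alpha.sum())
        log_A = digamma(beta) - digamma(beta.sum(axis=1, keepdims=True))
        log_z, gamma, xi_sum = _forward_backward(log_pi, log_A, logB)
        elbo = (
            log_z
            - _dirichlet_kl(alpha, prior_pi)
            - sum(_dirichlet_kl(beta[j], prior_A[j]) for j in range(n))
        )
        if elbo_trace and elbo - elbo_trace[-1] < tol:
            elbo_trace.append(elbo)
            converged = True
            break
        elbo_trace.append(elbo)
        alpha = prior_pi + gamma[0]
        beta = prior_A + xi_sum

    occupancy = gamma.sum(axis=0)
    occupancy = occupancy / occupancy.sum()
    return GazeHMM(
        means=means,
        covs=covs,
        alpha=alpha,
        beta=beta,
        prior_strength=prior_strength,
        window_s=window_s,
        occupancy=occupancy,
        n_obs=len(seq),
        elbo_trace=elbo_trace,
        converged=converged,
    )


def sequence_loglik(hmm: GazeHMM, seq: FixationSequence) -> float:
    """Forward-algorithm marginal log-likelihood (nats) under posterior means.

    Computed with per-step scaling, so sequences up to T ~ 10,000 do not
    underflow.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence has no likelihood")
    logB = _log_emission_matrix(seq.coords, hmm.means, hmm.covs)
    log_z, _, _ = _forward_backward(
        np.log(hmm.pi), np.log(hmm.A), logB
    )
    return log_z
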