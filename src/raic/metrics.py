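"""Gaze-rating statistics: normalised ratings, k-means groups, VH-LL, CVB.

VH-LL scores the expert's ordered ROI path under a participant's fitted
transition model: log pi(s1) + sum_m log A(s_m, s_{m+1}) along the path
1 -> 2 -> ... -> n. CVB is the Pearson correlation between VH-LL and the
per-participant-normalised impression rating (e.g. "beauty") within a rating
group. Group comparisons use a variance F-test gating an equal-variance
t-test versus a rank-sum test, one-tailed in the hypothesised direction.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .hmm import sequence_loglik
from .types import EvaluationGroups, ExpertGazePattern, FixationSequence, GazeHMM

__all__ = [
    "ATTRIBUTES",
    "normalize_ratings",
    "assign_groups_kmeans",
    "vh_ll",
    "cvb",
    "consistency_and_tests",
    "effect_size_and_power",
]

ATTRIBUTES = ["composition", "colour_harmony", "static_dynamic", "favourability", "beauty"]


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def normalize_ratings(table: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-standardise ratings within participant x attribute across images.

    Adds ``normalised`` and ``degenerate`` columns. The default denominator
    is the population SD (``ddof=0``); a zero-variance (or single-rating)
    participant is flagged degenerate with normalised value 0.
    """
    out = table.copy()
    out["normalised"] = 0.0
    out["degenerate"] = False
    for (_, _), idx in out.groupby(["participant_id", "attribute"]).groups.items():
        vals = out.loc[idx, "raw"].to_numpy(dtype=float)
        sd = vals.std(ddof=ddof) if len(vals) > ddof else 0.0
        if len(vals) < 2 or sd == 0.0:
            out.loc[idx, "degenerate"] = True
        else:
            out.loc[idx, "normalised"] = (vals - vals.mean()) / sd
    return out


def assign_groups_kmeans(
    values: pd.Series,
    image_id: str = "",
    attribute: str = "",
    k: int = 3,
    seed: int = 0,
    n_init: int = 25,
) -> EvaluationGroups:
    """1-D k-means into high/middle/low groups for one image x attribute.

    ``values`` maps participant_id -> normalised rating. Clusters are sorted
    by centroid so that the highest-centroid cluster is "high". When all
    values are identical the split is degenerate: everyone is "middle".
    """
    if len(values) < k:
        raise ValueError(f"need >= {k} participants, have {len(values)}")
    arr = values.to_numpy(dtype=float).reshape(-1, 1)
    if np.ptp(arr) == 0.0:
        return EvaluationGroups(
            image_id=image_id,
            attribute=attribute,
            assignment={p: "middle" for p in values.index},
            centroids={"high": float(arr[0, 0]), "middle": float(arr[0, 0]), "low": float(arr[0, 0])},
            degenerate=True,
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(arr)
    order = np.argsort(km.cluster_centers_.ravel())[::-1]  # high first
    names = ["high", "middle", "low"]
    relabel = {int(c): names[rank] for rank, c in enumerate(order)}
    assignment = {p: relabel[int(lab)] for p, lab in zip(values.index, km.labels_)}
    centroids = {names[rank]: float(km.cluster_centers_.ravel()[c]) for rank, c in enumerate(order)}
    return EvaluationGroups(
        image_id=image_id, attribute=attribute, assignment=assignment, centroids=centroids
    )


# ---------------------------------------------------------------------------
# VH-LL and CVB
# ---------------------------------------------------------------------------

def vh_ll(
    hmm: GazeHMM, egp: ExpertGazePattern, length_normalised: bool = False
) -> float:
    """Log-likelihood (nats) of the expert path under the participant model.

    The expert path visits the ROIs in index order; the statistic is
    log pi(s1) + sum log A(s_m, s_{m+1}) at the posterior-mean parameters.
    The Dirichlet posterior keeps every probability strictly positive, so
    the value is finite and <= 0.
    """
    n = egp.n_states
    if hmm.n_states != n:
        raise ValueError("model and expert pattern state spaces differ")
    pi, A = hmm.pi, hmm.A
    ll = math.log(pi[0])
    for m in range(n - 1):
        ll += math.log(A[m, m + 1])
    return ll / n if length_normalised else ll


def vh_ll_reverse(
    hmm: GazeHMM, seq: FixationSequence
) -> float:
    """Alternative direction: participant fixation data scored under a model."""
    return sequence_loglik(hmm, seq)


def cvb(vhll: np.ndarray, ratings: np.ndarray, subset: np.ndarray | None = None) -> dict:
    """Pearson correlation between VH-LL and normalised ratings in a group.

    Returns {"r", "n", "flag"}; fewer than 3 members or zero variance in
    either variable yields r = NaN with an explanatory flag rather than an
    exception.
    """
    vhll = np.asarray(vhll, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if subset is not None:
        vhll, ratings = vhll[subset], ratings[subset]
    n = len(vhll)
    if n < 3:
        return {"r": float("nan"), "n": n, "flag": "too_few"}
    if np.ptp(vhll) == 0.0 or np.ptp(ratings) == 0.0:
        return {"r": float("nan"), "n": n, "flag": "zero_variance"}
    r, _ = stats.pearsonr(vhll, ratings)
    return {"r": float(r), "n": n, "flag": "ok"}


def consistency_and_tests(
    cvb_high: float,
    cvb_low: float,
    expected_direction: str,
    vhll_high: np.ndarray,
    vhll_low: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Hypothesis-consistency label plus the gated one-tailed group test.

    ``expected_direction`` is "positive-message" (hypothesis: the high-rated
    group tracks the expert path more closely) or "negative-message" (the
    reverse). The label compares the two CVB values; the significance flag
    comes from a variance F-test gating an equal-variance t-test versus a
    rank-sum test on the VH-LL values, one-tailed in the hypothesised
    direction.
    """
    if expected_direction not in ("positive-message", "negative-message"):
        raise ValueError(f"unknown direction {expected_direction!r}")
    if np.isnan(cvb_high) or np.isnan(cvb_low):
        label = "none"
    else:
        hi_gt = cvb_high > cvb_low
        lo_gt = cvb_low > cvb_high
        if expected_direction == "positive-message":
            label = "consistent" if hi_gt else ("inconsistent" if lo_gt else "none")
        else:
            label = "consistent" if lo_gt else ("inconsistent" if hi_gt else "none")

    a = np.asarray(vhll_high, dtype=float)
    b = np.asarray(vhll_low, dtype=float)
    record = {"label": label, "test": None, "f_p": float("nan"), "p": float("nan"),
              "significant": False}
    if len(a) < 2 or len(b) < 2:
        return record
    # variance homogeneity: two-sided F test on sample variances
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        record.update(test="t", f_p=1.0, p=0.5)
        return record
    f = va / vb if vb > 0 else np.inf
    dfa, dfb = len(a) - 1, len(b) - 1
    f_p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    f_p = min(f_p, 1.0)
    greater_first = expected_direction == "positive-message"
    alternative = "greater" if greater_first else "less"
    if f_p >= alpha:
        t_res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
        record.update(test="t", f_p=float(f_p), p=float(t_res.pvalue))
    else:
        w_res = stats.mannwhitneyu(a, b, alternative=alternative)
        record.update(test="wilcoxon", f_p=float(f_p), p=float(w_res.pvalue))
    record["significant"] = bool(record["p"] < alpha)
    return record


# ---------------------------------------------------------------------------
# design-stage power computation
# ---------------------------------------------------------------------------

def effect_size_and_power(
    r: float, alpha: float = 0.05, power: float = 0.80
) -> dict:
    """Convert a correlation effect size to d and the required group size.

    d = 2r / sqrt(1 - r^2); the per-group n for a one-tailed two-group test
    at the given alpha/power follows the normal approximation
    n = ceil(((z_{1-alpha} + z_{power}) / d)^2), and the study total is three
    rating groups of that size.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    d = 2.0 * r / math.sqrt(1.0 - r * r)
    if d == 0.0:
        return {"d": 0.0, "n_per_group": float("inf"), "n_total": float("inf"),
                "flag": "infinite_n"}
    z = stats.norm.ppf(1 - alpha) + stats.norm.ppf(power)
    n_per_group = math.ceil((z / abs(d)) ** 2)
    return {"d": d, "n_per_group": n_per_group, "n_total": 3 * n_per_group, "flag": "ok"}
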