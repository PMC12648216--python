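"""Inter-coder reliability for multi-label verbal-response coding.

Three coders assign subsets of a 9-category codebook (L1..L7, M1, M2) to
each verbal response. Agreement is summarised per category as Fleiss' kappa
on presence/absence with a bootstrap CI and a full-agreement rate, and at
the multi-label level as pairwise Jaccard similarity statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CODEBOOK",
    "fleiss_kappa_from_counts",
    "fleiss_kappa_ci",
    "full_agreement",
    "jaccard_stats",
    "reliability_report",
]

CODEBOOK = ["L1", "L2", "L3", "L4", "L5", "L6", "L7", "M1", "M2"]


def fleiss_kappa_from_counts(counts: np.ndarray) -> tuple[float, str]:
    """Fleiss' kappa from an items x categories rating-count table.

    Every row must sum to the same number of raters. Returns (kappa, flag);
    kappa is NaN with flag ``"undefined"`` when expected agreement is 1
    (all ratings in a single category) unless observed agreement is also
    perfect, in which case kappa = 1 with flag ``"perfect"``.
    """
    counts = np.asarray(counts, dtype=float)
    n_items, _ = counts.shape
    raters = counts.sum(axis=1)
    if not np.allclose(raters, raters[0]):
        raise ValueError("all items must be rated by the same number of raters")
    m = raters[0]
    if m < 2:
        raise ValueError("need >= 2 raters")
    p_i = (np.sum(counts * (counts - 1), axis=1)) / (m * (m - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n_items * m)
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0 - 1e-15:
        # every rating in one category: chance agreement is 1, kappa is 0/0
        return float("nan"), "undefined"
    if p_bar >= 1.0 - 1e-15:
        return 1.0, "perfect"
    return (p_bar - p_e) / (1.0 - p_e), "ok"


def _universe(responses: pd.DataFrame) -> tuple[list, list]:
    """Full response/coder id lists.

    Taken from ``df.attrs`` when a generator recorded them (a response with
    an empty label set from every coder leaves no row but still counts);
    otherwise inferred from the data.
    """
    rids = responses.attrs.get("response_ids") or sorted(responses["response_id"].unique())
    coders = responses.attrs.get("coders") or sorted(responses["coder_id"].unique())
    return list(rids), list(coders)


def _presence_counts(responses: pd.DataFrame, category: str) -> np.ndarray:
    """Response x {present, absent} counts across coders for one category."""
    rids, coders = _universe(responses)
    has = (
        responses[responses["label"] == category]
        .groupby(["response_id", "coder_id"])
        .size()
        .clip(upper=1)
    )
    present = np.zeros(len(rids), dtype=int)
    idx = {r: i for i, r in enumerate(rids)}
    for (rid, _), _v in has.items():
        present[idx[rid]] += 1
    m = len(coders)
    return np.column_stack([present, m - present])


def fleiss_kappa_ci(
    responses: pd.DataFrame,
    category: str,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Fleiss' kappa for one category with a percentile bootstrap CI.

    ``responses`` is tidy with columns response_id, coder_id, label (one row
    per assigned label). Bootstrap resamples responses with replacement.
    """
    counts = _presence_counts(responses, category)
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 responses")
    kappa, flag = fleiss_kappa_from_counts(counts)
    rng = np.random.default_rng(seed)
    n = counts.shape[0]
    boots = []
    for _ in range(n_boot):
        k, f = fleiss_kappa_from_counts(counts[rng.integers(0, n, n)])
        if f != "undefined":
            boots.append(k)
    if boots and np.isfinite(kappa):
        lo, hi = np.percentile(boots, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    else:
        lo = hi = float("nan")
    return {
        "category": category,
        "n": n,
        "kappa": kappa,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "flag": flag,
    }


def full_agreement(responses: pd.DataFrame, category: str) -> float:
    """Fraction of responses on which all coders agree on presence/absence."""
    counts = _presence_counts(responses, category)
    m = counts[0].sum()
    return float(np.mean((counts[:, 0] == 0) | (counts[:, 0] == m)))


def _label_sets(responses: pd.DataFrame) -> dict[tuple, frozenset]:
    rids, coders = _universe(responses)
    sets: dict[tuple, set] = {(rid, cid): set() for rid in rids for cid in coders}
    for row in responses.itertuples(index=False):
        sets[(row.response_id, row.coder_id)].add(row.label)
    return {k: frozenset(v) for k, v in sets.items()}


def jaccard_stats(responses: pd.DataFrame, empty_empty: float = 1.0) -> dict:
    """Multi-label Jaccard agreement over all response x coder-pair values.

    Jaccard = |A&B|/|A|B|; two empty label sets score ``empty_empty``
    (default 1: agreement on "no labels"). Reports the mean, median and SD
    of the pooled values plus the mean of per-response medians.
    """
    sets = _label_sets(responses)
    rids, coders = _universe(responses)
    if len(coders) < 2:
        raise ValueError("need >= 2 coders")
    pooled = []
    per_resp_medians = []
    for rid in rids:
        vals = []
        for i in range(len(coders)):
            for j in range(i + 1, len(coders)):
                a, b = sets[(rid, coders[i])], sets[(rid, coders[j])]
                if not a and not b:
                    vals.append(empty_empty)
                else:
                    vals.append(len(a & b) / len(a | b))
        pooled.extend(vals)
        per_resp_medians.append(float(np.median(vals)))
    pooled_arr = np.array(pooled)
    return {
        "mean_pairwise": float(pooled_arr.mean()),
        "median": float(np.median(pooled_arr)),
        "sd": float(pooled_arr.std(ddof=1)) if len(pooled_arr) > 1 else 0.0,
        "mean_of_per_response_medians": float(np.mean(per_resp_medians)),
    }


def reliability_report(
    responses: pd.DataFrame,
    categories: list[str] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-category kappa/CI/full-agreement table over the codebook."""
    categories = categories or CODEBOOK
    rows = []
    for cat in categories:
        res = fleiss_kappa_ci(responses, cat, n_boot=n_boot, seed=seed)
        res["full_agreement"] = full_agreement(responses, cat)
        rows.append(res)
    return pd.DataFrame(rows)
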