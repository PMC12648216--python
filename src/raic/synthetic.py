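"""Synthetic study generator.

Emulates every input the analysis consumes: multi-expert elliptical ROI
annotations on a 1,920 x 1,080 canvas, two-strategy (focused/explorative)
Markov scanpaths over the ROI state space in 30-s trials, 10-point ratings
with a planted correlation between "beauty" and a supplied gaze-similarity
value, AR(1) pupil traces at 300 Hz with a group offset, and 3-coder
multi-label sets with a tunable agreement level. All randomness flows from
``SyntheticConfig.seed`` through named substreams, so identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .consensus import AnnotationSet
from .types import ROI, EvaluationGroups, ExpertGazePattern, FixationSequence, GazeHMM, PupilTrace

__all__ = [
    "SyntheticConfig",
    "gen_roi_layout",
    "render_labelled_mask",
    "gen_annotation_set",
    "gen_strategy_hmms",
    "perturb_hmm",
    "sample_scanpaths",
    "gen_ratings_linked",
    "gen_pupil_traces",
    "gen_coder_labels",
    "simulate_study",
]

# substream tags so each generator draws from an independent stream
_TAG_LAYOUT, _TAG_ANNOT, _TAG_HMM, _TAG_SCAN, _TAG_RATE, _TAG_PUPIL, _TAG_CODER = range(7)


def _stable_hash(*parts) -> int:
    """Process-independent 31-bit hash (Python's str hash is salted)."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF

# multi-label base rates per codebook category (L1..L7, M1, M2); chosen to
# span rare and common categories like real free-response codes
_CATEGORY_RATES = np.array([0.30, 0.12, 0.08, 0.25, 0.20, 0.06, 0.45, 0.35, 0.30])


@dataclass
class SyntheticConfig:
    canvas_width: int = 1920
    canvas_height: int = 1080
    n_rois: int = 13
    n_experts: int = 4
    n_participants: int = 48
    trial_seconds: float = 30.0
    fixation_rate: float = 3.0  # fixations per second
    planted_correlation: float = 0.30
    pupil_group_offset: float = 0.1  # a.u.; high-rated group shifted by -offset
    pupil_ar_coeff: float = 0.9
    pupil_noise_sd: float = 0.05  # stationary SD of the AR(1) noise, a.u.
    pupil_participant_sd: float = 0.06  # trial-level arousal offset SD, a.u.
    coder_agreement: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("canvas_width", "canvas_height", "n_experts", "n_participants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 1 <= self.n_rois <= 14:
            raise ValueError(f"n_rois must be in [1, 14], got {self.n_rois}")
        if self.trial_seconds <= 0:
            raise ValueError("trial_seconds must be positive")
        if self.fixation_rate <= 0:
            raise ValueError("fixation_rate must be positive")
        if not -1.0 <= self.planted_correlation <= 1.0:
            raise ValueError("planted_correlation must be in [-1, 1]")
        if not 0.0 <= self.pupil_ar_coeff < 1.0:
            raise ValueError("pupil_ar_coeff must be in [0, 1)")
        if not 0.0 <= self.coder_agreement <= 1.0:
            raise ValueError("coder_agreement must be a probability")

    def rng(self, tag: int, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag, extra])


# ---------------------------------------------------------------------------
# ROI layout and annotation masks
# ---------------------------------------------------------------------------

def gen_roi_layout(cfg: SyntheticConfig, image_index: int = 0) -> ExpertGazePattern:
    """Ground-truth layout: non-overlapping ellipses by rejection sampling."""
    rng = cfg.rng(_TAG_LAYOUT, image_index)
    w, h = cfg.canvas_width, cfg.canvas_height
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    rois: list[ROI] = []
    attempts = 0
    while len(rois) < cfg.n_rois:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place non-overlapping ROIs; canvas too small")
        a = rng.uniform(70, 120)  # semi-major, px
        b = a * rng.uniform(0.45, 0.85)
        cx = rng.uniform(a, w - a)
        cy = rng.uniform(a, h - a)
        if any(np.hypot(cx - x0, cy - y0) < a + r0 + 5 for (x0, y0), r0 in zip(centers, radii)):
            continue
        theta = rng.uniform(0, np.pi)
        centers.append((cx, cy))
        radii.append(a)
        rois.append(
            ROI(
                index=len(rois) + 1,
                cx=cx,
                cy=cy,
                major_axis_length=2 * a,
                minor_axis_length=2 * b,
                orientation=theta,
            )
        )
    return ExpertGazePattern(image_id=f"img{image_index:02d}", rois=rois)


def render_labelled_mask(
    rois: list[ROI], canvas: tuple[int, int]
) -> np.ndarray:
    """Rasterise ellipses into a labelled uint8 mask (0 = background)."""
    w, h = canvas
    out = np.zeros((h, w), dtype=np.uint8)
    for roi in rois:
        a = roi.major_axis_length / 2.0
        b = roi.minor_axis_length / 2.0
        r = int(np.ceil(max(a, b)))
        x0 = max(int(roi.cx) - r, 0)
        x1 = min(int(roi.cx) + r + 1, w)
        y0 = max(int(roi.cy) - r, 0)
        y1 = min(int(roi.cy) + r + 1, h)
        xs = np.arange(x0, x1) - roi.cx
        ys = np.arange(y0, y1) - roi.cy
        X, Y = np.meshgrid(xs, ys)
        c, s = np.cos(roi.orientation), np.sin(roi.orientation)
        u = X * c + Y * s
        v = -X * s + Y * c
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        out[y0:y1, x0:x1][inside] = roi.index
    return out


def gen_annotation_set(
    cfg: SyntheticConfig,
    image_index: int = 0,
    perturbation: float = 1.0,
    overgeneralised_expert: str | None = None,
    ground_truth: ExpertGazePattern | None = None,
) -> tuple[AnnotationSet, ExpertGazePattern]:
    """Expert annotation masks sharing one ground-truth layout.

    Each expert's ellipses are jittered in centroid, axes and orientation;
    with probability scaling in ``perturbation`` an ROI is dropped or
    oversized. ``perturbation=0`` reproduces the ground truth exactly for
    every expert. If ``overgeneralised_expert`` names an expert, that mask
    additionally contains a canvas-scale ellipse pushing its coverage above
    the 50% filter threshold.
    """
    truth = ground_truth or gen_roi_layout(cfg, image_index)
    rng = cfg.rng(_TAG_ANNOT, image_index)
    canvas = (cfg.canvas_width, cfg.canvas_height)
    masks: dict[str, np.ndarray] = {}
    for e in range(cfg.n_experts):
        eid = f"e{e + 1}"
        rois: list[ROI] = []
        for roi in truth.rois:
            if perturbation > 0 and rng.random() < 0.06 * perturbation and len(truth.rois) > 2:
                continue  # expert missed this ROI
            scale = float(np.exp(rng.normal(0.0, 0.2) * perturbation))
            if perturbation > 0 and rng.random() < 0.04 * perturbation:
                scale *= 1.6  # oversized annotation
            rois.append(
                ROI(
                    index=len(rois) + 1,
                    cx=float(np.clip(roi.cx + rng.normal(0, 55) * perturbation, 1, canvas[0] - 2)),
                    cy=float(np.clip(roi.cy + rng.normal(0, 55) * perturbation, 1, canvas[1] - 2)),
                    major_axis_length=roi.major_axis_length * scale,
                    minor_axis_length=roi.minor_axis_length * scale,
                    orientation=(roi.orientation + rng.normal(0, 0.3) * perturbation) % np.pi,
                )
            )
        if eid == overgeneralised_expert:
            giant = ROI(
                index=1,
                cx=canvas[0] / 2,
                cy=canvas[1] / 2,
                major_axis_length=0.90 * canvas[0],
                minor_axis_length=0.86 * canvas[1],
                orientation=0.0,
            )
            rois = [giant] + [
                ROI(index=r.index + 1, cx=r.cx, cy=r.cy,
                    major_axis_length=r.major_axis_length,
                    minor_axis_length=r.minor_axis_length,
                    orientation=r.orientation)
                for r in rois
            ]
        masks[eid] = render_labelled_mask(rois, canvas)
    return AnnotationSet(image_id=truth.image_id, canvas=canvas, masks=masks), truth


# ---------------------------------------------------------------------------
# strategy models and scanpaths
# ---------------------------------------------------------------------------

def gen_strategy_hmms(
    egp: ExpertGazePattern, strategy: str, seed: int = 0, axis_sigma_divisor: float = 4.0
) -> GazeHMM:
    """A representative strategy chain over the EGP state space.

    ``focused``: heavy self-transitions (mean diagonal >= 0.6) with the
    remaining mass concentrated on a small subset of ROIs. ``explorative``:
    near-uniform rows (row entropy >= 80% of log n). Rows are exactly
    stochastic; emissions come from the ROI geometry.
    """
    from .hmm import build_emissions

    n = egp.n_states
    if n < 2:
        raise ValueError("strategy models need >= 2 ROIs (degenerate model)")
    rng = np.random.default_rng([seed, _TAG_HMM, _stable_hash(strategy)])
    if strategy == "focused":
        A = np.zeros((n, n))
        focus = rng.choice(n, size=min(3, n), replace=False)
        for j in range(n):
            self_p = rng.uniform(0.62, 0.72)
            off = rng.dirichlet(np.where(np.isin(np.arange(n), focus), 4.0, 0.4)[
                np.arange(n) != j
            ])
            A[j, j] = self_p
            A[j, np.arange(n) != j] = (1 - self_p) * off
        pi = rng.dirichlet(np.where(np.isin(np.arange(n), focus), 6.0, 0.5))
    elif strategy == "explorative":
        A = rng.dirichlet(np.full(n, 50.0), size=n)
        pi = rng.dirichlet(np.full(n, 20.0))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    # gamma sampling at tiny concentrations can underflow to exact zeros;
    # keep every transition strictly positive
    A = np.maximum(A, 1e-12)
    A /= A.sum(axis=1, keepdims=True)
    pi = np.maximum(pi, 1e-12)
    pi /= pi.sum()
    means, covs = build_emissions(egp, axis_sigma_divisor)
    # encode point-mass parameters as strong Dirichlet posteriors
    hmm = GazeHMM(
        means=means,
        covs=covs,
        alpha=pi * 1e6,
        beta=A * 1e6,
        occupancy=_stationary(A),
        n_obs=int(round(30 * 3)),
    )
    return hmm


def _stationary(A: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eig(A.T)
    v = np.abs(np.real(evecs[:, np.argmax(np.real(evals))]))
    return v / v.sum()


def perturb_hmm(hmm: GazeHMM, jitter: float, rng: np.random.Generator) -> GazeHMM:
    """Individual variant of a strategy model: Dirichlet-resampled rows.

    ``jitter`` in (0, 1]: smaller means tighter around the strategy
    representative (concentration ~ 1/jitter per row).
    """
    conc = max(1.0 / max(jitter, 1e-6), 1.0) * 50.0
    A = np.vstack([rng.dirichlet(np.maximum(row * conc, 1e-3)) for row in hmm.A])
    A = np.maximum(A, 1e-12)
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.maximum(hmm.pi * conc, 1e-3))
    pi = np.maximum(pi, 1e-12)
    pi /= pi.sum()
    return GazeHMM(
        means=hmm.means,
        covs=hmm.covs,
        alpha=pi * 1e6,
        beta=A * 1e6,
        occupancy=_stationary(A),
        n_obs=hmm.n_obs,
    )


def sample_scanpaths(
    hmm: GazeHMM,
    cfg: SyntheticConfig,
    participant_ids: list[str],
    image_id: str,
    condition: str = "colour",
    inject_gap_for: set[str] | None = None,
    gap_span_s: tuple[float, float] = (10.0, 12.6),
    substream: int = 0,
) -> list[FixationSequence]:
    """Markov-chain fixation sequences for a set of participants.

    Fixation durations are log-normal (median 250 ms) and consecutive
    fixations are separated by a short saccade interval whose mean is chosen
    so that fixations arrive at ``fixation_rate`` on average — the trial is
    tiled with fixations, as in real free viewing, so no large gaps occur
    unless injected. Positions are drawn from the visited state's Gaussian.
    Participants in ``inject_gap_for`` have fixations inside ``gap_span_s``
    removed, creating a no-fixation span exceeding the 2-s exclusion
    threshold.
    """
    if cfg.fixation_rate <= 0:
        raise ValueError("fixation rate must be positive")
    inject_gap_for = inject_gap_for or set()
    pi, A = hmm.pi, hmm.A
    chols = np.linalg.cholesky(hmm.covs)
    mean_dur = 0.250 * np.exp(0.35**2 / 2)  # log-normal mean, s
    mean_sacc = max(1.0 / cfg.fixation_rate - mean_dur, 0.02)
    out: list[FixationSequence] = []
    for pid in participant_ids:
        rng = cfg.rng(_TAG_SCAN, _stable_hash(pid, image_id, substream))
        n_max = int(cfg.trial_seconds * cfg.fixation_rate * 2) + 8
        durations = np.exp(rng.normal(np.log(0.250), 0.35, size=n_max))
        saccades = rng.exponential(mean_sacc, size=n_max)
        onsets = np.concatenate([[saccades[0]], saccades[0] + np.cumsum(durations[:-1] + saccades[1:])])
        keep_n = onsets < cfg.trial_seconds
        onsets, durations = onsets[keep_n], durations[keep_n]
        if len(onsets) == 0:
            onsets = np.array([0.05 * cfg.trial_seconds])
            durations = np.array([0.25])
        durations = np.minimum(durations, cfg.trial_seconds - onsets)
        states = np.empty(len(onsets), dtype=int)
        states[0] = rng.choice(len(pi), p=pi)
        for t in range(1, len(onsets)):
            states[t] = rng.choice(len(pi), p=A[states[t - 1]])
        z = rng.standard_normal((len(onsets), 2))
        pos = hmm.means[states] + np.einsum("tij,tj->ti", chols[states], z)
        keep = np.ones(len(onsets), dtype=bool)
        if pid in inject_gap_for:
            keep = (onsets < gap_span_s[0]) | (onsets >= gap_span_s[1])
            if not keep.any():
                keep[0] = True
        out.append(
            FixationSequence(
                participant_id=pid,
                image_id=image_id,
                condition=condition,
                x=pos[keep, 0],
                y=pos[keep, 1],
                onset_ms=onsets[keep] * 1000.0,
                duration_ms=durations[keep] * 1000.0,
                trial_length_ms=cfg.trial_seconds * 1000.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ratings, pupil, coder labels
# ---------------------------------------------------------------------------

def gen_ratings_linked(similarities: pd.DataFrame, cfg: SyntheticConfig) -> pd.DataFrame:
    """Integer 1-10 ratings with "beauty" linked to gaze similarity.

    ``similarities`` has columns participant_id, image_id, similarity
    (typically VH-LL values). Per image, the latent beauty score is
    rho * z(similarity) + sqrt(1 - rho^2) * noise with rho =
    ``planted_correlation``, then mapped affinely to the 10-point scale and
    rounded. "favourability" shares part of the beauty latent; the other
    attributes are independent. A constant similarity column is flagged
    degenerate (``df.attrs["degenerate_images"]``).
    """
    if similarities["participant_id"].nunique() < 3:
        raise ValueError("need >= 3 participants")
    rho = cfg.planted_correlation
    rng = cfg.rng(_TAG_RATE)
    rows = []
    degenerate_images = []
    for image_id, sub in similarities.groupby("image_id", sort=True):
        sub = sub.sort_values("participant_id")
        s = sub["similarity"].to_numpy(dtype=float)
        if np.ptp(s) == 0.0:
            degenerate_images.append(image_id)
            z = np.zeros_like(s)
        else:
            z = (s - s.mean()) / s.std()
        eps = rng.standard_normal(len(s))
        beauty = rho * z + np.sqrt(max(1 - rho**2, 0.0)) * eps
        fav = 0.75 * beauty + 0.66 * rng.standard_normal(len(s))
        others = {
            attr: rng.standard_normal(len(s))
            for attr in ("composition", "colour_harmony", "static_dynamic")
        }
        seen = rng.random(len(s)) < 0.15
        latents = {"beauty": beauty, "favourability": fav, **others}
        for attr, latent in latents.items():
            raw = np.clip(np.rint(5.5 + 1.8 * latent), 1, 10).astype(int)
            for pid, val, sb in zip(sub["participant_id"], raw, seen):
                rows.append(
                    {
                        "participant_id": pid,
                        "image_id": image_id,
                        "attribute": attr,
                        "raw": int(val),
                        "seen_before": bool(sb),
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["degenerate_images"] = degenerate_images
    return out


def gen_pupil_traces(
    groups: EvaluationGroups,
    cfg: SyntheticConfig,
    n_spikes: int = 0,
    missing_run: int = 0,
) -> list[PupilTrace]:
    """AR(1) pupil traces (300 Hz x 30 s) with a high-group constriction.

    Every participant x eye gets a personal baseline; the trial trace is
    baseline + a trial-level arousal offset (SD ``pupil_participant_sd``,
    shared across eyes, absent from the rest screen, so baseline correction
    cannot remove it) + AR(1) noise, shifted by -``pupil_group_offset`` for
    members of the high-rated group. The 5-s rest trace shares only the
    baseline. Optional injections: ``n_spikes`` +10-sigma spikes and one
    missing run of ``missing_run`` samples per trial.
    """
    fs = 300.0
    n_trial = int(cfg.trial_seconds * fs)
    n_rest = int(5 * fs)
    a = cfg.pupil_ar_coeff
    innov_sd = cfg.pupil_noise_sd * np.sqrt(1 - a**2)
    out: list[PupilTrace] = []
    for pid in sorted(groups.assignment):
        prng = cfg.rng(_TAG_PUPIL, _stable_hash(pid, groups.image_id))
        base = prng.normal(4.0, 0.3)
        arousal = prng.normal(0.0, cfg.pupil_participant_sd)
        offset = arousal - (
            cfg.pupil_group_offset if groups.assignment[pid] == "high" else 0.0
        )
        for eye in ("left", "right"):
            def ar1(n: int) -> np.ndarray:
                eta = prng.normal(0.0, innov_sd, n)
                x = lfilter([1.0], [1.0, -a], eta)
                return x

            rest = base + ar1(n_rest)
            samples = base + offset + ar1(n_trial)
            if n_spikes > 0:
                pos = prng.integers(100, n_trial - 100, n_spikes)
                samples[pos] += 10.0 * cfg.pupil_noise_sd
            if missing_run > 0:
                start = int(prng.integers(200, n_trial - missing_run - 200))
                samples[start:start + missing_run] = np.nan
            out.append(
                PupilTrace(
                    participant_id=pid,
                    image_id=groups.image_id,
                    eye=eye,
                    samples=samples,
                    rest_trace=rest,
                    fs=fs,
                )
            )
    return out


def gen_coder_labels(n_items: int, cfg: SyntheticConfig) -> pd.DataFrame:
    """3-coder multi-label sets over the 9-category codebook.

    Ground-truth label presence is Bernoulli per category; each coder copies
    the truth with probability ``coder_agreement`` and otherwise flips an
    independent fair coin, so agreement 1 gives identical sets and agreement
    0 gives independent random labelling (kappa ~ 0).
    """
    from .reliability import CODEBOOK

    if n_items < 2:
        raise ValueError("need >= 2 items")
    rng = cfg.rng(_TAG_CODER)
    truth = rng.random((n_items, len(CODEBOOK))) < _CATEGORY_RATES
    rows = []
    for c in range(3):
        coder = f"c{c + 1}"
        copy = rng.random((n_items, len(CODEBOOK))) < cfg.coder_agreement
        coin = rng.random((n_items, len(CODEBOOK))) < 0.5
        labels = np.where(copy, truth, coin)
        for i in range(n_items):
            for k, cat in enumerate(CODEBOOK):
                if labels[i, k]:
                    rows.append(
                        {"response_id": f"r{i:04d}", "coder_id": coder, "label": cat}
                    )
    df = pd.DataFrame(rows, columns=["response_id", "coder_id", "label"])
    # record the full universes so empty label sets still count downstream
    df.attrs["response_ids"] = [f"r{i:04d}" for i in range(n_items)]
    df.attrs["coders"] = ["c1", "c2", "c3"]
    return df


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(
    cfg: SyntheticConfig,
    n_images: int = 12,
    with_pupil: bool = True,
    with_coders: bool = True,
    windows: tuple[float, ...] = (3, 6, 9, 12, 15, 18, 21, 24, 27, 30),
    inject_exclusions: bool = True,
):
    """A complete synthetic study bundle.

    Half the images carry a positive message (hypothesis: the high-rated
    group tracks the expert path more closely), half a negative one. Half
    the participants view with a focused strategy, half exploratively; each
    gets an individual Markov chain perturbed around their strategy's
    representative. "Beauty" ratings are planted against the generating
    chain's expert-path log-likelihood at ``cfg.planted_correlation``;
    pupil traces carry the high-group constriction offset. A few trials get
    injected fixation gaps so the exclusion stage has work to do.
    """
    from .io import StudyBundle
    from .metrics import assign_groups_kmeans, vh_ll

    participants = [f"p{i + 1:02d}" for i in range(cfg.n_participants)]
    strategies = {
        pid: ("focused" if i < cfg.n_participants // 2 else "explorative")
        for i, pid in enumerate(participants)
    }
    image_ids = [f"img{i:02d}" for i in range(n_images)]
    directions = {
        iid: ("positive-message" if i < n_images // 2 else "negative-message")
        for i, iid in enumerate(image_ids)
    }
    # a deterministic sprinkle of gap-injected (to-be-excluded) trials
    gap_plan: dict[str, set[str]] = {iid: set() for iid in image_ids}
    if inject_exclusions:
        gap_plan[image_ids[0]] = set(participants[:3])
        if n_images > 2:
            gap_plan[image_ids[2]] = set(participants[3:5])

    annotations = {}
    fixations: list[FixationSequence] = []
    sim_rows = []
    truths = {}
    for i, iid in enumerate(image_ids):
        ann, truth = gen_annotation_set(cfg, image_index=i)
        annotations[iid] = ann
        truths[iid] = truth
        reps = {
            s: gen_strategy_hmms(truth, s, seed=cfg.seed * 997 + i)
            for s in ("focused", "explorative")
        }
        for pid in participants:
            rng = cfg.rng(_TAG_HMM, _stable_hash("indiv", pid, iid))
            indiv = perturb_hmm(reps[strategies[pid]], jitter=0.15, rng=rng)
            fixations.extend(
                sample_scanpaths(
                    indiv, cfg, [pid], iid, inject_gap_for=gap_plan[iid],
                )
            )
            sim_rows.append(
                {"participant_id": pid, "image_id": iid, "similarity": vh_ll(indiv, truth)}
            )
    similarities = pd.DataFrame(sim_rows)
    ratings = gen_ratings_linked(similarities, cfg)

    pupil: list[PupilTrace] = []
    if with_pupil:
        beauty = ratings[ratings["attribute"] == "beauty"]
        for iid in image_ids:
            sub = beauty[beauty["image_id"] == iid].set_index("participant_id")["raw"]
            z = (sub - sub.mean()) / (sub.std(ddof=0) or 1.0)
            groups = assign_groups_kmeans(z, image_id=iid, attribute="beauty", seed=cfg.seed)
            pupil.extend(gen_pupil_traces(groups, cfg))

    coder = gen_coder_labels(cfg.n_participants * n_images, cfg) if with_coders else None
    config = {
        "seed": cfg.seed,
        "participants": participants,
        "image_directions": directions,
        "windows": list(windows),
        "alpha": 0.05,
        "canvas": [cfg.canvas_width, cfg.canvas_height],
        "strategies": strategies,
    }
    bundle = StudyBundle(
        config=config,
        annotations=annotations,
        fixations=fixations,
        ratings=ratings,
        pupil=pupil,
        coder_labels=coder,
    )
    bundle.ground_truth = truths  # kept for simulation-side checks
    return bundle
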