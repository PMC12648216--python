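"""Multi-expert ROI annotation consensus and agreement statistics.

Each expert supplies a labelled mask per image (integer labels 1..k in path
order on the canvas). The module cleans the masks, drops overgeneralised
annotations, selects the representative expert by F1 against a leave-one-out
majority-vote consensus (with a documented tie-break cascade), extracts the
ellipse geometry of the winner's ROIs, and quantifies inter-expert agreement
with a grid-based Fleiss' kappa plus consensus-cell ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .reliability import fleiss_kappa_from_counts
from .types import ROI, ExpertGazePattern

__all__ = [
    "AnnotationSet",
    "preprocess_mask",
    "preprocess_labelled",
    "coverage_filter",
    "mask_scores",
    "select_representative",
    "grid_fleiss_kappa",
    "roi_geometry",
]


@dataclass
class AnnotationSet:
    """Per-image expert annotations: labelled masks sharing one canvas.

    ``masks[expert_id]`` is an integer image with 0 = background and labels
    1..k in expert path order.
    """

    image_id: str
    canvas: tuple[int, int]  # (width, height)
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w, h = self.canvas
        for eid, m in self.masks.items():
            if m.shape != (h, w):
                raise ValueError(
                    f"{self.image_id}/{eid}: mask shape {m.shape} != canvas (h,w)=({h},{w})"
                )

    def binary(self, expert_id: str) -> np.ndarray:
        return self.masks[expert_id] > 0


# ---------------------------------------------------------------------------
# mask preprocessing and filtering
# ---------------------------------------------------------------------------

def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return x * x + y * y <= radius * radius


def preprocess_mask(
    mask: np.ndarray, min_blob_px: int = 25, opening_radius: int = 1
) -> np.ndarray:
    """Clean a binary mask: small-blob removal, hole filling, opening.

    Connected components smaller than ``min_blob_px`` pixels are removed,
    interior holes filled, then a morphological opening with a disc
    structuring element applied. Idempotent on already-clean input for
    sufficiently regular shapes. An empty result raises a warning and is
    returned as-is (empty).
    """
    m = np.asarray(mask).astype(bool)
    lab, n = ndimage.label(m)
    if n:
        sizes = np.bincount(lab.ravel())
        small = sizes < min_blob_px
        small[0] = False
        m = m & ~small[lab]
    m = ndimage.binary_fill_holes(m)
    if opening_radius > 0:
        m = ndimage.binary_opening(m, structure=_disk(opening_radius))
    if not m.any():
        warnings.warn("mask empty after preprocessing", stacklevel=2)
    return m


def preprocess_labelled(
    labelled: np.ndarray, min_blob_px: int = 25, opening_radius: int = 1
) -> np.ndarray:
    """Apply :func:`preprocess_mask` per label, preserving distinct labels.

    Adjacent touching ROIs with distinct labels stay distinct components.
    Labels that vanish entirely are dropped; survivors are relabelled to a
    contiguous 1..k preserving the original order. Each label is processed
    inside its padded bounding box only.
    """
    labelled = np.asarray(labelled)
    out = np.zeros_like(labelled, dtype=np.uint8)
    pad = opening_radius + 1
    slices = ndimage.find_objects(labelled)
    next_label = 1
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        ys = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labelled.shape[0]))
        xs = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labelled.shape[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cleaned = preprocess_mask(labelled[ys, xs] == lab, min_blob_px, opening_radius)
        if cleaned.any():
            out[ys, xs][cleaned] = next_label
            next_label += 1
    return out


def coverage_filter(
    masks: dict[str, np.ndarray], max_coverage: float = 0.5, median_factor: float = 1.5
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Drop overgeneralised annotations.

    A mask is excluded when its coverage fraction exceeds ``max_coverage``
    (default 50% of the image) or ``median_factor`` times the within-image
    median coverage. The log records which rule(s) fired.
    """
    if not masks:
        raise ValueError("coverage_filter needs at least one mask")
    coverages = {eid: float(np.mean(m > 0)) for eid, m in masks.items()}
    med = float(np.median(list(coverages.values())))
    kept: dict[str, np.ndarray] = {}
    log: list[dict] = []
    for eid, m in masks.items():
        cov = coverages[eid]
        rules = []
        if cov > max_coverage:
            rules.append("coverage>0.5")
        if cov > median_factor * med:
            rules.append("coverage>1.5*median")
        if rules:
            log.append({"expert_id": eid, "coverage": cov, "rules": "+".join(rules)})
        else:
            kept[eid] = m
    if not kept:
        raise ValueError("all expert masks excluded by the coverage filter")
    return kept, log


def mask_scores(a: np.ndarray, b: np.ndarray) -> dict:
    """Pixel-wise overlap scores between two binary masks.

    IoU = |a&b|/|a|b|; Dice = F1 = 2|a&b|/(|a|+|b|). Two empty masks score 1
    with a degenerate flag (agreement on emptiness).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    sa, sb = int(np.count_nonzero(a)), int(np.count_nonzero(b))
    if sa == 0 and sb == 0:
        return {"f1": 1.0, "iou": 1.0, "dice": 1.0, "degenerate": True}
    union = sa + sb - inter
    iou = inter / union if union else 0.0
    dice = 2 * inter / (sa + sb)
    return {"f1": dice, "iou": iou, "dice": dice, "degenerate": False}


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def _loo_consensus(binaries: dict[str, np.ndarray], held_out: str) -> np.ndarray:
    """Strict-majority vote of all experts except ``held_out``."""
    others = [m for eid, m in binaries.items() if eid != held_out]
    stack = np.stack(others).astype(np.uint8)
    needed = len(others) // 2 + 1  # strict majority
    return stack.sum(axis=0) >= needed


def select_representative(
    annotations: AnnotationSet,
    preprocess: bool = True,
    min_blob_px: int = 25,
    opening_radius: int = 1,
) -> tuple[ExpertGazePattern, dict]:
    """Pick the representative expert and extract the ROI geometry.

    Pipeline: per-label preprocessing -> coverage filter -> per-expert F1
    against the leave-one-out strict-majority consensus -> argmax F1 with
    ties broken by (i) higher ROI count, (ii) greater IoU with consensus,
    (iii) coverage closest to the group median. The winner's labelled map is
    turned into ordered ellipse geometry via connected-component moments.
    """
    labelled = {
        eid: (preprocess_labelled(m, min_blob_px, opening_radius) if preprocess else m)
        for eid, m in annotations.masks.items()
    }
    kept, excl_log = coverage_filter(labelled)
    if len(kept) < 2:
        raise ValueError(
            f"{annotations.image_id}: need >= 2 surviving masks to form a "
            f"leave-one-out consensus, have {len(kept)}"
        )
    binaries = {eid: m > 0 for eid, m in kept.items()}
    coverages = {eid: float(np.mean(b)) for eid, b in binaries.items()}
    med_cov = float(np.median(list(coverages.values())))

    rows = []
    for eid in sorted(kept):
        cons = _loo_consensus(binaries, eid)
        scores = mask_scores(binaries[eid], cons)
        rows.append(
            {
                "expert_id": eid,
                "f1": scores["f1"],
                "iou": scores["iou"],
                "dice": scores["dice"],
                "roi_count": int(kept[eid].max()),
                "coverage": coverages[eid],
            }
        )

    # tie-break cascade: F1 desc, ROI count desc, IoU desc, |cov - median| asc
    rows.sort(
        key=lambda r: (
            -r["f1"],
            -r["roi_count"],
            -r["iou"],
            abs(r["coverage"] - med_cov),
            r["expert_id"],
        )
    )
    winner = rows[0]
    rois = roi_geometry(kept[winner["expert_id"]])
    egp = ExpertGazePattern(
        image_id=annotations.image_id,
        rois=rois,
        source_expert_id=winner["expert_id"],
    )
    report = {
        "image_id": annotations.image_id,
        "representative": winner["expert_id"],
        "representative_roi_count": winner["roi_count"],
        "representative_area_fraction": winner["coverage"],
        "mean_iou": float(np.mean([r["iou"] for r in rows])),
        "mean_dice": float(np.mean([r["dice"] for r in rows])),
        "per_expert": rows,
        "coverage_exclusions": excl_log,
        "kept_masks": kept,  # cleaned labelled masks, for agreement stats
    }
    return egp, report


# ---------------------------------------------------------------------------
# grid agreement statistics
# ---------------------------------------------------------------------------

def _to_grid(mask: np.ndarray, grid: tuple[int, int], threshold: float) -> np.ndarray:
    """Downsample a binary mask to an occupancy grid.

    Cells partition the real-valued canvas extents equally; each pixel is
    assigned by its centre location. A cell is marked when its occupied
    fraction exceeds ``threshold`` (0 means "any pixel occupied").
    """
    h, w = mask.shape
    rows, cols = grid
    ri = np.minimum(((np.arange(h) + 0.5) * rows / h).astype(int), rows - 1)
    ci = np.minimum(((np.arange(w) + 0.5) * cols / w).astype(int), cols - 1)
    cell = ri[:, None] * cols + ci[None, :]
    occ = np.bincount(cell.ravel(), weights=mask.astype(float).ravel(), minlength=rows * cols)
    tot = np.bincount(cell.ravel(), minlength=rows * cols)
    frac = occ / tot
    return frac > threshold


def grid_fleiss_kappa(
    masks: dict[str, np.ndarray],
    grid: tuple[int, int] = (32, 64),
    occupancy_threshold: float = 0.0,
    sensitivity: bool = False,
) -> dict:
    """Inter-expert agreement on the cell grid.

    Each kept mask is reduced to a binary occupancy grid; Fleiss' kappa is
    computed over cells (items) x experts (raters) x 2 categories, together
    with the fraction of cells marked by >= 3 experts and by all experts.
    With ``sensitivity=True``, repeats at 24x48 and 16x32 grids and at a 20%
    occupancy threshold.
    """
    if len(masks) < 2:
        raise ValueError("need >= 2 masks for agreement statistics")

    def one(grid_, thr):
        grids = np.stack(
            [_to_grid(np.asarray(m) > 0, grid_, thr) for _, m in sorted(masks.items())]
        )
        m, n_cells = grids.shape[0], grids.shape[1]
        marked = grids.sum(axis=0)  # per cell, how many experts marked it
        counts = np.column_stack([marked, m - marked])
        kappa, flag = fleiss_kappa_from_counts(counts)
        if flag == "undefined" and np.all((marked == 0) | (marked == m)):
            # unanimous in a single category: agreement perfect, chance = 1
            kappa, flag = 1.0, "perfect_degenerate"
        return {
            "grid": f"{grid_[0]}x{grid_[1]}",
            "threshold": thr,
            "fleiss_kappa": kappa,
            "kappa_flag": flag,
            "consensus_3plus_ratio": float(np.mean(marked >= min(3, m))),
            "consensus_all_ratio": float(np.mean(marked == m)),
            "n_cells": int(n_cells),
        }

    out = one(grid, occupancy_threshold)
    if sensitivity:
        out["sensitivity"] = [
            one((24, 48), occupancy_threshold),
            one((16, 32), occupancy_threshold),
            one(grid, 0.2),
        ]
    return out


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def roi_geometry(labelled: np.ndarray) -> list[ROI]:
    """Ellipse geometry (centroid, axes, orientation) per label 1..k.

    Axis lengths are those of the ellipse whose second central moments match
    the pixel region (full length = 4 sqrt(eigenvalue)); orientation is the
    major-axis angle from +x toward +y, modulo pi, with 0 reported for
    (near-)circular regions by convention.
    """
    labelled = np.asarray(labelled)
    k = int(labelled.max())
    rois: list[ROI] = []
    for lab in range(1, k + 1):
        ys, xs = np.nonzero(labelled == lab)
        if len(xs) == 0:
            raise ValueError(f"label {lab} is empty")
        cx, cy = float(xs.mean()), float(ys.mean())
        dx, dy = xs - cx, ys - cy
        cov = np.array(
            [
                [np.mean(dx * dx), np.mean(dx * dy)],
                [np.mean(dx * dy), np.mean(dy * dy)],
            ]
        )
        evals, evecs = np.linalg.eigh(cov)
        lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
        major = 4.0 * np.sqrt(lam_major)
        minor = 4.0 * np.sqrt(lam_minor)
        if major - minor < 1e-9 * max(major, 1.0):
            theta = 0.0
        else:
            vx, vy = evecs[:, 1]
            theta = float(np.arctan2(vy, vx)) % np.pi
        rois.append(
            ROI(
                index=lab,
                cx=cx,
                cy=cy,
                major_axis_length=max(major, 1e-9),
                minor_axis_length=max(minor, 1e-9),
                orientation=theta,
            )
        )
    return rois
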