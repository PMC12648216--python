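"""End-to-end pipeline driver: consensus -> HMM fits -> statistics -> tables.

Stage order mirrors the analysis design: expert-mask consensus per image,
trial exclusion and rating normalisation/grouping, per-participant HMM fits
in cumulative 3-s windows, two-cluster strategy models, VH-LL/CVB tables
with consistency labels and group tests, pupil window tests, and the
coder-reliability report. Every stage writes tidy CSV; a provenance record
captures the config hash and seed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_hmms, label_strategies
from .consensus import grid_fleiss_kappa, select_representative
from .hmm import build_emissions, exclude_trials, fit_vb_hmm, window_sequence
from .io import StudyBundle, config_hash
from .metrics import (
    assign_groups_kmeans,
    consistency_and_tests,
    cvb,
    normalize_ratings,
    vh_ll,
)
from .pupil import lmm_window_test, preprocess_trace, summarize_pupil_table
from .reliability import jaccard_stats, reliability_report
from .types import EvaluationGroups

__all__ = ["run_pipeline", "report"]

GROUP_ATTRIBUTES = ("beauty", "favourability")


def _consensus_stage(bundle: StudyBundle, outdir: Path) -> dict:
    egps = {}
    rows = []
    for iid in bundle.image_ids:
        ann = bundle.annotations[iid]
        egp, rep = select_representative(ann)
        agree = grid_fleiss_kappa(rep["kept_masks"], sensitivity=True)
        egps[iid] = egp
        rows.append(
            {
                "image_id": iid,
                "n_experts": len(ann.masks),
                "representative": rep["representative"],
                "rep_roi_count": rep["representative_roi_count"],
                "mean_iou": round(rep["mean_iou"], 4),
                "mean_dice": round(rep["mean_dice"], 4),
                "consensus_3of4": round(agree["consensus_3plus_ratio"], 4),
                "consensus_all": round(agree["consensus_all_ratio"], 4),
                "rep_area_frac": round(rep["representative_area_fraction"], 4),
                "fleiss_kappa": round(agree["fleiss_kappa"], 4),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "agreement.csv", index=False)
    return egps


def _grouping_stage(bundle: StudyBundle, norm: pd.DataFrame, analysed: dict, outdir: Path):
    seed = int(bundle.config.get("seed", 0))
    groups: dict[tuple[str, str], EvaluationGroups] = {}
    rows = []
    for iid in bundle.image_ids:
        for attr in GROUP_ATTRIBUTES:
            sub = norm[
                (norm["image_id"] == iid)
                & (norm["attribute"] == attr)
                & (norm["participant_id"].isin(analysed[iid]))
            ].set_index("participant_id")["normalised"]
            g = assign_groups_kmeans(sub, image_id=iid, attribute=attr, seed=seed)
            groups[(iid, attr)] = g
            counts = g.counts
            rows.append(
                {
                    "image_id": iid, "attribute": attr,
                    "high": counts["high"], "middle": counts["middle"], "low": counts["low"],
                    "analysed": len(sub),
                    "total": len(bundle.config.get("participants", [])) or len(sub),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "groups.csv", index=False)
    return groups


def run_pipeline(bundle: StudyBundle, outdir: str | Path, skip_pupil: bool = False) -> Path:
    """Execute every stage on a study bundle, writing results CSVs.

    Stages that lack input (no pupil traces, no coder labels) are skipped
    with a warning; any hard failure aborts with the stage name while
    earlier outputs remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    windows = [float(w) for w in cfg.get("windows", [3, 6, 9, 12, 15, 18, 21, 24, 27, 30])]
    alpha = float(cfg.get("alpha", 0.05))
    seed = int(cfg.get("seed", 0))

    stage = "consensus"
    try:
        egps = _consensus_stage(bundle, outdir)

        stage = "exclusion"
        kept, excl = exclude_trials(bundle.fixations)
        pd.DataFrame(excl, columns=["participant_id", "image_id", "rule", "max_gap_s"]).to_csv(
            outdir / "exclusions.csv", index=False
        )
        analysed = {
            iid: sorted({s.participant_id for s in kept if s.image_id == iid})
            for iid in bundle.image_ids
        }

        stage = "ratings"
        norm = normalize_ratings(bundle.ratings)
        groups = _grouping_stage(bundle, norm, analysed, outdir)

        stage = "hmm_fits"
        vhll_rows = []
        models: dict[tuple[str, float], dict[str, object]] = {}
        for iid in bundle.image_ids:
            egp = egps[iid]
            emissions = build_emissions(egp)
            trials = [s for s in kept if s.image_id == iid]
            for w in windows:
                fits = {}
                for seq in trials:
                    wseq = window_sequence(seq, w)
                    if len(wseq) == 0:
                        continue
                    hmm = fit_vb_hmm(wseq, emissions, window_s=(0.0, w))
                    fits[seq.participant_id] = hmm
                    vhll_rows.append(
                        {
                            "image_id": iid, "window_s": w,
                            "participant_id": seq.participant_id,
                            "vh_ll": vh_ll(hmm, egp),
                        }
                    )
                models[(iid, w)] = fits
        vhll_df = pd.DataFrame(vhll_rows)
        vhll_df.round(6).to_csv(outdir / "vhll.csv", index=False)

        stage = "clustering"
        cluster_rows = []
        memberships: dict[tuple[str, float, str], set] = {}
        for (iid, w), fits in models.items():
            pids = sorted(fits)
            if len(pids) < 2:
                continue
            clus = label_strategies(
                cluster_hmms([fits[p] for p in pids], K=2, n_restarts=10, seed=seed)
            )
            for c in (0, 1):
                lab = clus.labels[c]
                members = {pids[i] for i in np.flatnonzero(clus.assignments == c)}
                memberships[(iid, w, lab)] = members
                cluster_rows.append(
                    {
                        "image_id": iid, "window_s": w, "cluster": lab,
                        "n_members": len(members),
                        "mean_self_transition": float(
                            np.trace(clus.representatives[c].A)
                            / clus.representatives[c].n_states
                        ),
                    }
                )
        pd.DataFrame(cluster_rows).round(6).to_csv(outdir / "clusters.csv", index=False)

        stage = "raic_metrics"
        raic_rows = []
        vhll_idx = vhll_df.set_index(["image_id", "window_s", "participant_id"])["vh_ll"]
        for iid in bundle.image_ids:
            direction = bundle.image_direction(iid)
            for attr in GROUP_ATTRIBUTES:
                g = groups[(iid, attr)]
                nsub = norm[
                    (norm["image_id"] == iid) & (norm["attribute"] == attr)
                ].set_index("participant_id")["normalised"]
                for w in windows:
                    for lab in ("focused", "explorative"):
                        members = memberships.get((iid, w, lab), set())
                        res = {}
                        vh = {}
                        for grp in ("high", "low"):
                            pids = [
                                p for p in g.members(grp)
                                if p in members and (iid, w, p) in vhll_idx.index
                            ]
                            v = np.array([vhll_idx.loc[(iid, w, p)] for p in pids])
                            r = np.array([nsub.loc[p] for p in pids])
                            res[grp] = cvb(v, r)
                            vh[grp] = v
                        test = consistency_and_tests(
                            res["high"]["r"], res["low"]["r"], direction,
                            vh["high"], vh["low"], alpha=alpha,
                        )
                        raic_rows.append(
                            {
                                "image_id": iid, "attribute": attr, "window_s": w,
                                "cluster": lab, "direction": direction,
                                "cvb_high": res["high"]["r"], "n_high": res["high"]["n"],
                                "cvb_low": res["low"]["r"], "n_low": res["low"]["n"],
                                "label": test["label"], "test": test["test"],
                                "p": test["p"], "significant": test["significant"],
                            }
                        )
        pd.DataFrame(raic_rows).round(6).to_csv(outdir / "raic_series.csv", index=False)

        stage = "pupil"
        if bundle.pupil and not skip_pupil:
            processed: dict[tuple[str, str], dict[str, np.ndarray]] = {}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for tr in bundle.pupil:
                    preprocess_trace(tr)
                    if tr.usable:
                        processed.setdefault((tr.image_id, tr.eye), {})[
                            tr.participant_id
                        ] = tr.processed
            pupil_rows = []
            for iid in bundle.image_ids:
                g = groups[(iid, "beauty")]
                for eye in ("left", "right"):
                    traces = processed.get((iid, eye), {})
                    for w in windows:
                        res = lmm_window_test(traces, g, w, alpha=alpha)
                        pupil_rows.append(
                            {"image_id": iid, "eye": eye, "window_s": w, **res}
                        )
            pupil_df = pd.DataFrame(pupil_rows)
            pupil_df.round(6).to_csv(outdir / "pupil_results.csv", index=False)
            summarize_pupil_table(pupil_df, alpha=alpha).round(4).to_csv(
                outdir / "pupil_summary.csv"
            )
        else:
            warnings.warn("pupil stage skipped (no traces)", stacklevel=2)

        stage = "reliability"
        if bundle.coder_labels is not None and len(bundle.coder_labels):
            rel = reliability_report(bundle.coder_labels, seed=seed)
            rel.round(6).to_csv(outdir / "reliability.csv", index=False)
            jac = jaccard_stats(bundle.coder_labels)
            pd.DataFrame([jac]).round(6).to_csv(outdir / "jaccard.csv", index=False)

        stage = "provenance"
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(
                {
                    "config_hash": config_hash(cfg),
                    "seed": seed,
                    "version": __version__,
                    "windows": windows,
                    "alpha": alpha,
                },
                fh, indent=2, sort_keys=True,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def report(results_dir: str | Path) -> Path:
    """Render a plain-text summary of the results directory."""
    results_dir = Path(results_dir)
    lines = ["# Study report", ""]
    for name, title in [
        ("agreement.csv", "Inter-expert agreement"),
        ("groups.csv", "Rating groups"),
        ("exclusions.csv", "Excluded trials"),
        ("raic_series.csv", "VH-LL/CVB series"),
        ("pupil_summary.csv", "Pupil effect sizes (significant cells)"),
        ("reliability.csv", "Coder reliability"),
        ("jaccard.csv", "Multi-label Jaccard"),
    ]:
        fpath = results_dir / name
        lines.append(f"## {title}")
        if fpath.exists():
            df = pd.read_csv(fpath)
            if name == "raic_series.csv" and len(df):
                sig = df[df["significant"] == True]  # noqa: E712
                lines.append(f"rows: {len(df)}; significant cells: {len(sig)}")
                for _, r in sig.iterrows():
                    lines.append(
                        f"  {r['image_id']} {r['attribute']} {r['window_s']}s "
                        f"{r['cluster']}: label={r['label']} p={r['p']:.4f}"
                    )
            else:
                lines.append(df.to_string(index=False, max_rows=40))
        else:
            lines.append("(absent)")
        lines.append("")
    out = results_dir / "summary.txt"
    out.write_text("\n".join(lines))
    return out
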