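"""Readers, writers and the study bundle.

All tabular interchange is plain CSV with documented headers; annotation
masks travel as 8-bit grayscale images (0 = background, labels 1..k in path
order). A study directory holds a ``manifest.yaml`` naming the images,
participants and component files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consensus import AnnotationSet
from .types import FixationSequence, PupilTrace

__all__ = [
    "StudyBundle",
    "load_study",
    "write_study",
    "fixations_to_frame",
    "frame_to_fixations",
    "pupil_to_frame",
    "frame_to_pupil",
]

FIXATION_COLUMNS = ["participant_id", "image_id", "condition", "x", "y", "onset_ms", "duration_ms"]
RATING_COLUMNS = ["participant_id", "image_id", "attribute", "raw", "seen_before"]
PUPIL_COLUMNS = ["participant_id", "image_id", "eye", "phase", "t_ms", "value"]
CODER_COLUMNS = ["response_id", "coder_id", "label"]


@dataclass
class StudyBundle:
    """Everything one study run consumes, cross-referenced."""

    config: dict
    annotations: dict[str, AnnotationSet]  # image_id -> masks
    fixations: list[FixationSequence]
    ratings: pd.DataFrame
    pupil: list[PupilTrace] = field(default_factory=list)
    coder_labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        images = set(self.annotations)
        participants = set(self.config.get("participants", []))
        for seq in self.fixations:
            if seq.image_id not in images:
                raise ValueError(f"fixation trial references unknown image {seq.image_id!r}")
            if participants and seq.participant_id not in participants:
                raise ValueError(
                    f"fixation trial references unknown participant {seq.participant_id!r}"
                )
            if np.any(seq.onset_ms >= seq.trial_length_ms):
                raise ValueError(
                    f"{seq.participant_id}/{seq.image_id}: fixation onset beyond trial length"
                )
        missing = set(self.ratings["image_id"]) - images
        if missing:
            raise ValueError(f"ratings reference unknown images {sorted(missing)}")

    @property
    def image_ids(self) -> list[str]:
        return sorted(self.annotations)

    def image_direction(self, image_id: str) -> str:
        return self.config["image_directions"][image_id]


# ---------------------------------------------------------------------------
# frame conversions
# ---------------------------------------------------------------------------

def fixations_to_frame(seqs: list[FixationSequence]) -> pd.DataFrame:
    rows = []
    for s in seqs:
        for i in range(len(s)):
            rows.append(
                (s.participant_id, s.image_id, s.condition,
                 s.x[i], s.y[i], s.onset_ms[i], s.duration_ms[i])
            )
    return pd.DataFrame(rows, columns=FIXATION_COLUMNS)


def frame_to_fixations(df: pd.DataFrame, trial_length_ms: float = 30_000.0) -> list[FixationSequence]:
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation table missing columns {sorted(missing)}")
    out = []
    for (pid, iid, cond), sub in df.groupby(
        ["participant_id", "image_id", "condition"], sort=True
    ):
        sub = sub.sort_values("onset_ms")
        out.append(
            FixationSequence(
                participant_id=str(pid),
                image_id=str(iid),
                condition=str(cond),
                x=sub["x"].to_numpy(float),
                y=sub["y"].to_numpy(float),
                onset_ms=sub["onset_ms"].to_numpy(float),
                duration_ms=sub["duration_ms"].to_numpy(float),
                trial_length_ms=trial_length_ms,
            )
        )
    return out


def pupil_to_frame(traces: list[PupilTrace]) -> pd.DataFrame:
    frames = []
    for t in traces:
        for phase, series in (("rest", t.rest_trace), ("trial", t.samples)):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": t.participant_id,
                        "image_id": t.image_id,
                        "eye": t.eye,
                        "phase": phase,
                        "t_ms": np.arange(len(series)) * 1000.0 / t.fs,
                        "value": series,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def frame_to_pupil(df: pd.DataFrame, fs: float = 300.0) -> list[PupilTrace]:
    missing = set(PUPIL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pupil table missing columns {sorted(missing)}")
    out = []
    for (pid, iid, eye), sub in df.groupby(["participant_id", "image_id", "eye"], sort=True):
        rest = sub[sub["phase"] == "rest"].sort_values("t_ms")["value"].to_numpy(float)
        trial = sub[sub["phase"] == "trial"].sort_values("t_ms")["value"].to_numpy(float)
        out.append(
            PupilTrace(
                participant_id=str(pid), image_id=str(iid), eye=str(eye),
                samples=trial, rest_trace=rest, fs=fs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# study directory round-trip
# ---------------------------------------------------------------------------

def write_study(bundle: StudyBundle, path: str | Path) -> Path:
    """Write a study directory: manifest, CSV tables, mask images."""
    from imageio.v3 import imwrite

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "masks").mkdir(exist_ok=True)
    mask_files = {}
    for iid, ann in bundle.annotations.items():
        mask_files[iid] = {}
        for eid, mask in ann.masks.items():
            fname = f"masks/{iid}_{eid}.png"
            imwrite(path / fname, mask.astype(np.uint8))
            mask_files[iid][eid] = fname
    fixations_to_frame(bundle.fixations).to_csv(path / "fixations.csv", index=False)
    bundle.ratings[RATING_COLUMNS].to_csv(path / "ratings.csv", index=False)
    manifest = {
        "config": bundle.config,
        "images": {
            iid: {"canvas": list(bundle.annotations[iid].canvas), "masks": mask_files[iid]}
            for iid in bundle.image_ids
        },
        "fixations": "fixations.csv",
        "ratings": "ratings.csv",
    }
    if bundle.pupil:
        pupil_to_frame(bundle.pupil).to_csv(path / "pupil.csv", index=False, float_format="%.5f")
        manifest["pupil"] = "pupil.csv"
    if bundle.coder_labels is not None:
        bundle.coder_labels[CODER_COLUMNS].to_csv(path / "coder_labels.csv", index=False)
        manifest["coder_labels"] = "coder_labels.csv"
        manifest["coder_universe"] = {
            "response_ids": list(bundle.coder_labels.attrs.get("response_ids", [])),
            "coders": list(bundle.coder_labels.attrs.get("coders", [])),
        }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_study(path: str | Path) -> StudyBundle:
    """Read a study directory written by :func:`write_study`."""
    from imageio.v3 import imread

    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml in {path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    annotations = {}
    for iid, entry in manifest["images"].items():
        masks = {}
        for eid, fname in entry["masks"].items():
            fpath = path / fname
            if not fpath.exists():
                raise FileNotFoundError(f"manifest references missing mask file {fname}")
            masks[eid] = np.asarray(imread(fpath))
        annotations[iid] = AnnotationSet(
            image_id=iid, canvas=tuple(entry["canvas"]), masks=masks
        )
    fixations = frame_to_fixations(pd.read_csv(path / manifest["fixations"]))
    ratings = pd.read_csv(path / manifest["ratings"])
    pupil = []
    if "pupil" in manifest:
        fpath = path / manifest["pupil"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing pupil file {manifest['pupil']}")
        pupil = frame_to_pupil(pd.read_csv(fpath))
    coder = None
    if "coder_labels" in manifest:
        coder = pd.read_csv(path / manifest["coder_labels"])
        uni = manifest.get("coder_universe", {})
        if uni.get("response_ids"):
            coder.attrs["response_ids"] = uni["response_ids"]
            coder.attrs["coders"] = uni["coders"]
    return StudyBundle(
        config=manifest["config"],
        annotations=annotations,
        fixations=fixations,
        ratings=ratings,
        pupil=pupil,
        coder_labels=coder,
    )


def config_hash(config: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
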