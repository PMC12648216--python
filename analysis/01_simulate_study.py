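"""Generate the synthetic study and write it to disk.

Builds the full study — 48 participants viewing 12 images (six carrying a
positive message, six a negative one), four expert annotators per image,
ratings with the planted gaze-similarity link, pupil traces and coder
labels — and writes the portable parts (masks, fixations, ratings, coder
labels) to study/. Pupil traces are regenerated deterministically from the
same seed by later steps instead of being written (they are ~10M samples).

Run from the repository root:  python analysis/01_simulate_study.py
"""

from pathlib import Path

from raic.io import write_study
from raic.synthetic import SyntheticConfig, simulate_study

SEED = 0
ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    bundle = simulate_study(cfg, n_images=12)
    pupil = bundle.pupil
    bundle.pupil = []  # keep the on-disk study light; traces are reproducible
    out = write_study(bundle, ROOT / "results" / "study")
    bundle.pupil = pupil
    print(f"study written to {out}")
    print(f"  images:       {len(bundle.image_ids)}")
    print(f"  participants: {len(bundle.config['participants'])}")
    print(f"  trials:       {len(bundle.fixations)}")
    print(f"  rating rows:  {len(bundle.ratings)}")
    print(f"  pupil traces: {len(pupil)} (regenerated on demand from seed {SEED})")


if __name__ == "__main__":
    main()
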