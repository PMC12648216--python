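"""Trial exclusion, rating normalisation and k-means evaluation groups.

Applies the 2-s fixation-gap exclusion rule, z-normalises each
participant's ratings across images, and splits participants per image into
high/middle/low groups by 1-D k-means on the normalised "beauty" and
"favourability" scores. Writes results/exclusions.csv and
results/groups.csv.

Run after 01:  python analysis/03_exclusion_and_rating_groups.py
"""

from pathlib import Path

import pandas as pd

from raic.hmm import exclude_trials
from raic.metrics import assign_groups_kmeans, normalize_ratings
from raic.synthetic import SyntheticConfig, simulate_study

SEED = 0
ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    bundle = simulate_study(SyntheticConfig(seed=SEED), n_images=12,
                            with_pupil=False, with_coders=False)
    kept, excl = exclude_trials(bundle.fixations)
    out = ROOT / "results"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(excl, columns=["participant_id", "image_id", "rule", "max_gap_s"]).to_csv(
        out / "exclusions.csv", index=False
    )
    print(f"excluded {len(excl)} of {len(bundle.fixations)} trials:")
    for e in excl:
        print(f"  {e['participant_id']} on {e['image_id']} ({e['rule']})")

    norm = normalize_ratings(bundle.ratings)
    rows = []
    for iid in bundle.image_ids:
        analysed = sorted({s.participant_id for s in kept if s.image_id == iid})
        for attr in ("beauty", "favourability"):
            sub = norm[
                (norm["image_id"] == iid) & (norm["attribute"] == attr)
                & (norm["participant_id"].isin(analysed))
            ].set_index("participant_id")["normalised"]
            g = assign_groups_kmeans(sub, image_id=iid, attribute=attr, seed=SEED)
            rows.append({"image_id": iid, "attribute": attr, **g.counts,
                         "analysed": len(sub), "total": 48})
    groups = pd.DataFrame(rows)
    groups.to_csv(out / "groups.csv", index=False)
    print("\ngroup sizes per image (beauty):")
    print(groups[groups["attribute"] == "beauty"].to_string(index=False))


if __name__ == "__main__":
    main()
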