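"""Inter-coder reliability for the verbal-response labels.

Generates the 3-coder multi-label sets (576 responses, one per participant
x image) and reports per-category Fleiss' kappa with bootstrap 95% CIs and
full-agreement rates, plus the multi-label Jaccard summary. Writes
results/reliability.csv and results/jaccard.csv.

Run standalone:  python analysis/07_coder_reliability.py
"""

from pathlib import Path

import pandas as pd

from raic.reliability import jaccard_stats, reliability_report
from raic.synthetic import SyntheticConfig, gen_coder_labels

SEED = 0
ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    labels = gen_coder_labels(48 * 12, cfg)
    rep = reliability_report(labels, seed=SEED)
    jac = jaccard_stats(labels)
    out = ROOT / "results"
    out.mkdir(parents=True, exist_ok=True)
    rep.round(4).to_csv(out / "reliability.csv", index=False)
    pd.DataFrame([jac]).round(4).to_csv(out / "jaccard.csv", index=False)
    print(rep.round(3).to_string(index=False))
    print("\nmulti-label Jaccard:")
    for k, v in jac.items():
        print(f"  {k}: {v:.3f}")
    print(f"\nwrote {out / 'reliability.csv'} and jaccard.csv")


if __name__ == "__main__":
    main()
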