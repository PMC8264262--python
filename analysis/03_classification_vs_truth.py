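#!/usr/bin/env python
"""Cross-tabulate pipeline classifications against the phantom's generative
truth (run 02_run_pipeline.py first). Writes
results/classification_vs_truth.tsv."""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    metrics = pd.read_csv(ROOT / "pipeline" / "subject_metrics.tsv", sep="\t")
    cls = pd.read_csv(ROOT / "pipeline" / "classifications.tsv", sep="\t")
    df = metrics.merge(cls[["subject_id", "wd_positive", "itd_positive", "ccd_positive"]],
                       on="subject_id")
    chronic = df[df.group == "chronic"]

    rows = []
    for name, truth, call in (
        ("wallerian_degeneration", "wd_true", "wd_positive"),
        ("ipsilateral_thalamic_diaschisis", "itd_true", "itd_positive"),
        ("crossed_cerebellar_diaschisis", "ccd_true", "ccd_positive"),
    ):
        agree = int((chronic[truth] == chronic[call]).sum())
        rows.append(
            {
                "entity": name,
                "true_positives": int(chronic[truth].sum()),
                "called_positives": int(chronic[call].sum()),
                "agreement": f"{agree}/{len(chronic)}",
            }
        )
        print(f"{name}: truth {rows[-1]['true_positives']}, called "
              f"{rows[-1]['called_positives']}, agreement {rows[-1]['agreement']}")
    pd.DataFrame(rows).to_csv(ROOT / "classification_vs_truth.tsv", sep="\t", index=False)

    non_chronic = df[df.group != "chronic"]
    print(f"non-chronic WD-positive calls: {int(non_chronic.wd_positive.sum())} "
          f"(expected 0: no acute or healthy subject carries peduncular atrophy)")


if __name__ == "__main__":
    main()
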