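#!/usr/bin/env python
"""Longitudinal response classification of the 14-patient cohort.

Runs target selection (top-5 by SUVmax) and the PERCIST-adapted classifier
over every follow-up scan, taking the last scan's category as each
patient's final outcome, and writes the per-scan assessments and the final
category distribution.
"""

from pathlib import Path

import pandas as pd

from spectquant.workflows import cohort14_outcomes

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1
HEALTHY_LIVER_SUV = 3.34  # CR clearance reference


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out = cohort14_outcomes(seed=SEED, background_suv=HEALTHY_LIVER_SUV)

    assessments = pd.DataFrame([
        {"patient_id": a.patient_id, "baseline_scan": a.baseline_scan,
         "followup_scan": a.followup_scan, "delta_pct": round(a.delta_pct, 2),
         "category": a.category, "note": a.note}
        for a in out["assessments"]
    ])
    assessments.to_csv(RESULTS / "response_assessments.csv", index=False)

    finals = pd.DataFrame(sorted(out["final_categories"].items()),
                          columns=["patient_id", "final_category"])
    finals.to_csv(RESULTS / "final_categories.csv", index=False)
    dist = pd.DataFrame([out["distribution"]])
    dist.to_csv(RESULTS / "category_distribution.csv", index=False)

    print(f"{len(finals)} patients, {len(assessments)} follow-up assessments "
          f"(background SUV {HEALTHY_LIVER_SUV})")
    counts = finals["final_category"].value_counts().to_dict()
    print(f"  final categories: {counts}")
    print(f"  distribution (%): {out['distribution']}")
    multi = assessments[assessments["patient_id"].isin(
        [p for p, n in assessments["patient_id"].value_counts().items() if n > 1])]
    for pid, grp in multi.groupby("patient_id"):
        print(f"  {pid}: {' -> '.join(grp['category'])} "
              f"(final {out['final_categories'][pid]})")


if __name__ == "__main__":
    main()
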