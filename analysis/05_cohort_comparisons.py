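#!/usr/bin/env python
"""Cohort-versus-included comparisons from published summary statistics.

The study cohort's eligibility funnel (554 eligible; 17 discontinued,
251 excluded for motion, 64 for missing clinical data) and the printed
(mean, SD, n) / 2x2 count rows are inputs here: this script recomputes the
participant-flow arithmetic, the Welch t statistics for the continuous
rows, the pooled-variance sensitivity value for the Barthel index, and the
2x2 chi-square for the categorical rows, writing results/table1_checks.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from delnet.pipeline import participant_flow
from delnet.stats import chi2_2x2, summary_ttest

ROOT = Path(__file__).resolve().parents[1]

# published summary rows: (label, mean_cohort, sd, n_cohort, mean_incl, sd, n)
CONTINUOUS = [
    ("age", 72.1, 5.0, 554, 71.2, 4.9, 222),
    ("iq", 105.0, 12.7, 554, 105.0, 12.2, 222),
    ("mmse", 28.6, 1.4, 554, 28.7, 1.4, 222),
    ("barthel", 98.2, 5.0, 554, 98.4, 4.8, 222),
]

# published 2x2 count rows: (label, [[yes_cohort, no_cohort], [yes_incl, no_incl]])
CATEGORICAL = [
    ("alcohol_misuse", [[25, 485], [11, 211]]),
    ("depression", [[24, 447], [10, 212]]),
    ("tia_stroke", [[183, 371], [54, 168]]),
]


def main(argv=None):
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    analyzed = participant_flow(554, {"discontinued_fmri": 17,
                                      "motion_quality": 251,
                                      "missing_clinical": 64})
    print(f"participant flow: 554 eligible - (17 + 251 + 64) = {analyzed} analyzed")

    rows = []
    for label, ma, sa, na, mb, sb, nb in CONTINUOUS:
        t, p = summary_ttest(ma, sa, na, mb, sb, nb)
        rows.append({"variable": label, "test": "welch_t", "stat": round(t, 3),
                     "p": round(p, 4)})
    tb, pb = summary_ttest(98.2, 5.0, 554, 98.4, 4.8, 222, method="pooled")
    rows.append({"variable": "barthel", "test": "pooled_t (sensitivity)",
                 "stat": round(tb, 3), "p": round(pb, 4)})
    for label, table in CATEGORICAL:
        chi2, p = chi2_2x2(table)
        rows.append({"variable": label, "test": "chi2_2x2",
                     "stat": round(chi2, 3), "p": round(p, 4)})
    rows.append({"variable": "participant_flow", "test": "arithmetic",
                 "stat": analyzed, "p": None})
    out = pd.DataFrame(rows)
    out.to_csv(results / "table1_checks.csv", index=False)
    print(out.to_string(index=False))
    print("note: Welch t reproduces the published age (2.30), MMSE (-0.90) "
          "and IQ (0.00) values; the Barthel row matches only under pooled "
          "variance (-0.51)")


if __name__ == "__main__":
    sys.exit(main())
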