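#!/usr/bin/env python
"""Desk-check the built-in NSCLC cohort arithmetic.

Recomputes the responder-proportion table and the histology
stratification from the printed per-antigen tallies and clinical table
of the built-in 26-patient immunomonitoring cohort, writing both under
results/reference_cohort/.
"""

import json
from pathlib import Path

from immunocall import fmt_percent, render_responder_table, summarize_pool_tallies
from immunocall.reference_cohort import (
    ANTIGEN_RESPONSE_TALLIES,
    AT_LEAST_ONE_TALLY,
    DISCOVERY_COHORT_SIZE,
    discovery_cohort,
)
from immunocall.response import histology_fractions

OUT = Path("results/reference_cohort")


def main() -> None:
    summary = summarize_pool_tallies(
        ANTIGEN_RESPONSE_TALLIES, DISCOVERY_COHORT_SIZE, AT_LEAST_ONE_TALLY
    )
    table = render_responder_table(summary)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "responder_table.csv", lineterminator="\n")
    print(table.to_string())
    print(f"\nmean antigen responses per patient: "
          f"{summary.mean_pools_per_patient:.1f} "
          f"(= {sum(n for n, _ in ANTIGEN_RESPONSE_TALLIES.values())}"
          f"/{DISCOVERY_COHORT_SIZE})")

    fractions = histology_fractions(discovery_cohort())
    payload = {s: {"count": c, "of": n, "percent": fmt_percent(100 * c / n)}
               for s, (c, n) in fractions.items()}
    (OUT / "histology_fractions.json").write_text(json.dumps(payload, indent=1) + "\n")
    for s, rec in payload.items():
        print(f"{s}: {rec['count']}/{rec['of']} ({rec['percent']})")
    print(f"wrote {OUT}/responder_table.csv and histology_fractions.json")


if __name__ == "__main__":
    main()
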