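#!/usr/bin/env python
"""Generate the study's synthetic inputs with planted truth.

Emulates a microarray lung cohort (14 normal lungs, 86 AC and 60 SCC
tumors, 48-tissue reference panel) over the 14-antigen panel, and a
26-patient multimer immunomonitoring experiment with paired ±anti-PD-1
tubes. Writes TSV/CSV bundles plus truth JSONs under results/inputs/.
"""

from pathlib import Path

import pandas as pd

from immunocall import (
    ExpressionSimConfig,
    FlowSimConfig,
    default_antigen_pools,
    default_gene_panel,
    gen_expression_cohort,
    gen_flow_cohort,
    write_fixture_bundle,
)
from immunocall.io import write_cohort_table

SEED = 42
OUT = Path("results/inputs")


def main() -> None:
    expr_cfg = ExpressionSimConfig(genes=default_gene_panel(), seed=SEED)
    cohort, expr_truth = gen_expression_cohort(expr_cfg)
    write_fixture_bundle(cohort, expr_truth, OUT)
    n_act = int(expr_truth.activated.to_numpy().sum())
    print(f"expression cohort: {cohort.values.shape[0]} genes x "
          f"{cohort.values.shape[1]} samples, {n_act} activated tumor/gene cells")

    flow_cfg = FlowSimConfig(antigen_pools=default_antigen_pools(),
                             include_ici=True, seed=SEED + 1)
    observations, flow_truth = gen_flow_cohort(flow_cfg)
    write_fixture_bundle(observations, flow_truth, OUT)
    patients = sorted({o.patient_id for o in observations})
    n_resp = sum(flow_truth.responder.values())
    print(f"flow cohort: {len(patients)} patients x "
          f"{len(flow_cfg.antigen_pools)} pools, {n_resp} planted responder cells")

    # alternate AC/SCC so the stratified summaries have both strata
    histology = ["AC" if i % 2 == 0 else "SCC" for i in range(len(patients))]
    table = pd.DataFrame({"histology": histology, "stage": "nd", "smoking": "Unknown"},
                         index=pd.Index(patients, name="patient_id"))
    write_cohort_table(table, OUT / "cohort.tsv")
    print(f"wrote fixture bundles to {OUT}/")


if __name__ == "__main__":
    main()
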