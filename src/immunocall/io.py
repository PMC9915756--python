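"""Readers and writers for the pipeline's plain-text dialects.

Expression bundles are three TSVs: ``expression.tsv`` (first column
``gene_id``, one column per sample), ``samples.tsv`` (``sample_id, group,
subtype, platform``) and ``genes.tsv`` (``gene_id, gene_class``). Flow
experiments are one CSV (``patient_id, antigen_pool, condition, ici,
cd8_events, multimer_events``) with pools semicolon-joined, and patient
cohorts one TSV (``patient_id, histology, stage, smoking``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import ExpressionCohort, FlowObservation

FLOW_COLUMNS = ["patient_id", "antigen_pool", "condition", "ici", "cd8_events", "multimer_events"]


def write_expression_bundle(cohort: ExpressionCohort, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr = directory / "expression.tsv"
    samples = directory / "samples.tsv"
    genes = directory / "genes.tsv"
    cohort.values.rename_axis("gene_id").to_csv(expr, sep="\t", lineterminator="\n")
    cohort.samples.rename_axis("sample_id").to_csv(samples, sep="\t", lineterminator="\n")
    cohort.genes.rename_axis("gene_id").to_csv(genes, sep="\t", lineterminator="\n")
    return [expr, samples, genes]


def read_expression_bundle(
    expr_path: str | Path, samples_path: str | Path, genes_path: str | Path
) -> ExpressionCohort:
    values = pd.read_csv(expr_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(
        samples_path, sep="\t", index_col="sample_id", keep_default_na=False, na_values=[]
    )
    genes = pd.read_csv(genes_path, sep="\t", index_col="gene_id")
    return ExpressionCohort(values=values, samples=samples, genes=genes)


def write_flow_csv(observations: Iterable[FlowObservation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "patient_id": o.patient_id,
            "antigen_pool": o.pool,
            "condition": "post",
            "ici": int(o.ici),
            "cd8_events": o.cd8_events,
            "multimer_events": o.multimer_events,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=FLOW_COLUMNS).to_csv(path, index=False, lineterminator="\n")
    return path


def read_flow_csv(path: str | Path) -> list[FlowObservation]:
    frame = pd.read_csv(path)
    missing = set(FLOW_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"flow CSV missing columns: {sorted(missing)}")
    out = []
    for rec in frame.itertuples(index=False):
        out.append(
            FlowObservation(
                patient_id=str(rec.patient_id),
                antigen_pool=frozenset(str(rec.antigen_pool).split(";")),
                ici=bool(int(rec.ici)),
                cd8_events=int(rec.cd8_events),
                multimer_events=int(rec.multimer_events),
            )
        )
    return out


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Patient metadata table: ``patient_id, histology, stage, smoking``."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    if "patient_id" not in frame.columns or "histology" not in frame.columns:
        raise ValueError("cohort table needs patient_id and histology columns")
    if frame["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in cohort table")
    return frame.set_index("patient_id")


def write_cohort_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.rename_axis("patient_id").to_csv(path, sep="\t", lineterminator="\n")
    return path
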